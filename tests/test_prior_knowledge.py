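import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentition.candidate_model import Combination
from dentition.prior_knowledge import (
    ObjectiveWeights,
    PriorConfig,
    PriorContext,
    delta,
    delta_of_gap,
    derive_params,
    fp_tooth,
    neighbor_set,
    objective,
    signed_gap,
)
from tests.conftest import make_candidate

W = 640.0


def combo_with(entries: dict) -> Combination:
    choice = [None] * 32
    for t, cx in entries.items():
        choice[t - 1] = make_candidate(t, cx, mu=1.0)
    return Combination(choice)


def full_arch_combo(spacing: float) -> Combination:
    """All 32 teeth, each jaw laid out with uniform spacing along its
    numbering direction."""
    entries = {}
    for t in range(1, 17):
        entries[t] = 100.0 + spacing * (t - 1)  # maxilla: number grows rightward
    for t in range(17, 33):
        entries[t] = 100.0 + spacing * (32 - t)  # mandible: number grows leftward
    return combo_with(entries)


class TestDeriveParams:
    def test_adjacent_maxillary_thresholds_at_width_640(self):
        p = derive_params(W, 4, 5)
        assert (p.b, p.e) == (8.8, 44.0)
        assert p.range == pytest.approx(35.2)
        assert p.a == pytest.approx(4.4)
        assert p.c == pytest.approx(17.6)
        assert p.d == pytest.approx(44.0)  # printed rule forces d = e
        assert p.f == pytest.approx(52.8)

    def test_quartile_variant_ends_plateau_at_third_quartile(self):
        p = derive_params(W, 4, 5, variant="quartile")
        assert p.d == pytest.approx(8.8 + 3 * 35.2 / 4)  # b + 3*Range/4 = 35.2
        assert p.d < p.e

    def test_mandibular_molar_pair_scales_e(self):
        p = derive_params(W, 18, 19)
        assert p.e == pytest.approx(66.0)  # 44 * 1.5
        rng = 66.0 - 8.8
        assert p.range == pytest.approx(rng)
        assert p.c == pytest.approx(8.8 + rng / 4)
        assert p.f == pytest.approx(66.0 + rng / 4)

    def test_mandible_center_pair_halves_b_and_recomputes(self):
        p = derive_params(W, 24, 25)
        assert p.b == pytest.approx(4.4)
        assert p.a == pytest.approx(2.2)
        rng = 44.0 - 4.4
        assert p.range == pytest.approx(rng)
        assert p.c == pytest.approx(4.4 + rng / 4)
        assert p.f == pytest.approx(44.0 + rng / 4)

    def test_next_nearest_pair_widens_close_cutoff_and_shifts(self):
        near = derive_params(W, 4, 5)
        p = derive_params(W, 4, 6)
        assert p.a == pytest.approx(near.c)  # cutoff becomes the unshifted c
        assert p.b == pytest.approx(near.b + near.c)
        assert p.c == pytest.approx(near.c + near.c)
        assert p.d == pytest.approx(near.d + near.c)
        assert p.e == pytest.approx(near.e + near.c)
        assert p.f == pytest.approx(near.f + near.c)

    @pytest.mark.parametrize("x,y", [(4, 8), (5, 5), (16, 17), (1, 20)])
    def test_invalid_pairs_rejected(self, x, y):
        with pytest.raises(ValueError):
            derive_params(W, x, y)

    def test_thresholds_are_ordered(self):
        for x, y in [(4, 5), (4, 6), (18, 19), (24, 25), (17, 19), (23, 25)]:
            p = derive_params(W, x, y)
            assert 0 < p.a <= p.b <= p.c <= p.d <= p.e <= p.f


class TestDelta:
    P = derive_params(W, 4, 5)

    @pytest.mark.parametrize(
        "g,expected",
        [
            (2.0, -4.0),            # closer than a = 4.4
            (4.4, 0.0),             # [a, b)
            (8.0, 0.0),
            (13.2, 0.5),            # midpoint of the [8.8, 17.6) ramp
            (17.6, 1.0),            # plateau start
            (30.0, 1.0),
            (43.999, 1.0),          # plateau runs to d = e = 44
            (44.0, 0.0),            # [e, f)
            (52.8, -4.0),           # beyond f
            (-10.0, -4.0),          # reversed pair
        ],
    )
    def test_piecewise_branches(self, g, expected):
        assert delta_of_gap(g, self.P) == pytest.approx(expected)

    def test_quartile_variant_has_a_descending_ramp(self):
        p = derive_params(W, 4, 5, variant="quartile")
        mid = (p.d + p.e) / 2
        assert delta_of_gap(mid, p) == pytest.approx(0.5)

    def test_missing_slot_scores_kappa(self):
        P = combo_with({4: 100.0})
        assert delta(4, 5, P, self.P) == self.P.kappa
        cfg = PriorConfig(kappa=0.25)
        p = derive_params(W, 4, 5, config=cfg)
        assert delta(4, 5, P, p) == 0.25

    def test_reversed_maxillary_pair_penalized(self):
        # T5 should sit right of T4; here it's 30 px to the left
        P = combo_with({4: 300.0, 5: 270.0})
        assert delta(4, 5, P, self.P) == -4.0

    def test_reversed_mandibular_pair_penalized(self):
        # mandibular numbers grow leftward: T21 right of T20 is reversed
        P = combo_with({20: 300.0, 21: 330.0})
        assert delta(20, 21, P, derive_params(W, 20, 21)) == -4.0

    def test_symmetric_in_argument_order(self):
        P = combo_with({4: 300.0, 5: 330.0})
        assert delta(4, 5, P, self.P) == delta(5, 4, P, self.P)

    @given(st.floats(-200, 200))
    @settings(max_examples=200, deadline=None)
    def test_codomain(self, g):
        v = delta_of_gap(g, self.P)
        assert v == -4.0 or 0.0 <= v <= 1.0

    def test_signed_gap_directions(self):
        assert signed_gap(4, 5, 100.0, 130.0) == 30.0    # maxilla, in order
        assert signed_gap(5, 4, 130.0, 100.0) == 30.0
        assert signed_gap(20, 21, 300.0, 280.0) == 20.0  # mandible, in order
        assert signed_gap(20, 21, 300.0, 330.0) == -30.0


class TestFpTooth:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (1, [2, 3]),
            (2, [1, 3, 4]),
            (16, [14, 15]),
            (17, [18, 19]),
            (20, [18, 19, 21, 22]),
            (32, [30, 31]),
        ],
    )
    def test_neighbor_sets_clip_at_jaw_boundaries(self, x, expected):
        assert sorted(neighbor_set(x)) == expected

    def test_plateau_neighbors_score_one(self):
        P = full_arch_combo(25.0)
        assert fp_tooth(8, P, W) == pytest.approx(1.0)

    def test_all_missing_neighbors_score_kappa(self):
        P = combo_with({8: 300.0})
        assert fp_tooth(8, P, W) == 0.0


class TestObjective:
    def test_perfect_arch_scores_one(self):
        # 25 px uniform spacing lies on the plateau for every pair context
        P = full_arch_combo(25.0)
        assert objective(P, W, ObjectiveWeights(0.8, 0.2)) == pytest.approx(1.0)

    def test_all_missing_scores_zero_with_default_kappa(self):
        P = Combination([None] * 32)
        assert objective(P, W) == 0.0

    def test_confidence_term_alone(self):
        P = full_arch_combo(25.0)
        assert objective(P, W, ObjectiveWeights(0.0, 1.0)) == pytest.approx(1.0)

    def test_linear_in_weights(self):
        P = full_arch_combo(21.0)  # some ramp deltas, not degenerate
        w1 = ObjectiveWeights(0.8, 0.2)
        w2 = ObjectiveWeights(0.3, 0.5)
        combined = ObjectiveWeights(1.1, 0.7)
        assert objective(P, W, w1) + objective(P, W, w2) == pytest.approx(
            objective(P, W, combined)
        )

    def test_too_close_duplicate_strictly_decreases_positional_score(self):
        P = full_arch_combo(25.0)
        clash = P.replaced(5, make_candidate(5, P[4].box.cx + 1.0, mu=1.0))
        assert objective(clash, W) < objective(P, W)


class TestBatchEvaluator:
    def test_matches_scalar_reference_on_random_combinations(self):
        rng = np.random.default_rng(7)
        ctx = PriorContext(W)
        for _ in range(30):
            entries = {}
            for t in range(1, 33):
                if rng.random() < 0.7:
                    entries[t] = float(rng.uniform(100, 540))
            P = combo_with(entries) if entries else Combination([None] * 32)
            assert math.isclose(
                ctx.objective_of(P), objective(P, W), rel_tol=0, abs_tol=1e-12
            )

    def test_batch_rows_scored_independently(self):
        ctx = PriorContext(W)
        P1 = full_arch_combo(25.0)
        P2 = full_arch_combo(21.0)
        cx1, mu1 = PriorContext.arrays_of(P1)
        cx2, mu2 = PriorContext.arrays_of(P2)
        batch = ctx.objective_batch(np.stack([cx1, cx2]), np.stack([mu1, mu2]))
        assert batch[0] == pytest.approx(ctx.objective_of(P1))
        assert batch[1] == pytest.approx(ctx.objective_of(P2))
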