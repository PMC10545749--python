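"""Heuristic combinatorial search over tooth-candidate combinations.

Selects one candidate (or "missing") per UTN slot to maximize the
prior-knowledge objective:

  step 0   greedy start: each slot's highest-confidence candidate (or a
           caller-supplied warm start);
  steps 1-5  coordinate-ascent sweeps over slots 1..32, trying every option
           (missing + each candidate) and keeping strict improvements, until
           a full sweep changes nothing or the sweep budget is spent;
  step 6   for every slot still marked missing that does have candidates, a
           round-robin (exhaustive joint) search over that slot and its
           same-jaw neighbors, capped by an option-product budget with a
           pairwise fallback; sweeps and round-robin alternate to a fixpoint;
  step 7   isolation exception: a chosen tooth whose immediate neighbors are
           all missing and which has exactly one present tooth on each side
           of it in the jaw may be renumbered toward the spatially nearer
           flanking tooth, when that strictly improves the objective.

Because eliminating duplicate detections is the purpose of the optimization,
one detector box may explain at most one tooth: options whose box coincides
(IOU >= ``exclusive_iou``) with a box selected in a different slot are
ineligible.  This matters chiefly for prosthesis-derived candidates, which
share one physical box across a whole range of tooth numbers.

The search is deterministic and the incumbent objective never decreases.
A brute-force enumeration oracle is provided for verification on instances
small enough to enumerate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .candidate_model import CandidateTable, Combination, jaw_numbers
from .prior_knowledge import (
    ObjectiveWeights,
    PriorConfig,
    PriorContext,
    neighbor_set,
)

__all__ = ["OptimizerConfig", "optimize", "brute_force_optimize"]


@dataclass(frozen=True)
class OptimizerConfig:
    max_sweeps: int = 10
    enable_round_robin: bool = True
    enable_isolation_exception: bool = True
    round_robin_budget: int = 5**5
    #: one detector box explains at most one tooth: a candidate is ineligible
    #: while a box overlapping it at or above this IOU is selected in another
    #: slot (None disables the constraint)
    exclusive_iou: float | None = 0.5

    def __post_init__(self) -> None:
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


def _conflict_matrix(slots: dict, threshold: float | None):
    """Global candidate indexing plus a padded boolean conflict matrix.

    conflicts[i, j] is True when candidates i and j sit in different slots
    but their boxes overlap at or above the threshold.  Index N (the pad row)
    never conflicts and stands for the missing option.
    """
    gidx: dict[int, np.ndarray] = {}
    boxes, slot_of = [], []
    n = 0
    for x in range(1, 33):
        ids = []
        for cand in slots[x]:
            boxes.append((cand.box.x1, cand.box.x2, cand.box.y1, cand.box.y2))
            slot_of.append(x)
            ids.append(n)
            n += 1
        gidx[x] = np.array(ids, dtype=int)
    conflicts = np.zeros((n + 1, n + 1), dtype=bool)
    if threshold is not None and n:
        b = np.array(boxes)
        x1, x2, y1, y2 = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
        iw = np.minimum(x2[:, None], x2[None, :]) - np.maximum(x1[:, None], x1[None, :])
        ih = np.minimum(y2[:, None], y2[None, :]) - np.maximum(y1[:, None], y1[None, :])
        inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
        area = (x2 - x1) * (y2 - y1)
        iou = inter / (area[:, None] + area[None, :] - inter)
        s = np.array(slot_of)
        conflicts[:n, :n] = (iou >= threshold) & (s[:, None] != s[None, :])
    return gidx, conflicts


class _State:
    """Incumbent combination as index choices plus cx/mu arrays."""

    def __init__(
        self,
        table: CandidateTable,
        ctx: PriorContext,
        exclusive_iou: float | None,
        warm_start: Combination | None = None,
    ):
        self.slots = {x: table[x] for x in range(1, 33)}
        self.ctx = ctx
        self.gidx, self.conflicts = _conflict_matrix(self.slots, exclusive_iou)
        self.pad = self.conflicts.shape[0] - 1
        # option index: -1 = missing, k >= 0 = k-th candidate of the slot
        self.idx = np.array(
            [0 if self.slots[x] else -1 for x in range(1, 33)], dtype=int
        )
        if warm_start is not None:
            for x in range(1, 33):
                cand = warm_start[x]
                self.idx[x - 1] = self.slots[x].index(cand) if cand is not None else -1
        self.cx = np.full(32, np.nan)
        self.mu = np.zeros(32)
        for x in range(1, 33):
            self._apply(x, int(self.idx[x - 1]))
        self.score = float(ctx.objective_batch(self.cx, self.mu)[0])

    def _apply(self, x: int, k: int) -> None:
        self.idx[x - 1] = k
        if k < 0:
            self.cx[x - 1] = np.nan
            self.mu[x - 1] = 0.0
        else:
            cand = self.slots[x][k]
            self.cx[x - 1] = cand.box.cx
            self.mu[x - 1] = cand.mu

    def _gid(self, x: int, k: int) -> int:
        return int(self.gidx[x][k]) if k >= 0 else self.pad

    def try_joint(self, assignment: dict[int, list[int]]) -> bool:
        """Exhaustively score an option product; adopt the best strictly
        improving feasible choice.  Returns True if the incumbent changed."""
        slots = sorted(assignment)
        combos = list(itertools.product(*(assignment[x] for x in slots)))
        n = len(combos)
        cx = np.tile(self.cx, (n, 1))
        mu = np.tile(self.mu, (n, 1))
        gids = np.full((n, len(slots)), self.pad, dtype=int)
        for i, combo in enumerate(combos):
            for j, (x, k) in enumerate(zip(slots, combo)):
                gids[i, j] = self._gid(x, k)
                if k < 0:
                    cx[i, x - 1] = np.nan
                    mu[i, x - 1] = 0.0
                else:
                    cand = self.slots[x][k]
                    cx[i, x - 1] = cand.box.cx
                    mu[i, x - 1] = cand.mu
        scores = self.ctx.objective_batch(cx, mu)
        # feasibility: no conflicts inside the group nor against the fixed rest
        outside = [
            self._gid(x, int(self.idx[x - 1]))
            for x in range(1, 33)
            if x not in assignment and self.idx[x - 1] >= 0
        ]
        if outside:
            bad = self.conflicts[gids][:, :, outside].any(axis=(1, 2))
            scores = np.where(bad, -np.inf, scores)
        for j1 in range(len(slots)):
            for j2 in range(j1 + 1, len(slots)):
                bad = self.conflicts[gids[:, j1], gids[:, j2]]
                scores = np.where(bad, -np.inf, scores)
        best = int(np.argmax(scores))
        if scores[best] > self.score:
            for x, k in zip(slots, combos[best]):
                self._apply(x, k)
            self.score = float(scores[best])
            return True
        return False

    def combination(self) -> Combination:
        choice = [
            self.slots[x][self.idx[x - 1]] if self.idx[x - 1] >= 0 else None
            for x in range(1, 33)
        ]
        return Combination(choice)


def _sweeps(state: _State, cfg: OptimizerConfig) -> None:
    for _ in range(cfg.max_sweeps):
        updated = False
        for x in range(1, 33):
            options = list(range(-1, len(state.slots[x])))
            if len(options) == 1:
                continue
            if state.try_joint({x: options}):
                updated = True
        if not updated:
            break


def _round_robin(state: _State, cfg: OptimizerConfig) -> None:
    for x in range(1, 33):
        if state.idx[x - 1] >= 0 or not state.slots[x]:
            continue
        group = [x] + neighbor_set(x)
        assignment = {s: list(range(-1, len(state.slots[s]))) for s in group}
        product_size = math.prod(len(v) for v in assignment.values())
        if product_size > cfg.round_robin_budget:
            # trim each slot to its highest-confidence options (keeping the
            # incumbent and the missing option) until the product fits
            k = max(len(v) for v in assignment.values())
            while k > 2 and product_size > cfg.round_robin_budget:
                k -= 1
                assignment = {
                    s: sorted(
                        {-1, int(state.idx[s - 1]), *range(min(k, len(state.slots[s])))}
                    )
                    for s in group
                }
                product_size = math.prod(len(v) for v in assignment.values())
        if product_size <= cfg.round_robin_budget:
            state.try_joint(assignment)
        else:
            for y in neighbor_set(x):
                state.try_joint(
                    {
                        x: list(range(-1, len(state.slots[x]))),
                        y: list(range(-1, len(state.slots[y]))),
                    }
                )


def _isolation_exception(state: _State, ctx: PriorContext) -> None:
    """Renumber an isolated chosen tooth toward its spatially nearer flank."""
    for x in range(1, 33):
        if state.idx[x - 1] < 0:
            continue
        jaw = jaw_numbers(x)
        near = [y for y in (x - 1, x + 1) if y in jaw]
        if any(state.idx[y - 1] >= 0 for y in near):
            continue
        left_present = [y for y in jaw if y < x and state.idx[y - 1] >= 0]
        right_present = [y for y in jaw if y > x and state.idx[y - 1] >= 0]
        if len(left_present) != 1 or len(right_present) != 1:
            continue
        cand = state.slots[x][state.idx[x - 1]]
        flanks = [left_present[0], right_present[0]]
        nearer = min(flanks, key=lambda y: abs(state.cx[y - 1] - cand.box.cx))
        target = nearer + 1 if nearer < x else nearer - 1
        if target == x or target not in jaw or state.idx[target - 1] >= 0:
            continue
        cx_row = state.cx.copy()
        mu_row = state.mu.copy()
        cx_row[x - 1], mu_row[x - 1] = np.nan, 0.0
        cx_row[target - 1], mu_row[target - 1] = cand.box.cx, cand.mu
        score = float(ctx.objective_batch(cx_row, mu_row)[0])
        if score > state.score:
            # move the candidate: record it renumbered in the target slot,
            # sharing the original's global id so exclusivity still holds
            state.slots[target] = state.slots[target] + (cand.renumbered(target),)
            state.gidx[target] = np.append(state.gidx[target], state.gidx[x][state.idx[x - 1]])
            state._apply(target, len(state.slots[target]) - 1)
            state._apply(x, -1)
            state.score = score


def optimize(
    table: CandidateTable,
    width: float,
    weights: ObjectiveWeights = ObjectiveWeights(),
    cfg: OptimizerConfig = OptimizerConfig(),
    prior_config: PriorConfig = PriorConfig(),
    warm_start: Combination | None = None,
) -> tuple[Combination, float]:
    """Run the full heuristic (steps 0-7); returns the best combination found
    and its objective value.

    ``warm_start`` replaces the greedy highest-confidence initialization with
    a given combination (every non-missing entry must be a table candidate);
    the pipeline uses this in proposed mode to seed the merged search with
    the tooth-only solution.
    """
    ctx = PriorContext(width, weights, prior_config)
    state = _State(table, ctx, cfg.exclusive_iou, warm_start)
    _sweeps(state, cfg)
    if cfg.enable_round_robin:
        while True:
            before = state.score
            _round_robin(state, cfg)
            _sweeps(state, cfg)
            if state.score <= before:
                break
    if cfg.enable_isolation_exception:
        _isolation_exception(state, ctx)
    return state.combination(), state.score


def brute_force_optimize(
    table: CandidateTable,
    width: float,
    weights: ObjectiveWeights = ObjectiveWeights(),
    prior_config: PriorConfig = PriorConfig(),
    exclusive_iou: float | None = 0.5,
    max_combinations: int = 2_000_000,
    batch_size: int = 65536,
) -> tuple[Combination, float]:
    """Exhaustive enumeration of every feasible combination (verification
    oracle, search-independent of the heuristic).

    Enumerates the full Cartesian product of {missing} + candidates over all
    32 slots, scoring in vectorized batches.  Refuses instances whose product
    exceeds ``max_combinations``.
    """
    ctx = PriorContext(width, weights, prior_config)
    slots = {x: table[x] for x in range(1, 33)}
    gidx, conflicts = _conflict_matrix(slots, exclusive_iou)
    pad = conflicts.shape[0] - 1
    option_lists = {x: list(range(-1, len(slots[x]))) for x in range(1, 33)}
    variable = [x for x, opts in option_lists.items() if len(opts) > 1]
    total = math.prod(len(option_lists[x]) for x in variable)
    if total > max_combinations:
        raise ValueError(f"instance too large to enumerate: {total} combinations")
    # per-slot option lookup tables; entry 0 is the missing option
    cx_opt = {x: np.array([np.nan] + [c.box.cx for c in slots[x]]) for x in variable}
    mu_opt = {x: np.array([0.0] + [c.mu for c in slots[x]]) for x in variable}
    gid_opt = {x: np.array([pad] + list(gidx[x]), dtype=int) for x in variable}
    best_score = -np.inf
    best_combo: tuple = ()
    product = itertools.product(*(option_lists[x] for x in variable))
    while True:
        chunk = list(itertools.islice(product, batch_size))
        if not chunk:
            break
        combos = np.asarray(chunk, dtype=int)  # (n, |variable|), -1 = missing
        n = len(chunk)
        cx = np.full((n, 32), np.nan)
        mu = np.zeros((n, 32))
        gids = np.empty((n, len(variable)), dtype=int)
        for j, x in enumerate(variable):
            col = combos[:, j] + 1
            cx[:, x - 1] = cx_opt[x][col]
            mu[:, x - 1] = mu_opt[x][col]
            gids[:, j] = gid_opt[x][col]
        scores = ctx.objective_batch(cx, mu)
        for j1 in range(len(variable)):
            for j2 in range(j1 + 1, len(variable)):
                scores = np.where(conflicts[gids[:, j1], gids[:, j2]], -np.inf, scores)
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score = float(scores[i])
            best_combo = chunk[i]
    choice = [None] * 32
    for x, k in zip(variable, best_combo):
        if k >= 0:
            choice[x - 1] = slots[x][k]
    return Combination(choice), best_score
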