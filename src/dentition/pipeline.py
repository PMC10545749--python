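"""End-to-end orchestration of the numbering pipeline.

proposed mode: positional filter -> occlusal-curve fit -> bridge splitting and
prosthesis number assignment -> merged candidate table -> combinatorial
optimization.  earlier mode skips the prosthesis stages and optimizes the
tooth-detector candidates alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

from .candidate_model import (
    COMPLETE_RESTORATIONS,
    Combination,
    ImageFrame,
    ProsthesisDetection,
    ToothCandidate,
    build_candidate_table,
)
from .detection_metrics import Detection, MatchReport, evaluate_detections
from .occlusal_geometry import (
    GeometryConfig,
    OcclusalFitError,
    OcclusalModel,
    fallback_occlusal_model,
    fit_occlusal_model,
)
from .optimizer import OptimizerConfig, optimize
from .prior_knowledge import ObjectiveWeights, PriorConfig
from .prosthesis_numbering import NumberingConfig, assign_tooth_numbers, prepare_sources
from .tooth_filter import FilterConfig, filter_tooth_candidates

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "combination_to_detections",
    "evaluate_scenes",
]

log = logging.getLogger("dentition")

MODES = ("proposed", "earlier")


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "proposed"
    filter: FilterConfig = FilterConfig()
    geometry: GeometryConfig = GeometryConfig()
    numbering: NumberingConfig = NumberingConfig()
    prior: PriorConfig = PriorConfig()
    weights: ObjectiveWeights = ObjectiveWeights()
    optimizer: OptimizerConfig = OptimizerConfig()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}: {self.mode!r}")


@dataclass
class PipelineResult:
    combination: Combination
    score: float
    occlusal_model: OcclusalModel
    stage_counts: dict


def run_pipeline(
    tooth_cands: list[ToothCandidate],
    prosthesis_dets: list[ProsthesisDetection] | None,
    frame: ImageFrame,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the numbering pipeline on one scene's candidates."""
    if config.mode == "proposed" and prosthesis_dets is None:
        raise ValueError("proposed mode requires prosthesis detections")

    counts = {"tooth_candidates_in": len(tooth_cands)}
    filtered = filter_tooth_candidates(tooth_cands, frame, config.filter)
    counts["after_position_filter"] = len(filtered)
    log.info("position filter: %d -> %d candidates", len(tooth_cands), len(filtered))

    try:
        model = fit_occlusal_model(filtered, frame, config.geometry)
    except OcclusalFitError as exc:
        log.warning("occlusal fit failed (%s); using fallback model", exc)
        model = fallback_occlusal_model(filtered, frame)

    merged = list(filtered)
    warm_start = None
    if config.mode == "proposed":
        step1_table = build_candidate_table(filtered)
        sources = prepare_sources(prosthesis_dets, config.numbering)
        counts["prosthesis_sources"] = len(sources)
        derived = assign_tooth_numbers(sources, model, step1_table, config.numbering)
        counts["prosthesis_candidates"] = len(derived)
        log.info(
            "prosthesis numbering: %d boxes -> %d candidates", len(sources), len(derived)
        )
        merged.extend(derived)
        # seed the merged search with the tooth-only solution so prosthesis
        # candidates enter as rechecks of treated/missing slots rather than
        # competing with sound teeth during initialization
        seed_cfg = dataclasses.replace(config.optimizer, enable_isolation_exception=False)
        warm_start, _ = optimize(
            step1_table, frame.width, config.weights, seed_cfg, config.prior
        )

    table = build_candidate_table(merged)
    counts["table_candidates"] = len(table)
    combination, score = optimize(
        table,
        frame.width,
        config.weights,
        config.optimizer,
        config.prior,
        warm_start=warm_start,
    )
    counts["selected_teeth"] = len(combination.present())
    log.info(
        "optimization: %d candidates -> %d teeth selected (f=%.4f)",
        len(table),
        counts["selected_teeth"],
        score,
    )
    return PipelineResult(combination, score, model, counts)


def combination_to_detections(
    P: Combination, drop_complete_restorations: bool = False
) -> list[Detection]:
    """Turn a combination into UTN-labelled detections for evaluation.

    ``drop_complete_restorations`` removes implants and bridge dentures first
    (for scoring against the tooth-annotation view).
    """
    out = []
    for cand in P.present():
        if drop_complete_restorations and cand.restoration in COMPLETE_RESTORATIONS:
            continue
        out.append(Detection(cand.box, cand.tooth_number, cand.mu))
    return out


def evaluate_scenes(results_and_gts, iou_threshold: float = 0.5) -> MatchReport:
    """Score (detections, ground-truth view) pairs across scenes."""
    return evaluate_detections(results_and_gts, iou_threshold)
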