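"""Convert prosthesis detections into numbered tooth candidates.

Prosthesis boxes carry no tooth number.  Each box is assigned the plausible
UTN range for its jaw and side of the dentition center (the downstream
combinatorial optimizer resolves the exact number):

    maxilla,  cx <  center  ->  1..13        maxilla,  cx >= center ->  3..16
    mandible, cx <  center  -> 20..32        mandible, cx >= center -> 17..29

A bridge box (one denture held by two abutment teeth) is first split along x
at a 33:30:33 ratio into left abutment / denture / right abutment sections.
When a prosthesis box spatially coincides with a tooth already produced by
the tooth detector (IOU at or above a threshold), its confidence is halved:
the tooth is likely already accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidate_model import (
    Box,
    CandidateTable,
    Origin,
    ProsthesisClass,
    ProsthesisDetection,
    Restoration,
    ToothCandidate,
)
from .detection_metrics import iou
from .occlusal_geometry import Jaw, OcclusalModel, jaw_of

__all__ = ["NumberingConfig", "NumberedBoxSource", "split_bridge", "assign_tooth_numbers"]

RESTORATION_OF_CLASS = {
    ProsthesisClass.INLAY: Restoration.INLAY,
    ProsthesisClass.CROWN: Restoration.CROWN,
    ProsthesisClass.IMPLANT: Restoration.IMPLANT,
}


@dataclass(frozen=True)
class NumberingConfig:
    halve_iou_threshold: float = 0.5
    bridge_ratio: tuple[int, int, int] = (33, 30, 33)
    classes_enabled: frozenset = frozenset(ProsthesisClass)


@dataclass(frozen=True)
class NumberedBoxSource:
    """A prosthesis-derived box ready for tooth-number assignment."""

    box: Box
    restoration: Restoration
    mu: float


def split_bridge(
    b: ProsthesisDetection, ratio: tuple[int, int, int] = (33, 30, 33)
) -> list[NumberedBoxSource]:
    """Partition a bridge box along x into abutment/denture/abutment sections.

    Section widths are proportional to ``ratio`` and tile the parent box
    exactly; all sections share the parent's cy, height and confidence.
    """
    if b.p_class is not ProsthesisClass.BRIDGE:
        raise ValueError(f"split_bridge requires a bridge detection, got {b.p_class}")
    total = sum(ratio)
    x1 = b.box.x1
    edges = [x1]
    for r in ratio:
        edges.append(edges[-1] + b.box.w * r / total)
    tags = (Restoration.BRIDGE_ABUTMENT, Restoration.BRIDGE_DENTURE, Restoration.BRIDGE_ABUTMENT)
    return [
        NumberedBoxSource(
            Box((lo + hi) / 2, b.box.cy, hi - lo, b.box.h), tag, b.mu
        )
        for lo, hi, tag in zip(edges[:-1], edges[1:], tags)
    ]


def _number_range(jaw: Jaw, left_of_center: bool) -> range:
    if jaw is Jaw.MAXILLA:
        return range(1, 14) if left_of_center else range(3, 17)
    return range(20, 33) if left_of_center else range(17, 30)


def prepare_sources(
    detections: list[ProsthesisDetection],
    config: NumberingConfig = NumberingConfig(),
) -> list[NumberedBoxSource]:
    """Split bridges and map the remaining classes to restoration tags."""
    sources: list[NumberedBoxSource] = []
    for det in detections:
        if det.p_class not in config.classes_enabled:
            continue
        if det.p_class is ProsthesisClass.BRIDGE:
            sources.extend(split_bridge(det, config.bridge_ratio))
        else:
            sources.append(
                NumberedBoxSource(det.box, RESTORATION_OF_CLASS[det.p_class], det.mu)
            )
    return sources


def assign_tooth_numbers(
    p_boxes: list[NumberedBoxSource],
    model: OcclusalModel,
    existing: CandidateTable,
    config: NumberingConfig = NumberingConfig(),
) -> list[ToothCandidate]:
    """Fan each prosthesis-derived box out to one candidate per number in its
    jaw/side range, halving confidence (once) when the box overlaps a tooth
    already detected in the tooth-detection step."""
    step1 = existing.all_candidates()
    out: list[ToothCandidate] = []
    for src in p_boxes:
        jaw = jaw_of(src.box, model)
        left = src.box.cx < model.center_x
        mu = src.mu
        if step1 and max(iou(src.box, c.box) for c in step1) >= config.halve_iou_threshold:
            mu = mu / 2
        for number in _number_range(jaw, left):
            out.append(
                ToothCandidate(
                    src.box, number, mu, src.restoration, Origin.PROSTHESIS_DETECTOR
                )
            )
    return out
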