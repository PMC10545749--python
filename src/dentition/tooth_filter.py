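"""Positional false-positive filter for tooth candidates.

The tooth-bearing oral cavity occupies roughly the central 55% of a panoramic
radiograph's width.  Candidates whose UTN class is incompatible with their
horizontal position are removed: central-to-left-side classes (T10-T24 in the
mirrored panoramic layout) cannot sit in the leftmost 40% of the image, and
right-side classes (T1-T7, T26-T32) cannot sit beyond 60% of the width.
T8, T9 and T25 are exempt from both rules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidate_model import ImageFrame, ToothCandidate

__all__ = ["FilterConfig", "filter_tooth_candidates"]

LEFT_RULE_NUMBERS = frozenset(range(10, 25))  # T10..T24
RIGHT_RULE_NUMBERS = frozenset(range(1, 8)) | frozenset(range(26, 33))  # T1..T7, T26..T32


@dataclass(frozen=True)
class FilterConfig:
    left_fraction: float = 0.40
    right_fraction: float = 0.60
    enabled: bool = True


def filter_tooth_candidates(
    cands: list[ToothCandidate],
    frame: ImageFrame,
    config: FilterConfig = FilterConfig(),
) -> list[ToothCandidate]:
    """Drop positionally impossible candidates; keep the rest in input order.

    Comparisons use the box center and are strict: a candidate exactly on a
    boundary is retained.
    """
    if not config.enabled:
        return list(cands)
    left = config.left_fraction * frame.width
    right = config.right_fraction * frame.width
    kept = []
    for c in cands:
        if c.tooth_number in LEFT_RULE_NUMBERS and c.box.cx < left:
            continue
        if c.tooth_number in RIGHT_RULE_NUMBERS and c.box.cx > right:
            continue
        kept.append(c)
    return kept
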