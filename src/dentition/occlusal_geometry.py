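"""Occlusal-curve geometry.

The upper and lower dentitions are approximated as quadratic curves fitted by
ordinary least squares to the tooth candidates' box centers.  The occlusion
line is the coefficient-wise (additive) mean of the two fits; the x of its
apex is the dentition center, falling back to the image midline when the apex
deviates more than a configured fraction (default 5%) of the image width.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .candidate_model import Box, ImageFrame, ToothCandidate

__all__ = [
    "Quadratic",
    "OcclusalModel",
    "OcclusalFitError",
    "Jaw",
    "GeometryConfig",
    "fit_occlusal_model",
    "fallback_occlusal_model",
    "jaw_of",
]

APEX_CURVATURE_EPS = 1e-12


@dataclass(frozen=True)
class Quadratic:
    """y = a2*x^2 + a1*x + a0 in pixel coordinates."""

    a2: float
    a1: float
    a0: float

    def __call__(self, x):
        return self.a2 * x * x + self.a1 * x + self.a0


@dataclass(frozen=True)
class OcclusalModel:
    upper: Quadratic
    lower: Quadratic
    occlusion: Quadratic
    center_x: float
    center_fallback_used: bool


class Jaw(str, enum.Enum):
    MAXILLA = "maxilla"
    MANDIBLE = "mandible"


@dataclass(frozen=True)
class GeometryConfig:
    center_deviation_fraction: float = 0.05


class OcclusalFitError(ValueError):
    """Too few or degenerate points to fit a jaw curve; callers may use
    :func:`fallback_occlusal_model`."""


def _fit_quadratic(points: list[tuple[float, float]], jaw: str) -> Quadratic:
    if len(points) < 3:
        raise OcclusalFitError(
            f"need at least 3 {jaw} candidates to fit the occlusal curve, "
            f"got {len(points)}; use fallback_occlusal_model"
        )
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(xs)) < 3:
        raise OcclusalFitError(
            f"{jaw} candidate centers are rank-deficient (fewer than 3 distinct "
            "x values); use fallback_occlusal_model"
        )
    a2, a1, a0 = np.polyfit(xs, ys, 2)
    return Quadratic(float(a2), float(a1), float(a0))


def _mean_curve(u: Quadratic, l: Quadratic) -> Quadratic:
    return Quadratic((u.a2 + l.a2) / 2, (u.a1 + l.a1) / 2, (u.a0 + l.a0) / 2)


def _center_from_apex(
    occ: Quadratic, frame: ImageFrame, config: GeometryConfig
) -> tuple[float, bool]:
    half = frame.width / 2
    if abs(occ.a2) < APEX_CURVATURE_EPS:
        return half, True
    apex_x = -occ.a1 / (2 * occ.a2)
    if abs(apex_x - half) > config.center_deviation_fraction * frame.width:
        return half, True
    return float(min(max(apex_x, 0.0), frame.width)), False


def fit_occlusal_model(
    cands: list[ToothCandidate],
    frame: ImageFrame,
    config: GeometryConfig = GeometryConfig(),
) -> OcclusalModel:
    """OLS quadratic fit per jaw on candidate box centers.

    Raises :class:`OcclusalFitError` when either jaw has fewer than three
    candidates with distinct center x values.
    """
    upper_pts = [(c.box.cx, c.box.cy) for c in cands if c.tooth_number <= 16]
    lower_pts = [(c.box.cx, c.box.cy) for c in cands if c.tooth_number >= 17]
    upper = _fit_quadratic(upper_pts, "maxillary")
    lower = _fit_quadratic(lower_pts, "mandibular")
    occ = _mean_curve(upper, lower)
    center_x, fallback = _center_from_apex(occ, frame, config)
    return OcclusalModel(upper, lower, occ, center_x, fallback)


def fallback_occlusal_model(
    cands: list[ToothCandidate], frame: ImageFrame
) -> OcclusalModel:
    """Degenerate model for unfittable inputs: horizontal lines at each jaw's
    mean center y (or at 1/3 and 2/3 of the height with no candidates), center
    at the image midline."""
    upper_ys = [c.box.cy for c in cands if c.tooth_number <= 16]
    lower_ys = [c.box.cy for c in cands if c.tooth_number >= 17]
    uy = float(np.mean(upper_ys)) if upper_ys else frame.height / 3
    ly = float(np.mean(lower_ys)) if lower_ys else 2 * frame.height / 3
    upper = Quadratic(0.0, 0.0, uy)
    lower = Quadratic(0.0, 0.0, ly)
    return OcclusalModel(upper, lower, _mean_curve(upper, lower), frame.width / 2, True)


def jaw_of(box: Box, model: OcclusalModel) -> Jaw:
    """Classify a box as maxillary or mandibular against the occlusion line.

    Smaller y is higher in image coordinates; a center exactly on the line
    counts as mandible (fixed tie rule).
    """
    return Jaw.MAXILLA if box.cy < model.occlusion(box.cx) else Jaw.MANDIBLE
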