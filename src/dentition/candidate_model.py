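"""Domain types and file I/O for tooth/prosthesis candidates.

Coordinate convention: absolute pixels, origin at the image's upper-left
corner, x rightward, y downward.  Boxes are stored in center format
(cx, cy, w, h); edges are the half-open intervals
[cx - w/2, cx + w/2) x [cy - h/2, cy + h/2).

Tooth classes follow the Universal Tooth Numbering (UTN) system: 1-16 for
the maxilla (upper right third molar through upper left third molar as seen
in the mirrored panoramic view), 17-32 for the mandible.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "ImageFrame",
    "Box",
    "Restoration",
    "Origin",
    "ProsthesisClass",
    "ToothCandidate",
    "ProsthesisDetection",
    "CandidateTable",
    "Combination",
    "AnnotationView",
    "GroundTruthSet",
    "DEFAULT_CONF_THRESHOLD",
    "read_candidates",
    "write_combination",
    "read_combination",
    "build_candidate_table",
    "maxilla_numbers",
    "mandible_numbers",
    "jaw_numbers",
]

#: Detector confidence threshold applied when reading candidate files.
DEFAULT_CONF_THRESHOLD = 0.35

MAXILLA = frozenset(range(1, 17))
MANDIBLE = frozenset(range(17, 33))


def maxilla_numbers() -> range:
    return range(1, 17)


def mandible_numbers() -> range:
    return range(17, 33)


def jaw_numbers(tooth_number: int) -> range:
    """Return the UTN range of the jaw that ``tooth_number`` belongs to."""
    if 1 <= tooth_number <= 16:
        return maxilla_numbers()
    if 17 <= tooth_number <= 32:
        return mandible_numbers()
    raise ValueError(f"tooth number out of range 1-32: {tooth_number}")


@dataclass(frozen=True)
class ImageFrame:
    """Pixel dimensions of a panoramic radiograph."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("frame width and height must be positive")


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box in center format (absolute pixels)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError("box width and height must be positive")
        for v in (self.cx, self.cy, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError("box coordinates must be finite")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h


class Restoration(str, enum.Enum):
    """Treatment state of a tooth candidate.

    The bridge class is refined into its two anatomically distinct parts:
    the supporting natural teeth (abutments) and the artificial middle tooth
    (denture).  Use :func:`collapse_restoration` for four-class reporting.
    """

    NORMAL = "normal"
    INLAY = "inlay"
    CROWN = "crown"
    IMPLANT = "implant"
    BRIDGE_ABUTMENT = "bridge_abutment"
    BRIDGE_DENTURE = "bridge_denture"


#: Complete restorations replace a missing tooth entirely; they are absent
#: from the tooth-annotation ground-truth view but present in the all view.
COMPLETE_RESTORATIONS = frozenset({Restoration.IMPLANT, Restoration.BRIDGE_DENTURE})


def collapse_restoration(r: Restoration) -> str:
    """Map the six-valued restoration enum onto the four prosthesis classes
    plus 'normal' (bridge abutment and denture both report as 'bridge')."""
    if r in (Restoration.BRIDGE_ABUTMENT, Restoration.BRIDGE_DENTURE):
        return "bridge"
    return r.value


class Origin(str, enum.Enum):
    TOOTH_DETECTOR = "tooth_detector"
    PROSTHESIS_DETECTOR = "prosthesis_detector"


class ProsthesisClass(str, enum.Enum):
    INLAY = "inlay"
    CROWN = "crown"
    IMPLANT = "implant"
    BRIDGE = "bridge"


@dataclass(frozen=True)
class ToothCandidate:
    """One detector box proposed for a tooth slot."""

    box: Box
    tooth_number: int
    mu: float
    restoration: Restoration = Restoration.NORMAL
    origin: Origin = Origin.TOOTH_DETECTOR

    def __post_init__(self) -> None:
        if not 1 <= self.tooth_number <= 32:
            raise ValueError(f"tooth number out of range 1-32: {self.tooth_number}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.mu}")

    def renumbered(self, tooth_number: int) -> "ToothCandidate":
        return replace(self, tooth_number=tooth_number)


@dataclass(frozen=True)
class ProsthesisDetection:
    """One prosthesis detector box (inlay, crown, implant or bridge)."""

    box: Box
    p_class: ProsthesisClass
    mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.mu}")


class AnnotationView(str, enum.Enum):
    """The three ground-truth views.

    tooth: natural teeth only (complete restorations omitted);
    prosthesis: the four prosthesis classes;
    all: tooth view plus implants and bridge dentures numbered by jaw position.
    """

    TOOTH = "tooth_annotation"
    PROSTHESIS = "prosthesis_annotation"
    ALL = "all_annotation"


@dataclass(frozen=True)
class GroundTruthSet:
    """Ground-truth boxes under one annotation view.

    Labels are UTN integers 1-32 for the tooth/all views and prosthesis class
    names for the prosthesis view.
    """

    view: AnnotationView
    boxes: tuple = ()

    def __post_init__(self) -> None:
        for _, label in self.boxes:
            if self.view is AnnotationView.PROSTHESIS:
                ProsthesisClass(label)
            elif not (isinstance(label, int) and 1 <= label <= 32):
                raise ValueError(f"UTN label out of range: {label!r}")


class CandidateTable:
    """Per-tooth candidate lists, each sorted by descending confidence.

    The "missing" option (phi) is implicit for every slot; an empty list
    means the slot offers only phi.  Ties in confidence are broken by larger
    box area, then by input order.
    """

    def __init__(self, candidates: Iterable[ToothCandidate] = ()):
        per_tooth: dict[int, list[tuple]] = {x: [] for x in range(1, 33)}
        for order, cand in enumerate(candidates):
            per_tooth[cand.tooth_number].append((-cand.mu, -cand.box.area, order, cand))
        self._per_tooth: dict[int, tuple[ToothCandidate, ...]] = {
            x: tuple(c for *_, c in sorted(entries, key=lambda t: t[:3]))
            for x, entries in per_tooth.items()
        }

    def __getitem__(self, tooth_number: int) -> tuple[ToothCandidate, ...]:
        return self._per_tooth[tooth_number]

    def slots(self) -> dict[int, tuple[ToothCandidate, ...]]:
        return dict(self._per_tooth)

    def all_candidates(self) -> list[ToothCandidate]:
        return [c for x in range(1, 33) for c in self._per_tooth[x]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._per_tooth.values())


def build_candidate_table(cands: Sequence[ToothCandidate]) -> CandidateTable:
    """Group candidates by tooth number, sorted non-increasing in confidence."""
    return CandidateTable(cands)


@dataclass
class Combination:
    """A full 32-slot assignment: one candidate or None (phi) per tooth."""

    choice: list  # 32 entries of Optional[ToothCandidate], slot x at index x-1

    def __post_init__(self) -> None:
        if len(self.choice) != 32:
            raise ValueError("a combination has exactly 32 slots")
        for x, cand in enumerate(self.choice, start=1):
            if cand is not None and cand.tooth_number != x:
                raise ValueError(
                    f"slot {x} holds candidate numbered {cand.tooth_number}"
                )

    def __getitem__(self, tooth_number: int):
        return self.choice[tooth_number - 1]

    def replaced(self, tooth_number: int, cand) -> "Combination":
        new = list(self.choice)
        new[tooth_number - 1] = cand
        return Combination(new)

    def missing_teeth(self) -> list[int]:
        return [x for x in range(1, 33) if self.choice[x - 1] is None]

    def present(self) -> list[ToothCandidate]:
        return [c for c in self.choice if c is not None]

    def __eq__(self, other) -> bool:
        return isinstance(other, Combination) and self.choice == other.choice


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: default class maps: YOLO class ids are 0-based
UTN_CLASS_MAP = {i: i + 1 for i in range(32)}
PROSTHESIS_CLASS_MAP = {
    0: ProsthesisClass.INLAY,
    1: ProsthesisClass.CROWN,
    2: ProsthesisClass.IMPLANT,
    3: ProsthesisClass.BRIDGE,
}


class CandidateParseError(ValueError):
    """Raised on malformed candidate/annotation records."""


def _parse_line(line: str, lineno: int, path: str):
    parts = line.split()
    if len(parts) not in (5, 6):
        raise CandidateParseError(
            f"{path}:{lineno}: expected 'class cx cy w h [conf]', got {len(parts)} fields"
        )
    try:
        cls = int(parts[0])
        vals = [float(v) for v in parts[1:]]
    except ValueError as exc:
        raise CandidateParseError(f"{path}:{lineno}: {exc}") from exc
    conf = vals[4] if len(vals) == 5 else 1.0
    return cls, vals[0], vals[1], vals[2], vals[3], conf


def read_candidates(
    path: Union[str, Path],
    frame: ImageFrame,
    class_map: Union[str, dict] = "tooth",
    *,
    dialect: str = "normalized",
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> list:
    """Read a YOLO-style detection/annotation text file.

    Each line is ``class cx cy w h [conf]``.  ``dialect`` declares whether
    coordinates are normalized to [0, 1] ("normalized") or absolute pixels
    ("absolute"); the file format itself does not record this.  Records with
    confidence below ``conf_threshold`` are dropped (detector inference
    setting; annotations without a confidence column default to 1.0).

    ``class_map`` is "tooth" (ids 0-31 -> UTN 1-32), "prosthesis"
    (ids 0-3 -> inlay/crown/implant/bridge) or an explicit dict.
    """
    if dialect not in ("normalized", "absolute"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if class_map == "tooth":
        mapping: dict = UTN_CLASS_MAP
    elif class_map == "prosthesis":
        mapping = PROSTHESIS_CLASS_MAP
    else:
        mapping = class_map

    out = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cls, cx, cy, w, h, conf = _parse_line(line, lineno, str(path))
            if cls not in mapping:
                raise CandidateParseError(
                    f"{path}:{lineno}: class id {cls} outside the declared scheme"
                )
            if dialect == "normalized":
                cx, w = cx * frame.width, w * frame.width
                cy, h = cy * frame.height, h * frame.height
            if conf < conf_threshold:
                continue
            label = mapping[cls]
            box = Box(cx, cy, w, h)
            if isinstance(label, ProsthesisClass):
                out.append(ProsthesisDetection(box, label, conf))
            else:
                out.append(ToothCandidate(box, int(label), conf))
    return out


def write_combination(P: Combination, frame: ImageFrame, path: Union[str, Path]) -> None:
    """Serialize a combination as JSON: one record per present tooth plus an
    explicit missing-teeth list.  Round-trips through :func:`read_combination`.
    """
    records = []
    for cand in P.present():
        records.append(
            {
                "tooth_number": cand.tooth_number,
                "cx": cand.box.cx,
                "cy": cand.box.cy,
                "w": cand.box.w,
                "h": cand.box.h,
                "mu": cand.mu,
                "restoration": cand.restoration.value,
                "origin": cand.origin.value,
            }
        )
    payload = {
        "frame": {"width": frame.width, "height": frame.height},
        "teeth": records,
        "missing_teeth": P.missing_teeth(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_combination(path: Union[str, Path]) -> tuple[Combination, ImageFrame]:
    payload = json.loads(Path(path).read_text())
    frame = ImageFrame(**payload["frame"])
    choice: list = [None] * 32
    for rec in payload["teeth"]:
        choice[rec["tooth_number"] - 1] = ToothCandidate(
            Box(rec["cx"], rec["cy"], rec["w"], rec["h"]),
            rec["tooth_number"],
            rec["mu"],
            Restoration(rec["restoration"]),
            Origin(rec["origin"]),
        )
    return Combination(choice), frame
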