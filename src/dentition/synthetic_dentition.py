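"""Synthetic panoramic-layout scene generator.

Produces box-level dental scenes (no rendered images): 16 tooth stations per
jaw placed along two quadratic arches spanning the central 55% of the image
width, with sampled missing teeth and prostheses, the three ground-truth
annotation views, and detector-style noisy candidates.

Layout follows the mirrored panoramic convention of the Universal Tooth
Numbering system: T1 at the image left of the upper arch through T16 at the
right; T17 at the image right of the lower arch through T32 at the left.
Both arches curve upward toward the image edges (the occlusal "smile"), so
each jaw's center-y is an exact quadratic in x and the occlusion line is
their mean.

The noise model emulates detector failure modes at controllable rates:
position/size jitter, duplicate detections, adjacent-number confusion, an
elevated miss rate for prosthetically treated teeth, and confidence noise.
With all noise parameters at zero the tooth candidates equal the
tooth-annotation ground truth exactly, with confidence 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .candidate_model import (
    AnnotationView,
    Box,
    CandidateTable,
    GroundTruthSet,
    ImageFrame,
    Origin,
    ProsthesisClass,
    ProsthesisDetection,
    Restoration,
    ToothCandidate,
    build_candidate_table,
    jaw_numbers,
)

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "Scene",
    "ZERO_NOISE",
    "generate_scene",
    "generate_batch",
    "generate_optimizer_instance",
    "scene_to_json",
    "scene_from_json",
    "write_scene_files",
]

ARCH_FRACTION = 0.55  # fraction of the width occupied by the tooth rows
MAX_MISSING_PER_JAW = 11  # keeps the >= 5 teeth-per-jaw inclusion rule


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise rates.

    pos_jitter / size_jitter are normal std devs as fractions of the box
    dimensions; conf_tp is the std dev of the downward confidence noise on
    true detections; conf_fp the width of the uniform confidence band of
    duplicate (spurious) detections above the 0.35 inference threshold.
    """

    pos_jitter: float = 0.10
    size_jitter: float = 0.05
    dup_prob: float = 0.10
    shift_prob: float = 0.05
    miss_prob_normal: float = 0.02
    miss_prob_treated: float = 0.15
    conf_tp: float = 0.10
    conf_fp: float = 0.30

    def __post_init__(self) -> None:
        for name in ("dup_prob", "shift_prob", "miss_prob_normal", "miss_prob_treated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.miss_prob_treated < self.miss_prob_normal:
            raise ValueError("treated teeth cannot be easier to detect than normal ones")


ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SceneSpec:
    """Generator parameters for one scene family."""

    frame: ImageFrame = ImageFrame(640, 640)
    arch_curvature: float = 0.002  # px^-1; upward curl of the arches
    jaw_gap_fraction: float = 0.09  # half-distance between the rows / height
    center_offset_fraction: float = 0.0  # arch center offset from the midline
    missing_prob: float = 0.08
    prosthesis_mix: dict = field(
        default_factory=lambda: {
            "inlay": 0.06,
            "crown": 0.06,
            "implant": 0.25,
            "bridge": 0.25,
        }
    )
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob out of [0,1]")
        for k, v in self.prosthesis_mix.items():
            if k not in ("inlay", "crown", "implant", "bridge") or not 0.0 <= v <= 1.0:
                raise ValueError(f"bad prosthesis_mix entry: {k}={v}")


@dataclass
class Scene:
    """One generated scene: ground truth in three views plus noisy candidates."""

    frame: ImageFrame
    seed: int
    tooth_gt: GroundTruthSet
    prosthesis_gt: GroundTruthSet
    all_gt: GroundTruthSet
    tooth_candidates: list
    prosthesis_detections: list
    tooth_status: dict  # UTN -> restoration name or "missing"

    def gt_view(self, view: AnnotationView) -> GroundTruthSet:
        return {
            AnnotationView.TOOTH: self.tooth_gt,
            AnnotationView.PROSTHESIS: self.prosthesis_gt,
            AnnotationView.ALL: self.all_gt,
        }[view]


def _station_of(tooth: int) -> int:
    """Left-to-right station index (0-15) of a UTN tooth within its jaw."""
    return tooth - 1 if tooth <= 16 else 32 - tooth


# mean mesiodistal crown widths (mm), central incisor through third molar;
# molars are markedly wider than incisors and mandibular incisors are the
# narrowest teeth - the anatomy behind the prior model's molar-widening and
# mandibular-center crowding adjustments
MAXILLA_WIDTHS_MM = (8.6, 6.6, 7.6, 7.1, 6.6, 10.1, 9.6, 8.5)
MANDIBLE_WIDTHS_MM = (5.3, 5.7, 6.8, 7.0, 7.1, 11.0, 10.5, 8.5)


def _station_widths(per_side: tuple) -> list[float]:
    """Left-to-right relative station widths for one jaw (mirror-symmetric:
    third molar ... central incisor | central incisor ... third molar)."""
    half = list(reversed(per_side))
    return half + list(per_side)


def _arch_layout(spec: SceneSpec):
    """Station center positions and box sizes for both jaws.

    Each jaw's 16 stations tile the central 55% of the width with widths
    proportional to the anatomical crown widths; mean spacing is therefore
    width * 0.55 / 16, matching the prior model's Range derivation.
    """
    w = spec.frame.width
    h = spec.frame.height
    spacing = ARCH_FRACTION * w / 16  # mean station pitch
    span = ARCH_FRACTION * w
    x0 = (1 - ARCH_FRACTION) / 2 * w
    arch_cx = w / 2 + spec.center_offset_fraction * w
    occ_y0 = h / 2
    gap = spec.jaw_gap_fraction * h
    tooth_h = 2.0 * spacing

    centers: dict[bool, list[float]] = {}
    widths: dict[bool, list[float]] = {}
    for upper, mm in ((True, MAXILLA_WIDTHS_MM), (False, MANDIBLE_WIDTHS_MM)):
        rel = _station_widths(mm)
        scale = span / sum(rel)
        ws = [r * scale for r in rel]
        edges = np.concatenate([[0.0], np.cumsum(ws)]) + x0
        centers[upper] = [(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])]
        widths[upper] = ws

    def station_box(tooth: int) -> Box:
        i = _station_of(tooth)
        upper = tooth <= 16
        cx = centers[upper][i]
        occ_y = occ_y0 - spec.arch_curvature * (cx - arch_cx) ** 2
        cy = occ_y - gap if upper else occ_y + gap
        return Box(cx, cy, 0.9 * widths[upper][i], tooth_h)

    # 0.9 * spacing is the mean tooth width, the jitter reference scale
    return station_box, spacing, 0.9 * spacing, tooth_h


def _sample_status(spec: SceneSpec, rng: np.random.Generator) -> dict:
    """Sample per-tooth presence and restoration."""
    draws = rng.random(32)
    status: dict[int, str] = {}
    for jaw_start in (1, 17):
        jaw = list(range(jaw_start, jaw_start + 16))
        miss = [t for t in jaw if draws[t - 1] < spec.missing_prob]
        if len(miss) > MAX_MISSING_PER_JAW:
            miss = sorted(miss, key=lambda t: draws[t - 1])[:MAX_MISSING_PER_JAW]
        for t in jaw:
            status[t] = "missing" if t in miss else "normal"

    mix = spec.prosthesis_mix
    # complete restorations on missing teeth (bridge needs two sound flanks)
    for t in range(1, 33):
        if status[t] != "missing":
            continue
        jaw = jaw_numbers(t)
        flanks = (t - 1, t + 1)
        bridge_ok = all(y in jaw and status.get(y) == "normal" for y in flanks)
        r = rng.random()
        if bridge_ok and r < mix["bridge"]:
            status[t] = "bridge_denture"
            status[t - 1] = "bridge_abutment"
            status[t + 1] = "bridge_abutment"
        elif r < mix["bridge"] + mix["implant"]:
            status[t] = "implant"
    # partial restorations on remaining sound teeth
    for t in range(1, 33):
        if status[t] != "normal":
            continue
        r = rng.random()
        if r < mix["inlay"]:
            status[t] = "inlay"
        elif r < mix["inlay"] + mix["crown"]:
            status[t] = "crown"
    return status


def _clip_mu(v: float) -> float:
    return float(min(1.0, max(0.36, v)))


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate one scene; a pure function of the spec (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    station_box, spacing, tooth_w, tooth_h = _arch_layout(spec)
    status = _sample_status(spec, rng)

    tooth_view: list[tuple] = []
    all_view: list[tuple] = []
    prosthesis_view: list[tuple] = []
    natural = {"normal", "inlay", "crown", "bridge_abutment"}
    for t in range(1, 33):
        box = station_box(t)
        st = status[t]
        if st == "bridge_denture":
            # the pontic fills the gap between the abutment teeth (station
            # order runs opposite to UTN in the mandible)
            left, right = sorted(
                (station_box(t - 1), station_box(t + 1)), key=lambda b: b.cx
            )
            box = Box((left.x2 + right.x1) / 2, box.cy, right.x1 - left.x2, box.h)
        if st in natural:
            tooth_view.append((box, t))
            all_view.append((box, t))
        elif st in ("implant", "bridge_denture"):
            all_view.append((box, t))
        if st == "inlay":
            prosthesis_view.append(
                (Box(box.cx, box.cy, box.w, box.h * 0.7), ProsthesisClass.INLAY)
            )
        elif st == "crown":
            prosthesis_view.append((box, ProsthesisClass.CROWN))
        elif st == "implant":
            prosthesis_view.append((box, ProsthesisClass.IMPLANT))
        elif st == "bridge_denture":
            # bridge annotation: bounding box of abutments and pontic
            parts = (station_box(t - 1), box, station_box(t + 1))
            x1 = min(p.x1 for p in parts)
            x2 = max(p.x2 for p in parts)
            y1 = min(p.y1 for p in parts)
            y2 = max(p.y2 for p in parts)
            prosthesis_view.append(
                (Box((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1), ProsthesisClass.BRIDGE)
            )

    noise = spec.noise
    tooth_candidates: list[ToothCandidate] = []
    for box, t in tooth_view:
        treated = status[t] != "normal"
        p_miss = noise.miss_prob_treated if treated else noise.miss_prob_normal
        if rng.random() < p_miss:
            continue
        restoration = Restoration(status[t])
        jaw = jaw_numbers(t)
        number = t
        if rng.random() < noise.shift_prob:
            step = -1 if rng.random() < 0.5 else 1
            number = t + step if t + step in jaw else t - step
        cand_box = _jitter_box(box, noise, rng, 1.0, tooth_w)
        mu = _clip_mu(1.0 - abs(rng.normal(0.0, noise.conf_tp)))
        tooth_candidates.append(
            ToothCandidate(cand_box, number, mu, restoration, Origin.TOOTH_DETECTOR)
        )
        if rng.random() < noise.dup_prob:
            dup_box = _jitter_box(box, noise, rng, 1.5, tooth_w)
            dup_mu = _clip_mu(0.36 + rng.random() * noise.conf_fp)
            tooth_candidates.append(
                ToothCandidate(dup_box, number, dup_mu, restoration, Origin.TOOTH_DETECTOR)
            )

    prosthesis_detections: list[ProsthesisDetection] = []
    for box, p_class in prosthesis_view:
        if rng.random() < noise.miss_prob_normal:
            continue
        det_box = _jitter_box(box, noise, rng, 1.0, tooth_w)
        mu = _clip_mu(1.0 - abs(rng.normal(0.0, noise.conf_tp)))
        prosthesis_detections.append(ProsthesisDetection(det_box, p_class, mu))

    return Scene(
        frame=spec.frame,
        seed=spec.seed,
        tooth_gt=GroundTruthSet(AnnotationView.TOOTH, tuple(tooth_view)),
        prosthesis_gt=GroundTruthSet(AnnotationView.PROSTHESIS, tuple(prosthesis_view)),
        all_gt=GroundTruthSet(AnnotationView.ALL, tuple(all_view)),
        tooth_candidates=tooth_candidates,
        prosthesis_detections=prosthesis_detections,
        tooth_status=status,
    )


def _jitter_box(
    box: Box, noise: NoiseSpec, rng: np.random.Generator, scale: float, tooth_w: float
) -> Box:
    # positional jitter scales with the tooth's own width on both axes,
    # capped at the mean tooth width so wide boxes (bridges) stay in register
    sigma = noise.pos_jitter * min(box.w, tooth_w) * scale
    dx = rng.normal(0.0, sigma) if noise.pos_jitter else 0.0
    dy = rng.normal(0.0, sigma) if noise.pos_jitter else 0.0
    sw = max(0.2, 1.0 + rng.normal(0.0, noise.size_jitter)) if noise.size_jitter else 1.0
    sh = max(0.2, 1.0 + rng.normal(0.0, noise.size_jitter)) if noise.size_jitter else 1.0
    return Box(box.cx + dx, box.cy + dy, box.w * sw, box.h * sh)


def generate_batch(spec: SceneSpec, n: int) -> tuple[list[Scene], dict]:
    """Generate n scenes with derived seeds (spec.seed + index) and a
    manifest recording the spec and the per-scene seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scenes = [generate_scene(replace(spec, seed=spec.seed + i)) for i in range(n)]
    manifest = {
        "spec": _spec_dict(spec),
        "n": n,
        "seeds": [spec.seed + i for i in range(n)],
    }
    return scenes, manifest


def _spec_dict(spec: SceneSpec) -> dict:
    d = asdict(spec)
    d["frame"] = {"width": spec.frame.width, "height": spec.frame.height}
    return d


# ---------------------------------------------------------------------------
# Small instances for optimizer verification
# ---------------------------------------------------------------------------

def generate_optimizer_instance(
    seed: int,
    frame: ImageFrame = ImageFrame(640, 640),
    n_present_per_jaw: int = 5,
    n_multi: int = 6,
) -> CandidateTable:
    """A partial dentition small enough for exhaustive enumeration.

    ``n_present_per_jaw`` slots per jaw get one candidate at (jittered) arch
    positions; ``n_multi`` of the populated slots additionally get a second
    candidate - either a near-duplicate at lower confidence or a decoy placed
    at an adjacent station (sometimes with the higher confidence), which the
    positional prior must reject.
    """
    rng = np.random.default_rng(seed)
    spec = SceneSpec(frame=frame, missing_prob=0.0, noise=ZERO_NOISE, seed=seed)
    station_box, spacing, *_ = _arch_layout(spec)

    slots: list[int] = []
    for jaw_start in (1, 17):
        picks = rng.choice(16, size=n_present_per_jaw, replace=False)
        slots.extend(int(jaw_start + p) for p in sorted(picks))

    cands: list[ToothCandidate] = []
    for t in slots:
        box = station_box(t)
        b = Box(box.cx + rng.normal(0, 2.0), box.cy + rng.normal(0, 2.0), box.w, box.h)
        cands.append(ToothCandidate(b, t, float(0.6 + 0.4 * rng.random())))

    multi = rng.choice(len(slots), size=min(n_multi, len(slots)), replace=False)
    for i in sorted(int(m) for m in multi):
        first = cands[i]
        t = first.tooth_number
        if rng.random() < 0.5:  # near-duplicate, lower confidence
            b = Box(first.box.cx + rng.normal(0, 3.0), first.box.cy, first.box.w, first.box.h)
            mu = float(max(0.36, first.mu - 0.1 - 0.3 * rng.random()))
        else:  # decoy at a neighboring station, confidence may exceed the first
            side = -1 if rng.random() < 0.5 else 1
            nb = t + side if t + side in jaw_numbers(t) else t - side
            b = Box(station_box(nb).cx, first.box.cy, first.box.w, first.box.h)
            mu = float(0.5 + 0.5 * rng.random())
        cands.append(ToothCandidate(b, t, mu))
    return build_candidate_table(cands)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _box_dict(b: Box) -> dict:
    return {"cx": b.cx, "cy": b.cy, "w": b.w, "h": b.h}


def scene_to_json(scene: Scene) -> str:
    """Serialize a scene to the JSON scene format (deterministic text)."""

    def gt_entries(gt: GroundTruthSet) -> list:
        return [
            {"box": _box_dict(b), "label": l.value if isinstance(l, ProsthesisClass) else l}
            for b, l in gt.boxes
        ]

    payload = {
        "frame": {"width": scene.frame.width, "height": scene.frame.height},
        "seed": scene.seed,
        "tooth_gt": gt_entries(scene.tooth_gt),
        "prosthesis_gt": gt_entries(scene.prosthesis_gt),
        "all_gt": gt_entries(scene.all_gt),
        "tooth_candidates": [
            {
                "box": _box_dict(c.box),
                "tooth_number": c.tooth_number,
                "mu": c.mu,
                "restoration": c.restoration.value,
                "origin": c.origin.value,
            }
            for c in scene.tooth_candidates
        ],
        "prosthesis_detections": [
            {"box": _box_dict(d.box), "p_class": d.p_class.value, "mu": d.mu}
            for d in scene.prosthesis_detections
        ],
        "tooth_status": {str(k): v for k, v in scene.tooth_status.items()},
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def scene_from_json(text: str) -> Scene:
    payload = json.loads(text)
    frame = ImageFrame(**payload["frame"])

    def boxes(entries, view):
        out = []
        for e in entries:
            label = e["label"]
            if view is AnnotationView.PROSTHESIS:
                label = ProsthesisClass(label)
            out.append((Box(**e["box"]), label))
        return GroundTruthSet(view, tuple(out))

    return Scene(
        frame=frame,
        seed=payload["seed"],
        tooth_gt=boxes(payload["tooth_gt"], AnnotationView.TOOTH),
        prosthesis_gt=boxes(payload["prosthesis_gt"], AnnotationView.PROSTHESIS),
        all_gt=boxes(payload["all_gt"], AnnotationView.ALL),
        tooth_candidates=[
            ToothCandidate(
                Box(**c["box"]),
                c["tooth_number"],
                c["mu"],
                Restoration(c["restoration"]),
                Origin(c["origin"]),
            )
            for c in payload["tooth_candidates"]
        ],
        prosthesis_detections=[
            ProsthesisDetection(Box(**d["box"]), ProsthesisClass(d["p_class"]), d["mu"])
            for d in payload["prosthesis_detections"]
        ],
        tooth_status={int(k): v for k, v in payload["tooth_status"].items()},
    )


def write_scene_files(scene: Scene, out_dir, stem: Optional[str] = None) -> dict:
    """Write one scene as scene JSON plus paired YOLO-style text files
    (normalized coordinates; detections carry a confidence column).

    Returns the mapping of role -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"scene_{scene.seed}"
    w, h = scene.frame.width, scene.frame.height

    def yolo_line(box: Box, cls: int, mu: Optional[float] = None) -> str:
        fields = [str(cls)] + [
            f"{v:.6f}" for v in (box.cx / w, box.cy / h, box.w / w, box.h / h)
        ]
        if mu is not None:
            fields.append(f"{mu:.4f}")
        return " ".join(fields)

    p_ids = {p: i for i, p in enumerate(ProsthesisClass)}
    paths = {}
    files = {
        "scene": (f"{stem}.json", scene_to_json(scene)),
        "tooth_gt": (
            f"{stem}_tooth_gt.txt",
            "\n".join(yolo_line(b, l - 1) for b, l in scene.tooth_gt.boxes),
        ),
        "all_gt": (
            f"{stem}_all_gt.txt",
            "\n".join(yolo_line(b, l - 1) for b, l in scene.all_gt.boxes),
        ),
        "prosthesis_gt": (
            f"{stem}_prosthesis_gt.txt",
            "\n".join(yolo_line(b, p_ids[l]) for b, l in scene.prosthesis_gt.boxes),
        ),
        "tooth_detections": (
            f"{stem}_tooth_det.txt",
            "\n".join(
                yolo_line(c.box, c.tooth_number - 1, c.mu) for c in scene.tooth_candidates
            ),
        ),
        "prosthesis_detections": (
            f"{stem}_prosthesis_det.txt",
            "\n".join(
                yolo_line(d.box, p_ids[d.p_class], d.mu)
                for d in scene.prosthesis_detections
            ),
        ),
    }
    for role, (name, text) in files.items():
        path = out_dir / name
        path.write_text(text + ("\n" if text else ""))
        paths[role] = path
    return paths
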