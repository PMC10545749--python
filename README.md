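# dentition

Prosthesis-aware tooth numbering for dental panoramic radiograph
detections.

Object detectors are good at finding teeth in panoramic X-rays, but their
raw output is not a dental chart: the same tooth can be detected twice
under different numbers, treated teeth (inlays, crowns) are missed more
often because prosthetic material distorts their appearance, and complete
restorations — implants and the artificial teeth (pontics) of fixed
bridges — are not natural teeth at all, so a tooth detector ignores them
and the count of truly missing teeth comes out wrong.

`dentition` turns two detectors' box lists — 32-class tooth candidates
(Universal Tooth Numbering, UTN) and 4-class prosthesis candidates (inlay,
crown, implant, bridge) — into a coherent 32-slot chart.  It filters
positionally impossible candidates, fits the two dental arches as
quadratics to locate the occlusion line and dentition center, converts
prosthesis boxes into numbered tooth candidates (splitting each bridge
33:30:33 into abutment/pontic/abutment sections), and then selects one
candidate or "missing" per tooth slot by maximizing a prior-knowledge
objective

```
f(P) = ω_p · f_p(P) + ω_c · f_c(P),        ω_p = 0.8, ω_c = 0.2
```

where `f_c` is the mean detector confidence of the chosen candidates and
`f_p` scores each tooth's center-x spacing against its neighbors
{x−2, x−1, x+1, x+2} with a trapezoidal score δ: −4 for reversed or
near-coincident pairs, 1 on the anatomically plausible plateau, −4 again
for impossibly distant pairs.  The thresholds derive from the assumption
that 16 teeth span ~55% of the image width, with adjustments for the
crowded mandibular front and the wide mandibular molars.  A deterministic
coordinate-ascent search with joint neighborhood moves performs the
maximization.  Everything is usable without radiographs or trained
weights: a synthetic dentition simulator generates box-level scenes (three
ground-truth annotation views plus detector-style noisy candidates) from a
seed, and an evaluation module provides IOU / precision / recall /
all-point-interpolated AP / mAP / F1 scoring.

Audience: researchers and engineers building automated dental charting
from panoramic radiographs, who have (or plan to train) their own
detectors and need the numbering, optimization and evaluation machinery
around them.

## Worked example

```
$ dentition demo --seed 7
scene seed=7: 31 tooth candidates, 5 prosthesis detections
ground truth (non-normal teeth): {3: 'inlay', 6: 'bridge_abutment', 7: 'bridge_denture',
 8: 'bridge_abutment', 15: 'crown', 21: 'inlay', 24: 'implant', 25: 'missing'}

[proposed] objective=0.8788
  teeth found: [1, 2, ..., 16, 18, ..., 24, 26, ..., 32]
  restorations: {3: 'inlay', 6: 'bridge_abutment', 7: 'bridge_denture',
                 8: 'bridge_abutment', 15: 'crown', 21: 'inlay', 24: 'implant'}
  missing: [17, 25]

[earlier] objective=0.7810
  teeth found: [1, ..., 6, 8, ..., 16, 18, ..., 23, 26, ..., 32]
  restorations: {3: 'inlay', 6: 'bridge_abutment', 8: 'bridge_abutment',
                 15: 'crown', 21: 'inlay'}
  missing: [7, 17, 24, 25]
```

The scene has a bridge at T6–T8 (T7 is the artificial pontic), an implant
at T24, and one genuinely missing tooth (T25).  The prosthesis-aware
("proposed") mode charts the pontic and the implant at their stations, so
only T25 and one tooth the simulated detector failed to find (T17) are
reported missing.  The tooth-only ("earlier") mode cannot see complete
restorations and wrongly reports T7 and T24 as missing — exactly the
failure the prosthesis information corrects.  The objective values are
f(P) for each mode's chosen chart.

The same pipeline is scriptable:

```
dentition simulate --n 20 --seed 0 --out scenes/     # scenes + YOLO-style files
dentition run --scene scenes/scene_0.json --mode proposed --out chart.json
dentition evaluate --scenes scenes/ --mode proposed  # per-class table + micro-F1
```

or called as a library (`dentition.run_pipeline`, `dentition.optimize`,
`dentition.evaluate_detections`, `dentition.generate_scene`).

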