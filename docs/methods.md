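# Methods

`dentition` charts a full dentition from noisy object-detector output on a
dental panoramic radiograph.  Its inputs are bounding boxes: tooth candidates
labelled with Universal Tooth Numbers (UTN 1–32) and, optionally, prosthesis
candidates labelled inlay / crown / implant / bridge.  Its output is one
chart: for each of the 32 tooth positions, either a single chosen box (with
a restoration tag) or "missing".  No image data is touched; everything
operates on box geometry and detector confidences.

## Coordinate and numbering conventions

Panoramic radiographs mirror left and right.  Pixels are addressed from the
upper-left corner, x rightward, y downward.  Under the UTN scheme the upper
row runs T1 (image left) through T16 (image right) and the lower row runs
T17 (image right) through T32 (image left): tooth numbers increase rightward
across the maxilla and leftward across the mandible.  Boxes are stored
center-format `(cx, cy, w, h)` in absolute pixels with half-open edges for
area computations.

## Pipeline

1. **Positional filter.**  The tooth-bearing region occupies roughly the
   central 55% of the image width.  Candidates whose UTN class cannot occur
   at their horizontal position are dropped: central classes T10–T24 in the
   leftmost 40% of the width, right-side classes T1–T7 and T26–T32 beyond
   60%.  Comparisons use the box center and are strict, so a candidate
   exactly on a boundary survives.  T8, T9 and T25 are exempt.

2. **Occlusal geometry.**  Each jaw's dentition is approximated as a
   quadratic y(x) fitted by unweighted ordinary least squares to the
   candidate box centers (at least three candidates with distinct x per jaw;
   otherwise a fallback model with horizontal rows is used and logged).  The
   occlusion line is the coefficient-wise mean of the two fits.  Its apex x
   is the dentition center unless it deviates from the image midline by more
   than 5% of the width (configurable), in which case the midline is used.
   Boxes are classified maxillary/mandibular by comparing their center y
   against the occlusion line (a center exactly on the line counts as
   mandible — an arbitrary documented tie rule).

3. **Prosthesis numbering** (proposed mode only).  A bridge box — one
   artificial tooth held by two abutment teeth — is first split along x at a
   fixed 33:30:33 ratio into abutment / denture / abutment sections that
   tile the box exactly.  Every prosthesis-derived box is then assigned the
   plausible UTN range for its jaw and side of the dentition center
   (maxilla-left 1–13, maxilla-right 3–16, mandible-left 20–32,
   mandible-right 17–29), producing one candidate per number in the range,
   all sharing the same physical box.  If the box coincides with a tooth the
   tooth detector already found (IOU ≥ 0.5 against any step-1 candidate,
   configurable), its confidence is halved — the tooth is probably already
   accounted for and the prosthesis candidate serves only as a recheck.

4. **Combinatorial optimization.**  One candidate (or "missing", written φ)
   is selected per slot by maximizing

       f(P) = ω_p · f_p(P) + ω_c · f_c(P),      ω_p = 0.8, ω_c = 0.2

   where f_c is the mean confidence over the 32 slots (φ contributes 0) and
   f_p is the mean, over slots, of the positional score of each tooth
   against its same-jaw neighbor set Ω = {x−2, x−1, x+1, x+2}.

### The positional score δ

For a pair of chosen teeth, let g be their center-x separation measured
along the jaw's numbering direction, so g < 0 means the pair is spatially
reversed.  δ(g) is a trapezoid with cliffs:

| region        | value                 | meaning              |
|---------------|-----------------------|----------------------|
| g < a         | −4                    | reversed or too close|
| [a, b)        | 0                     | suspiciously close   |
| [b, c)        | (g−b)/(c−b)           | ramp up              |
| [c, d)        | 1                     | plausible spacing    |
| [d, e)        | 1 − (g−d)/(e−d)       | ramp down            |
| [e, f)        | 0                     | suspiciously far     |
| g ≥ f         | −4                    | far too far          |
| either slot φ | κ (default 0)         | no information       |

The thresholds derive from the 55%-of-width assumption.  With `u = width ×
0.55 / 16` (the mean tooth pitch): `b = 0.4u`, `e = 2u`, `Range = e − b`,
`a = b/2`, `c = b + Range/4`, `f = e + Range/4`, and `d = c + 3·Range/4`.
That last rule makes d = e identically, so the ramp-down segment is empty; a
`quartile` variant with `d = b + 3·Range/4` (plateau ending at the third
quartile of Range, matching the derivation's stated intent) is available via
`PriorConfig(d_variant="quartile")`.  Three context adjustments, applied in
order: when both teeth lie in the crowded mandibular front (21–28), b is
halved and its dependents recomputed; when either tooth is a mandibular
molar (17–19, 30–32), e is multiplied by 1.5 and its dependents recomputed;
for next-nearest pairs (|x−y| = 2) the too-close cutoff a widens to the
unshifted c and b…f all shift outward by that same c.

The directional (signed) reading of g is essential: with an absolute gap a
mirror-reversed arrangement scores identically to the correct one, and
prosthesis-derived candidates — which appear in up to 14 slots with the same
box — then colonize mirrored or shifted configurations.  δ is symmetric
under swapping its two tooth arguments.

κ, the score of a comparison against a missing tooth, has no published
value; 0 (neutral) is the default.  Declaring a tooth missing therefore
costs only its confidence mass, counterbalanced by the −4 cliffs a
mispositioned candidate would incur.

### Search

The objective is maximized by a deterministic heuristic: greedy
initialization with each slot's highest-confidence candidate; coordinate-
ascent sweeps over slots 1–32 trying every option per slot and accepting
strict improvements, repeated (default ≤ 10) until a sweep changes nothing;
an exhaustive joint "round-robin" search over each still-missing slot and
its same-jaw neighbors, alternated with sweeps to a fixpoint; and finally an
isolation exception that may renumber a tooth stranded between missing
slots toward the spatially nearer flanking tooth when that strictly
improves the objective (the published wording of this last step is
ambiguous; the implementation is a documented reading and can be disabled).

Two search policies were added after the basic scheme proved brittle on
prosthesis-rich scenes:

* **Box exclusivity.**  One detector box may explain at most one tooth:
  options whose box overlaps a box selected in a different slot at IOU ≥
  0.5 are infeasible.  Without this, the number-range fan-out lets a single
  prosthesis box be charted as two or three adjacent teeth, since pairs
  more than two slots apart are never compared by δ.
* **Warm start.**  In proposed mode the merged search starts from the
  tooth-only solution rather than from greedy confidence order.  Prosthesis
  candidates often carry top confidence in a dozen slots at once; seeding
  them greedily creates interlocking wrong chains that single-slot moves
  cannot unwind.  Starting from the tooth-only chart, prosthesis candidates
  enter exactly as what they are: rechecks of treated or missing positions.

When a round-robin product exceeds the option budget (default 5^5), the
per-slot option lists are trimmed to their highest-confidence entries (the
incumbent and φ always kept) until the product fits, with a pairwise search
as last resort.  The incumbent score never decreases; identical inputs give
identical outputs.  A brute-force enumerator (`brute_force_optimize`) scores
the full feasible Cartesian product in vectorized batches and serves as the
verification oracle on instances small enough to enumerate; the heuristic
matches its optimum on ≥ 95% of seeded 10-tooth instances and never exceeds
it.

## Evaluation

Standard single-threshold detection scoring: a prediction is a true positive
if it overlaps an unmatched same-class ground-truth box at IOU ≥ 0.5,
matching greedily in descending confidence with at most one match per
ground-truth box; wrong class or insufficient overlap is a false positive;
unmatched ground truth is a false negative.  AP uses all-point
interpolation; mAP averages AP over classes present in the ground truth
(classes with detections but no ground truth contribute 0; classes with
neither are excluded); F1 is the harmonic mean of precision and recall, 0
when both are 0.  Reports can be produced against any of the three
annotation views, and complete restorations (implants, bridge dentures) can
be dropped from the output before scoring to mirror the tooth-only
comparison mode.

## Synthetic dentition generator

The simulator emulates the geometry of a panoramic radiograph at the box
level (no rendered images):

* **Arches.**  16 stations per jaw tile the central 55% of a 640×640 frame
  with widths proportional to standard mean mesiodistal crown widths
  (maxilla 8.6, 6.6, 7.6, 7.1, 6.6, 10.1, 9.6, 8.5 mm central incisor →
  third molar; mandible 5.3, 5.7, 6.8, 7.0, 7.1, 11.0, 10.5, 8.5 mm),
  mirrored about the midline.  This matters: the prior model's mandibular
  adjustments encode precisely this anatomy (wide molars, narrow lower
  incisors), and a uniform-pitch arch would place molar pairs on δ's ramp
  rather than its plateau.  Rows follow quadratic "smile" curves (default
  curvature 0.002 px⁻¹) separated by ±9% of the image height around the
  occlusal line; tooth boxes are 0.9 of their station width and two mean
  pitches tall.
* **Dentition state.**  Teeth go missing independently (default probability
  0.08, capped so each jaw keeps ≥ 5 teeth).  A missing tooth flanked by two
  sound neighbors becomes a bridge with probability 0.25 (its neighbors
  become abutments) or an implant with probability 0.25; sound teeth get an
  inlay or crown with probability 0.06 each.  Rates are fixed defaults
  chosen to produce prosthesis-bearing scenes at roughly the prevalence the
  method targets; they are not fitted to any dataset.
* **Ground-truth views.**  Tooth annotation: natural teeth only (crowned,
  inlaid and abutment teeth included; implants and bridge dentures
  excluded).  Prosthesis annotation: inlay boxes cover the crown region
  (0.7 of tooth height), crown and implant boxes equal the tooth box, and a
  bridge box is the bounding box of both abutments and the pontic.  The
  pontic's box — also its entry in the all annotation — is the gap between
  the abutments, which is what the artificial tooth physically occupies.
  All annotation: tooth view plus implants and pontics at their stations.
* **Detector noise.**  Each ground-truth tooth is missed with probability
  0.02 (0.15 if treated — prostheses distort tooth appearance), has its
  number confused with an adjacent one with probability 0.05, is duplicated
  with probability 0.10, and is jittered in position (σ = 0.10 of its own
  width, capped at the mean tooth width, per axis) and size (σ = 5%).
  True-detection confidence is 1 − |N(0, 0.1)| clipped to [0.36, 1];
  duplicate confidence is uniform in [0.36, 0.66].  With every rate at zero
  the candidates equal the tooth annotation exactly at confidence 1, which
  pins the end-to-end identity tests.  Scenes are pure functions of their
  seed (one generator stream, fixed draw order).

What the generator does **not** emulate: real radiographic appearance and
detector-specific error correlations, tilted or overlapping teeth,
deciduous/supernumerary teeth, bridges spanning more than one missing tooth,
root remnants, and annotation disagreement.  Passing the synthetic
benchmarks therefore demonstrates the correctness and stability of the
charting logic under controlled noise, not clinical performance.

## Known limitations

* Adjacent-number confusion is unrecoverable by design of the objective: no
  candidate carries the true number, and the positional model compares
  relative spacings only.  At the default 5% confusion rate this is the
  dominant residual error of the noisy benchmark (~0.95 micro-F1).
* The fixed 33:30:33 bridge split assumes roughly equal spans; with strongly
  unequal abutments (premolar–molar bridges) the middle section can shift a
  few pixels off the pontic, occasionally landing at IOU ≈ 0.49 against the
  pontic's box.
* When a tooth adjacent to a prosthesis cluster is missed, arrangements
  shifted by one slot can tie with the true one (κ = 0 makes comparisons
  against missing neighbors free), and the search keeps whichever it reached
  first.  Absolute arch position — which would break such ties — is used
  only for the coarse number ranges, mirroring the method's design.
* The earlier (tooth-only) mode cannot chart implants or pontics at all;
  that gap is the point of the prosthesis-aware mode.
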