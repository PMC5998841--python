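# Methods

This note documents the models and procedures implemented in
`angiotrack`, the design decisions taken where the problem left real
freedom, the synthetic study conditions, and the known limitations.

## Coordinate and acquisition conventions

Pixel coordinates, origin top-left, `x` = column, `y` = row, so `y`
grows toward the cell–gel interface and the monolayer sits at large
`y`. The acquisition emulated throughout is label-free phase-contrast
imaging at 20×, 1532×2048 px, one frame per day per device slot over
4–5 days, plus one end-point confocal stack supplying exact nuclei
coordinates. The reference frame for registration is the end-point
frame, because tracking runs backward from it.

## Registration

Post edges are detected on a Canny edge map (σ = 2) with a Hough
transform at 1 px / 0.5° resolution; peaks are accepted above 12 % of
the accumulator maximum. Labelling is two-stage and exploits the
device geometry: the top and bottom edges are the two strongest
near-horizontal lines in the whole image; the slanted sides are then
searched only inside the row band those two edges delimit, because the
vessel — whose walls can fall in the same angular window — lies above
the post. Each accepted line is refined to sub-bin accuracy by a
total-least-squares fit of its supporting edge pixels (two passes with
shrinking bands, 4 px then 1.5 px); without this refinement the 0.5°
accumulator quantisation alone exceeds the transform tolerances. The
five labelled intersections (four corners plus the extended-side apex
`a_p`) give the similarity transform in closed form (Umeyama); when
correspondences are unlabelled, ICP alternates nearest-point matching
with the closed-form solve (tolerance 1e-6, 50 iterations). Frames are
resampled bilinearly with zero fill and the post quadrilateral is
blanked. On the synthetic suite the recovered transforms are within
0.2 % scale, 0.002 rad and 1.5 px of truth (worst case over 50 slots).

## Vessel segmentation

The interface parabola `y(x) = a1 (x − a_p + a3)² + a2` is fitted by
exhaustive grid search (defaults: `a1` ∈ ±2e-4 in 9 steps, `a3` ∈
±80 px in 9 steps, `a2` every 4 px), maximising the mean Sobel
gradient magnitude along the curve; the choice between intensity,
gradient and overlap scores was open, and the gradient line integral
was chosen because the interface is an edge, not a region.
The `a2` search is bounded above the post's top edge (known from
registration) and blanked pixels are excluded, otherwise the fit locks
onto the post or the resampling boundary. A flat score surface flags
the result low-confidence. Segmentation then follows the stated
recipe, in this order: mask below the parabola, Otsu threshold on the
remaining pixels, morphological closing (disk radius 15), hole
filling, and removal of components below 20 000 px (a 20 000-px
component is kept, 19 999 is removed). Skeletonisation uses the ridge
of the exact Euclidean distance transform so the inscribed-disk radii
come with it; chains are split at junction pixels, spurs shorter than
8 px are dropped, and every chain is oriented interface-proximal end
first so arc length grows into the gel — the convention the
no-overtaking constraint relies on.

## Detection

The patch classifier is exactly the two-conv architecture (20@5×5,
20@10×10, each ReLU + 2×2 max-pool, fc-10, dropout 0.5, softmax-2) on
100×100 single-channel patches, implemented directly in numpy
(shift-and-matmul convolutions, SGD with momentum 0.9 on
cross-entropy; defaults lr 0.003, batch 32, weight decay 1e-4).
Training templates are augmented twelve-fold: the original, three
rotations and two flips, plus a Gaussian-noise copy of each. The bank
pairs cell-centred patches (±3 px jitter, matching the detector's
stride grid) with two kinds of negatives: uniform background crops and
hard negatives whose centre sits a ring of 12–30 px from a nucleus —
without the hard negatives the positive response region is so wide
that adjacent cells merge into one cluster. Inference is dense
convolutional evaluation of the whole frame; because both pools have
stride 2 this equals patch evaluation on a stride-4 grid exactly
(verified to machine precision), and arbitrary strides fall back to a
patch loop. Positive windows (score ≥ 0.5) are grouped by 8-connected
components, clusters under 4 windows are dropped, each cluster emits
its centroid, and candidates outside the vessel mask dilated by 10 px
are discarded. On the synthetic suite this detector reaches precision
and recall ≥ 0.9 (five-fold CV accuracy ≥ 0.9 on the bank); the
detector is pluggable and the tracker accepts detection CSVs directly,
which is how the tracking benchmark runs.

## Backward multiple-hypothesis tracking

State `[x, y, vx, vy]` with constant-velocity transition at Δt = −1
day; observation = position. Defaults (sized to the scaled study
conditions below): `Q = diag(9, 9, 49, 49)` px², `R = 4·I` px²,
validation gate 5.991 (χ², 2 dof, 95 %). Initial states sit exactly on
the end-point nuclei (positional variance 4 px²); velocity defaults to
zero with a 500× inflated variance, and when the vessel model and the
known migration statistics are supplied, to a drift prior along the
local centerline tangent pointing away from the interface — sprouting
cells migrate outward, and the drift prior is what makes the first
backward step (the only one without a learned velocity) informative.
The gated-KF baseline receives the same prior so the comparison
isolates the association strategy.

Per-track hypothesis trees follow the deferred-association scheme: at
every backward step a branch spawns a child per gated detection, a
monolayer-entry child when the prediction lies within `entry_band` of
the interface parabola (and below `b1`), and an unobserved
continuation. Two probability scales coexist deliberately:

* the **reported** probabilities are the per-branch per-step
  normalised weights (association `|2πS|^(−1/2) e^(−d²/2)`, entry
  `(b1−y)^(−b2)`, jointly normalised to sum to 1 — this sum is an
  invariant tested to 1e-12);
* **pruning and selection** use per-step Bayes factors: association
  likelihood divided by the clutter density λ_c (expected false
  detections per px²), entry prior times a fixed scale, and the miss
  probability for coasting. Selecting on products of normalised
  per-step probabilities has a clutter-escape pathology — a branch that
  wanders into an empty region has only itself to normalise against
  and collects probability-1 steps — which in trials inverted the
  ranking of the associators; Bayes factors against clutter are the
  standard track-oriented MHT remedy.

`b1 = 1700` px and `b2 = 2.47` are kept at their published values for
the full-size acquisition; for scenes of other heights
`MhtConfig.scaled_for_height` preserves the 168-px margin of `b1`
above the largest admissible `y`, which keeps the entry weight's range
over the admissible band scale-independent.

Joint selection maximises the summed log Bayes factors over one chain
per track under the biological constraints, with merged-group
semantics: two tracks claiming the same earlier observation are one
cell from that frame backward (a division seen in reverse), so their
shared factors count once, each merge multiplies the division prior
`p_division`, merged tracks must share all earlier events, daughters
must lie within `division_radius` of each other at their birth frame,
at most two merge groups may claim one observation (one split per
day), and two cells on the same centerline chain may not exchange arc
order between consecutive frames (ignoring pairs closer than
`ordering_margin` = 15 px, about a nucleus diameter, where estimated
positions cannot order them reliably). Small instances (product of
branch counts within `max_joint_candidates`) are solved by exhaustive
enumeration — the configuration under which selection is
oracle-verified; larger instances enumerate each track's full chain
set (depth-first, capped at 256 per track) and solve the selection as
a mixed-integer program (HiGHS through scipy): one binary per chain,
per-observation capacity constraints, an auxiliary binary per shared
observation applying the division prior and removing the
double-counted likelihood, and pairwise exclusions for
diverging-history or distant-daughter merges. The overtaking
constraint is not encoded in the program; a coordinate-ascent polish
under the exact scorer enforces it afterwards. A Murty-k-best
assignment walk remains as the fallback if the solver fails. The
selected chains are assembled into a lineage forest (division nodes
with exactly two children; entry and out-of-focus annotations) and a
per-frame tracks table.

The hypothesis-count law — N₀·M^(t−1) enumerated hypotheses at the
final expansion when every branch has exactly M children and none
terminates — holds by construction in the per-track expansion
machinery and is asserted on a constructed no-termination scenario.

## Synthetic study conditions

No image data accompany the original study, so the generator defines
the benchmark conditions. Parameters the source states are taken
directly: image geometry and daily sampling, 100×100 templates,
disk-15 closing and the 20 000-px area opening, the 15–48 h doubling
time as the one-split-per-day cap, `b1`/`b2`, M = 4. Everything else
is invented and was calibrated against the study's *observable*
signatures rather than guessed blind: the published accuracies of the
three baseline associators (26.7 %, 53.0 %, 60.1 %) and the sparsity
of divisions/entries in the published lineage plots are measurable
consequences of the motion statistics, and the generator's defaults
were iterated until the synthetic benchmark reproduces that profile.
The resulting conditions, at the standard 2/3-scale benchmark scene
(1024×1365 px; `SimulationConfig.benchmark()`):

* persistent directed migration: each cell draws a base outward speed
  once (40 ± 15 px/day across cells) and wanders ±3 px/day — the
  constant-velocity premise of the tracker, and of the source method,
  presumes this kind of persistence;
* speed-ranked single file: within a file the cell farther from the
  interface is the faster one (tip cells are the most migratory), so
  followers do not pile up behind leaders; cells never reach the end
  of the modelled centerline within the study window (the real sprout
  elongates at tip speed);
* nucleus spacing ≥ 30 px; division daughters appear ~1.3 nucleus
  radii either side of the parent; divisions at 0.1 per cell per day;
  monolayer entries at 1 per day inside a 150-px band above the
  interface; 5 %/day focus loss; detection noise σ = 2 px, 1 false
  positive per frame inside the vessel, 5 % misses; per-frame
  misalignment of ±3 % scale, ±0.03 rad, ±20 px.

Tracker parameters for the benchmark are derived from these stated
conditions, not fitted per run: λ_c = FP rate / dilated vessel area,
miss probability = FN + focus-loss rates, division prior = the
generator's division probability, entry band = 1.3× the generator
band, division radius = 1.5× the nucleus spacing, and Q/R from the
motion statistics — the same calibration-to-data the source describes
for its own empirical parameters.

Under these conditions, aggregated over 50 seeded slots, the
associators rank nearest-neighbour 0.41 < Hungarian 0.45 < gated KF
0.65 < multiple-hypothesis tracker 0.80. The qualitative ranking, the
mechanism behind it (the MHT recovers entries and divisions and defers
ambiguous first steps) and the approximate baseline levels match the
published real-data comparison; the MHT's absolute accuracy stays
about five points below the published 86.4 %, which is an honest
residual: with one frame per day, positions-only detections, migration
steps comparable to cell spacing, genuinely ambiguous division-versus-
entry events near the interface and a 95 % gate that by construction
clips 5 % of true associations, part of the association posterior mass
simply lies on wrong but self-consistent histories. Ground truth for
the real data was curated by eye on images, where appearance
continuity resolves ties that positions alone cannot.

## What the synthetic tests do and do not show

Passing the synthetic suite shows the pipeline's mechanics are correct
(oracle equivalences, exact formula values, recovery of known
transforms/parabolas/tracks) and that the method ordering emerges for
the stated reasons. It does not certify performance on real
micrographs: the renderer's halo/texture model is far simpler than
phase-contrast optics, vessels are static across frames, appearance
carries no identity information, and the detector's published
cross-validation accuracy on real templates is not reproducible
without the original data.

## Numerical choices and degenerate inputs

Gating inverts S directly and falls back to the pseudo-inverse when S
is exactly singular (the Q = R = 0 noise-free regime), raising an
error only if the innovation leaves the covariance range. Constraint
violations subtract 1e4 from a joint score instead of −∞ so local
search can traverse infeasible regions; a solution is reported
consistent only at zero violations. Ties in branch ordering resolve by
lowest observation index then lowest track id. Constant images raise
on Otsu; empty masks raise on skeletonisation; an empty post-filter
segmentation is a warning, not an error. Problem sizes in the test and
acceptance runs (scene scale, seeds per benchmark, bank sizes, epochs)
are the package's standard desk-scale settings; all are parameters of
the respective functions.
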