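# angiotrack

Backward multiple-hypothesis Kalman tracking of endothelial cells (ECs)
within angiogenic vessels grown in microfluidic devices.

## The problem

Angiogenesis assays in microfluidic devices are imaged label-free by
phase-contrast microscopy once per day over one to two weeks; only at
the end point is a stained confocal stack acquired, giving exact nuclei
coordinates but no history. Between consecutive frames a cell migrates
a distance comparable to the spacing between cells, cells divide, new
cells enter the vessel from the monolayer at the cell–gel interface,
and cells drift out of focus — so frame-to-frame linking is genuinely
ambiguous and naive nearest-neighbour association fails. `angiotrack`
reconstructs the full cell histories (trajectories and lineage, with
division, monolayer-entry and focus-loss events) by filtering
**backward** from the trustworthy end point, for biologists who need
per-cell migration and proliferation statistics from such assays.

## The method

The system runs four stages:

1. **Registration.** Daily frames are acquired with manual repositioning.
   The four straight edges of the device's trapezoidal post are detected
   with the Hough transform (refined by total-least-squares fits to the
   supporting edge pixels), labelled by geometric role, and intersected;
   the labelled intersections give a closed-form (Procrustes) similarity
   transform onto the end-point frame, with iterative closest point as
   the unlabelled fallback. Pixels on the post side are blanked.
2. **Vessel segmentation.** The cell–gel interface is fitted by a
   parabola `y(x) = a1 (x − a_p + a3)² + a2` (brute-force grid search on
   the gradient-magnitude line integral, anchored at the post apex
   `a_p`); pixels below it are masked; Otsu's threshold, morphological
   closing (disk radius 15), hole filling and an area opening
   (components < 20 000 px removed) give the binary vessel, which is
   reduced to its medial axis transform — centerline chains with
   inscribed-disk radii — supporting reconstruction and arc-length
   ordering.
3. **Detection.** A small CNN (two convolutions of 20 filters, 5×5 and
   10×10, each ReLU + 2×2 max-pool; a 10-unit fully connected layer
   with dropout; 2-way softmax) classifies 100×100 patches as
   cell/non-cell, trained on augmented templates (rotations, flips,
   Gaussian noise; five-fold cross-validation). Because both pools have
   stride 2, dense evaluation over the whole frame is exactly a
   stride-4 sliding window; connected clusters of positive windows
   yield one candidate at the cluster centroid, and candidates outside
   the (dilated) vessel are discarded. The tracker equally accepts
   detection tables from CSV.
4. **Tracking.** One track per end-point nucleus, filtered backward with
   a constant-velocity Kalman filter (Δt = −1 day; χ² validation gate,
   default 5.991). At each step a track hypothesises: association with
   each gated detection, weighted by `|2πS|^(−1/2) exp(−d²/2)`;
   monolayer entry, weighted by the interface prior `(b1 − y)^(−b2)`
   (defaults b1 = 1700 px, b2 = 2.47); or unobserved continuation.
   Hypotheses are kept per track (M = 4 by default, probabilities
   normalised per step), and the jointly most probable consistent
   combination is selected under the biological constraints: at most
   two tracks may share one earlier observation (a division; daughters
   must be adjacent at birth), merged tracks share their earlier
   history, and cells in one vessel branch cannot overtake each other
   along the centerline. Joint selection is exact: exhaustive on small
   instances, a mixed-integer program (HiGHS) over the factorised
   per-track chain sets otherwise. The output is a tracks table and a
   lineage forest with division/entry/focus-loss annotations.

Baselines for comparison: greedy nearest-neighbour linking, backward
Kalman filtering with validation gating (single best observation), and
frame-pair Hungarian assignment on constant-velocity predictions.

Because no image data are deposited with the original study, the
package ships a first-class synthetic generator (`angiotrack.synthgen`)
that emulates the whole acquisition — device post, interface parabola,
branched vessel, nuclei with halos, per-frame misalignment, divisions,
entries, focus loss, detection noise — with ground truth, so every
stage is testable end to end with no downloads.

## Worked example

```python
import numpy as np
from scipy import ndimage
from angiotrack import synthgen as sg, track as tk
from angiotrack.evaluate import association_accuracy, baseline_gated_kf

cfg = sg.SimulationConfig.benchmark(rng_seed=5)
ds = sg.simulate_dataset(cfg, render=False)     # trajectories + detections
truth = ds.truth

# calibrate the tracker to the acquisition's known noise figures
area = float(ndimage.binary_dilation(truth.vessel.mask,
                                     iterations=5).sum())
speed_mean, speed_std = cfg.migration_speed
drift_std = float(np.hypot(speed_std, cfg.speed_jitter_daily))
mht_cfg = tk.MhtConfig.scaled_for_height(
    cfg.image_shape[0], clutter_density=cfg.false_positive_rate / area,
    p_unobserved=0.1, p_division=cfg.division_prob_per_day,
    entry_band=1.3 * cfg.entry_band,
    division_radius=1.5 * cfg.min_cell_separation)
result = tk.run_backward_mht(
    truth.endpoint_cells(), ds.detections, config=mht_cfg,
    vessel=truth.vessel, interface=truth.parabola,
    drift_speed=speed_mean, drift_std=drift_std)

acc = association_accuracy(result.links(), truth.truth_links())
kf = association_accuracy(
    baseline_gated_kf(truth.endpoint_cells(), ds.detections,
                      vessel=truth.vessel, drift_speed=speed_mean,
                      drift_std=drift_std),
    truth.truth_links())
print(f"MHT      {acc.correct}/{acc.total} = {acc.accuracy:.2f}")
print(f"gated KF {kf.correct}/{kf.total} = {kf.accuracy:.2f}")
print("divisions found:", len(result.lineage.division_nodes()))
result.lineage.plot(path="lineage.png")
```

prints:

```
MHT      28/35 = 0.80
gated KF 18/35 = 0.51
divisions found: 2
```

i.e. of the 35 ground-truth backward links in this slot the full
tracker recovers 28 while the single-hypothesis gated filter recovers
18, and the lineage forest contains two division branch points;
`lineage.png` shows the forest with entries as red stars and
out-of-focus frames as green stars.

The synthetic pipeline end to end (simulate → register → segment →
detect → track → evaluate) runs from the shell:

```bash
angiotrack all --out run1 --seed 7
```

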