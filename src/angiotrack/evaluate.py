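"""Detection and association metrics plus baseline associators.

Detection quality is scored by matching detected cell positions against
ground-truth positions within a radius (greedy nearest-pair, one-to-one)
and reporting precision ``TP/(TP+FP)``, recall ``TP/(TP+FN)`` and their
harmonic mean F1.  Association quality is the fraction of ground-truth
backward links (cell at frame k -> its own or its parent's position at
frame k-1, or a monolayer-entry event) that the tracker reproduces.

Three reference associators are provided for comparison with the full
multiple-hypothesis tracker: greedy nearest-neighbour linking, backward
Kalman filtering with validation gating (single best observation, no
branching), and frame-pair Hungarian assignment on constant-velocity
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .track import KalmanParams, Link, kf_gate, kf_predict, kf_update, \
    velocity_init


class UndefinedMetricError(ZeroDivisionError):
    """Precision or recall has a zero denominator."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class AssociationResult:
    correct: int
    total: int

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else float("nan")


def confusion_counts(detections, truth_positions,
                     match_radius: float = 15.0) -> ConfusionCounts:
    """Greedy nearest-pair matching of detections to true positions.

    Candidate pairs within ``match_radius`` are claimed in order of
    increasing distance, each detection and each truth at most once;
    matches are TP, unmatched detections FP, unmatched truths FN.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth_positions, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return ConfusionCounts(TP=0, FP=len(det), FN=len(tru))
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(len(det))
             for j in range(len(tru)) if d[i, j] <= match_radius]
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    return ConfusionCounts(TP=tp, FP=len(det) - tp, FN=len(tru) - tp)


def precision_recall_f1(c: ConfusionCounts):
    """Precision, recall and F1 (fractions in [0, 1])."""
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: no detections")
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: no true positives")
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    if precision + recall == 0:
        return precision, recall, 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def association_accuracy(predicted_links, truth_links,
                         match_radius: float = 15.0) -> AssociationResult:
    """Fraction of ground-truth backward links the tracker reproduces.

    Each truth link at frame k is resolved to the nearest unused
    predicted link at the same frame within ``match_radius`` of the
    cell position.  A ``move``/``div`` truth link is correct when the
    predicted earlier-frame position agrees within ``match_radius``
    (coasted, prediction-only links count on the same terms); an
    ``entry`` truth link requires a predicted entry event.  Division
    links are counted per daughter.
    """
    by_frame: dict = {}
    for i, link in enumerate(predicted_links):
        by_frame.setdefault(link.frame, []).append(i)
    used = set()
    correct = 0
    total = 0
    for tl in truth_links:
        total += 1
        cands = []
        for i in by_frame.get(tl.frame, []):
            if i in used:
                continue
            d = np.hypot(predicted_links[i].pos[0] - tl.pos[0],
                         predicted_links[i].pos[1] - tl.pos[1])
            if d <= match_radius:
                cands.append((d, i))
        if not cands:
            continue
        _, i = min(cands)
        used.add(i)
        pl = predicted_links[i]
        if tl.kind == "entry":
            correct += pl.kind == "entry"
        else:
            if pl.kind == "entry" or pl.prev_pos is None \
                    or tl.prev_pos is None:
                continue
            d = np.hypot(pl.prev_pos[0] - tl.prev_pos[0],
                         pl.prev_pos[1] - tl.prev_pos[1])
            correct += d <= match_radius
    return AssociationResult(correct=int(correct), total=int(total))


# ----------------------------------------------------------------------
# baseline associators
# ----------------------------------------------------------------------

def _frames_xy(detections_per_frame):
    out = []
    for d in detections_per_frame:
        if hasattr(d, "columns"):
            out.append(d[["x", "y"]].to_numpy(dtype=float)
                       if len(d) else np.empty((0, 2)))
        else:
            out.append(np.asarray(d, dtype=float).reshape(-1, 2))
    return out


def baseline_nearest_neighbor(endpoint_cells, detections_per_frame):
    """Backward greedy nearest-neighbour association.

    Going backward one frame at a time, each track (in id order) claims
    the nearest detection not yet claimed in the previous frame and
    jumps to it; tracks left without a detection keep their position.
    """
    dets = _frames_xy(detections_per_frame)
    pos = np.atleast_2d(np.asarray(endpoint_cells, dtype=float)).copy()
    T = len(dets) - 1
    links = []
    for k in range(T, 0, -1):
        cand = dets[k - 1]
        claimed = set()
        for i in range(len(pos)):
            cur = tuple(pos[i])
            if len(cand) == 0:
                links.append(Link(k, cur, "none", cur, i))
                continue
            d = np.linalg.norm(cand - pos[i], axis=1)
            order = np.argsort(d)
            j = next((int(jj) for jj in order if jj not in claimed), None)
            if j is None:
                links.append(Link(k, cur, "none", cur, i))
            else:
                claimed.add(j)
                links.append(Link(k, cur, "obs", tuple(cand[j]), i))
                pos[i] = cand[j]
    return links


def baseline_gated_kf(endpoint_cells, detections_per_frame,
                      params: KalmanParams | None = None,
                      pos_var: float = 4.0, vel_factor: float = 500.0,
                      vessel=None, drift_speed: float = 0.0,
                      drift_std: float | None = None):
    """Backward Kalman filter with validation gating, per track.

    Each track is updated with the single best-matched observation
    (smallest Mahalanobis distance) inside its validation gate; with no
    observation in the gate, no update occurs and the track coasts on
    the prediction.  No branching, entry or division reasoning.
    """
    params = params if params is not None else KalmanParams.default()
    dets = _frames_xy(detections_per_frame)
    states = velocity_init(endpoint_cells, params=params, pos_var=pos_var,
                           vel_factor=vel_factor, vessel=vessel,
                           drift_speed=drift_speed, drift_std=drift_std)
    T = len(dets) - 1
    links = []
    for k in range(T, 0, -1):
        cand = dets[k - 1]
        for i, st in enumerate(states):
            cur = tuple(st.position)
            pred = kf_predict(st, params)
            best = None
            for z in cand:
                g = kf_gate(pred, z, params, track_id=i)
                if g.in_gate and (best is None or g.d2 < best.d2):
                    best = g
            if best is None:
                states[i] = pred
                links.append(Link(k, cur, "none", tuple(pred.position), i))
            else:
                states[i] = kf_update(pred, best, params)
                links.append(Link(k, cur, "obs",
                                  tuple(states[i].position), i))
    return links


def baseline_hungarian(endpoint_cells, detections_per_frame):
    """Frame-pair minimal-cost one-to-one assignment.

    Positions are predicted one frame back with a constant-velocity
    model (velocity from the previous association), the Euclidean
    distance matrix between predictions and detections is solved by the
    Hungarian algorithm, and unmatched tracks carry prediction-only
    links.
    """
    dets = _frames_xy(detections_per_frame)
    pos = np.atleast_2d(np.asarray(endpoint_cells, dtype=float)).copy()
    vel = np.zeros_like(pos)
    T = len(dets) - 1
    links = []
    for k in range(T, 0, -1):
        cand = dets[k - 1]
        pred = pos + vel
        cur = [tuple(p) for p in pos]
        assigned = {}
        if len(cand):
            cost = np.linalg.norm(pred[:, None, :] - cand[None, :, :],
                                  axis=2)
            rows, cols = linear_sum_assignment(cost)
            assigned = dict(zip(rows.tolist(), cols.tolist()))
        for i in range(len(pos)):
            if i in assigned:
                j = assigned[i]
                links.append(Link(k, cur[i], "obs", tuple(cand[j]), i))
                vel[i] = cand[j] - pos[i]
                pos[i] = cand[j]
            else:
                links.append(Link(k, cur[i], "none", tuple(pred[i]), i))
                pos[i] = pred[i]
    return links


def truth_links_from(truth) -> list:
    """Adapter: ground-truth links from a synthetic GroundTruth."""
    return truth.truth_links()


# ----------------------------------------------------------------------
# standard synthetic tracking benchmark
# ----------------------------------------------------------------------

def run_tracking_benchmark(seeds, sim_config=None,
                           params: KalmanParams | None = None,
                           mht_config=None, match_radius: float = 15.0,
                           methods=("nn", "hungarian", "kf", "mht")
                           ) -> dict:
    """Aggregate association accuracy of all associators over seeds.

    For every seed one synthetic slot is simulated (trajectories and
    noisy detections only; no rendering — the tracker operates on
    detection tables), each associator links the end-point cells
    backward, and correct/total link counts are accumulated.  Returns
    ``{method: AssociationResult}``.
    """
    import dataclasses as _dc

    from . import synthgen as _sg
    from .track import MhtConfig, run_backward_mht

    from scipy import ndimage as _ndi

    if sim_config is None:
        sim_config = _sg.SimulationConfig.benchmark()
    params = params if params is not None else KalmanParams.default()
    totals = {m: [0, 0] for m in methods}
    for seed in seeds:
        cfg = _dc.replace(sim_config, rng_seed=int(seed))
        ds = _sg.simulate_dataset(cfg, render=False)
        truth = ds.truth
        endpoint = truth.endpoint_cells()
        tl = truth.truth_links()
        if mht_config is not None:
            mc = mht_config
        else:
            # calibrate the tracker to the acquisition's stated noise
            # figures: false detections land inside the (dilated)
            # vessel, and a present cell goes undetected when missed
            # or out of focus
            area = float(_ndi.binary_dilation(truth.vessel.mask,
                                              iterations=5).sum())
            mc = MhtConfig.scaled_for_height(
                cfg.image_shape[0],
                clutter_density=max(cfg.false_positive_rate, 0.25) / area,
                p_unobserved=min(cfg.false_negative_rate
                                 + cfg.outoffocus_prob, 0.5) or 0.1,
                p_division=max(cfg.division_prob_per_day, 0.02),
                entry_band=1.3 * cfg.entry_band,
                division_radius=1.5 * cfg.min_cell_separation)
        drift = float(cfg.migration_speed[0])
        drift_std = float(np.hypot(cfg.migration_speed[1],
                                   cfg.speed_jitter_daily))
        for m in methods:
            if m == "nn":
                links = baseline_nearest_neighbor(endpoint, ds.detections)
            elif m == "hungarian":
                links = baseline_hungarian(endpoint, ds.detections)
            elif m == "kf":
                links = baseline_gated_kf(endpoint, ds.detections, params,
                                          vessel=truth.vessel,
                                          drift_speed=drift,
                                          drift_std=drift_std)
            else:
                res = run_backward_mht(endpoint, ds.detections,
                                       params=params, config=mc,
                                       vessel=truth.vessel,
                                       interface=truth.parabola,
                                       drift_speed=drift,
                                       drift_std=drift_std)
                links = res.links()
            acc = association_accuracy(links, tl, match_radius)
            totals[m][0] += acc.correct
            totals[m][1] += acc.total
    return {m: AssociationResult(correct=c, total=t)
            for m, (c, t) in totals.items()}
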