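"""Backward multiple-hypothesis Kalman tracking with biological priors.

Tracks are initialised at the end point from the (confocal-derived)
nuclei coordinates — the one time point where every cell is known — and
filtered backward in time (constant-velocity model, Delta-t = -1 day)
against the per-frame detections.  At each backward step every branch
of every track spawns child hypotheses:

* association with each detection inside the chi-squared validation
  gate, weighted by the Gaussian association likelihood
  ``|2*pi*S|^(-1/2) * exp(-d^2/2)``;
* monolayer entry (the track is new, having migrated in from the
  cell-gel interface), weighted by the empirical interface prior
  ``(b1 - y)^(-b2)`` and offered only when the predicted position lies
  within a band above the interface parabola;
* unobserved continuation (out of focus), a configurable constant
  weight.

The weights of a branch's children are normalised to sum to one for
that time step, branches are pruned to the best ``M`` per track, and
after reaching the first frame the jointly most probable consistent
combination of branches is selected.  Consistency encodes the
biological constraints: at most two cells at time k may share one
observation at time k-1 (a division — cells split at most once per
day), and cells in the same vessel branch may not exchange arc-length
order (no overtaking).  Divisions, monolayer entries and focus-loss
events are assembled into a lineage forest.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .vessel import OutOfVesselError, VesselModel, arc_position


class NumericalError(RuntimeError):
    """Singular innovation covariance during gating."""


# ----------------------------------------------------------------------
# Kalman filtering
# ----------------------------------------------------------------------

@dataclass
class KalmanParams:
    """Constant-velocity backward filter matrices and gate threshold.

    ``F`` propagates ``[x, y, vx, vy]`` by ``dt = -1`` day, ``H``
    selects the position, ``Q``/``R`` are the process and observation
    noise covariances, and ``gate_gamma`` is the chi-squared validation
    gate on the squared Mahalanobis distance (default 5.991, the 95th
    percentile with 2 degrees of freedom).
    """

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    gate_gamma: float = 5.991

    def __post_init__(self):
        for name in ("F", "H", "Q", "R"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gate_gamma <= 0:
            raise ValueError("gate_gamma must be positive")

    @classmethod
    def default(cls, q_pos: float = 9.0, q_vel: float = 49.0,
                r: float = 4.0, dt: float = -1.0, gate_gamma: float = 5.991
                ) -> "KalmanParams":
        """Defaults sized to the acquisition: persistent directed
        migration whose effective day-to-day velocity wander —
        intrinsic speed fluctuation plus centerline curvature and
        crowding behind slower neighbours — is of order 7 px/day
        (``q_vel``), with ~3 px of unmodelled lateral jitter
        (``q_pos``) and ~2 px detection noise (``r``)."""
        F = np.array([[1, 0, dt, 0],
                      [0, 1, 0, dt],
                      [0, 0, 1, 0],
                      [0, 0, 0, 1]], dtype=float)
        H = np.array([[1, 0, 0, 0],
                      [0, 1, 0, 0]], dtype=float)
        Q = np.diag([q_pos, q_pos, q_vel, q_vel]).astype(float)
        R = r * np.eye(2)
        return cls(F=F, H=H, Q=Q, R=R, gate_gamma=gate_gamma)


@dataclass
class CellState:
    """State ``[x, y, vx, vy]`` with 4x4 covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(4)
        self.cov = np.asarray(self.cov, dtype=float).reshape(4, 4)

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]


@dataclass
class GateResult:
    innovation: np.ndarray    # 2-vector, z - H x
    S: np.ndarray             # 2x2 innovation covariance
    K: np.ndarray             # 4x2 Kalman gain
    d2: float                 # squared Mahalanobis distance
    in_gate: bool


def kf_predict(state: CellState, params: KalmanParams) -> CellState:
    """Backward prediction: prior mean ``F x`` and covariance
    ``F P F' + Q``."""
    mean = params.F @ state.mean
    cov = params.F @ state.cov @ params.F.T + params.Q
    return CellState(mean=mean, cov=cov)


def kf_gate(pred: CellState, z, params: KalmanParams,
            track_id=None) -> GateResult:
    """Innovation, its covariance, the gain and the Mahalanobis gate."""
    z = np.asarray(z, dtype=float).reshape(2)
    innovation = z - params.H @ pred.mean
    S = params.H @ pred.cov @ params.H.T + params.R
    tag = "" if track_id is None else f" for track {track_id}"
    try:
        Sinv = np.linalg.inv(S)
        Sinv_y = Sinv @ innovation
    except np.linalg.LinAlgError:
        # exactly-determined state (Q = R = 0): the Gaussian is
        # degenerate; the distance is defined only for innovations in
        # the range of S, via the pseudo-inverse
        Sinv = np.linalg.pinv(S, hermitian=True)
        Sinv_y = Sinv @ innovation
        resid = S @ Sinv_y - innovation
        if np.linalg.norm(resid) > 1e-6 * max(
                1.0, np.linalg.norm(innovation)):
            raise NumericalError(
                f"singular innovation covariance{tag}") from None
    if not np.all(np.isfinite(Sinv_y)):
        raise NumericalError(f"singular innovation covariance{tag}")
    K = pred.cov @ params.H.T @ Sinv
    d2 = float(innovation @ Sinv_y)
    return GateResult(innovation=innovation, S=S, K=K, d2=d2,
                      in_gate=d2 < params.gate_gamma)


def kf_update(pred: CellState, gate: GateResult,
              params: KalmanParams | None = None) -> CellState:
    """Posterior mean ``x + K y`` and covariance ``(I - K H) P``."""
    H = params.H if params is not None else np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    mean = pred.mean + gate.K @ gate.innovation
    cov = (np.eye(4) - gate.K @ H) @ pred.cov
    return CellState(mean=mean, cov=cov)


def association_probability(gate: GateResult) -> float:
    """Unnormalised Gaussian association weight
    ``|2 pi S|^(-1/2) exp(-d^2/2)``."""
    det = float(np.linalg.det(2.0 * np.pi * gate.S))
    return math.exp(-0.5 * gate.d2) / math.sqrt(det)


@dataclass
class MhtConfig:
    """Multiple-hypothesis bookkeeping and biological-prior parameters.

    ``M`` branches are kept per track per step.  ``b1`` (pixels) and
    ``b2`` parameterise the monolayer-entry prior ``(b1 - y)^(-b2)``;
    the defaults are the empirical values for the 1532-row acquisition
    geometry — for scenes of other heights use
    :meth:`scaled_for_height`, which keeps the 168-px margin of ``b1``
    above the largest admissible ``y``.

    Branches are scored by per-step Bayes factors so that hypotheses
    of different shapes are comparable: an association contributes the
    Gaussian likelihood divided by ``clutter_density`` (expected false
    detections per pixel squared — dividing by it stops branches that
    wander into empty image regions from collecting free probability),
    a monolayer entry contributes the interface prior times
    ``entry_scale``, and the unobserved/out-of-focus continuation
    contributes the constant ``p_unobserved`` (the probability that a
    present cell yields no detection).  The same weights, normalised
    to sum to one per branch per step, are the reported hypothesis
    probabilities.  Setting ``p_unobserved`` to zero disables coasting
    except as a forced fallback.
    """

    M: int = 4
    b1: float = 1700.0
    b2: float = 2.47
    max_children_per_observation: int = 2
    enforce_ordering: bool = True
    prune_epsilon: float = 1e-6
    entry_band: float = 300.0
    p_unobserved: float = 0.1
    clutter_density: float = 5e-6
    entry_scale: float = 3e6
    p_division: float = 0.2
    division_radius: float = 40.0   # px; max daughter separation at
    #                                 their birth frame
    joint_selection: bool = True
    max_joint_candidates: int = 20000
    arc_max_dist: float = 80.0
    ordering_margin: float = 15.0   # px; tighter pairs are not ordered

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.b2 <= 0:
            raise ValueError("b2 must be positive")

    @classmethod
    def scaled_for_height(cls, image_height: float, **kwargs) -> "MhtConfig":
        kwargs.setdefault("b1", float(image_height) + 168.0)
        return cls(**kwargs)


def monolayer_probability(y_pred: float, config: MhtConfig) -> float:
    """Unnormalised monolayer-entry weight ``(b1 - y)^(-b2)``.

    Cells nearer the cell-gel interface (larger ``y``) are more likely
    to be new tracks.  ``y_pred`` must lie below ``b1``.
    """
    if y_pred >= config.b1:
        raise ValueError(
            f"predicted y={y_pred} is outside the domain (b1={config.b1})")
    return float((config.b1 - y_pred) ** (-config.b2))


# ----------------------------------------------------------------------
# hypothesis branches
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HypothesisBranch:
    """One association history of one track, endpoint backward.

    ``events[s]`` describes the transition from frame ``T - s`` to
    ``T - s - 1``: ``('obs', j)``, ``('entry',)`` (the track is new at
    frame ``T - s``; the branch terminates) or ``('none',)`` (coasting,
    out of focus).  ``states`` holds the per-frame posteriors from the
    endpoint down to the branch's birth frame.  ``log_prob``
    accumulates the log of the per-step normalised probabilities (the
    reported hypothesis probability); ``log_lik`` accumulates the log
    Bayes factors used for pruning and selection (see
    :class:`MhtConfig`).
    """

    track_id: int
    events: tuple = ()
    states: tuple = ()
    log_prob: float = 0.0
    log_lik: float = 0.0
    step_probs: tuple = ()
    step_logws: tuple = ()
    terminated: bool = False

    def position(self, endpoint_frame: int, frame: int):
        idx = endpoint_frame - frame
        if idx < 0 or idx >= len(self.states):
            return None
        return self.states[idx].position

    def birth_frame(self, endpoint_frame: int) -> int:
        return endpoint_frame - len(self.states) + 1


def _event_rank(event):
    if event[0] == "obs":
        return (0, event[1])
    if event[0] == "entry":
        return (1, 0)
    return (2, 0)


def _branch_key(br: HypothesisBranch):
    return (-br.log_lik, tuple(_event_rank(e) for e in br.events))


def _as_xy(detections) -> np.ndarray:
    if isinstance(detections, pd.DataFrame):
        if len(detections) == 0:
            return np.empty((0, 2))
        return detections[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(detections, dtype=float)
    return arr.reshape(-1, 2)


def _interface_y(interface, x: float) -> float:
    if hasattr(interface, "y"):
        return float(interface.y(x))
    if callable(interface):
        return float(interface(x))
    return float(interface)


def expand_hypotheses(branches, detections, params: KalmanParams,
                      config: MhtConfig, interface=None,
                      keep: int | None = None):
    """One backward expansion step for one track.

    Returns ``(new_branches, diagnostics)`` where the diagnostics carry
    the per-branch normalisation sums (each must be 1) and the number
    of admissible children enumerated before pruning.  Terminated
    (entry) branches pass through unchanged and compete with the new
    children for the ``M`` slots.
    """
    dets = _as_xy(detections)
    keep = config.M if keep is None else keep
    new, norm_sums, n_children, forced = [], [], 0, 0
    for br in branches:
        if br.terminated:
            new.append(br)
            continue
        pred = kf_predict(br.states[-1], params)
        cands = []
        for j, z in enumerate(dets):
            g = kf_gate(pred, z, params, track_id=br.track_id)
            if g.in_gate:
                w = association_probability(g) / config.clutter_density
                cands.append((("obs", j), w, kf_update(pred, g, params)))
        if interface is not None and pred.mean[1] < config.b1:
            gap = _interface_y(interface, pred.mean[0]) - pred.mean[1]
            if 0.0 <= gap <= config.entry_band:
                w = config.entry_scale * monolayer_probability(
                    pred.mean[1], config)
                cands.append((("entry",), w, None))
        if config.p_unobserved > 0:
            cands.append((("none",), config.p_unobserved, pred))
        cands = [c for c in cands if c[1] > 0]
        if not cands:   # dead end: coast, flagged
            forced += 1
            new.append(HypothesisBranch(
                br.track_id, br.events + (("none",),),
                br.states + (pred,), br.log_prob, br.log_lik,
                br.step_probs + (1.0,), br.step_logws + (0.0,), False))
            continue
        w = np.array([c[1] for c in cands], dtype=float)
        p = w / w.sum()
        norm_sums.append(float(p.sum()))
        n_children += len(cands)
        for (event, wi, state), pi in zip(cands, p):
            if pi < config.prune_epsilon:
                continue
            terminated = event[0] == "entry"
            states = br.states if terminated else br.states + (state,)
            new.append(HypothesisBranch(
                br.track_id, br.events + (event,), states,
                br.log_prob + math.log(pi),
                br.log_lik + math.log(wi),
                br.step_probs + (pi,),
                br.step_logws + (math.log(wi),), terminated))
    new.sort(key=_branch_key)
    # event-diverse pruning: the best child of each last-event kind is
    # retained ahead of the plain top-M cut, so coast and entry
    # hypotheses survive even when many association chains outscore
    # them individually
    if len(new) > keep:
        picked, seen_last, rest = [], set(), []
        for br in new:
            last = br.events[-1] if br.events else None
            kind = last[0] if last is not None else None
            if kind is not None and kind not in seen_last:
                seen_last.add(kind)
                picked.append(br)
            else:
                rest.append(br)
        picked = picked[:keep]
        for br in rest:
            if len(picked) >= keep:
                break
            picked.append(br)
        picked.sort(key=_branch_key)
        new = picked
    diag = {"norm_sums": norm_sums, "n_children": n_children,
            "forced_coasts": forced}
    return new[:keep], diag


def vessel_tangent(vessel: VesselModel, point, max_dist: float = 80.0,
                   span: int = 3):
    """Unit tangent of the nearest centerline, oriented away from the
    interface (the direction of growing arc length)."""
    try:
        b, _ = arc_position(vessel, point, max_dist=max_dist)
    except OutOfVesselError:
        return None
    chain = vessel.branches[b]
    d = np.linalg.norm(chain - np.asarray(point, dtype=float), axis=1)
    i = int(np.argmin(d))
    a, c = max(i - span, 0), min(i + span, len(chain) - 1)
    if a == c:
        return None
    t = chain[c] - chain[a]
    n = np.linalg.norm(t)
    return t / n if n > 0 else None


def velocity_init(endpoint_cells, detections_prev=None,
                  params: KalmanParams | None = None, pos_var: float = 4.0,
                  vel_factor: float = 500.0,
                  vessel: VesselModel | None = None,
                  drift_speed: float = 0.0, drift_std: float | None = None):
    """Initial states at the end point.

    The confocal end-point coordinates are accurate, so the positional
    variance is small.  By default velocity is initialised to zero
    with a variance ``vel_factor`` times larger, letting the first
    backward update learn it.  When the vessel model and a
    ``drift_speed`` are supplied, the prior instead encodes what is
    known about sprouting migration — cells advance along the
    centerline away from the interface — as a tangent-directed mean
    velocity with standard deviation ``drift_std``, which sharpens the
    otherwise very wide first backward gate.  ``detections_prev`` is
    accepted for interface compatibility but unused.
    """
    del detections_prev, params
    cells = np.atleast_2d(np.asarray(endpoint_cells, dtype=float))
    states = []
    for x, y in cells:
        v = np.zeros(2)
        vel_var = pos_var * vel_factor
        if vessel is not None and drift_speed > 0:
            t = vessel_tangent(vessel, (x, y))
            if t is not None:
                v = drift_speed * t
                if drift_std is not None:
                    vel_var = float(drift_std) ** 2
        P0 = np.diag([pos_var, pos_var, vel_var, vel_var])
        states.append(CellState(mean=np.array([x, y, v[0], v[1]]),
                                cov=P0))
    return states


# ----------------------------------------------------------------------
# joint selection
# ----------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def score_joint(combo, endpoint_frame: int, config: MhtConfig,
                vessel: VesselModel | None = None,
                arc_cache: dict | None = None,
                violators: set | None = None):
    """Score and admissibility of one joint branch combination.

    Walks the backward steps maintaining merge groups: two tracks that
    claim the same observation at a step are, from that frame backward,
    one physical cell (a division seen in reverse), so their subsequent
    events must coincide and their shared step factors are counted
    once, not per track; every merge multiplies the division prior
    ``p_division`` (cells divide at most once per day, so an
    observation may be claimed by at most
    ``max_children_per_observation`` distinct groups).  Cells in the
    same vessel branch must keep their arc-length order between
    consecutive frames (no overtaking).

    Returns ``(score, consistent, n_merges)``; ``score`` is the summed
    log Bayes factors over distinct groups plus the merge penalties.
    Constraint violations subtract a large penalty (rather than
    yielding ``-inf``) so that search can move through and out of
    infeasible combinations; ``consistent`` is True only when there is
    no violation.
    """
    n = len(combo)
    uf = _UnionFind(n)
    arc_cache = {} if arc_cache is None else arc_cache
    log_p_div = math.log(config.p_division)
    violations = 0
    BIG = 1e4

    def arc(ti, frame):
        key = (id(combo[ti]), frame)
        if key not in arc_cache:
            pos = combo[ti].position(endpoint_frame, frame)
            val = None
            if pos is not None and vessel is not None:
                try:
                    val = arc_position(vessel, pos,
                                       max_dist=config.arc_max_dist)
                except OutOfVesselError:
                    val = None
            arc_cache[key] = val
        return arc_cache[key]

    score = 0.0
    n_merges = 0
    max_steps = max((len(br.events) for br in combo), default=0)
    for s in range(max_steps):
        # merged groups must agree on the event (or all be finished)
        groups = {}
        for ti, br in enumerate(combo):
            ev = br.events[s] if s < len(br.events) else None
            groups.setdefault(uf.find(ti), []).append((ti, ev))
        usage = {}
        for root, members in groups.items():
            evs = [ev for _, ev in members]
            if any(e != evs[0] for e in evs):
                violations += 1
                if violators is not None:
                    violators.update(ti for ti, _ in members)
            ev = evs[0]
            if ev is None:
                continue
            # one factor per group (shared factors counted once); the
            # lowest-id member's weight stands for the merged cell
            ti0 = min(ti for ti, _ in members)
            score += combo[ti0].step_logws[s]
            if ev[0] == "obs":
                usage.setdefault(ev[1], []).append(root)
        for roots in usage.values():
            if len(roots) > config.max_children_per_observation:
                violations += len(roots) \
                    - config.max_children_per_observation
                if violators is not None:
                    for r in roots:
                        violators.update(
                            ti for ti in range(n) if uf.find(ti) == r)
            if len(roots) >= 2:
                roots = sorted(roots)
                # daughters sit close together at their birth frame: a
                # Gaussian kernel in their separation favours adjacent
                # siblings over same-file neighbours, with a hard limit
                hi = endpoint_frame - s
                pa = combo[roots[0]].position(endpoint_frame, hi)
                pb = combo[roots[1]].position(endpoint_frame, hi)
                if pa is not None and pb is not None and \
                        np.hypot(*(pa - pb)) > config.division_radius:
                    violations += 1
                    if violators is not None:
                        violators.update(roots[:2])
                for r in roots[1:]:
                    uf.union(roots[0], r)
                score += log_p_div
                n_merges += 1
        if config.enforce_ordering and vessel is not None:
            hi, lo = endpoint_frame - s, endpoint_frame - s - 1
            rep_of: dict = {}
            for ti, br in enumerate(combo):
                if br.position(endpoint_frame, hi) is not None \
                        and br.position(endpoint_frame, lo) is not None:
                    rep_of.setdefault(uf.find(ti), ti)
            # one representative per merged group: a merged pair is one
            # cell and its members' estimates coincide up to noise
            alive = sorted(rep_of.values())
            for a, b in itertools.combinations(alive, 2):
                if uf.find(a) == uf.find(b):
                    continue
                pa_hi, pb_hi = arc(a, hi), arc(b, hi)
                pa_lo, pb_lo = arc(a, lo), arc(b, lo)
                if None in (pa_hi, pb_hi, pa_lo, pb_lo):
                    continue
                if pa_hi[0] != pb_hi[0] or pa_lo[0] != pb_lo[0]:
                    continue
                d_hi = pa_hi[1] - pb_hi[1]
                d_lo = pa_lo[1] - pb_lo[1]
                # estimated positions carry a few px of noise; only
                # clear-cut swaps count as overtaking
                if d_hi * d_lo < 0 and min(abs(d_hi), abs(d_lo)) \
                        > config.ordering_margin:
                    violations += 1
                    if violators is not None:
                        violators.update((a, b))
    return score - BIG * violations, violations == 0, n_merges


def check_joint_consistency(combo, endpoint_frame: int, config: MhtConfig,
                            vessel: VesselModel | None = None,
                            arc_cache: dict | None = None) -> bool:
    """Cross-track admissibility of one branch combination."""
    return score_joint(combo, endpoint_frame, config, vessel,
                       arc_cache)[1]


def _select_joint(track_branches, endpoint_frame: int, config: MhtConfig,
                  vessel: VesselModel | None):
    """Exact joint selection by exhaustive enumeration.

    Evaluates every combination of the per-track branch lists under
    :func:`score_joint` and returns the maximiser; ties resolve to the
    lexicographically first combination in per-track branch order
    (lowest observation index, then lowest track id).  Intended for
    small instances; the caller falls back to the assignment-based
    joint walk when the product of branch counts exceeds
    ``max_joint_candidates``.
    """
    lists = [sorted(bl, key=_branch_key) for bl in track_branches]
    arc_cache: dict = {}
    sizes = [len(bl) for bl in lists]
    best, best_score = None, -np.inf
    evaluated = 0
    for idx in itertools.product(*[range(sz) for sz in sizes]):
        combo = [lists[t][i] for t, i in enumerate(idx)]
        sc = score_joint(combo, endpoint_frame, config, vessel,
                         arc_cache)[0]
        evaluated += 1
        if sc > best_score:
            best, best_score = combo, sc
    if best is None:
        best = [bl[0] for bl in lists]
    return best, best_score > -1e4, evaluated


# ----------------------------------------------------------------------
# joint assignment walk (large instances)
# ----------------------------------------------------------------------

_INF_COST = 1e9


def _candidate_weights(state, dets, params, config, interface):
    """Admissible events for one track at one backward step."""
    pred = kf_predict(state, params)
    out = {}
    for j, z in enumerate(dets):
        g = kf_gate(pred, z, params)
        if g.in_gate:
            w = association_probability(g) / config.clutter_density
            out[("obs", j)] = (math.log(max(w, 1e-300)),
                               kf_update(pred, g, params))
    if interface is not None and pred.mean[1] < config.b1:
        gap = _interface_y(interface, pred.mean[0]) - pred.mean[1]
        if 0.0 <= gap <= config.entry_band:
            w = config.entry_scale * monolayer_probability(pred.mean[1],
                                                           config)
            out[("entry",)] = (math.log(w), None)
    out[("none",)] = (math.log(config.p_unobserved), pred)
    return out


class _Chain:
    """One track's history inside a global hypothesis."""

    __slots__ = ("events", "states", "logws", "terminated")

    def __init__(self, events=(), states=(), logws=(), terminated=False):
        self.events = events
        self.states = states
        self.logws = logws
        self.terminated = terminated

    def extend(self, event, state, logw):
        if event[0] == "entry":
            return _Chain(self.events + (event,), self.states,
                          self.logws + (logw,), True)
        return _Chain(self.events + (event,), self.states + (state,),
                      self.logws + (logw,), False)


def _solve_step(reps, cand, dets_n, config, bans=(), k_best=1):
    """Capacity-2 joint assignment for one step of one hypothesis.

    Rows are the active merge-group representatives; columns are two
    copies of every detection (the second copy costs the division
    prior — a second claimer rides the first claimer's likelihood),
    plus one coast and, where admissible, one entry column per group.
    ``bans`` are (rep, column-kind, j) triples excluded from this
    solve.  Returns up to ``k_best`` assignments ``{rep: column}`` in
    non-increasing quality (Murty partitioning).
    """
    if not reps:
        return []
    cols = []
    for j in range(dets_n):
        cols.append(("c1", j))
        cols.append(("c2", j))
    for i in reps:
        cols.append(("coast", i))
        if ("entry",) in cand[i]:
            cols.append(("entry", i))
    base = np.full((len(reps), len(cols)), _INF_COST)
    log_p_div = math.log(config.p_division)
    banset = set(bans)
    for r, i in enumerate(reps):
        for c, col in enumerate(cols):
            if (i, col[0], col[1]) in banset:
                continue
            if col[0] == "c1" and ("obs", col[1]) in cand[i]:
                base[r, c] = -cand[i][("obs", col[1])][0]
            elif col[0] == "c2" and ("obs", col[1]) in cand[i]:
                base[r, c] = -log_p_div
            elif col[0] == "coast" and col[1] == i:
                base[r, c] = -cand[i][("none",)][0]
            elif col[0] == "entry" and col[1] == i:
                base[r, c] = -cand[i][("entry",)][0]

    def solve(cost):
        rows, colidx = linear_sum_assignment(cost)
        if cost[rows, colidx].max() >= _INF_COST:
            return None, np.inf
        return tuple(colidx), float(cost[rows, colidx].sum())

    sol0, c0 = solve(base)
    if sol0 is None:
        return []
    if k_best <= 1:
        return [{i: cols[sol0[r]] for r, i in enumerate(reps)}]
    # Murty's partitioning for the k best assignments
    results = []
    queue = [(c0, sol0, base)]
    while queue and len(results) < k_best:
        queue.sort(key=lambda x: x[0])
        cost0, sol, mat = queue.pop(0)
        results.append(sol)
        for r in range(len(reps)):
            sub = mat.copy()
            sub[r, sol[r]] = _INF_COST        # ban this pair
            for r2 in range(r):               # fix earlier pairs
                sub[r2, :] = _INF_COST
                sub[r2, sol[r2]] = mat[r2, sol[r2]]
            s2, c2 = solve(sub)
            if s2 is not None and all(s2 != q[1] for q in queue) \
                    and s2 not in results:
                queue.append((c2, s2, sub))
    return [{i: cols[sol[r]] for r, i in enumerate(reps)}
            for sol in results]


def _forced_update(state, z, params):
    pred = kf_predict(state, params)
    g = kf_gate(pred, z, params)
    return kf_update(pred, g, params)


def _apply_assignment(chains, groups, assign, cand, dets, params, config):
    """Apply a group assignment; returns (chains, groups, contribution).

    The event of a group applies to every member; a member's own
    Kalman posterior is kept so merged daughters retain their distinct
    endpoint-side histories.  The deduplicated contribution counts one
    factor per group (its lowest-id member, matching
    :func:`score_joint`) and the division prior once per new merge.
    """
    log_p_div = math.log(config.p_division)
    members: dict = {}
    for ti, g in enumerate(groups):
        members.setdefault(g, []).append(ti)
    new_chains = list(chains)
    new_groups = list(groups)
    contribution = 0.0
    claimers: dict = {}
    for rep, col in assign.items():
        if col[0] in ("c1", "c2"):
            claimers.setdefault(col[1], []).append((col[0], rep))
            continue
        if col[0] == "coast":
            contribution += cand[rep][("none",)][0]
            for ti in members[rep]:
                st = kf_predict(chains[ti].states[-1], params)
                new_chains[ti] = chains[ti].extend(
                    ("none",), st, cand[rep][("none",)][0])
        elif col[0] == "entry":
            contribution += cand[rep][("entry",)][0]
            for ti in members[rep]:
                new_chains[ti] = chains[ti].extend(
                    ("entry",), None, cand[rep][("entry",)][0])
    for j, who in claimers.items():
        who.sort()              # c1 before c2; rep ids ascending
        reps_here = [rep for _, rep in who]
        primary = min(reps_here)
        contribution += cand[primary][("obs", j)][0]
        if len(reps_here) == 2:
            contribution += log_p_div
        for rep in reps_here:
            for ti in members[rep]:
                logw = cand[rep][("obs", j)][0]
                if ti == rep and ("obs", j) in cand[rep]:
                    st = cand[rep][("obs", j)][1]
                else:
                    st = _forced_update(chains[ti].states[-1], dets[j],
                                        params)
                new_chains[ti] = chains[ti].extend(("obs", j), st, logw)
        if len(reps_here) == 2:
            keep = min(reps_here)
            drop = max(reps_here)
            for ti in range(len(new_groups)):
                if new_groups[ti] == drop:
                    new_groups[ti] = keep
    return new_chains, tuple(new_groups), contribution


def _ordering_violations(new_chains, groups, config, vessel, arc_cache):
    """Overtaking pairs introduced by the last step, as rep pairs."""
    if not config.enforce_ordering or vessel is None:
        return []

    def arc(ch, back):
        if len(ch.states) <= back:
            return None
        pos = ch.states[-1 - back].position
        key = (round(pos[0], 1), round(pos[1], 1))
        if key not in arc_cache:
            try:
                arc_cache[key] = arc_position(vessel, pos,
                                              max_dist=config.arc_max_dist)
            except OutOfVesselError:
                arc_cache[key] = None
        return arc_cache[key]

    reps = sorted({g for ti, g in enumerate(groups)
                   if not new_chains[ti].terminated})
    bad = []
    for a, b in itertools.combinations(reps, 2):
        pa_hi, pb_hi = arc(new_chains[a], 1), arc(new_chains[b], 1)
        pa_lo, pb_lo = arc(new_chains[a], 0), arc(new_chains[b], 0)
        if None in (pa_hi, pb_hi, pa_lo, pb_lo):
            continue
        if pa_hi[0] != pb_hi[0] or pa_lo[0] != pb_lo[0]:
            continue
        d_hi = pa_hi[1] - pb_hi[1]
        d_lo = pa_lo[1] - pb_lo[1]
        if d_hi * d_lo < 0 and min(abs(d_hi), abs(d_lo)) \
                > config.ordering_margin:
            bad.append((a, b))
    return bad


def _joint_walk(root_states, dets_per_frame, params, config, vessel,
                interface, endpoint_frame):
    """Backward multiple-hypothesis walk with joint per-step expansion.

    Maintains ``M`` global hypotheses.  Each hypothesis carries one
    Kalman chain per track plus the merge-group structure (two tracks
    that shared an observation are one cell from that frame backward
    and act as a single row from then on).  A step expands a
    hypothesis by solving the capacity-2 assignment of group rows to
    detections/coast/entry columns, by near-best variants of it (one
    chosen pair banned at a time), and by targeted re-solves when an
    assignment introduces overtaking.  Children are scored with the
    deduplicated Bayes factors (division prior per merge) and pruned
    back to the ``M`` most probable distinct event histories.  At the
    first step every track's association weight is evaluated under
    each of its root motion priors and the best is used.
    """
    n = len(root_states)
    chains0 = [_Chain(states=(root_states[i][0],)) for i in range(n)]
    hyps = [(0.0, chains0, tuple(range(n)))]
    arc_cache: dict = {}
    for k in range(endpoint_frame, 0, -1):
        dets = _as_xy(dets_per_frame[k - 1])
        first = k == endpoint_frame
        children: dict = {}
        for score0, chains, groups in hyps:
            reps = sorted({g for ti, g in enumerate(groups)
                           if not chains[ti].terminated})
            cand = {}
            for i in reps:
                if first and len(root_states[i]) > 1:
                    merged: dict = {}
                    for st in root_states[i]:
                        cw = _candidate_weights(st, dets, params, config,
                                                interface)
                        for ev, payload in cw.items():
                            if ev not in merged \
                                    or payload[0] > merged[ev][0]:
                                merged[ev] = payload
                    cand[i] = merged
                else:
                    cand[i] = _candidate_weights(chains[i].states[-1],
                                                 dets, params, config,
                                                 interface)

            k_best = max(2 * config.M, 8) * (4 if first else 1)
            assignments = [(a, ()) for a in _solve_step(
                reps, cand, len(dets), config, k_best=k_best)]
            if not assignments:
                continue

            step_children = []
            for assign, bans in assignments:
                nc, ng, contrib = _apply_assignment(
                    chains, groups, assign, cand, dets, params, config)
                bad = _ordering_violations(nc, ng, config, vessel,
                                           arc_cache)
                # targeted repairs to untangle overtaking: swapping the
                # offending pair's assignments, or banning one of them
                tries = 0
                while bad and tries < 4:
                    a, b = bad[0]
                    repaired = None
                    trial_assignments = []
                    ca, cb = assign.get(a), assign.get(b)
                    swappable = (
                        ca is not None and cb is not None
                        and ca[0] in ("c1", "c2")
                        and cb[0] in ("c1", "c2")
                        and ("obs", ca[1]) in cand[b]
                        and ("obs", cb[1]) in cand[a])
                    if swappable:
                        sw = dict(assign)
                        sw[a], sw[b] = cb, ca
                        trial_assignments.append((sw, bans))
                    for who in (a, b):
                        col = assign.get(who)
                        if col is None or col[0] not in ("c1", "c2"):
                            continue
                        nb = bans + ((who, col[0], col[1]),)
                        vs = _solve_step(reps, cand, len(dets), config,
                                         nb)
                        if vs:
                            trial_assignments.append((vs[0], nb))
                    for v, nb in trial_assignments:
                        nc2, ng2, contrib2 = _apply_assignment(
                            chains, groups, v, cand, dets, params,
                            config)
                        bad2 = _ordering_violations(nc2, ng2, config,
                                                    vessel, arc_cache)
                        if len(bad2) < len(bad) and (
                                repaired is None
                                or contrib2 > repaired[3]):
                            repaired = (nc2, ng2, bad2, contrib2, v, nb)
                    if repaired is None:
                        break
                    nc, ng, bad, contrib, assign, bans = repaired
                    tries += 1
                step_children.append(
                    (score0 + contrib - 1e4 * len(bad), nc, ng))
            for sc, nc, ng in step_children:
                sig = tuple(ch.events for ch in nc)
                if sig not in children or sc > children[sig][0]:
                    children[sig] = (sc, nc, ng)
        if children:
            hyps = sorted(children.values(), key=lambda h: -h[0])
            hyps = hyps[:max(config.M, 1)]
    return hyps[0][0], hyps[0][1]


def _enumerate_chains(root_states, dets_per_frame, params, config,
                      interface, endpoint_frame, per_track_cap=256):
    """All plausible event chains per track (factorised hypothesis set).

    Depth-first expansion from every root motion prior through the
    gated candidates of each backward step; chains are capped per
    track by their own log Bayes factor when the combinatorial count
    exceeds ``per_track_cap``.
    """
    all_chains = []
    for roots in root_states:
        frontier = [_Chain(states=(st,)) for st in roots]
        for k in range(endpoint_frame, 0, -1):
            dets = _as_xy(dets_per_frame[k - 1])
            nxt = []
            for ch in frontier:
                if ch.terminated:
                    nxt.append(ch)
                    continue
                cand = _candidate_weights(ch.states[-1], dets, params,
                                          config, interface)
                for ev, (lw, st) in cand.items():
                    nxt.append(ch.extend(ev, st, lw))
            if len(nxt) > per_track_cap:
                nxt.sort(key=lambda c: -sum(c.logws))
                nxt = nxt[:per_track_cap]
            frontier = nxt
        # deduplicate identical event histories (different roots)
        seen = {}
        for ch in frontier:
            key = ch.events
            if key not in seen or sum(ch.logws) > sum(seen[key].logws):
                seen[key] = ch
        all_chains.append(sorted(seen.values(),
                                 key=lambda c: -sum(c.logws)))
    return all_chains


def _select_ilp(all_chains, endpoint_frame, config, vessel):
    """Joint MAP selection over the factorised chain sets via MILP.

    One binary per candidate chain (exactly one per track); linear
    capacity constraints allow at most two distinct tracks per
    observation; an auxiliary binary per (step, observation) applies
    the division prior and removes the double-counted likelihood when
    an observation is shared.  Pairs of chains that share an
    observation but then follow different histories are excluded (a
    merged pair is one cell).  The overtaking constraint is not
    encoded here; the caller polishes the solution with the exact
    scorer.  Returns the chosen chain per track, or None if the solver
    fails.
    """
    from scipy.optimize import LinearConstraint, milp
    from scipy.sparse import lil_matrix

    n_tracks = len(all_chains)
    x_index = []                       # var -> (track, chain)
    track_vars = []
    for t, chains in enumerate(all_chains):
        track_vars.append([])
        for c, ch in enumerate(chains):
            track_vars[t].append(len(x_index))
            x_index.append((t, c))
    n_x = len(x_index)

    # claims[(s, j)] -> list of (var, logw, track)
    claims: dict = {}
    for t, chains in enumerate(all_chains):
        for c, ch in enumerate(chains):
            v = track_vars[t][c]
            for s, ev in enumerate(ch.events):
                if ev[0] == "obs":
                    claims.setdefault((s, ev[1]), []).append(
                        (v, ch.logws[s], t))
    shared_keys = [key for key, lst in claims.items()
                   if len({t for _, _, t in lst}) >= 2]
    y_of = {key: n_x + i for i, key in enumerate(shared_keys)}
    n_var = n_x + len(shared_keys)

    cost = np.zeros(n_var)
    for t, chains in enumerate(all_chains):
        for c, ch in enumerate(chains):
            cost[track_vars[t][c]] = -sum(ch.logws)
    log_p_div = math.log(config.p_division)
    for key in shared_keys:
        lst = claims[key]
        mean_w = float(np.mean([w for _, w, _ in lst]))
        cost[y_of[key]] = -(log_p_div - mean_w)

    cons = []
    A = lil_matrix((n_tracks, n_var))
    for t in range(n_tracks):
        for v in track_vars[t]:
            A[t, v] = 1.0
    cons.append(LinearConstraint(A.tocsr(), 1.0, 1.0))

    if shared_keys:
        rows = []
        lo, hi = [], []
        B = lil_matrix((2 * len(shared_keys), n_var))
        for i, key in enumerate(shared_keys):
            for v, _, _ in claims[key]:
                B[2 * i, v] = 1.0
                B[2 * i + 1, v] = 1.0
            B[2 * i, y_of[key]] = -1.0       # u - y <= 1
            B[2 * i + 1, y_of[key]] = -2.0   # u - 2y >= 0
            lo += [-np.inf, 0.0]
            hi += [1.0, np.inf]
        cons.append(LinearConstraint(B.tocsr(), lo, hi))

    # merged-equality: chains sharing an observation must share their
    # entire histories from that step backward; valid merges carry the
    # daughter-separation kernel as a pair cost
    forbidden = set()
    for key in shared_keys:
        lst = claims[key]
        s0 = key[0]
        for (va, wa, ta), (vb, wb, tb) in itertools.combinations(lst, 2):
            if ta == tb:
                continue
            ca = all_chains[ta][[i for i, vv in enumerate(track_vars[ta])
                                 if vv == va][0]]
            cb = all_chains[tb][[i for i, vv in enumerate(track_vars[tb])
                                 if vv == vb][0]]
            # find first shared step
            first = None
            for s in range(min(len(ca.events), len(cb.events))):
                if ca.events[s][0] == "obs" \
                        and ca.events[s] == cb.events[s]:
                    first = s
                    break
            if first is None or first != s0:
                continue
            if ca.events[first:] != cb.events[first:]:
                forbidden.add((min(va, vb), max(va, vb)))
                continue
            # daughters must sit close together at the merge frame
            pa = ca.states[min(first, len(ca.states) - 1)].position
            pb = cb.states[min(first, len(cb.states) - 1)].position
            if np.hypot(*(pa - pb)) > config.division_radius:
                forbidden.add((min(va, vb), max(va, vb)))
    if forbidden:
        C = lil_matrix((len(forbidden), n_var))
        for i, (va, vb) in enumerate(sorted(forbidden)):
            C[i, va] = 1.0
            C[i, vb] = 1.0
        cons.append(LinearConstraint(C.tocsr(), -np.inf, 1.0))

    res = milp(c=cost, constraints=cons,
               integrality=np.ones(n_var),
               bounds=(0, 1),
               options={"time_limit": 30.0})
    if res.x is None:
        return None
    combo = [None] * n_tracks
    for t in range(n_tracks):
        vals = [res.x[v] for v in track_vars[t]]
        combo[t] = all_chains[t][int(np.argmax(vals))]
    return combo


def _polish_selection(combo_chains, all_chains, endpoint_frame, config,
                      vessel, track_ids=None):
    """Exact-score coordinate sweeps over the chain sets."""
    branches = [HypothesisBranch(
        track_id=i if track_ids is None else track_ids[i],
        events=ch.events, states=ch.states, step_logws=ch.logws,
        log_lik=float(sum(ch.logws)), terminated=ch.terminated)
        for i, ch in enumerate(combo_chains)]
    lists = [[HypothesisBranch(
        track_id=branches[t].track_id, events=ch.events, states=ch.states,
        step_logws=ch.logws, log_lik=float(sum(ch.logws)),
        terminated=ch.terminated) for ch in chains[:40]]
        for t, chains in enumerate(all_chains)]
    arc_cache: dict = {}

    def sc(combo):
        return score_joint(combo, endpoint_frame, config, vessel,
                           arc_cache)[0]

    best = list(branches)
    best_score = sc(best)
    for _ in range(6):
        improved = False
        for t in range(len(best)):
            for br in lists[t]:
                if br.events == best[t].events:
                    continue
                cand = best[:t] + [br] + best[t + 1:]
                s2 = sc(cand)
                if s2 > best_score:
                    best, best_score = cand, s2
                    improved = True
        if not improved:
            break
    return best, best_score


def _finalize_branch(track_id, chain, dets_per_frame, params, config,
                     interface, endpoint_frame):
    """Normalised per-step probabilities for a walk-built chain."""
    probs, logps = [], 0.0
    for s, ev in enumerate(chain.events):
        state = chain.states[min(s, len(chain.states) - 1)]
        k = endpoint_frame - s
        dets = _as_xy(dets_per_frame[k - 1])
        cand = _candidate_weights(state, dets, params, config, interface)
        if ev not in cand:          # root-prior mismatch; renormalise
            cand[ev] = (chain.logws[s], None)
        ws = np.array([math.exp(min(lw, 300.0)) for lw, _ in cand.values()])
        p = math.exp(min(cand[ev][0], 300.0)) / ws.sum()
        probs.append(min(p, 1.0))
        logps += math.log(max(p, 1e-300))
    return HypothesisBranch(
        track_id=track_id, events=chain.events, states=chain.states,
        log_prob=logps, log_lik=float(sum(chain.logws)),
        step_probs=tuple(probs), step_logws=chain.logws,
        terminated=chain.terminated)


# ----------------------------------------------------------------------
# lineage
# ----------------------------------------------------------------------

@dataclass
class LineageNode:
    node_id: int
    track_ids: list
    start_frame: int
    end_frame: int
    parent: int | None = None
    children: list = field(default_factory=list)
    event: str = "root"           # 'root' | 'entry' | 'division'
    oof_frames: list = field(default_factory=list)


@dataclass
class LineageTree:
    """Forest of track segments with division/entry/focus annotations."""

    nodes: list

    def leaves(self):
        return [n for n in self.nodes if not n.children]

    def division_nodes(self):
        return [n for n in self.nodes if n.children]

    def to_json(self) -> str:
        return json.dumps([{
            "node_id": n.node_id, "track_ids": list(n.track_ids),
            "start_frame": n.start_frame, "end_frame": n.end_frame,
            "parent": n.parent, "children": list(n.children),
            "event": n.event, "oof_frames": list(n.oof_frames),
        } for n in self.nodes], indent=2)

    def plot(self, path=None, ax=None):
        """Lineage plot: lines are tracked cells, branch points are
        divisions, red stars monolayer entries, green stars frames out
        of focus."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ypos = {}
        leaves = self.leaves()
        for i, n in enumerate(leaves):
            ypos[n.node_id] = float(i)
        for n in sorted(self.nodes, key=lambda m: -m.end_frame):
            if n.node_id not in ypos and n.children:
                ypos[n.node_id] = float(np.mean(
                    [ypos[c] for c in n.children if c in ypos]))
        for n in self.nodes:
            y = ypos.get(n.node_id, 0.0)
            ax.plot([n.start_frame, n.end_frame], [y, y], "b-", lw=1.5)
            for c in n.children:
                ax.plot([n.end_frame, n.end_frame],
                        [y, ypos.get(c, y)], "b-", lw=1.0)
            if n.event == "entry":
                ax.plot(n.start_frame, y, "r*", ms=10)
            for f in n.oof_frames:
                ax.plot(f, y, "g*", ms=8)
        ax.set_xlabel("frame (day)")
        ax.set_yticks([])
        ax.set_title("cell lineage")
        if path is not None:
            ax.figure.savefig(path, dpi=120)
            plt.close(ax.figure)
        return ax


def build_lineage(selected, endpoint_frame: int) -> LineageTree:
    """Assemble the lineage forest from the selected branches."""
    n = len(selected)
    uf = _UnionFind(n)
    nodes = [LineageNode(node_id=i, track_ids=[selected[i].track_id],
                         start_frame=endpoint_frame,
                         end_frame=endpoint_frame)
             for i in range(n)]
    current = {i: i for i in range(n)}   # group root -> node id
    next_id = n
    max_steps = max((len(br.events) for br in selected), default=0)
    for s in range(max_steps):
        frame_lo = endpoint_frame - s - 1
        usage = {}
        for ti, br in enumerate(selected):
            if s >= len(br.events):
                continue
            ev = br.events[s]
            root = uf.find(ti)
            node = nodes[current[root]]
            if ev[0] == "entry":
                node.start_frame = endpoint_frame - s
                node.event = "entry"
            else:
                node.start_frame = frame_lo
                if ev[0] == "none":
                    if frame_lo not in node.oof_frames:
                        node.oof_frames.append(frame_lo)
                else:
                    usage.setdefault((ev[1],), set()).add(root)
        for roots in usage.values():
            roots = sorted(roots)
            if len(roots) >= 2:
                parent = LineageNode(node_id=next_id, track_ids=[],
                                     start_frame=frame_lo,
                                     end_frame=frame_lo, event="root")
                for r in roots:
                    child = nodes[current[r]]
                    child.parent = parent.node_id
                    child.start_frame = endpoint_frame - s
                    if child.event == "root":
                        child.event = "division"
                    parent.children.append(child.node_id)
                    parent.track_ids += child.track_ids
                nodes.append(parent)
                base = roots[0]
                for r in roots[1:]:
                    uf.union(base, r)
                current[uf.find(base)] = parent.node_id
                next_id += 1
    return LineageTree(nodes=nodes)


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

@dataclass
class Link:
    """One recovered backward association at ``frame`` -> ``frame-1``."""

    frame: int
    pos: tuple
    kind: str                 # 'obs' | 'entry' | 'none'
    prev_pos: tuple | None
    track_id: int = -1


@dataclass
class TrackingResult:
    endpoint_frame: int
    selected: list
    track_branches: list
    lineage: LineageTree
    diagnostics: dict

    def links(self) -> list:
        out = []
        for br in self.selected:
            for s, ev in enumerate(br.events):
                frame = self.endpoint_frame - s
                pos = tuple(br.states[s].position)
                if ev[0] == "entry":
                    out.append(Link(frame, pos, "entry", None, br.track_id))
                else:
                    prev = tuple(br.states[s + 1].position)
                    out.append(Link(frame, pos, ev[0], prev, br.track_id))
        return out

    def to_table(self) -> pd.DataFrame:
        rows = []
        for br in self.selected:
            for s, st in enumerate(br.states):
                frame = self.endpoint_frame - s
                event = br.events[s][0] if s < len(br.events) else ""
                rows.append({"frame": frame, "track_id": br.track_id,
                             "x": st.mean[0], "y": st.mean[1],
                             "event": event,
                             "probability": math.exp(br.log_prob)})
        return pd.DataFrame(rows).sort_values(
            ["track_id", "frame"]).reset_index(drop=True)


def run_backward_mht(endpoint_cells, detections_per_frame,
                     params: KalmanParams | None = None,
                     config: MhtConfig | None = None,
                     vessel: VesselModel | None = None,
                     interface=None, pos_var: float = 4.0,
                     vel_factor: float = 500.0, drift_speed: float = 0.0,
                     drift_std: float | None = None) -> TrackingResult:
    """Track every end-point cell backward to the first frame.

    ``detections_per_frame`` is one table or ``(n, 2)`` array per frame
    (index = frame; the end-point frame's detections are unused since
    tracks start from the exact end-point coordinates).  Returns the
    selected hypotheses, the lineage forest, and diagnostics including
    the per-branch normalisation sums and the number of hypotheses
    enumerated at the final expansion.
    """
    params = params if params is not None else KalmanParams.default()
    config = config if config is not None else MhtConfig()
    cells = np.atleast_2d(np.asarray(endpoint_cells, dtype=float))
    if cells.size == 0:
        raise ValueError("need at least one end-point cell")
    t = len(detections_per_frame)
    if t < 2:
        raise ValueError("need at least two frames")
    T = t - 1
    states = velocity_init(cells, params=params, pos_var=pos_var,
                           vel_factor=vel_factor, vessel=vessel,
                           drift_speed=drift_speed, drift_std=drift_std)
    tracks = [[HypothesisBranch(track_id=i, states=(st,))]
              for i, st in enumerate(states)]
    root_states = [[br.states[0] for br in bl] for bl in tracks]
    diag = {"norm_sums": [], "per_step_children": [], "forced_coasts": 0}
    for k in range(T, 0, -1):
        dets = detections_per_frame[k - 1]
        step_children = 0
        for i in range(len(tracks)):
            tracks[i], d = expand_hypotheses(tracks[i], dets, params,
                                             config, interface=interface)
            step_children += d["n_children"]
            diag["norm_sums"] += d["norm_sums"]
            diag["forced_coasts"] += d["forced_coasts"]
        diag["per_step_children"].append(step_children)
    diag["n_final_hypotheses"] = diag["per_step_children"][-1] if T else 0
    if not config.joint_selection:
        selected = [sorted(bl, key=_branch_key)[0] for bl in tracks]
        diag["joint_selection_ok"] = True
    else:
        n_combos = 1
        for bl in tracks:
            n_combos *= len(bl)
            if n_combos > config.max_joint_candidates:
                break
        if n_combos <= config.max_joint_candidates:
            selected, ok, examined = _select_joint(tracks, T, config,
                                                   vessel)
            diag["joint_selection_ok"] = ok
            diag["joint_candidates_examined"] = examined
            diag["joint_selection_mode"] = "exhaustive"
        else:
            all_chains = _enumerate_chains(root_states,
                                           detections_per_frame, params,
                                           config, interface, T)
            combo = _select_ilp(all_chains, T, config, vessel)
            if combo is not None:
                polished, score = _polish_selection(combo, all_chains, T,
                                                    config, vessel)
                chains = [_Chain(events=b.events, states=b.states,
                                 logws=b.step_logws,
                                 terminated=b.terminated)
                          for b in polished]
                diag["joint_selection_mode"] = "milp"
            else:   # solver failure: fall back to the assignment walk
                score, chains = _joint_walk(root_states,
                                            detections_per_frame, params,
                                            config, vessel, interface, T)
                diag["joint_selection_mode"] = "assignment-walk"
            selected = [_finalize_branch(i, ch, detections_per_frame,
                                         params, config, interface, T)
                        for i, ch in enumerate(chains)]
            diag["joint_selection_ok"] = score > -1e4
            diag["joint_score"] = float(score)
    lineage = build_lineage(selected, T)
    return TrackingResult(endpoint_frame=T, selected=selected,
                          track_branches=tracks, lineage=lineage,
                          diagnostics=diag)
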