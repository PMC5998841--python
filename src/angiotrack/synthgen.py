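"""Synthetic angiogenesis time-lapse benchmark generator.

Emulates the data the tracking system consumes: daily phase-contrast
frames of an angiogenic sprout in a microfluidic device, end-point
nuclei coordinates, per-frame detections, and full ground truth.  The
scene contains a trapezoidal post (four straight edges used as
registration landmarks), a parabola-bounded cell-gel interface with a
textured monolayer below it, a branched vessel region above it, and
dark elliptical cell nuclei surrounded by bright halo rings.  Frames
are misaligned by per-frame similarity transforms, mimicking manual
daily acquisition.

The simulated biology follows the priors the tracker encodes: cells
migrate along the vessel centerline and cannot overtake one another,
divide at most once per day, enter the vessel from the monolayer in a
band above the interface, and may drift out of focus (their detections
stop while the cells persist).  Migration statistics are invented —
the defaults (40 +/- 15 px/day along the centerline at 20x, i.e. a few
cell diameters) are documented in the methods note and exposed in
:class:`SimulationConfig`.

Coordinates are pixels, origin top-left, ``x`` the column, ``y`` the
row; the monolayer sits at large ``y``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import transform as sktransform
from scipy import ndimage as ndi

from .registration import LineSet, SimilarityTransform
from .vessel import ParabolaParams, VesselModel


class InvalidConfigError(ValueError):
    """Simulation configuration that cannot produce a valid scene."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic device slot.

    Image geometry defaults to the 1532 x 2048 px acquisition at 20x
    with one frame per day.  Probabilities are per day; rates are
    expected counts per day.
    """

    image_shape: tuple = (1532, 2048)
    n_frames: int = 4
    n_initial_cells: int = 8
    migration_speed: tuple = (60.0, 22.0)     # px/day (mean, std across cells)
    speed_jitter_daily: float = 4.5           # px/day, day-to-day wander
    division_prob_per_day: float = 0.1
    monolayer_entry_rate: float = 1.0         # expected new cells/day
    outoffocus_prob: float = 0.05             # per cell per day
    detection_noise_sigma: float = 3.0        # px
    false_positive_rate: float = 1.0          # expected FP/frame
    false_negative_rate: float = 0.05         # per in-focus cell
    misalignment_scale: tuple = (0.97, 1.03)
    misalignment_rotation: float = 0.03       # +/- rad
    misalignment_translation: float = 20.0    # +/- px
    rng_seed: int = 0
    # geometry / appearance (the morphology is invented; see docs)
    vessel_radius: float = 38.0
    vessel_length_frac: float = 0.45
    n_vessel_branches: int = 1
    interface_y_frac: float = 0.72
    interface_curvature: float = -0.8e-4
    entry_band: float = 225.0                 # px above the interface
    cell_radius: float = 13.5                 # nucleus semi-axis, px
    halo_width: float = 6.0
    min_cell_separation: float = 45.0
    template_size: int = 100

    @classmethod
    def benchmark(cls, **kwargs) -> "SimulationConfig":
        """Standard scaled-down study conditions (2/3 linear scale).

        The geometry, migration statistics and event rates of the full
        acquisition shrunk to a 1024 x 1365 px scene, used by the
        tracking benchmark, the detector suite and the acceptance
        checks so that runs stay desk-sized.
        """
        base = dict(image_shape=(1024, 1365), n_frames=4,
                    n_initial_cells=6, migration_speed=(40.0, 15.0),
                    speed_jitter_daily=3.0, division_prob_per_day=0.1,
                    detection_noise_sigma=2.0, vessel_radius=25.0,
                    interface_curvature=-1.2e-4, entry_band=150.0,
                    cell_radius=9.0, halo_width=4.0,
                    min_cell_separation=30.0)
        base.update(kwargs)
        return cls(**base)

    def __post_init__(self):
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise InvalidConfigError("image_shape must be positive")
        if self.n_frames < 2:
            raise InvalidConfigError("need at least 2 frames")
        for name in ("division_prob_per_day", "outoffocus_prob",
                     "false_negative_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.vessel_length_frac * h * 2 * self.vessel_radius <= 0:
            raise InvalidConfigError("zero-area vessel")
        if self.vessel_length_frac <= 0 or self.vessel_radius <= 0:
            raise InvalidConfigError("zero-area vessel")


@dataclass
class TrackTruth:
    """Ground-truth history of one cell."""

    track_id: int
    parent_id: int | None
    birth_frame: int
    birth_event: str                  # 'initial' | 'division' | 'entry'
    pos: dict = field(default_factory=dict)   # frame -> (x, y)
    arc: dict = field(default_factory=dict)   # frame -> (path_id, s)
    oof_frame: int | None = None
    end_frame: int | None = None      # last frame with a position

    def in_focus(self, frame: int) -> bool:
        return self.oof_frame is None or frame < self.oof_frame


@dataclass
class TruthLink:
    """One backward association the tracker should recover.

    A link at ``frame k`` states where the cell at ``pos`` came from:
    its own (or its parent's) position at ``k - 1`` for kind
    ``'move'``/``'div'``, or the monolayer for kind ``'entry'``.
    """

    frame: int
    pos: tuple
    kind: str             # 'move' | 'div' | 'entry'
    prev_pos: tuple | None


@dataclass
class GroundTruth:
    config: SimulationConfig
    vessel: VesselModel
    parabola: ParabolaParams
    tracks: dict
    paths: list = field(default_factory=list, repr=False)
    transforms: list | None = None

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def positions(self, frame: int, include_oof: bool = True):
        ids, pts = [], []
        for tid, tr in sorted(self.tracks.items()):
            if frame in tr.pos and (include_oof or tr.in_focus(frame)):
                ids.append(tid)
                pts.append(tr.pos[frame])
        return ids, np.array(pts).reshape(-1, 2)

    def endpoint_cells(self) -> np.ndarray:
        """End-point nuclei coordinates (confocal stand-in, exact)."""
        _, pts = self.positions(self.n_frames - 1, include_oof=True)
        return pts

    def truth_links(self) -> list:
        links = []
        for tid, tr in sorted(self.tracks.items()):
            for k in sorted(tr.pos):
                if k == 0:
                    continue
                if tr.birth_frame == k:
                    if tr.birth_event == "entry":
                        links.append(TruthLink(k, tr.pos[k], "entry", None))
                    elif tr.birth_event == "division":
                        par = self.tracks[tr.parent_id]
                        links.append(TruthLink(k, tr.pos[k], "div",
                                               par.pos[k - 1]))
                else:
                    links.append(TruthLink(k, tr.pos[k], "move",
                                           tr.pos[k - 1]))
        return links

    def n_leaves(self) -> int:
        """Tracks that persist to the final frame (lineage leaves)."""
        last = self.n_frames - 1
        return sum(1 for tr in self.tracks.values() if last in tr.pos)

    def to_frame_table(self) -> pd.DataFrame:
        rows = []
        for tid, tr in sorted(self.tracks.items()):
            for k in sorted(tr.pos):
                x, y = tr.pos[k]
                event = ""
                if k == tr.birth_frame and tr.birth_event != "initial":
                    event = tr.birth_event
                if tr.oof_frame is not None and k >= tr.oof_frame:
                    event = (event + "+oof").lstrip("+")
                rows.append({"frame": k, "track_id": tid,
                             "parent_id": -1 if tr.parent_id is None
                             else tr.parent_id,
                             "x": x, "y": y, "event": event})
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# vessel geometry
# ----------------------------------------------------------------------

def _walk(rng, start, heading, length, step=4.0, wiggle=0.015,
          clamp=0.35):
    pts = [np.asarray(start, dtype=float)]
    h0 = heading
    n = max(int(length / step), 2)
    for _ in range(n):
        heading += rng.normal(0.0, wiggle)
        heading = np.clip(heading, h0 - clamp, h0 + clamp)
        pts.append(pts[-1] + step * np.array([np.cos(heading),
                                              np.sin(heading)]))
    return np.array(pts), heading


def simulate_vessel(config: SimulationConfig, rng=None):
    """Generate a branched vessel rooted at the interface parabola.

    Returns ``(VesselModel, ParabolaParams)``.  The centerline is a
    random smooth walk growing away from the interface (decreasing
    ``y``); optional side branches fork from the trunk.  The binary
    mask is the union of tapered disks along the centerlines, clipped
    to the region above the parabola.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_shape
    ap = w / 2.0
    parabola = ParabolaParams(a1=config.interface_curvature,
                              a2=config.interface_y_frac * h,
                              a3=0.0, ap=ap)
    x0 = ap + rng.uniform(-0.12, 0.12) * w
    start = np.array([x0, parabola.y(x0)])
    length = config.vessel_length_frac * h
    trunk, _ = _walk(rng, start, -np.pi / 2 + rng.normal(0, 0.1), length)
    branches = [trunk]
    junctions = []
    for _ in range(config.n_vessel_branches):
        j = int(len(trunk) * rng.uniform(0.4, 0.6))
        side_heading = -np.pi / 2 + rng.choice([-1.0, 1.0]) \
            * (0.55 + rng.uniform(0.0, 0.25))
        side, _ = _walk(rng, trunk[j], side_heading, 0.5 * length)
        branches.append(side)
        junctions.append(trunk[j])

    mask = np.zeros((h, w), dtype=bool)
    for chain in branches:
        n = len(chain)
        for i, (x, y) in enumerate(chain):
            r = max(config.vessel_radius * (1.0 - 0.25 * i / n), 10.0)
            rr, cc = skdraw.disk((y, x), r, shape=(h, w))
            mask[rr, cc] = True
    ys = parabola.y(np.arange(w))
    mask[np.arange(h)[:, None] > ys[None, :]] = False
    if not mask.any():
        raise InvalidConfigError("configuration produced a zero-area vessel")
    radii = []
    for chain in branches:
        n = len(chain)
        radii.append(np.maximum(
            config.vessel_radius * (1.0 - 0.25 * np.arange(n) / n), 10.0))
    vessel = VesselModel(mask=mask, branches=branches, radii=radii,
                         junctions=np.array(junctions).reshape(-1, 2))
    return vessel, parabola


# ----------------------------------------------------------------------
# trajectory simulation
# ----------------------------------------------------------------------

class _Path:
    """A root-to-leaf centerline with arc-length parametrisation."""

    def __init__(self, points):
        self.points = np.asarray(points, dtype=float)
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.arcs = np.concatenate([[0.0], np.cumsum(steps)])
        self.length = float(self.arcs[-1])

    def at(self, s, lateral=0.0):
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arcs, s, side="right")) - 1
        i = min(max(i, 0), len(self.points) - 2)
        seg = self.points[i + 1] - self.points[i]
        seglen = np.linalg.norm(seg)
        t = 0.0 if seglen == 0 else (s - self.arcs[i]) / seglen
        p = self.points[i] + t * seg
        tangent = seg / max(seglen, 1e-9)
        normal = np.array([-tangent[1], tangent[0]])
        return p + lateral * normal


def _build_paths(vessel: VesselModel):
    """Root-to-leaf paths; side branches are grafted onto the trunk."""
    trunk = vessel.branches[0]
    paths = [_Path(trunk)]
    shared = {}
    trunk_arcs = _Path(trunk).arcs
    for b in range(1, len(vessel.branches)):
        side = vessel.branches[b]
        d = np.linalg.norm(trunk - side[0], axis=1)
        j = int(np.argmin(d))
        pts = np.vstack([trunk[:j + 1], side])
        paths.append(_Path(pts))
        shared[(0, b)] = float(trunk_arcs[j])
    # shared trunk length between any two side paths
    for a in range(1, len(paths)):
        for b in range(a + 1, len(paths)):
            shared[(a, b)] = min(shared[(0, a)], shared[(0, b)])
    return paths, shared


def _ordered_pair(shared, pa, sa, pb, sb):
    """Whether two cells are order-constrained (same or shared segment)."""
    if pa == pb:
        return True
    key = (min(pa, pb), max(pa, pb))
    lim = shared.get(key, 0.0)
    return sa <= lim and sb <= lim


def simulate_trajectories(config: SimulationConfig, vessel: VesselModel,
                          parabola: ParabolaParams | None = None,
                          rng=None) -> GroundTruth:
    """Forward-time cell simulation constrained to the vessel.

    Migration is persistent and directed, as in sprouting endothelium:
    each cell draws a base outward speed once (``migration_speed``
    gives its mean and cell-to-cell spread) and advances along its
    root-to-leaf path by that speed plus a small daily wander
    (``speed_jitter_daily``) and lateral jitter; moves are clamped so
    that co-resident cells never exchange arc-length order or overlap.
    Divisions (at most one per cell per day) replace the parent by two
    daughters at a nucleus-diameter arc offset, inheriting its speed;
    monolayer entries spawn near the path root (within the configured
    band above the interface) with fresh speeds; out-of-focus cells
    stop emitting detections but keep migrating in the truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if parabola is None:
        h, w = config.image_shape
        parabola = ParabolaParams(a1=config.interface_curvature,
                                  a2=config.interface_y_frac * h,
                                  a3=0.0, ap=w / 2.0)
    paths, shared = _build_paths(vessel)
    mean, std = config.migration_speed
    sep = max(config.min_cell_separation, 4.0)

    tracks: dict[int, TrackTruth] = {}
    live: dict[int, dict] = {}      # track_id -> {path, s, lat}
    next_id = 0

    def record(tid, frame):
        st = live[tid]
        p = paths[st["path"]].at(st["s"], st["lat"])
        tracks[tid].pos[frame] = (float(p[0]), float(p[1]))
        tracks[tid].arc[frame] = (st["path"], float(st["s"]))
        tracks[tid].end_frame = frame

    def spawn(frame, parent, event, path, s, lat, speed=None):
        nonlocal next_id
        tid = next_id
        next_id += 1
        if speed is None:
            speed = max(rng.normal(mean, std), 5.0)
        tracks[tid] = TrackTruth(track_id=tid, parent_id=parent,
                                 birth_frame=frame, birth_event=event)
        live[tid] = {"path": path, "s": float(s), "lat": float(lat),
                     "v": float(speed)}
        record(tid, frame)
        return tid

    # --- frame 0: seed cells with minimum separation ------------------
    # leave headroom so no cell reaches the end of the modelled
    # centerline within the study window (the real sprout elongates at
    # tip speed; a hard stop at the chain end would be an artefact)
    headroom = (config.n_frames - 1) * (mean + std)
    placed = []
    for _ in range(config.n_initial_cells):
        for _try in range(200):
            path = int(rng.integers(len(paths)))
            s_hi = max(paths[path].length - 8.0 - headroom,
                       0.3 * paths[path].length)
            # resident sprout cells sit above the monolayer margin;
            # the band next to the interface is where entries appear
            s_lo = min(0.6 * config.entry_band, 0.5 * s_hi)
            s = rng.uniform(s_lo, s_hi)
            ok = all(abs(s - s2) >= sep or not
                     _ordered_pair(shared, path, s, p2, s2)
                     for p2, s2 in placed)
            if ok:
                break
        placed.append((path, s))
        spawn(0, None, "initial", path, s,
              rng.normal(0.0, 0.2 * config.vessel_radius))

    # tip cells are the most migratory: re-rank the drawn speeds so
    # that, within each ordered file, the cell farther from the
    # interface is the faster one — single-file migration without
    # pile-ups, with distinct per-cell speeds
    order = sorted(live, key=lambda t: -live[t]["s"])
    speeds = sorted((live[t]["v"] for t in live), reverse=True)
    for t, v in zip(order, speeds):
        live[t]["v"] = v

    # --- daily evolution ---------------------------------------------
    for k in range(1, config.n_frames):
        # move front-to-back so order clamping is one-sided
        order = sorted(live, key=lambda t: -live[t]["s"])
        prev = {t: dict(live[t]) for t in live}
        moved = []
        for tid in order:
            st = live[tid]
            ds = rng.normal(st["v"], config.speed_jitter_daily)
            new_s = float(np.clip(st["s"] + ds, 1.0,
                                  paths[st["path"]].length - 2.0))
            gap = 0.8 * sep   # nuclei have physical extent; no overlap
            for t2 in moved:
                st2, pv2 = live[t2], prev[t2]
                if _ordered_pair(shared, st["path"], prev[tid]["s"],
                                 pv2["path"], pv2["s"]) \
                        and pv2["s"] > prev[tid]["s"]:
                    new_s = min(new_s, st2["s"] - gap)
            st["s"] = max(new_s, 0.5)
            st["lat"] = float(np.clip(
                st["lat"] + rng.normal(0.0, 0.08 * config.vessel_radius),
                -0.5 * config.vessel_radius, 0.5 * config.vessel_radius))
            moved.append(tid)

        # divisions: parent ends at k-1, daughters appear at k
        for tid in list(live):
            if tracks[tid].birth_frame == k:
                continue
            if rng.random() < config.division_prob_per_day:
                st = live.pop(tid)
                # daughter nuclei appear adjacent, about one nucleus
                # diameter apart, centred on the parent position
                off = 1.3 * config.cell_radius
                for d_off in (off, -off):
                    spawn(k, tid, "division", st["path"],
                          max(st["s"] + d_off, 0.5), st["lat"],
                          speed=max(st["v"] + rng.normal(0.0, 4.0), 5.0))
            else:
                record(tid, k)

        # monolayer entries near the interface band
        for _ in range(rng.poisson(config.monolayer_entry_rate)):
            path = int(rng.integers(len(paths)))
            s = rng.uniform(2.0, max(0.6 * config.entry_band, 10.0))
            for _try in range(20):   # keep clear of resident nuclei
                if all(abs(s - st2["s"]) >= 0.6 * sep or not
                       _ordered_pair(shared, path, s, st2["path"],
                                     st2["s"])
                       for st2 in live.values()):
                    break
                s = rng.uniform(2.0, max(0.6 * config.entry_band, 10.0))
            ahead = [st2["v"] for st2 in live.values()
                     if _ordered_pair(shared, path, s, st2["path"],
                                      st2["s"]) and st2["s"] > s]
            v_entry = None
            if ahead:
                v_entry = max(min(ahead) - abs(rng.normal(4.0, 3.0)), 5.0)
            spawn(k, None, "entry", path, s,
                  rng.normal(0.0, 0.2 * config.vessel_radius),
                  speed=v_entry)

        # out-of-focus transitions
        for tid in live:
            tr = tracks[tid]
            if tr.oof_frame is None and tr.birth_frame < k \
                    and rng.random() < config.outoffocus_prob:
                tr.oof_frame = k

    return GroundTruth(config=config, vessel=vessel, parabola=parabola,
                       tracks=tracks, paths=paths)


# ----------------------------------------------------------------------
# detections
# ----------------------------------------------------------------------

def emulate_detections(truth: GroundTruth, config: SimulationConfig,
                       rng=None) -> list:
    """Noisy detection tables, one DataFrame per frame.

    In-focus ground-truth positions are jittered by the detection noise,
    dropped with the false-negative rate, and contaminated by a Poisson
    number of false positives placed uniformly inside the (dilated)
    vessel mask.  Coordinates are in the registered reference system.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    dil = ndi.binary_dilation(truth.vessel.mask, iterations=5)
    fp_rows, fp_cols = np.nonzero(dil)
    out = []
    for k in range(config.n_frames):
        _, pts = truth.positions(k, include_oof=False)
        rows = []
        for x, y in pts:
            if rng.random() < config.false_negative_rate:
                continue
            rows.append((k, x + rng.normal(0, config.detection_noise_sigma),
                         y + rng.normal(0, config.detection_noise_sigma),
                         1.0))
        for _ in range(rng.poisson(config.false_positive_rate)):
            i = int(rng.integers(len(fp_rows)))
            rows.append((k, float(fp_cols[i]), float(fp_rows[i]), 1.0))
        out.append(pd.DataFrame(rows, columns=["frame", "x", "y", "score"]))
    return out


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _hesse(p1, p2):
    """Hesse normal form of the line through two points (skimage range)."""
    d = np.asarray(p2, float) - np.asarray(p1, float)
    n = np.array([d[1], -d[0]])
    n = n / np.linalg.norm(n)
    theta = np.arctan2(n[1], n[0])
    rho = float(n @ np.asarray(p1, float))
    if theta >= np.pi / 2:
        theta -= np.pi
        rho = -rho
    elif theta < -np.pi / 2:
        theta += np.pi
        rho = -rho
    return rho, theta


def post_geometry(config: SimulationConfig):
    """Trapezoidal post corners and the analytic post-edge lines.

    Corner layout (x, y): top-left, top-right, bottom-right,
    bottom-left.  Line labels: 1 = left slant (through TL/BL),
    2 = top (TL/TR), 3 = bottom (BL/BR), 4 = right slant (TR/BR).
    The extended lines 1 and 4 intersect at the apex above the top
    edge, whose x-coordinate ``a_p`` anchors the interface parabola.
    """
    h, w = config.image_shape
    cx = w / 2.0
    y_top, y_bot = 0.76 * h, 0.92 * h
    tl = (cx - 0.25 * w, y_top)
    tr = (cx + 0.25 * w, y_top)
    br = (cx + 0.32 * w, y_bot)
    bl = (cx - 0.32 * w, y_bot)
    corners = np.array([tl, tr, br, bl])
    r1, t1 = _hesse(tl, bl)
    r2, t2 = _hesse(tl, tr)
    r3, t3 = _hesse(bl, br)
    r4, t4 = _hesse(tr, br)
    lines = LineSet(rho=[r1, r2, r3, r4], theta=[t1, t2, t3, t4])
    return corners, lines


def render_scene(truth: GroundTruth, frame: int, rng=None,
                 pad: int = 0) -> np.ndarray:
    """Render one frame in the reference coordinate system.

    With ``pad > 0`` the scene is rendered on a canvas extended by
    ``pad`` pixels on every side (the device extends beyond the field
    of view), so that misaligned frames resampled from it contain no
    empty border.  Reference coordinate ``(x, y)`` maps to canvas pixel
    ``(x + pad, y + pad)``.
    """
    config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 100 + frame)
    h, w = config.image_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    img = np.full((hp, wp), 0.5)
    img += 0.03 * ((np.arange(wp) - pad) / w)[None, :]  # illumination ramp
    img += rng.normal(0.0, 0.02, (hp, wp))

    # monolayer below the interface parabola
    ys = truth.parabola.y(np.arange(wp) - pad)
    below = (np.arange(hp) - pad)[:, None] > ys[None, :]
    img[below] += 0.08
    n_blobs = max(int(below.sum() / 4000), 1)
    rows, cols = np.nonzero(below)
    if len(rows):
        pick = rng.integers(len(rows), size=n_blobs)
        for i in pick:
            rr, cc = skdraw.disk((rows[i], cols[i]),
                                 rng.uniform(3, 6), shape=(hp, wp))
            img[rr, cc] -= 0.18

    img[pad:pad + h, pad:pad + w][truth.vessel.mask] += 0.20

    # trapezoidal post (dark) -> four high-contrast straight edges
    corners, _ = post_geometry(config)
    rr, cc = skdraw.polygon(corners[:, 1] + pad, corners[:, 0] + pad,
                            shape=(hp, wp))
    img[rr, cc] = 0.12

    # cells: bright halo ring around a dark elliptical nucleus
    a = config.cell_radius
    for tid, tr in sorted(truth.tracks.items()):
        if frame not in tr.pos:
            continue
        x, y = tr.pos[frame]
        x, y = x + pad, y + pad
        rot = rng.uniform(0, np.pi)
        b = a * rng.uniform(0.65, 0.9)
        if tr.in_focus(frame):
            rr, cc = skdraw.ellipse(y, x, a + config.halo_width,
                                    b + config.halo_width,
                                    shape=(hp, wp), rotation=rot)
            img[rr, cc] = 0.88
            rr, cc = skdraw.ellipse(y, x, a, b, shape=(hp, wp),
                                    rotation=rot)
            img[rr, cc] = 0.18
        else:  # nearly invisible out-of-focus smudge
            rr, cc = skdraw.ellipse(y, x, a * 1.5, b * 1.5,
                                    shape=(hp, wp), rotation=rot)
            img[rr, cc] -= 0.04
    return np.clip(img, 0.0, 1.0)


def _render_pad(config: SimulationConfig) -> int:
    """Canvas margin guaranteeing misaligned frames stay inside."""
    h, w = config.image_shape
    d = float(max(h, w))
    lo, hi = config.misalignment_scale
    scale_slack = d * max(hi - 1.0, 0.0, 1.0 - lo)
    rot_slack = d * np.sin(config.misalignment_rotation)
    return int(np.ceil(scale_slack + rot_slack
                       + config.misalignment_translation)) + 8


def sample_misalignment(config: SimulationConfig, rng) -> SimilarityTransform:
    lo, hi = config.misalignment_scale
    return SimilarityTransform(
        scale=float(rng.uniform(lo, hi)),
        rotation=float(rng.uniform(-config.misalignment_rotation,
                                   config.misalignment_rotation)),
        translation=(float(rng.uniform(-config.misalignment_translation,
                                       config.misalignment_translation)),
                     float(rng.uniform(-config.misalignment_translation,
                                       config.misalignment_translation))))


def render_frames(truth: GroundTruth, config: SimulationConfig | None = None,
                  rng=None):
    """Render the misaligned image stack plus detections and transforms.

    Returns ``(frames, detections, transforms)``.  ``transforms[k]``
    maps frame-``k`` pixel coordinates into the reference system (the
    end-point frame, which gets the identity); this is exactly the
    transform the registration stage must recover.  Detections are in
    reference coordinates (the tracker operates after registration).
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 3)
    t = config.n_frames
    pad = _render_pad(config)
    shift = np.eye(3)
    shift[0, 2] = shift[1, 2] = pad
    transforms = []
    frames = []
    for k in range(t):
        T = SimilarityTransform() if k == t - 1 \
            else sample_misalignment(config, rng)
        transforms.append(T)
        scene = render_scene(truth, k, pad=pad)
        warped = sktransform.warp(
            scene, inverse_map=sktransform.ProjectiveTransform(
                matrix=shift @ T.matrix),
            order=1, cval=0.0, preserve_range=True,
            output_shape=config.image_shape)
        frames.append(warped)
    detections = emulate_detections(truth, config, rng)
    truth.transforms = transforms
    return frames, detections, transforms


# ----------------------------------------------------------------------
# template bank
# ----------------------------------------------------------------------

def make_template_bank(config: SimulationConfig, n_cell: int = 100,
                       n_noncell: int = 100, rng=None):
    """Labelled 100x100 patches for detector training.

    Cell patches are centred on rendered in-focus nuclei; non-cell
    patches are background, monolayer, halo-adjacent or post-edge
    crops whose centre is at least one nucleus-plus-halo away from any
    cell centre.  Returns ``(patches, labels)`` with label 1 = cell.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 4)
    size = config.template_size
    half = size // 2
    h, w = config.image_shape
    if h < size + 2 or w < size + 2:
        raise InvalidConfigError("image too small for templates")
    cells, noncells = [], []
    trial = 0
    while (len(cells) < n_cell or len(noncells) < n_noncell) and trial < 60:
        cfg = dataclasses.replace(config,
                                  rng_seed=config.rng_seed + 1000 + trial)
        vessel, parabola = simulate_vessel(cfg)
        truth = simulate_trajectories(cfg, vessel, parabola)
        for k in range(cfg.n_frames):
            if len(cells) >= n_cell and len(noncells) >= n_noncell:
                break
            scene = render_scene(truth, k)
            _, pts = truth.positions(k, include_oof=False)
            for x, y in pts:
                if len(cells) >= n_cell:
                    break
                # small jitter so the positive class covers the
                # detector's stride-grid offsets
                r = int(round(y + rng.uniform(-3, 3)))
                c = int(round(x + rng.uniform(-3, 3)))
                if half <= r < h - half and half <= c < w - half:
                    cells.append(scene[r - half:r + half,
                                       c - half:c + half].copy())
            guard = config.cell_radius + config.halo_width + 4
            near_min = config.cell_radius + 3
            for a in range(6 * n_noncell):
                if len(noncells) >= n_noncell:
                    break
                if a % 2 == 0 and len(pts):
                    # hard negative: a nucleus just off-centre (centre
                    # pixel outside the nucleus), so the classifier
                    # localises rather than merely detects
                    x0, y0 = pts[int(rng.integers(len(pts)))]
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(near_min, 30.0)
                    r = int(round(y0 + rad * np.sin(ang)))
                    c = int(round(x0 + rad * np.cos(ang)))
                    min_req = near_min
                else:
                    r = int(rng.integers(half, h - half))
                    c = int(rng.integers(half, w - half))
                    min_req = guard
                if not (half <= r < h - half and half <= c < w - half):
                    continue
                if len(pts) == 0 or np.min(np.hypot(pts[:, 0] - c,
                                                    pts[:, 1] - r)) \
                        >= min_req:
                    noncells.append(scene[r - half:r + half,
                                          c - half:c + half].copy())
        trial += 1
    if len(cells) < n_cell or len(noncells) < n_noncell:
        raise InvalidConfigError("could not harvest enough templates")
    patches = np.stack(cells[:n_cell] + noncells[:n_noncell]).astype(
        np.float32)
    labels = np.concatenate([np.ones(n_cell, dtype=int),
                             np.zeros(n_noncell, dtype=int)])
    return patches, labels


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    truth: GroundTruth
    frames: list
    detections: list
    transforms: list


def simulate_dataset(config: SimulationConfig,
                     render: bool = True) -> SyntheticDataset:
    """Vessel + trajectories (+ rendered frames) under one seed."""
    vessel, parabola = simulate_vessel(config)
    truth = simulate_trajectories(config, vessel, parabola)
    if render:
        frames, detections, transforms = render_frames(truth, config)
    else:
        frames, transforms = [], []
        detections = emulate_detections(truth, config)
    return SyntheticDataset(truth=truth, frames=frames,
                            detections=detections, transforms=transforms)
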