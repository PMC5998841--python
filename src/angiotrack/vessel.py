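"""Vessel segmentation and medial-axis representation.

The region of interest is the sprouting vessel above the cell-gel
interface.  The interface is modelled by a parabola anchored at the
post-apex x-coordinate ``ap`` obtained during registration,

    y(x) = a1 * (x - ap + a3)**2 + a2 ,

and everything below it (larger row index ``y``) is masked out.  The
thresholded image is cleaned by morphological closing, hole filling and
an area-opening, and the resulting binary vessel shape is converted to a
medial axis transform (MAT): centerline chains plus an inscribed-disk
radius per centerline point.  The MAT supports reconstruction of the
mask and arc-length ordering of points along a vessel branch, which the
tracker uses to enforce the no-overtaking constraint.

Coordinates are pixel-based, origin at the top-left corner, ``x`` the
column and ``y`` the row; ``y`` increases toward the cell-gel interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import filters as skfilters
from skimage import morphology as skmorph


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. constant image)."""


class OutOfVesselError(ValueError):
    """Raised when a point is queried too far from any centerline."""


@dataclass
class ParabolaParams:
    """Interface parabola ``y(x) = a1*(x - ap + a3)**2 + a2``."""

    a1: float
    a2: float
    a3: float
    ap: float
    low_confidence: bool = False

    def y(self, x):
        x = np.asarray(x, dtype=float)
        return self.a1 * (x - self.ap + self.a3) ** 2 + self.a2


@dataclass
class VesselModel:
    """Binary vessel mask plus centerline chains with per-point radii.

    ``branches`` is a list of ``(n, 2)`` float arrays of ``(x, y)``
    centerline points; each chain is oriented root-first, the root being
    the chain end nearest the interface (largest ``y``).  ``radii``
    holds the matching inscribed-disk radius arrays and ``junctions``
    the skeleton branch points.
    """

    mask: np.ndarray
    branches: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    junctions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    # caches for arc queries
    _tree: cKDTree = field(default=None, repr=False, compare=False)
    _index: np.ndarray = field(default=None, repr=False, compare=False)
    _arcs: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.branches = [np.asarray(b, dtype=float) for b in self.branches]
        self.radii = [np.asarray(r, dtype=float) for r in self.radii]

    def arc_lengths(self, branch_id: int) -> np.ndarray:
        """Cumulative arc length from the branch root to every point."""
        self._build_cache()
        return self._arcs[branch_id]

    def _build_cache(self):
        if self._tree is not None:
            return
        pts, idx, arcs = [], [], []
        for b, chain in enumerate(self.branches):
            steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
            arcs.append(np.concatenate([[0.0], np.cumsum(steps)]))
            pts.append(chain)
            idx.append(np.column_stack([np.full(len(chain), b),
                                        np.arange(len(chain))]))
        self._arcs = arcs
        all_pts = np.vstack(pts)
        self._tree = cKDTree(all_pts)
        self._index = np.vstack(idx).astype(int)

    def reconstruct(self, shape=None) -> np.ndarray:
        """Union of inscribed disks centred on the centerline points."""
        if shape is None:
            shape = self.mask.shape
        out = np.zeros(shape, dtype=bool)
        for chain, rad in zip(self.branches, self.radii):
            for (x, y), r in zip(chain, rad):
                rr, cc = skdraw.disk((y, x), max(r, 0.5), shape=shape)
                out[rr, cc] = True
        return out

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def fit_interface_parabola(image, ap, a1_grid=None, a2_grid=None,
                           a3_grid=None, y_max=None) -> ParabolaParams:
    """Brute-force grid search for the cell-gel interface parabola.

    The fit score for a candidate ``(a1, a2, a3)`` is the mean Sobel
    gradient magnitude sampled along the curve; the interface is the
    strongest horizontal-scale edge in the masked image, so the best
    grid point maximises that line integral.  ``y_max`` bounds the
    ``a2`` search from below in the image (the interface lies above
    the post, whose top-edge row is known from registration).  Zeroed
    pixels (post/outside-view blanking) and their boundaries are
    excluded from the score.  A flat score surface (no interface in
    view) flags the returned best grid point as ``low_confidence``.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if a1_grid is None:
        a1_grid = np.linspace(-2e-4, 2e-4, 9)
    if a2_grid is None:
        a2_grid = np.arange(0.3 * h, (0.95 * h if y_max is None
                                      else min(y_max, h)), 4.0)
    if a3_grid is None:
        a3_grid = np.linspace(-80.0, 80.0, 9)
    grad = np.hypot(skfilters.sobel_h(image), skfilters.sobel_v(image))
    blank = ndi.binary_dilation(image == 0, iterations=3)
    grad[blank] = 0.0

    x = np.arange(w)
    a2_grid = np.asarray(a2_grid, dtype=float)
    best = (-np.inf, None)
    scores = []
    for a1 in a1_grid:
        for a3 in a3_grid:
            y_base = a1 * (x - ap + a3) ** 2
            yy = np.rint(y_base[None, :] + a2_grid[:, None]).astype(int)
            valid = (yy >= 0) & (yy < h)
            yc = np.clip(yy, 0, h - 1)
            vals = grad[yc, x[None, :]] * valid
            n = valid.sum(axis=1)
            with np.errstate(invalid="ignore"):
                s = np.where(n > w // 2, vals.sum(axis=1) / np.maximum(n, 1),
                             -np.inf)
            scores.append(s[np.isfinite(s)])
            k = int(np.argmax(s))
            if s[k] > best[0]:
                best = (s[k], (float(a1), float(a2_grid[k]), float(a3)))
    allscores = np.concatenate([s for s in scores if s.size])
    span = allscores.max() - allscores.min() if allscores.size else 0.0
    low_conf = (not np.isfinite(best[0])) or span <= 1e-12 \
        or span < 1e-3 * max(abs(allscores.max()), 1e-12)
    if best[1] is None:
        a1, a2, a3 = 0.0, float(a2_grid[0]), 0.0
        low_conf = True
    else:
        a1, a2, a3 = best[1]
    return ParabolaParams(a1, a2, a3, float(ap), low_confidence=bool(low_conf))


def otsu_threshold(image) -> float:
    """Histogram threshold maximising between-class variance."""
    image = np.asarray(image)
    if image.min() == image.max():
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(skfilters.threshold_otsu(image))


def mask_below_parabola(image, parabola: ParabolaParams, fill=0.0):
    """Zero (or ``fill``) all pixels below the interface curve."""
    image = np.asarray(image, dtype=float).copy()
    h, w = image.shape
    ys = parabola.y(np.arange(w))
    rows = np.arange(h)[:, None]
    image[rows > ys[None, :]] = fill
    return image


@dataclass
class MorphologyConfig:
    closing_radius: int = 15
    min_area: int = 20000


def segment_vessel(binary, config: MorphologyConfig | None = None) -> np.ndarray:
    """Clean a thresholded image into the binary vessel shape.

    Applies, in order: morphological closing with a disk structuring
    element, hole filling, and removal of connected components smaller
    than ``min_area`` pixels (components of exactly ``min_area`` pixels
    are kept).
    """
    if config is None:
        config = MorphologyConfig()
    binary = np.asarray(binary, dtype=bool)
    closed = skmorph.closing(binary, skmorph.disk(config.closing_radius))
    filled = ndi.binary_fill_holes(closed)
    lab, n = ndi.label(filled)
    if n == 0:
        return filled
    sizes = np.bincount(lab.ravel())
    keep = sizes >= config.min_area
    keep[0] = False
    out = keep[lab]
    return out


_NEIGH = np.ones((3, 3), dtype=int)


def _skeleton_chains(skel: np.ndarray):
    """Order skeleton pixels into simple chains split at junctions."""
    nb = ndi.convolve(skel.astype(int), _NEIGH, mode="constant") - 1
    junctions = skel & (nb >= 3)
    body = skel & ~junctions
    lab, n = ndi.label(body, structure=_NEIGH)
    chains = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(lab == i)
        pix = set(zip(rr.tolist(), cc.tolist()))
        # count neighbours within the segment
        def deg(p):
            r, c = p
            return sum((r + dr, c + dc) in pix
                       for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                       if (dr, dc) != (0, 0))
        ends = [p for p in pix if deg(p) <= 1]
        start = min(ends) if ends else min(pix)
        order = [start]
        seen = {start}
        cur = start
        while len(order) < len(pix):
            r, c = cur
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q != cur and q in pix and q not in seen:
                        nxt = q
                        break
                if nxt is not None:
                    break
            if nxt is None:  # disconnected remainder (rare thick clusters)
                rest = pix - seen
                nxt = min(rest, key=lambda q: (q[0] - r) ** 2 + (q[1] - c) ** 2)
            order.append(nxt)
            seen.add(nxt)
            cur = nxt
        chains.append(np.array([(c, r) for r, c in order], dtype=float))
    jr, jc = np.nonzero(junctions)
    return chains, np.column_stack([jc, jr]).astype(float)


def medial_axis_transform(mask, min_branch_len: int = 8) -> VesselModel:
    """Medial axis of a binary mask, ordered into branch chains.

    Uses the ridge of the exact Euclidean distance transform (scikit-
    image ``medial_axis``), so each centerline point carries its
    distance to the boundary as the inscribed-disk radius.  Chains are
    oriented with the interface-proximal end (largest ``y``) first, so
    that arc length grows moving away from the monolayer.  Side chains
    shorter than ``min_branch_len`` pixels (skeletonisation spurs) are
    dropped when longer chains exist.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask has no medial axis")
    skel, dist = skmorph.medial_axis(mask, return_distance=True)
    chains, junctions = _skeleton_chains(skel)
    long_chains = [c for c in chains if len(c) >= min_branch_len]
    if long_chains:
        chains = long_chains
    branches, radii = [], []
    for chain in chains:
        # root-first: the end with the larger y is closer to the interface
        if chain[0, 1] < chain[-1, 1]:
            chain = chain[::-1]
        r = dist[chain[:, 1].astype(int), chain[:, 0].astype(int)]
        branches.append(chain)
        radii.append(np.maximum(r, 0.5))
    return VesselModel(mask=mask, branches=branches, radii=radii,
                       junctions=junctions)


def arc_position(vessel: VesselModel, point, max_dist: float = 60.0):
    """Branch id and arc length (from the branch root) nearest a point.

    Raises :class:`OutOfVesselError` when the point lies farther than
    ``max_dist`` from every centerline point.
    """
    vessel._build_cache()
    point = np.asarray(point, dtype=float)
    d, i = vessel._tree.query(point)
    if d > max_dist:
        raise OutOfVesselError(
            f"point {point.tolist()} is {d:.1f} px from the nearest "
            f"centerline (limit {max_dist})")
    b, k = vessel._index[i]
    return int(b), float(vessel._arcs[b][k])
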