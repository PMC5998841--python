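"""Frame registration from the trapezoidal post-edge lines.

The microfluidic device carries a trapezoidal post whose four straight
edges are stable landmarks across the daily acquisitions.  Each frame
is aligned to the end-point frame (the reference for backward tracking)
by (1) detecting the four edges with the Hough transform, (2) labelling
them by geometric role and intersecting designated pairs to obtain
corresponding feature points, and (3) solving for the similarity
transform (scale, rotation, translation) that maps the frame onto the
reference — in closed form when the labelled correspondences are
available, or by iterative closest point when they are not.  After
resampling, pixels on the post side of the identified edges are set to
zero so the post is never mistaken for vessel or cells.

Lines are stored in Hesse normal form ``x*cos(theta) + y*sin(theta) =
rho`` with the scikit-image convention ``theta in [-pi/2, pi/2)``.
Labels: 1 = left slanted edge, 2 = top edge, 3 = bottom edge,
4 = right slanted edge; the apex point ``a_p`` is the intersection of
lines 1 and 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import feature as skfeature
from skimage import transform as sktransform
from skimage.transform import hough_line, hough_line_peaks


class RegistrationError(RuntimeError):
    """Line detection failed (fewer than four usable edges)."""


class DegenerateGeometryError(ValueError):
    """Parallel line pair or coincident point set."""


#: adjacent line pairs whose intersections serve as registration
#: features, in fixed label order; the last pair (1, 4) yields ``a_p``.
INTERSECTION_PAIRS = ((1, 2), (2, 4), (1, 3), (3, 4), (1, 4))


@dataclass
class LineSet:
    """Four post-edge lines in Hesse normal form, labelled 1-4."""

    rho: np.ndarray    # (4,) pixels, index i -> label i+1
    theta: np.ndarray  # (4,) radians

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.rho.shape != (4,) or self.theta.shape != (4,):
            raise ValueError("LineSet requires exactly 4 labelled lines")

    def line(self, label: int):
        return float(self.rho[label - 1]), float(self.theta[label - 1])


@dataclass
class SimilarityTransform:
    """Similarity transform ``p' = s * R(angle) @ p + t`` on (x, y)."""

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return sktransform.SimilarityTransform(
            scale=self.scale, rotation=self.rotation,
            translation=self.translation).params

    @classmethod
    def from_matrix(cls, m) -> "SimilarityTransform":
        t = sktransform.SimilarityTransform(matrix=np.asarray(m, dtype=float))
        return cls(scale=float(t.scale), rotation=float(t.rotation),
                   translation=(float(t.translation[0]),
                                float(t.translation[1])))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))])
        out = (self.matrix @ h.T).T[:, :2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)

    def to_dict(self) -> dict:
        return {"scale": self.scale, "rotation": self.rotation,
                "translation": list(self.translation)}

    @classmethod
    def from_dict(cls, d) -> "SimilarityTransform":
        return cls(scale=d["scale"], rotation=d["rotation"],
                   translation=tuple(d["translation"]))


@dataclass
class HoughConfig:
    """Line-detection parameters (1 px / 0.5 deg accumulator bins)."""

    canny_sigma: float = 2.0
    theta_step: float = np.deg2rad(0.5)
    peak_threshold: float = 0.12  # fraction of the accumulator maximum
    num_peaks: int = 16
    min_distance: int = 15        # rho bins between peaks
    min_angle: int = 10           # theta bins between peaks
    # angular windows of the device's line families (radians):
    # top/bottom edges are near-horizontal, the trapezoid sides slant
    # at a known angle range (left side positive theta, right negative)
    horizontal_window: float = 0.35   # |theta| within this of pi/2
    slant_range: tuple = (0.25, 0.80)


def _hough_peaks(edges, config: "HoughConfig"):
    n_theta = max(int(np.round(np.pi / config.theta_step)), 4)
    thetas = np.linspace(-np.pi / 2, np.pi / 2, n_theta, endpoint=False)
    acc, angles, dists = hough_line(edges, theta=thetas)
    if acc.max() == 0:
        return np.array([]), np.array([]), np.array([])
    val, th, rho = hough_line_peaks(
        acc, angles, dists, num_peaks=config.num_peaks,
        threshold=config.peak_threshold * acc.max(),
        min_distance=config.min_distance, min_angle=config.min_angle)
    order = np.argsort(-np.asarray(val))
    return (np.asarray(val)[order], np.asarray(th)[order],
            np.asarray(rho)[order])


def _normalize_hesse(rho, theta):
    if theta >= np.pi / 2:
        theta -= np.pi
        rho = -rho
    elif theta < -np.pi / 2:
        theta += np.pi
        rho = -rho
    return rho, theta


def _refine_line(edges, rho, theta, bands=(4.0, 1.5)):
    """Sub-bin refinement: total-least-squares fit of the edge pixels
    within a shrinking band around the Hough line."""
    rr, cc = np.nonzero(edges)
    for band in bands:
        d = cc * np.cos(theta) + rr * np.sin(theta) - rho
        m = np.abs(d) < band
        if m.sum() < 20:
            return rho, theta
        x, y = cc[m].astype(float), rr[m].astype(float)
        mx, my = x.mean(), y.mean()
        u = np.column_stack([x - mx, y - my])
        _, _, vt = np.linalg.svd(u, full_matrices=False)
        nx, ny = vt[1]
        theta_new = np.arctan2(ny, nx)
        rho_new = nx * mx + ny * my
        rho, theta = _normalize_hesse(rho_new, theta_new)
    return rho, theta


def detect_post_lines(image, config: HoughConfig | None = None,
                      frame: int | None = None) -> LineSet:
    """Detect the four post edges with the Hough transform.

    Two-stage labelling exploiting the device geometry: the post's
    top and bottom edges are the two strongest near-horizontal lines
    in the whole image; the slanted sides are then searched only
    within the row band those two edges delimit (the vessel, whose
    walls can fall in the same angular range, lies above the post).
    Each selected line is refined to sub-bin accuracy by a
    total-least-squares fit of the supporting edge pixels.
    """
    if config is None:
        config = HoughConfig()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    edges = skfeature.canny(image, sigma=config.canny_sigma)
    val, th, rho = _hough_peaks(edges, config)
    if len(val) == 0:
        raise RegistrationError(
            f"no lines detected{_frame_tag(frame)}: empty accumulator")
    horiz = [i for i in range(len(val))
             if abs(abs(th[i]) - np.pi / 2) < config.horizontal_window]
    if len(horiz) < 2:
        raise RegistrationError(
            f"fewer than two horizontal post edges{_frame_tag(frame)}")

    def y_at_mid(i):
        return (rho[i] - (w / 2) * np.cos(th[i])) / np.sin(th[i])

    lo, hi = config.slant_range
    # try horizontal pairs strongest-first until one delimits a band
    # containing both slanted sides
    for a in range(min(len(horiz), 4)):
        for b in range(a + 1, min(len(horiz), 4)):
            i2, i3 = horiz[a], horiz[b]
            ys = [y_at_mid(i2), y_at_mid(i3)]
            if ys[0] > ys[1]:
                i2, i3 = i3, i2
                ys = ys[::-1]
            if ys[1] - ys[0] < 0.05 * h:
                continue
            band_lo = max(int(ys[0]) - 8, 0)
            band_hi = min(int(ys[1]) + 8, h)
            band_edges = np.zeros_like(edges)
            band_edges[band_lo:band_hi] = edges[band_lo:band_hi]
            bval, bth, brho = _hough_peaks(band_edges, config)
            left = [i for i in range(len(bval)) if lo <= bth[i] <= hi]
            right = [i for i in range(len(bval)) if -hi <= bth[i] <= -lo]
            if not left or not right:
                continue
            i1, i4 = left[0], right[0]
            raw = [(brho[i1], bth[i1]), (rho[i2], th[i2]),
                   (rho[i3], th[i3]), (brho[i4], bth[i4])]
            support = [band_edges, edges, edges, band_edges]
            refined = [_refine_line(sup, r, t)
                       for sup, (r, t) in zip(support, raw)]
            return LineSet(rho=[r for r, _ in refined],
                           theta=[t for _, t in refined])
    raise RegistrationError(
        f"could not find the slanted post edges{_frame_tag(frame)}")


def _frame_tag(frame):
    return "" if frame is None else f" (frame {frame})"


def _intersect(l1, l2):
    (r1, t1), (r2, t2) = l1, l2
    a = np.array([[np.cos(t1), np.sin(t1)], [np.cos(t2), np.sin(t2)]])
    if abs(np.linalg.det(a)) < 1e-10:
        raise DegenerateGeometryError("parallel lines do not intersect")
    return np.linalg.solve(a, np.array([r1, r2]))


def line_intersections(lines: LineSet) -> np.ndarray:
    """Feature points from the designated adjacent line pairs.

    Returns a ``(5, 2)`` array ordered as :data:`INTERSECTION_PAIRS`;
    the final point is ``a_p``, the lines-1/4 apex used by the
    interface parabola.
    """
    pts = [_intersect(lines.line(i), lines.line(j))
           for i, j in INTERSECTION_PAIRS]
    return np.array(pts)


def _umeyama(moving, fixed) -> SimilarityTransform:
    t = sktransform.SimilarityTransform.from_estimate(
        np.asarray(moving, float), np.asarray(fixed, float))
    if not t or not np.all(np.isfinite(t.params)) or t.scale <= 0:
        raise DegenerateGeometryError(
            "similarity estimation failed (coincident points?)")
    return SimilarityTransform.from_matrix(t.params)


def estimate_transform(moving_pts, fixed_pts, correspondences: bool = True,
                       tol: float = 1e-6, max_iter: int = 50
                       ) -> SimilarityTransform:
    """Least-squares similarity transform mapping moving onto fixed.

    With ``correspondences=True`` the i-th points correspond and the
    closed-form (Umeyama/Procrustes) solution is returned.  Otherwise
    ICP alternates nearest-point correspondence with the closed-form
    solve until the parameter change falls below ``tol`` or ``max_iter``
    iterations.
    """
    moving = np.atleast_2d(np.asarray(moving_pts, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed_pts, dtype=float))
    if len(moving) < 2 or len(fixed) < 2:
        raise ValueError("need at least 2 points on each side")
    if np.allclose(moving, moving[0]) or np.allclose(fixed, fixed[0]):
        raise DegenerateGeometryError("all points coincident")
    if correspondences:
        if len(moving) != len(fixed):
            raise ValueError("labelled point sets must have equal size")
        return _umeyama(moving, fixed)
    tree = cKDTree(fixed)
    T = SimilarityTransform()
    prev = None
    for _ in range(max_iter):
        warped = T.apply(moving)
        _, idx = tree.query(warped)
        T = _umeyama(moving, fixed[idx])
        p = np.array([T.scale, T.rotation, *T.translation])
        if prev is not None and np.max(np.abs(p - prev)) < tol:
            break
        prev = p
    return T


def post_polygon(lines: LineSet) -> np.ndarray:
    """Corners of the post quadrilateral (labels 1^2, 2^4, 4^3, 3^1)."""
    p12 = _intersect(lines.line(1), lines.line(2))
    p24 = _intersect(lines.line(2), lines.line(4))
    p43 = _intersect(lines.line(4), lines.line(3))
    p31 = _intersect(lines.line(3), lines.line(1))
    return np.array([p12, p24, p43, p31])


def apply_transform_and_mask(image, T: SimilarityTransform,
                             lines: LineSet | None = None,
                             output_shape=None) -> np.ndarray:
    """Resample a frame into the reference system and blank the post.

    ``T`` maps frame coordinates to reference coordinates; bilinear
    interpolation with zero fill outside the frame.  When ``lines`` is
    given (detected in frame coordinates) the post quadrilateral is
    transformed along and its interior set to zero.
    """
    image = np.asarray(image, dtype=float)
    if output_shape is None:
        output_shape = image.shape
    inv = sktransform.SimilarityTransform(matrix=np.linalg.inv(T.matrix))
    out = sktransform.warp(image, inverse_map=inv, order=1, cval=0.0,
                           output_shape=output_shape, preserve_range=True)
    if lines is not None:
        corners = T.apply(post_polygon(lines))
        rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0],
                                shape=output_shape)
        out[rr, cc] = 0.0
    return out
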