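"""Feature geometry: segmentation, spline outlines, and tangent-angle maps.

Coordinate conventions (used everywhere in the package): pixel-centered,
0-based, x to the right and y down in the displayed image; angles are
measured counter-clockwise from +x *as displayed*, i.e. a direction
(dx, dy) has angle atan2(-dy, dx), reduced mod 180 because features and
polarizations are axes, not vectors.  θ = 0 when the horizontal excitation
polarization is parallel to the local feature tangent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "CircleFit",
    "SplineOutline",
    "ThetaSamples",
    "direction_angle_deg",
    "detect_circle",
    "segment_outline",
    "fit_spline",
    "assign_theta",
]


def direction_angle_deg(dx, dy) -> np.ndarray:
    """Axis angle of direction (dx, dy), CCW from +x in display coords, mod 180."""
    return np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float))) % 180.0


@dataclass(frozen=True)
class CircleFit:
    cx: float
    cy: float
    radius: float
    score: float


def detect_circle(
    image: np.ndarray,
    radius_range: tuple[float, float] = (8.0, 80.0),
    n_radii: int | None = None,
    threshold: float = 0.25,
) -> CircleFit:
    """Best-scoring circle in a bright-ring image via the Hough transform.

    The image is thresholded (Otsu) to ring pixels, which vote in the
    circular Hough accumulator over the requested radius range.  Ties in
    accumulator score break deterministically toward the smaller (row-major)
    center, then the smaller radius.  Raises if no accumulator peak exceeds
    ``threshold`` (normalized votes).
    """
    from skimage.filters import threshold_otsu
    from skimage.transform import hough_circle

    img = np.asarray(image, dtype=float)
    if not np.any(img > 0) or np.ptp(img) == 0:
        raise ValueError("no circle found: blank image")
    edges = img > threshold_otsu(img)
    if not edges.any():
        raise ValueError("no circle found: empty foreground")
    lo, hi = radius_range
    if n_radii is None:
        n_radii = max(int(round(hi - lo)) + 1, 2)
    radii = np.linspace(lo, hi, n_radii)
    acc = hough_circle(edges, radii, normalize=True, full_output=False)
    # deterministic peak: max score, ties -> smaller (cy, cx), then radius
    flat = acc.reshape(acc.shape[0], -1)
    best = None
    for ri in range(flat.shape[0]):
        k = int(np.argmax(flat[ri]))
        sc = float(flat[ri, k])
        cy, cx = np.unravel_index(k, acc.shape[1:])
        cand = (-sc, int(cy), int(cx), float(radii[ri]))
        if best is None or cand < best:
            best = cand
    score = -best[0]
    if score < threshold:
        raise ValueError(f"no circle found: best accumulator score {score:.3f} < {threshold}")
    return CircleFit(cx=float(best[2]), cy=float(best[1]), radius=best[3], score=score)


def segment_outline(
    image: np.ndarray,
    method: str = "circle",
    band: float = 2.0,
    radius_range: tuple[float, float] = (8.0, 80.0),
    mask: np.ndarray | None = None,
    eraser: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of pixels to analyze.

    ``circle``: Hough-detected circle dilated to a ±``band`` px annulus;
    ``threshold``: Otsu foreground; ``mask_file``: an externally supplied
    mask (stands in for manual segmentation).  An ``eraser`` mask subtracts
    pixels (the manual-exclusion mechanism).  Raises on an empty result.
    """
    img = np.asarray(image, dtype=float)
    if method == "circle":
        fit = detect_circle(img, radius_range=radius_range)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        d = np.hypot(xx - fit.cx, yy - fit.cy)
        out = np.abs(d - fit.radius) <= band
    elif method == "threshold":
        from skimage.filters import threshold_otsu

        out = img > threshold_otsu(img)
    elif method in ("mask", "mask_file"):
        if mask is None:
            raise ValueError("method 'mask_file' requires a mask")
        out = np.asarray(mask).astype(bool)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    if eraser is not None:
        out = out & ~np.asarray(eraser).astype(bool)
    if not out.any():
        raise ValueError("segmentation produced an empty mask")
    return out


@dataclass
class SplineOutline:
    """Cubic-spline approximation of a feature outline with dense tangents.

    ``dense_xy`` samples the spline at <= ``spacing`` px arc increments;
    ``tangent_deg`` holds the axis angle of the local tangent at each dense
    sample (display CCW from +x, mod 180).
    """

    anchors: np.ndarray  # (n, 2) x, y
    closed: bool
    dense_xy: np.ndarray  # (m, 2)
    tangent_deg: np.ndarray  # (m,)
    curvature: np.ndarray = field(default=None)  # |dT/ds| per dense sample, 1/px

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.dense_xy[:, 0], "y": self.dense_xy[:, 1], "tangent_deg": self.tangent_deg}
        )


def _anchors_from_mask(mask: np.ndarray, n_anchors: int = 16) -> np.ndarray:
    """Ordered anchors from the longest contour of a boolean mask."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)  # (row, col) = (y, x)
    idx = np.linspace(0, len(contour) - 1, n_anchors, endpoint=False).astype(int)
    return contour[idx][:, ::-1].astype(float)  # -> (x, y)


def fit_spline(
    anchors_or_mask,
    closed: bool = True,
    spacing: float = 0.5,
    n_anchors: int = 16,
) -> SplineOutline:
    """Interpolating cubic spline through anchor points, densely resampled.

    Accepts an (n, 2) array of (x, y) anchors or a boolean mask (anchors then
    taken from its longest contour).  Closed outlines use a periodic spline
    (>= 4 anchors); open ones a natural spline (>= 2 anchors; 2-anchor input
    degenerates to a straight segment).  Consecutive duplicate anchors are
    removed before fitting.  Dense samples carry analytic tangent angles and
    curvatures.
    """
    arr = np.asarray(anchors_or_mask)
    if arr.dtype == bool or (arr.ndim == 2 and arr.shape[1] > 2):
        anchors = _anchors_from_mask(arr.astype(bool), n_anchors=n_anchors)
    else:
        anchors = np.asarray(arr, dtype=float).reshape(-1, 2)
    # deduplicate consecutive (and closing) repeats
    keep = [0]
    for i in range(1, len(anchors)):
        if np.hypot(*(anchors[i] - anchors[keep[-1]])) > 1e-9:
            keep.append(i)
    if closed and len(keep) > 1 and np.hypot(*(anchors[keep[-1]] - anchors[keep[0]])) < 1e-9:
        keep = keep[:-1]
    anchors = anchors[keep]
    n = len(anchors)
    if closed and n < 4:
        raise ValueError("closed outline needs >= 4 distinct anchors")
    if not closed and n < 2:
        raise ValueError("open outline needs >= 2 distinct anchors")

    if not closed and n == 2:
        # straight segment
        p0, p1 = anchors
        seg_len = float(np.hypot(*(p1 - p0)))
        m = max(int(np.ceil(seg_len / spacing)) + 1, 2)
        t = np.linspace(0, 1, m)
        xy = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        ang = np.full(m, direction_angle_deg(p1[0] - p0[0], p1[1] - p0[1]))
        return SplineOutline(anchors=anchors, closed=False, dense_xy=xy,
                             tangent_deg=ang, curvature=np.zeros(m))

    pts = np.vstack([anchors, anchors[:1]]) if closed else anchors
    k = min(3, len(pts) - 1)
    tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0.0, per=int(closed), k=k)
    # estimate arc length, then resample at <= spacing
    uu = np.linspace(0, 1, 2048)
    x, y = splev(uu, tck)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    total = arc[-1]
    m = max(int(np.ceil(total / spacing)) + 1, 8)
    u_dense = np.interp(np.linspace(0, total, m, endpoint=not closed), arc, uu)
    xd, yd = splev(u_dense, tck)
    dx, dy = splev(u_dense, tck, der=1)
    ddx, ddy = splev(u_dense, tck, der=2)
    speed = np.hypot(dx, dy)
    ang = direction_angle_deg(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.abs(dx * ddy - dy * ddx) / np.where(speed > 0, speed**3, np.inf)
    # continuity warning (self-intersecting or badly ordered anchors)
    dang = np.abs(np.diff(ang))
    dang = np.minimum(dang, 180.0 - dang)
    if dang.size and dang.max() >= 30.0:
        log.warning("spline tangent jumps %.1f deg between dense samples; "
                    "check anchor ordering", dang.max())
    return SplineOutline(
        anchors=anchors,
        closed=closed,
        dense_xy=np.stack([xd, yd], axis=1),
        tangent_deg=ang,
        curvature=curv,
    )


@dataclass
class ThetaSamples:
    """The quantitation currency: (θ, log₂ r) pairs extracted from one object.

    θ is the angle between the horizontal excitation polarization and the
    local feature tangent, in [0, 180) degrees; weights are intensity-derived
    and nonnegative.  Only finite log₂ r values are stored.
    """

    theta_deg: np.ndarray
    log2r: np.ndarray
    weight: np.ndarray
    modality: str = "1p"
    geometry: str = "membrane"
    object_id: str = "object"

    def __post_init__(self):
        t = np.asarray(self.theta_deg, dtype=float) % 180.0
        y = np.asarray(self.log2r, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        ok = np.isfinite(y) & np.isfinite(t) & np.isfinite(w) & (w >= 0)
        self.theta_deg, self.log2r, self.weight = t[ok], y[ok], w[ok]
        self.modality = str(self.modality).lower()
        self.geometry = str(self.geometry).lower()

    @property
    def n(self) -> int:
        return self.theta_deg.size

    def theta_span_deg(self) -> float:
        """Covered span of θ, mod 180 (largest gap complement)."""
        if self.n < 2:
            return 0.0
        t = np.sort(np.unique(np.round(self.theta_deg, 6)))
        gaps = np.diff(np.concatenate([t, [t[0] + 180.0]]))
        return 180.0 - float(gaps.max())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "object_id": self.object_id,
                "modality": self.modality,
                "geometry": self.geometry,
                "theta_deg": self.theta_deg,
                "log2r": self.log2r,
                "weight": self.weight,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ThetaSamples":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            theta_deg=df["theta_deg"].to_numpy(),
            log2r=df["log2r"].to_numpy(),
            weight=df["weight"].to_numpy(),
            modality=str(df["modality"].iloc[0]) if len(df) else "1p",
            geometry=str(df["geometry"].iloc[0]) if len(df) else "membrane",
            object_id=str(df["object_id"].iloc[0]) if len(df) else "object",
        )


def assign_theta(
    ldmap,
    outline: SplineOutline,
    geometry: str = "membrane",
    max_distance: float = 3.0,
    modality: str | None = None,
    object_id: str = "object",
    mask: np.ndarray | None = None,
    max_curvature: float | None = None,
) -> ThetaSamples:
    """Associate every valid pixel with the tangent angle of its nearest
    outline point.

    Pixels farther than ``max_distance`` px from the dense spline samples are
    dropped; ``mask`` restricts candidates further; outline points whose
    local curvature exceeds ``max_curvature`` (1/px) are excluded (automatic
    irregularity rejection).  Returns θ (mod 180), log₂ of the pixel's
    dichroic ratio, and intensity weights.
    """
    valid = ldmap.valid.copy()
    if mask is not None:
        valid &= np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(valid)
    if xs.size == 0:
        raise ValueError("no valid pixels to assign")
    pts = outline.dense_xy
    tangents = outline.tangent_deg
    if max_curvature is not None and outline.curvature is not None:
        ok = outline.curvature <= max_curvature
        if not ok.any():
            raise ValueError("all outline points excluded by curvature threshold")
        pts, tangents = pts[ok], tangents[ok]
    tree = cKDTree(pts)
    d, idx = tree.query(np.stack([xs, ys], axis=1))
    near = d <= max_distance
    if not near.any():
        raise ValueError(f"no valid pixels within {max_distance} px of the outline")
    theta = tangents[idx[near]] % 180.0
    with np.errstate(divide="ignore", invalid="ignore"):
        l2r = np.log2(np.where(ldmap.ld > 0, ldmap.ld, np.nan))
    return ThetaSamples(
        theta_deg=theta,
        log2r=l2r[ys[near], xs[near]],
        weight=ldmap.intensity[ys[near], xs[near]],
        modality=modality or "1p",
        geometry=geometry,
        object_id=object_id,
    )
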