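"""Fitting dichroic-ratio curves and inferring orientational distributions.

One-photon log₂ r(θ) curves are fitted by

    log2(r) = A_1P + log2[(1 + B_1P cos 2(θ−φ1)) / (1 − B_1P cos 2(θ−φ2))]

and two-photon curves by

    log2(r) = A_2P + log2[(1 + B_2P cos 2(θ−φ1) + C_2P cos 4(θ−φ1)) /
                          (1 − B_2P cos 2(θ−φ2) + C_2P cos 4(θ−φ2))]

The inverse problem — which wrapped-Gaussian tilt distribution (α0, σ)
explains the data — is solved by scanning a precomputed lookup table of
dichroic shape parameters, scoring each cell by r², RMSD and χ² with the
curve offset profiled out, and mapping the scores as heat maps.  1P data
constrain only one shape parameter and therefore leave a degenerate band of
(α0, σ) combinations; adding 2P data collapses the band to a single best
cell.  Confidence regions come from bootstrap resampling over objects;
two-component mixtures are searched exhaustively on a coarse grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import ThetaSamples
from .orientation import (
    DichroicShapeParams,
    LookupTable,
    TiltDistribution,
    build_lookup_table,
    default_lookup_table,
    tilt_entropy_bits,
)

#: grid step (degrees) of the default heat-map table
MAP_GRID_STEP = 1.0
#: grid step of the default table behind Gaussian-restricted 2P fits (coarse:
#: the restricted search visits every cell × phase combination)
RESTRICTED_GRID_STEP = 5.0


def _map_table() -> LookupTable:
    return default_lookup_table(MAP_GRID_STEP)

log = logging.getLogger(__name__)

__all__ = [
    "Fit1PResult",
    "Fit2PResult",
    "GoodnessMap",
    "MixtureCandidate",
    "eq1_log2r",
    "eq2_log2r",
    "fit_1p",
    "fit_2p",
    "pool_and_fit",
    "goodness_map",
    "bootstrap_confidence",
    "mixture_search",
    "rmax_to_orientation",
]

#: θ-bin width (degrees) for the sufficient statistics behind goodness maps
THETA_BIN_DEG = 0.25
N_THETA_BINS = int(round(180.0 / THETA_BIN_DEG))
#: number of coarse θ bins used to estimate per-point scatter for χ²
CHI2_BINS = 18


# ---------------------------------------------------------------------------
# parametric curves


def eq1_log2r(theta_deg, a, b, phi1_deg, phi2_deg):
    """One-photon parametric dichroic curve."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    p1, p2 = np.radians(phi1_deg), np.radians(phi2_deg)
    num = 1.0 + b * np.cos(2 * (t - p1))
    den = 1.0 - b * np.cos(2 * (t - p2))
    return a + np.log2(np.maximum(num, 1e-12) / np.maximum(den, 1e-12))


def eq2_log2r(theta_deg, a, b, c, phi1_deg, phi2_deg):
    """Two-photon parametric dichroic curve."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    p1, p2 = np.radians(phi1_deg), np.radians(phi2_deg)
    num = 1.0 + b * np.cos(2 * (t - p1)) + c * np.cos(4 * (t - p1))
    den = 1.0 - b * np.cos(2 * (t - p2)) + c * np.cos(4 * (t - p2))
    return a + np.log2(np.maximum(num, 1e-12) / np.maximum(den, 1e-12))


# ---------------------------------------------------------------------------
# shared helpers


def _concat(samples) -> ThetaSamples:
    if isinstance(samples, ThetaSamples):
        return samples
    sets = list(samples)
    if len(sets) == 1:
        return sets[0]
    return ThetaSamples(
        theta_deg=np.concatenate([s.theta_deg for s in sets]),
        log2r=np.concatenate([s.log2r for s in sets]),
        weight=np.concatenate([s.weight for s in sets]),
        modality=sets[0].modality,
        geometry=sets[0].geometry,
        object_id="pooled",
    )


def _check_fit_preconditions(s: ThetaSamples) -> None:
    if s.n < 8:
        raise ValueError(f"need >= 8 samples, got {s.n}")
    span = s.theta_span_deg()
    if span < 60.0:
        raise ValueError(f"theta span {span:.1f} deg < 60 deg required for fitting")


def _chi2_sigmas(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point σ estimated from local scatter in CHI2_BINS θ-bins."""
    bins = np.floor(theta / 180.0 * CHI2_BINS).astype(int) % CHI2_BINS
    global_sd = y.std(ddof=1) if y.size > 1 else 1.0
    global_sd = max(global_sd, 1e-8)
    sig = np.full(y.size, global_sd)
    for b in range(CHI2_BINS):
        sel = bins == b
        if sel.sum() >= 3:
            sd = y[sel].std(ddof=1)
            sig[sel] = max(sd, 1e-8)
    return sig


def _fit_scores(theta, y, w, fitted) -> tuple[float, float, float]:
    resid = y - fitted
    w_tot = w.sum()
    if w_tot <= 0:
        return np.nan, np.nan, np.nan
    ybar = np.average(y, weights=w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    sse = float(np.sum(w * resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rmsd = float(np.sqrt(np.mean(resid**2)))
    sig = _chi2_sigmas(theta, y)
    chi2 = float(np.sum((resid / sig) ** 2))
    return r2, rmsd, chi2


def _signed_extremum(curve_fn) -> float:
    """Signed extremum with the largest magnitude of a fitted curve on [0, 180).

    Near-ties between the positive and negative lobes (the ideal A=0 curves
    are exactly antisymmetric) resolve to the extremum closer to θ = 0,
    following the convention r_max = F_h(θ=0)/F_v(θ=0).
    """
    th = np.arange(0.0, 180.0, 0.05)
    vals = curve_fn(th)
    i_hi = int(np.argmax(vals))
    i_lo = int(np.argmin(vals))
    tie = max(1e-9, 0.02 * max(abs(vals[i_hi]), abs(vals[i_lo])))
    if abs(abs(vals[i_hi]) - abs(vals[i_lo])) <= tie:
        d_hi = min(th[i_hi], 180.0 - th[i_hi])
        d_lo = min(th[i_lo], 180.0 - th[i_lo])
        return float(vals[i_hi] if d_hi <= d_lo else vals[i_lo])
    return float(vals[i_hi] if abs(vals[i_hi]) > abs(vals[i_lo]) else vals[i_lo])


# ---------------------------------------------------------------------------
# Eq. (1) / Eq. (2) fits


@dataclass
class Fit1PResult:
    """Parameters and quality scores of a one-photon curve fit."""

    a1p: float
    b1p: float
    phi1_deg: float
    phi2_deg: float
    log2_rmax: float
    r2: float
    rmsd: float
    chi2: float
    n: int
    zero_variance: bool = False

    def curve(self, theta_deg):
        return eq1_log2r(theta_deg, self.a1p, self.b1p, self.phi1_deg, self.phi2_deg)


@dataclass
class Fit2PResult:
    """Parameters and quality scores of a two-photon curve fit."""

    a2p: float
    b2p: float
    c2p: float
    phi1_deg: float
    phi2_deg: float
    restricted: bool
    log2_rmax: float
    r2: float
    rmsd: float
    chi2: float
    n: int
    alpha0: float | None = None  # restricted fits: best Gaussian cell
    sigma: float | None = None
    zero_variance: bool = False

    def curve(self, theta_deg):
        return eq2_log2r(theta_deg, self.a2p, self.b2p, self.c2p, self.phi1_deg, self.phi2_deg)


#: maximum allowed |φ1 − φ2| in degrees (sanity bound on the two phases)
PHI_SPLIT_MAX = 20.0


def fit_1p(samples) -> Fit1PResult:
    """Weighted nonlinear least-squares fit of pooled 1P samples by the
    one-photon curve, with multi-start over phase and amplitude.

    ``log2_rmax`` is the signed extremum of the fitted curve with the largest
    magnitude.  Zero-variance data yield B≈0 with the r² slot flagged.
    """
    s = _concat(samples)
    _check_fit_preconditions(s)
    th, y, w = s.theta_deg, s.log2r, np.maximum(s.weight, 0.0)
    if not np.any(w > 0):
        w = np.ones_like(y)
    sw = np.sqrt(w / w.mean())
    a0 = float(np.average(y, weights=w))

    def resid(p):
        a, b, phim, dphi = p
        return sw * (eq1_log2r(th, a, b, phim + dphi / 2, phim - dphi / 2) - y)

    best = None
    for phi0 in (0.0, 45.0, 90.0, 135.0):
        for b0 in (0.1, 0.5, 0.9):
            try:
                sol = least_squares(
                    resid,
                    x0=[a0, b0, phi0, 0.0],
                    bounds=([-np.inf, 0.0, -360.0, -PHI_SPLIT_MAX],
                            [np.inf, 0.999, 360.0, PHI_SPLIT_MAX]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - defensive
                continue
            key = (round(sol.cost, 12), sol.x[1])  # ties -> smaller B (parsimony)
            if best is None or key < best[0]:
                best = (key, sol)
    if best is None:
        raise RuntimeError("1P fit failed from every start")
    a, b, phim, dphi = best[1].x
    phi1, phi2 = phim + dphi / 2, phim - dphi / 2
    fitted = eq1_log2r(th, a, b, phi1, phi2)
    r2, rmsd, chi2 = _fit_scores(th, y, w, fitted)
    zero_var = bool(np.allclose(y, y[0])) if y.size else True
    return Fit1PResult(
        a1p=float(a),
        b1p=float(b),
        phi1_deg=float(phi1 % 180.0),
        phi2_deg=float(phi2 % 180.0),
        log2_rmax=_signed_extremum(lambda t: eq1_log2r(t, a, b, phi1, phi2)),
        r2=np.nan if zero_var else r2,
        rmsd=rmsd,
        chi2=chi2,
        n=s.n,
        zero_variance=zero_var,
    )


#: strict-positivity margin for the free 2P fit: both intensity polynomials
#: must clear this floor, which also forbids the degenerate near-singular
#: curves (denominator → 0) that would otherwise chase noise with spikes
POSITIVITY_MARGIN = 1e-2


def _positivity_penalty(b, c, scale=1e3):
    beta = np.radians(np.arange(0.0, 180.0, 1.0))
    num = 1.0 + b * np.cos(2 * beta) + c * np.cos(4 * beta)
    den = 1.0 - b * np.cos(2 * beta) + c * np.cos(4 * beta)
    v = min(num.min(), den.min())
    return scale * max(0.0, POSITIVITY_MARGIN - v)


def fit_2p(samples, restricted: bool = False, table: LookupTable | None = None) -> Fit2PResult:
    """Fit pooled 2P samples by the two-photon curve.

    Unrestricted: free (A, B, C, φ1, φ2) under the constraint that both
    intensity polynomials stay positive over [0°, 180°).  Restricted:
    (B_2P, C_2P) are tied to a wrapped-Gaussian distribution via the lookup
    table and the search runs over (α0, σ, A, φ).
    """
    s = _concat(samples)
    _check_fit_preconditions(s)
    th, y, w = s.theta_deg, s.log2r, np.maximum(s.weight, 0.0)
    if not np.any(w > 0):
        w = np.ones_like(y)
    sw = np.sqrt(w / w.mean())
    a0 = float(np.average(y, weights=w))
    geometry = s.geometry

    if restricted:
        if table is None:
            table = default_lookup_table(RESTRICTED_GRID_STEP)
        cell, phi, a = _restricted_2p_search(th, y, w, table, geometry)
        # convert axis-frame table params to the θ-frame of the fitting curve:
        # for a membrane β = 90° − θ flips the sign of the cos2 term
        b = float(table.b2p.ravel()[cell]) * (-1.0 if geometry == "membrane" else 1.0)
        c = float(table.c2p.ravel()[cell])
        if b < 0:  # canonical form B >= 0 (φ shifted by 90°)
            b, phi = -b, phi + 90.0
        i, j = np.unravel_index(cell, table.shape)
        fitted = eq2_log2r(th, a, b, c, phi, phi)
        r2, rmsd, chi2 = _fit_scores(th, y, w, fitted)
        zero_var = bool(np.allclose(y, y[0])) if y.size else True
        return Fit2PResult(
            a2p=float(a), b2p=b, c2p=c, phi1_deg=float(phi % 180.0),
            phi2_deg=float(phi % 180.0), restricted=True,
            log2_rmax=_signed_extremum(lambda t: eq2_log2r(t, a, b, c, phi, phi)),
            r2=np.nan if zero_var else r2, rmsd=rmsd, chi2=chi2, n=s.n,
            alpha0=float(table.alpha0[i]), sigma=float(table.sigma[j]),
            zero_variance=zero_var,
        )

    # tiny ridge on (B, C): negligible for identified parameters, pins the
    # flat-data degeneracy (B = 0 leaves C unconstrained) at zero
    ridge = 1e-3

    def resid(p):
        a, b, c, phim, dphi = p
        r = sw * (eq2_log2r(th, a, b, c, phim + dphi / 2, phim - dphi / 2) - y)
        pen = _positivity_penalty(b, c)
        return np.concatenate([r, [pen, ridge * b, ridge * c]])

    starts = [(b0, c0, phi0)
              for phi0 in (0.0, 45.0, 90.0, 135.0)
              for b0 in (0.1, 0.5, 0.9)
              for c0 in (0.05, 0.3)]
    if table is not None:
        # seed with the Gaussian-restricted optimum so the free fit can only improve
        cell, phi_r, a_r = _restricted_2p_search(th, y, w, table, geometry)
        sgn = -1.0 if geometry == "membrane" else 1.0
        starts.append((sgn * float(table.b2p.ravel()[cell]), float(table.c2p.ravel()[cell]), phi_r))
    best = None
    for b0, c0, phi0 in starts:
        try:
            sol = least_squares(
                resid,
                x0=[a0, b0, c0, phi0, 0.0],
                # |B| up to the delta-pole extreme 4/3 plus headroom; |C| is
                # physically capped at 1/3 (delta pole), bounded generously
                bounds=([-np.inf, -1.5, -0.6, -360.0, -PHI_SPLIT_MAX],
                        [np.inf, 1.5, 0.6, 360.0, PHI_SPLIT_MAX]),
                method="trf",
            )
        except Exception:  # pragma: no cover - defensive
            continue
        key = (round(sol.cost, 12), abs(sol.x[1]))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError("2P fit failed from every start")
    # nested-model check: retain C only if it improves the fit significantly,
    # otherwise the weakly identified cos4θ direction chases noise
    best_red = None
    for phi0 in (0.0, 45.0, 90.0, 135.0):
        for b0 in (0.1, 0.5, 0.9):
            try:
                sol = least_squares(
                    lambda p: resid([p[0], p[1], 0.0, p[2], p[3]]),
                    x0=[a0, b0, phi0, 0.0],
                    bounds=([-np.inf, -1.5, -360.0, -PHI_SPLIT_MAX],
                            [np.inf, 1.5, 360.0, PHI_SPLIT_MAX]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if best_red is None or sol.cost < best_red.cost:
                best_red = sol
    use_reduced = False
    if best_red is not None:
        sse_full = 2.0 * best[1].cost
        sse_red = 2.0 * best_red.cost
        dof = max(s.n - 5, 1)
        use_reduced = (sse_red - sse_full) < 4.0 * sse_full / dof
    if use_reduced:
        a, b, phim, dphi = best_red.x
        c = 0.0
    else:
        a, b, c, phim, dphi = best[1].x
    if b < 0:
        # canonical form B >= 0: cos2(θ−φ) = −cos2(θ−φ−90°), cos4 unchanged
        b, phim = -b, phim + 90.0
    phi1, phi2 = phim + dphi / 2, phim - dphi / 2
    fitted = eq2_log2r(th, a, b, c, phi1, phi2)
    r2, rmsd, chi2 = _fit_scores(th, y, w, fitted)
    zero_var = bool(np.allclose(y, y[0])) if y.size else True
    return Fit2PResult(
        a2p=float(a), b2p=float(b), c2p=float(c),
        phi1_deg=float(phi1 % 180.0), phi2_deg=float(phi2 % 180.0),
        restricted=False,
        log2_rmax=_signed_extremum(lambda t: eq2_log2r(t, a, b, c, phi1, phi2)),
        r2=np.nan if zero_var else r2, rmsd=rmsd, chi2=chi2, n=s.n,
        zero_variance=zero_var,
    )


def _restricted_2p_search(th, y, w, table: LookupTable, geometry: str):
    """Coarse grid search over lookup cells × phase, offset profiled."""
    b_flat = table.b2p.ravel()
    c_flat = table.c2p.ravel()
    wsum = w.sum()
    best = None
    t = np.radians(th)
    for phi in np.arange(0.0, 180.0, 5.0):
        # curve in feature angle θ: β depends on geometry via the forward map
        shift = np.radians(phi)
        x = np.cos(2 * (t - shift))
        z = np.cos(4 * (t - shift))
        if geometry == "membrane":
            x = -x  # β = 90 − θ flips the cos2 term
        num = 1.0 + b_flat[:, None] * x[None, :] + c_flat[:, None] * z[None, :]
        den = 1.0 - b_flat[:, None] * x[None, :] + c_flat[:, None] * z[None, :]
        pred = np.log2(np.maximum(num, 1e-12) / np.maximum(den, 1e-12))
        resid0 = y[None, :] - pred
        a_prof = (resid0 * w[None, :]).sum(axis=1) / wsum
        sse = (w[None, :] * (resid0 - a_prof[:, None]) ** 2).sum(axis=1)
        k = int(np.argmin(sse))
        if best is None or sse[k] < best[0]:
            best = (float(sse[k]), k, float(phi), float(a_prof[k]))
    _, cell, phi, a = best
    return cell, phi, a


# ---------------------------------------------------------------------------
# goodness maps over the (alpha0, sigma) grid


@dataclass
class GoodnessMap:
    """Agreement between data and every tabulated (α0, σ) distribution."""

    alpha0: np.ndarray
    sigma: np.ndarray
    r2: np.ndarray
    rmsd: np.ndarray
    chi2: np.ndarray
    best_alpha0: float
    best_sigma: float
    best_idx: tuple[int, int]
    geometry: str = "membrane"
    modalities: tuple[str, ...] = ()
    confidence: np.ndarray | None = None
    r2_defined: bool = True

    def near_optimal_cells(self, delta_r2: float = 0.005) -> int:
        """Number of cells within ``delta_r2`` of the maximum r²."""
        if not self.r2_defined:
            return int(np.isfinite(self.rmsd).sum())
        m = np.nanmax(self.r2)
        return int(np.sum(self.r2 >= m - delta_r2))


class _BinnedModality:
    """Sufficient statistics of one object's samples on the θ-bin grid.

    Stores (Σw, Σwy, Σwy²) per bin for three weightings — intensity weights
    (r²), unit weights (RMSD) and 1/σ² weights (χ²) — which is all a
    profiled-offset quadratic fit needs.  Statistics are additive across
    objects, which makes bootstrap refits a matter of summing arrays.
    """

    __slots__ = ("modality", "stats", "n")

    def __init__(self, s: ThetaSamples):
        self.modality = s.modality
        self.n = s.n
        idx = np.floor(s.theta_deg / 180.0 * N_THETA_BINS).astype(int) % N_THETA_BINS
        sig = _chi2_sigmas(s.theta_deg, s.log2r)
        self.stats = {}
        for name, w in (
            ("w", np.maximum(s.weight, 0.0)),
            ("u", np.ones(s.n)),
            ("c", 1.0 / sig**2),
        ):
            W = np.bincount(idx, weights=w, minlength=N_THETA_BINS)
            S = np.bincount(idx, weights=w * s.log2r, minlength=N_THETA_BINS)
            Q = np.bincount(idx, weights=w * s.log2r**2, minlength=N_THETA_BINS)
            self.stats[name] = (W, S, Q)


def _bin_centers() -> np.ndarray:
    return (np.arange(N_THETA_BINS) + 0.5) * THETA_BIN_DEG


#: cache of predicted-curve matrices keyed by (table identity, modality, geometry)
_PRED_CACHE: dict = {}


def _pred_matrix(table: LookupTable, modality: str, geometry: str) -> np.ndarray:
    """Predicted log₂ r at every θ-bin center for every lookup cell (cached)."""
    key = (id(table), modality, geometry)
    hit = _PRED_CACHE.get(key)
    if hit is not None and hit[0] is table:
        return hit[1]
    out = _pred_matrix_compute(table, modality, geometry)
    if len(_PRED_CACHE) > 16:
        _PRED_CACHE.clear()
    _PRED_CACHE[key] = (table, out)
    return out


def _pred_matrix_compute(table: LookupTable, modality: str, geometry: str) -> np.ndarray:
    t = np.radians(_bin_centers())
    x = np.cos(2 * t)
    z = np.cos(4 * t)
    if geometry == "membrane":
        x = -x
    if modality == "1p":
        b = table.b1p.ravel()[:, None]
        num = 1.0 + b * x[None, :]
        den = 1.0 - b * x[None, :]
    else:
        b = table.b2p.ravel()[:, None]
        c = table.c2p.ravel()[:, None]
        num = 1.0 + b * x[None, :] + c * z[None, :]
        den = 1.0 - b * x[None, :] + c * z[None, :]
    return np.log2(np.maximum(num, 1e-12) / np.maximum(den, 1e-12))


def _sse_profiled(pred: np.ndarray, W, S, Q, profile_offset=True):
    """Weighted SSE per cell with the additive offset profiled out."""
    Wt, St, Qt = W.sum(), S.sum(), Q.sum()
    if Wt <= 0:
        return np.full(pred.shape[0], np.nan), 0.0
    PS = pred @ S
    PW = pred @ W
    PPW = (pred**2) @ W
    sse = Qt - 2 * PS + PPW
    if profile_offset:
        sse = sse - (St - PW) ** 2 / Wt
        sst = Qt - St**2 / Wt
    else:
        sst = Qt
    return sse, float(sst)


def _group_binned(sample_sets, table, geometry):
    """Binned stats per object per modality + pred matrices per modality."""
    if isinstance(sample_sets, ThetaSamples):
        sample_sets = [sample_sets]
    binned = [_BinnedModality(s) for s in sample_sets if s.n > 0]
    if not binned:
        raise ValueError("no samples supplied")
    modalities = sorted({b.modality for b in binned})
    preds = {m: _pred_matrix(table, m, geometry) for m in modalities}
    return binned, modalities, preds


def goodness_map(
    sample_sets,
    table: LookupTable | None = None,
    geometry: str = "membrane",
    profile_offsets: bool = True,
) -> GoodnessMap:
    """Score every tabulated (α0, σ) cell against the data.

    Accepts one or several :class:`ThetaSamples` (multiple modalities give a
    combined map with a shared distribution and per-modality offsets).  For
    every cell the predicted curve is compared to the binned data with the
    offset profiled out by weighted least squares; slices report r²
    (intensity-weighted), RMSD (unweighted), and χ² (scatter-estimated
    per-point variances).  Best cell maximizes r² (equivalently minimizes the
    pooled weighted SSE).
    """
    if table is None:
        table = _map_table()
    binned, modalities, preds = _group_binned(sample_sets, table, geometry)
    ncells = table.b1p.size
    sse_w = np.zeros(ncells)
    sst_w = 0.0
    sse_u = np.zeros(ncells)
    n_tot = 0
    chi2 = np.zeros(ncells)
    for m in modalities:
        group = [b for b in binned if b.modality == m]
        pred = preds[m]
        for kind, acc in (("w", "w"), ("u", "u"), ("c", "c")):
            W = sum(b.stats[kind][0] for b in group)
            S = sum(b.stats[kind][1] for b in group)
            Q = sum(b.stats[kind][2] for b in group)
            sse, sst = _sse_profiled(pred, W, S, Q, profile_offsets)
            if kind == "w":
                sse_w += sse
                sst_w += sst
            elif kind == "u":
                sse_u += sse
                n_tot += sum(b.n for b in group)
            else:
                chi2 += sse
    r2_defined = sst_w > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (1.0 - sse_w / sst_w if r2_defined else np.full(ncells, np.nan)).reshape(table.shape)
    rmsd = np.sqrt(np.maximum(sse_u, 0.0) / max(n_tot, 1)).reshape(table.shape)
    chi2 = chi2.reshape(table.shape)
    k = int(np.argmin(sse_w))
    i, j = np.unravel_index(k, table.shape)
    return GoodnessMap(
        alpha0=table.alpha0,
        sigma=table.sigma,
        r2=r2,
        rmsd=rmsd,
        chi2=chi2,
        best_alpha0=float(table.alpha0[i]),
        best_sigma=float(table.sigma[j]),
        best_idx=(int(i), int(j)),
        geometry=geometry,
        modalities=tuple(modalities),
        r2_defined=bool(r2_defined),
    )


# ---------------------------------------------------------------------------
# pooled fits


@dataclass
class PooledFit:
    """Separate and combined fits of pooled multi-experiment data."""

    fit1p: Fit1PResult | None
    fit2p: Fit2PResult | None
    map1p: GoodnessMap | None
    map2p: GoodnessMap | None
    map_combined: GoodnessMap | None
    combined_alpha0: float | None
    combined_sigma: float | None
    predicted_1p_from_2p: tuple[np.ndarray, np.ndarray] | None = None


def pool_and_fit(
    sample_sets,
    table: LookupTable | None = None,
    geometry: str = "membrane",
) -> PooledFit:
    """Pool objects and fit 1P, 2P, and combined 1P+2P data.

    Concatenates samples per modality, fits the parametric curves, and runs
    the (α0, σ) scan separately for each modality and for the combined set
    (shared distribution, independent offsets).  When 2P data are present, a
    predicted 1P curve implied by the 2P best cell is emitted as well.
    """
    if isinstance(sample_sets, ThetaSamples):
        sample_sets = [sample_sets]
    if table is None:
        table = _map_table()
    by_mod: dict[str, list[ThetaSamples]] = {}
    for s in sample_sets:
        by_mod.setdefault(s.modality, []).append(s)
    fit1 = fit2 = m1 = m2 = None
    if "1p" in by_mod:
        fit1 = fit_1p(by_mod["1p"])
        m1 = goodness_map(by_mod["1p"], table, geometry)
    else:
        log.info("no 1P sample sets; 1P slots absent")
    if "2p" in by_mod:
        fit2 = fit_2p(by_mod["2p"], restricted=False, table=table)
        m2 = goodness_map(by_mod["2p"], table, geometry)
    else:
        log.info("no 2P sample sets; 2P slots absent")
    mc = None
    ca = cs = None
    if len(by_mod) >= 1:
        all_sets = [s for group in by_mod.values() for s in group]
        mc = goodness_map(all_sets, table, geometry)
        ca, cs = mc.best_alpha0, mc.best_sigma
    pred_artifact = None
    if m2 is not None:
        i, j = m2.best_idx
        dist = TiltDistribution.single(float(m2.alpha0[i]), float(m2.sigma[j]), geometry)
        from .orientation import predict_log2r

        th = np.arange(0.0, 180.0, 1.0)
        pred_artifact = (th, predict_log2r(dist, th, "1p", geometry))
    return PooledFit(
        fit1p=fit1,
        fit2p=fit2,
        map1p=m1,
        map2p=m2,
        map_combined=mc,
        combined_alpha0=ca,
        combined_sigma=cs,
        predicted_1p_from_2p=pred_artifact,
    )


# ---------------------------------------------------------------------------
# bootstrap confidence regions


def bootstrap_confidence(
    sample_sets,
    table: LookupTable | None = None,
    geometry: str = "membrane",
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
):
    """Bootstrap confidence mask for the combined (α0, σ) fit.

    The resampling unit is the object (cell/vesicle): all sample sets sharing
    an ``object_id`` enter or leave a bootstrap replicate together, because
    pixels within an object are correlated.  Each replicate refits the best
    cell; the mask is the smallest set of grid cells containing at least
    ``level`` of the replicate best-fits (the full-data best cell is always
    included).  Deterministic given ``seed``.

    Returns ``(mask, counts, gmap)``: boolean grid, per-cell best-fit counts,
    and the full-data goodness map with ``confidence`` filled in.
    """
    if isinstance(sample_sets, ThetaSamples):
        sample_sets = [sample_sets]
    if table is None:
        table = _map_table()
    if n_boot < 50:
        log.warning("n_boot=%d < 50: confidence mask will be coarse", n_boot)
    object_ids = sorted({s.object_id for s in sample_sets})
    if len(object_ids) < 2:
        raise ValueError("bootstrap needs >= 2 objects (resampling unit is the object)")
    binned, modalities, preds = _group_binned(sample_sets, table, geometry)
    by_object: dict[str, list[_BinnedModality]] = {oid: [] for oid in object_ids}
    for s, b in zip([s for s in sample_sets if s.n > 0], binned):
        by_object[s.object_id].append(b)
    # per-object per-modality sufficient statistics, projected through the
    # prediction matrix once so each bootstrap replicate is a small matmul
    ncells = table.b1p.size
    n_obj = len(object_ids)
    rng = np.random.default_rng(seed)
    mult = np.zeros((n_boot, n_obj))
    for b in range(n_boot):
        mult[b] = np.bincount(rng.integers(0, n_obj, n_obj), minlength=n_obj)
    sse_boot = np.zeros((n_boot, ncells))
    for m in modalities:
        Wmat = np.stack([
            sum((bb.stats["w"][0] for bb in by_object[o] if bb.modality == m),
                np.zeros(N_THETA_BINS)) for o in object_ids
        ])
        Smat = np.stack([
            sum((bb.stats["w"][1] for bb in by_object[o] if bb.modality == m),
                np.zeros(N_THETA_BINS)) for o in object_ids
        ])
        Qmat = np.stack([
            sum((bb.stats["w"][2] for bb in by_object[o] if bb.modality == m),
                np.zeros(N_THETA_BINS)) for o in object_ids
        ])
        pred = preds[m]
        P_S = Smat @ pred.T      # (n_obj, ncells): Σ_bins pred·S per object
        P_W = Wmat @ pred.T
        P2_W = Wmat @ (pred**2).T
        w_tot = Wmat.sum(axis=1)
        s_tot = Smat.sum(axis=1)
        q_tot = Qmat.sum(axis=1)
        Wt = mult @ w_tot        # (n_boot,)
        St = mult @ s_tot
        Qt = mult @ q_tot
        PS = mult @ P_S          # (n_boot, ncells)
        PW = mult @ P_W
        PPW = mult @ P2_W
        with np.errstate(invalid="ignore", divide="ignore"):
            sse = Qt[:, None] - 2 * PS + PPW
            ok = Wt > 0
            sse[ok] -= (St[ok, None] - PW[ok]) ** 2 / Wt[ok, None]
        sse_boot += np.where(np.isfinite(sse), sse, 0.0)
    best_cells = np.argmin(sse_boot, axis=1)
    counts = np.bincount(best_cells, minlength=ncells)
    order = np.argsort(-counts, kind="stable")
    need = int(np.ceil(level * n_boot))
    cum = np.cumsum(counts[order])
    take = int(np.searchsorted(cum, need)) + 1
    mask = np.zeros(ncells, dtype=bool)
    mask[order[:take]] = True
    gmap = goodness_map(sample_sets, table, geometry)
    mask[np.ravel_multi_index(gmap.best_idx, table.shape)] = True
    mask = mask.reshape(table.shape)
    gmap.confidence = mask
    return mask, counts.reshape(table.shape), gmap


# ---------------------------------------------------------------------------
# two-Gaussian mixture search


@dataclass
class MixtureCandidate:
    """One candidate pair of wrapped-Gaussian components."""

    alpha0_a: float
    sigma_a: float
    alpha0_b: float
    sigma_b: float
    fraction_a: float
    b1p: float
    b2p: float
    c2p: float
    residual: float
    r2: float
    entropy_bits: float | None = None

    def distribution(self, geometry: str = "membrane") -> TiltDistribution:
        return TiltDistribution.mixture(
            (self.alpha0_a, self.sigma_a), (self.alpha0_b, self.sigma_b),
            self.fraction_a, geometry=geometry,
        )


def mixture_search(
    targets: DichroicShapeParams,
    alpha0_step: float = 5.0,
    sigma_values=None,
    fraction_step: float = 0.1,
    top_k: int = 20,
    entropy_pool: int = 200,
) -> list[MixtureCandidate]:
    """Exhaustive search for two-Gaussian mixtures matching (B1P, B2P, C2P).

    Mixture absorption moments are weight-linear, so every candidate's shape
    parameters come from a single closed-form evaluation over the component
    grid.  Candidates are ranked by squared residual against the three
    targets (r² reported alongside); near-ties are broken by the higher
    differential entropy of the mixture tilt density (preferring the least
    committed distribution), computed for the ``entropy_pool`` best.
    """
    if not all(np.isfinite(v) for v in (targets.b1p, targets.b2p, targets.c2p)):
        raise ValueError("targets must be finite")
    a_grid = np.arange(0.0, 90.0 + 1e-9, alpha0_step)
    s_grid = np.asarray(
        sigma_values if sigma_values is not None else np.arange(5.0, 46.0, 5.0), float
    )
    table = build_lookup_table(a_grid, s_grid)
    # component moments back from the shape params is awkward; recompute directly
    from .orientation import compute_moments

    comps = [(a, s) for a in a_grid for s in s_grid]
    m2 = np.empty(len(comps))
    m4 = np.empty(len(comps))
    for i, (a, s) in enumerate(comps):
        mom = compute_moments(TiltDistribution.single(a, s))
        m2[i], m4[i] = mom.m2, mom.m4
    nc = len(comps)
    ii, jj = np.triu_indices(nc)
    fr = np.arange(fraction_step, 1.0, fraction_step)
    # same-component pairs are pure single Gaussians: keep once at f = 1
    pair_i = np.concatenate([np.repeat(ii[ii < jj], fr.size), np.arange(nc)])
    pair_j = np.concatenate([np.repeat(jj[ii < jj], fr.size), np.arange(nc)])
    pair_f = np.concatenate([np.tile(fr, int((ii < jj).sum())), np.ones(nc)])
    mm2 = pair_f * m2[pair_i] + (1 - pair_f) * m2[pair_j]
    mm4 = pair_f * m4[pair_i] + (1 - pair_f) * m4[pair_j]
    b1 = (3 * mm2 - 1) / (mm2 + 1)
    dc = 3 * mm4 / 8 + 3 * (mm2 - mm4) / 8 + 9 * (1 - 2 * mm2 + mm4) / 64
    b2 = (mm4 / 2 - 3 * (1 - 2 * mm2 + mm4) / 16) / dc
    c2 = (mm4 / 8 - 3 * (mm2 - mm4) / 8 + 3 * (1 - 2 * mm2 + mm4) / 64) / dc
    t = np.array([targets.b1p, targets.b2p, targets.c2p])
    ss = (b1 - t[0]) ** 2 + (b2 - t[1]) ** 2 + (c2 - t[2]) ** 2
    sst = float(np.sum((t - t.mean()) ** 2))
    order = np.argsort(ss, kind="stable")[: max(entropy_pool, top_k)]
    cands = []
    for k in order:
        i, j, f = int(pair_i[k]), int(pair_j[k]), float(pair_f[k])
        cand = MixtureCandidate(
            alpha0_a=comps[i][0], sigma_a=comps[i][1],
            alpha0_b=comps[j][0], sigma_b=comps[j][1],
            fraction_a=f,
            b1p=float(b1[k]), b2p=float(b2[k]), c2p=float(c2[k]),
            residual=float(ss[k]),
            r2=float(1.0 - ss[k] / sst) if sst > 0 else np.nan,
        )
        cand.entropy_bits = tilt_entropy_bits(cand.distribution())
        cands.append(cand)
    # rank: residual first; near-ties (within 1e-9) favor higher entropy
    cands.sort(key=lambda c: (round(c.residual / 1e-9) * 1e-9, -c.entropy_bits))
    return cands[:top_k]


# ---------------------------------------------------------------------------
# r_max -> orientation


@dataclass
class OrientationMatch:
    """Grid cells whose predicted log₂(r_max) matches supplied values."""

    mask: np.ndarray  # boolean (n_alpha0, n_sigma)
    cells: list[tuple[float, float]]
    achievable: dict  # modality -> (min, max) of predicted log2_rmax
    tolerance: float


def rmax_to_orientation(
    log2_rmax_1p: float | None = None,
    log2_rmax_2p: float | None = None,
    table: LookupTable | None = None,
    geometry: str = "membrane",
    tolerance: float = 0.05,
) -> OrientationMatch:
    """All (α0, σ) cells consistent with measured log₂(r_max) values.

    1P-only input yields a level-set curve of cells (one shape parameter
    cannot pin down two distribution parameters); adding a 2P value narrows
    the set.  Values outside the achievable range give an empty set together
    with the achievable range report.
    """
    if log2_rmax_1p is None and log2_rmax_2p is None:
        raise ValueError("at least one modality value is required")
    if table is None:
        table = _map_table()
    mask = np.ones(table.shape, dtype=bool)
    achievable = {}
    for modality, value in (("1p", log2_rmax_1p), ("2p", log2_rmax_2p)):
        curves = _pred_matrix(table, modality, geometry)  # θ-bin centers
        # signed extremum of largest magnitude; exact ± ties resolve to θ = 0
        t0 = np.radians(0.0)
        x0 = -np.cos(2 * t0) if geometry == "membrane" else np.cos(2 * t0)
        z0 = np.cos(4 * t0)
        if modality == "1p":
            b = table.b1p.ravel()
            v0 = np.log2(np.maximum(1 + b * x0, 1e-12) / np.maximum(1 - b * x0, 1e-12))
        else:
            b, c = table.b2p.ravel(), table.c2p.ravel()
            v0 = np.log2(
                np.maximum(1 + b * x0 + c * z0, 1e-12)
                / np.maximum(1 - b * x0 + c * z0, 1e-12)
            )
        vext = curves[np.arange(curves.shape[0]), np.argmax(np.abs(curves), axis=1)]
        pred = np.where(np.abs(v0) >= np.abs(vext) - 1e-12, v0, vext).reshape(table.shape)
        achievable[modality] = (float(np.nanmin(pred)), float(np.nanmax(pred)))
        if value is not None:
            mask &= np.abs(pred - value) <= tolerance
    cells = [
        (float(table.alpha0[i]), float(table.sigma[j]))
        for i, j in zip(*np.nonzero(mask))
    ]
    return OrientationMatch(mask=mask, cells=cells, achievable=achievable, tolerance=tolerance)
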