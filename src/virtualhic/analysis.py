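"""Downstream analytics of virtual Hi-C output.

Covers the quantitative readouts of the assay: contact/ligation frequency
versus genomic separation P(s) and its power-law exponent, ligation
frequency versus native Euclidean distance and its sigmoidal length scale,
Knight-Ruiz matrix balancing, and the compartment diagnostics built on the
observed/expected Pearson correlation matrix (first principal component,
singular value spectrum, column sums).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.spatial.distance import pdist

from .maps import ContactMatrix, DataError
from .model import SIGMA_NM, ParameterError


@dataclass
class ScalingCurve:
    """Frequency versus distance, genomic (beads) or Euclidean (nm).

    ``y`` may contain NaN where a bin is undefined (no candidates); counts
    holds the per-bin sample size; fit holds the result of the last fit
    applied to this curve.
    """

    x: np.ndarray
    y: np.ndarray
    counts: np.ndarray
    kind: str = "genomic"  # 'genomic' | 'euclidean'
    fit: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise DataError("abscissa must be strictly increasing")
        valid = ~np.isnan(self.y)
        if np.any(self.y[valid] < 0):
            raise DataError("frequencies must be non-negative")


def _matrix_data(matrix) -> np.ndarray:
    data = matrix.data if isinstance(matrix, ContactMatrix) else np.asarray(
        matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1] or data.size == 0:
        raise DataError("need a non-empty square matrix")
    return data


def ps_curve(matrix, log_bins: bool = False, n_log_bins: int = 30) -> ScalingCurve:
    """Mean map entry versus genomic separation, normalised to unit sum.

    At separation s the frequency is the mean of all entries with
    |i - j| = s; with log_bins, separations are pooled into geometric bins
    (count-weighted means, geometric-mean abscissa). The curve is
    normalised to sum 1 over s >= 1 so fitted exponents are scale-free.
    """
    data = _matrix_data(matrix)
    n = data.shape[0]
    if n < 2:
        raise DataError("matrix too small for a scaling curve")
    s = np.arange(1, n)
    sums = np.array([np.trace(data, offset=k) for k in s], dtype=float)
    counts = (n - s).astype(float)
    if log_bins:
        edges = np.unique(np.geomspace(1, n - 1, n_log_bins + 1).round()
                          .astype(int))
        xs, ys, cs = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (s >= lo) & (s < hi) if hi < edges[-1] else (s >= lo) & (s <= hi)
            if not m.any():
                continue
            cs.append(counts[m].sum())
            ys.append(sums[m].sum() / counts[m].sum())
            xs.append(np.exp(np.mean(np.log(s[m]))))
        x = np.array(xs)
        y = np.array(ys)
        c = np.array(cs)
    else:
        x, y, c = s.astype(float), sums / counts, counts
    total = np.nansum(y)
    if total > 0:
        y = y / total
    return ScalingCurve(x, y, c, "genomic")


def fit_power_exponent(curve: ScalingCurve, s_range: tuple | None = None):
    """Least-squares power-law exponent of a scaling curve in log-log space.

    Default fit window is s in [3, n/10], excluding the short-range
    bond-dominated regime. Non-positive frequencies in the window are
    excluded with a warning. Returns (exponent, stderr) and records the
    fit on the curve.
    """
    if s_range is None:
        s_range = (3.0, max(curve.x.max() / 10.0, 6.0))
    lo, hi = s_range
    m = (curve.x >= lo) & (curve.x <= hi) & ~np.isnan(curve.y)
    if np.any(curve.y[m] <= 0):
        warnings.warn("non-positive frequencies excluded from power-law fit")
        m &= curve.y > 0
    if m.sum() < 3:
        raise DataError("need >= 3 positive points in the fit range")
    res = stats.linregress(np.log10(curve.x[m]), np.log10(curve.y[m]))
    curve.fit = {"type": "power", "exponent": float(res.slope),
                 "stderr": float(res.stderr), "s_range": (float(lo), float(hi)),
                 "n_points": int(m.sum())}
    return float(res.slope), float(res.stderr)


def euclidean_ligation_curve(results, bin_width_nm: float = 2.0,
                             exclude_adjacent: bool = False) -> ScalingCurve:
    """Ligation frequency versus native Euclidean end-pair distance.

    For each experiment the candidate pairs are all unordered pairs of free
    ends present at digestion time, at their separation in the native
    structure; the frequency in a distance bin is (ligated pairs)/(candidate
    pairs) pooled over experiments. Bins with no candidates are undefined
    (NaN), not zero, and the curve is deliberately NOT normalised: it is a
    per-pair ligation probability, not a distribution.

    exclude_adjacent drops pairs of ends on the same or adjacent beads
    (self-religation of a single cut and single-bead self-circles).
    """
    if bin_width_nm <= 0:
        raise ParameterError("bin_width_nm must be positive")
    cand_d, lig_d = [], []
    for res in results:
        pos = res.end_native_positions
        k = pos.shape[0]
        if k < 2:
            continue
        d = pdist(pos) * SIGMA_NM
        if exclude_adjacent:
            beads = res.end_beads
            ia, ja = np.triu_indices(k, 1)
            keep = np.abs(beads[ia] - beads[ja]) > 1
            d = d[keep]
        cand_d.append(d)
        ends = res.event_end_array()
        if len(ends):
            dv = np.linalg.norm(pos[ends[:, 0]] - pos[ends[:, 1]],
                                axis=1) * SIGMA_NM
            if exclude_adjacent:
                keep = np.abs(res.end_beads[ends[:, 0]]
                              - res.end_beads[ends[:, 1]]) > 1
                dv = dv[keep]
            lig_d.append(dv)
    if not cand_d:
        raise DataError("no experiments with >= 2 free ends")
    cand = np.concatenate(cand_d)
    lig = np.concatenate(lig_d) if lig_d else np.empty(0)
    dmax = cand.max() if cand.size else bin_width_nm
    edges = np.arange(0.0, dmax + 2 * bin_width_nm, bin_width_nm)
    nc, _ = np.histogram(cand, bins=edges)
    nl, _ = np.histogram(lig, bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(nc > 0, nl / np.maximum(nc, 1), np.nan)
    x = 0.5 * (edges[:-1] + edges[1:])
    return ScalingCurve(x, y, nc.astype(float), "euclidean")


@dataclass
class SigmoidFit:
    """Logistic fit A / (1 + exp((d - midpoint)/width)) of a decay curve."""

    midpoint: float
    width: float
    amplitude: float
    success: bool
    residual: float


def fit_sigmoid(curve: ScalingCurve) -> SigmoidFit:
    """Least-squares logistic fit of a decaying Euclidean ligation curve.

    Returns midpoint d_1/2 (same units as the abscissa, nm for Euclidean
    curves), width and amplitude. A non-decaying input or a failed
    optimisation yields success=False with the residual report.
    """
    m = ~np.isnan(curve.y) & (curve.counts > 0)
    x, y = curve.x[m], curve.y[m]
    if x.size < 4:
        return SigmoidFit(np.nan, np.nan, np.nan, False, np.inf)
    third = max(1, x.size // 3)
    if y[:third].mean() <= y[-third:].mean():
        return SigmoidFit(np.nan, np.nan, np.nan, False, np.inf)

    def logistic(d, A, dhalf, wdt):
        return A / (1.0 + np.exp((d - dhalf) / wdt))

    A0 = y[:third].mean()
    half = A0 / 2.0
    below = np.nonzero(y < half)[0]
    d0 = x[below[0]] if below.size else x[x.size // 2]
    try:
        popt, _ = optimize.curve_fit(
            logistic, x, y, p0=[A0, d0, max(curve.x[1] - curve.x[0], 1e-3)],
            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError):
        return SigmoidFit(np.nan, np.nan, np.nan, False, np.inf)
    resid = float(np.sqrt(np.mean((logistic(x, *popt) - y) ** 2)))
    fit = SigmoidFit(float(popt[1]), float(popt[2]), float(popt[0]), True,
                     resid)
    curve.fit = {"type": "sigmoid", "midpoint": fit.midpoint,
                 "width": fit.width, "amplitude": fit.amplitude,
                 "residual": resid}
    return fit


def half_plateau_distance(curve: ScalingCurve,
                          plateau_max: float = 12.0) -> float:
    """Distance at which the curve first falls to half its small-d plateau.

    The plateau is the count-weighted mean frequency over defined bins with
    abscissa below ``plateau_max`` (default 12 nm, safely inside the 15 nm
    capture radius); the crossing is linearly interpolated between the
    bracketing defined bins.
    """
    valid = ~np.isnan(curve.y) & (curve.counts > 0)
    pm = valid & (curve.x < plateau_max)
    if not pm.any():
        raise DataError("no defined bins below the plateau range")
    plateau = float(np.average(curve.y[pm], weights=curve.counts[pm]))
    half = plateau / 2.0
    xs, ys = curve.x[valid], curve.y[valid]
    prev = None
    for i in range(xs.size):
        if ys[i] >= half:
            prev = i
            continue
        if prev is None:
            continue
        # first downward crossing
        x0, y0, x1, y1 = xs[prev], ys[prev], xs[i], ys[i]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
    return float(xs[-1])


class BalanceError(RuntimeError):
    """Knight-Ruiz balancing failed to converge on the supported rows."""


@dataclass
class BalancedMatrix:
    """KR-balanced map: diag(x) A diag(x) with unit row/column sums.

    Masked (all-zero) rows/columns are excluded from balancing and left
    zero; their scaling entries are NaN. residual is max |row sum - 1| on
    the supported rows.
    """

    matrix: np.ndarray
    scaling: np.ndarray
    mask: np.ndarray
    residual: float
    iterations: int


def kr_balance(matrix, tol: float = 1e-6, max_iter: int = 1000) -> BalancedMatrix:
    """Knight-Ruiz balancing of a symmetric non-negative matrix.

    Newton iteration with an inner conjugate-gradient solve (the 'bnewt'
    scheme), applied to the submatrix of rows with non-zero support; the
    masked rows are reported in metadata rather than balanced. Raises
    BalanceError naming the offending rows when the support structure does
    not admit a positive balancing within max_iter outer/inner steps.
    """
    A = _matrix_data(matrix)
    if np.any(A < 0):
        raise DataError("matrix must be non-negative")
    if not np.allclose(A, A.T, rtol=1e-10, atol=1e-12):
        raise DataError("matrix must be symmetric")
    mask = A.sum(axis=1) > 0
    if not mask.any():
        raise BalanceError("all rows are empty")
    S = np.ascontiguousarray(A[np.ix_(mask, mask)])
    n = S.shape[0]

    # bnewt: inexact Newton with CG inner iterations and clipping bounds
    x = np.ones(n)
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (S @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    total_inner = 0
    while np.max(np.abs(rk)) > tol:
        outer += 1
        if outer > max_iter or total_inner > 50 * max_iter:
            bad = np.flatnonzero(mask)[np.argsort(np.abs(rk))[-5:]]
            raise BalanceError(
                f"no convergence in {max_iter} iterations; worst rows {bad.tolist()}")
        k = 0
        y = np.ones(n)
        innertol = max(eta ** 2 * rout, (tol * 0.5) ** 2)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (S @ (x * p)) + v * p
            denom = p @ w
            if not np.isfinite(denom) or denom <= 0:
                raise BalanceError(
                    "inner CG breakdown: support structure admits no "
                    "positive balancing")
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > n:
                break
        total_inner += k
        x = x * y
        v = x * (S @ x)
        if not np.isfinite(v).all() or (v <= 0).any():
            bad = np.flatnonzero(mask)[np.flatnonzero(~np.isfinite(v)
                                                      | (v <= 0))[:5]]
            raise BalanceError(
                f"balancing diverged on rows {bad.tolist()}: "
                "support structure admits no positive balancing")
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        eta = g * rat
        if g * eta ** 2 > 0.1:
            eta = max(eta, g * eta ** 2)
        eta = max(min(eta, etamax), stop_tol / max(np.sqrt(rout), 1e-300))

    B = np.zeros_like(A)
    B[np.ix_(mask, mask)] = S * np.outer(x, x)
    B = 0.5 * (B + B.T)
    scaling = np.full(A.shape[0], np.nan)
    scaling[mask] = x
    resid = float(np.max(np.abs(B[mask][:, mask].sum(axis=1) - 1.0)))
    return BalancedMatrix(B, scaling, mask, resid, outer)


@dataclass
class PCMResult:
    """Observed/expected Pearson correlation matrix with a validity mask."""

    pcm: np.ndarray
    mask: np.ndarray  # rows with defined (non-constant) O/E profiles


def pearson_correlation_matrix(matrix) -> PCMResult:
    """Observed/expected transform followed by row-pairwise correlation.

    Each diagonal s of the map is divided by its mean (where positive);
    rows with zero variance after the transform are masked with a warning.
    The PCM has unit diagonal on valid rows and NaN elsewhere.
    """
    data = _matrix_data(matrix).copy()
    n = data.shape[0]
    oe = np.zeros_like(data)
    for s in range(n):
        d = np.diagonal(data, offset=s)
        mu = d.mean()
        vals = d / mu if mu > 0 else d
        idx = np.arange(n - s)
        oe[idx, idx + s] = vals
        oe[idx + s, idx] = vals
    std = oe.std(axis=1)
    mask = std > 0
    if not mask.all():
        warnings.warn(f"{int((~mask).sum())} zero-variance rows masked in PCM")
    pcm = np.full((n, n), np.nan)
    if mask.any():
        sub = np.corrcoef(oe[mask])
        sub = np.atleast_2d(sub)
        pcm[np.ix_(mask, mask)] = sub
        ii = np.flatnonzero(mask)
        pcm[ii, ii] = 1.0
    return PCMResult(pcm, mask)


def _pcm_and_mask(pcm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pcm, PCMResult):
        return pcm.pcm, pcm.mask
    arr = _matrix_data(pcm)
    mask = ~np.isnan(arr).all(axis=1)
    return arr, mask


def first_principal_component(pcm, reference=None) -> np.ndarray:
    """Leading eigenvector of the PCM, one entry per bin, unit norm.

    Masked bins get 0. Sign convention: positive correlation with the
    ``reference`` track when given (e.g. a planted A/B compartment track),
    otherwise a positive first valid element.
    """
    arr, mask = _pcm_and_mask(pcm)
    sub = arr[np.ix_(mask, mask)]
    w, v = linalg.eigh(sub)
    vec = v[:, np.argmax(w)]
    full = np.zeros(arr.shape[0])
    full[mask] = vec
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        r = float(np.corrcoef(full[mask], ref[mask])[0, 1])
        if r < 0:
            full = -full
    else:
        first = np.flatnonzero(mask)[0]
        if full[first] < 0:
            full = -full
    norm = np.linalg.norm(full)
    return full / norm if norm > 0 else full


def svd_spectrum(pcm) -> np.ndarray:
    """Singular values of the PCM's valid submatrix, descending."""
    arr, mask = _pcm_and_mask(pcm)
    sub = arr[np.ix_(mask, mask)]
    return linalg.svdvals(sub)


def column_sums(matrix, window: int = 21):
    """Per-column totals and a centred moving average (window bins)."""
    data = _matrix_data(matrix)
    sums = data.sum(axis=0)
    if window < 1:
        raise ParameterError("window must be >= 1")
    kernel = np.ones(window) / window
    ma = np.convolve(sums, kernel, mode="same")
    # correct edge bins for partial kernel overlap
    norm = np.convolve(np.ones_like(sums), kernel, mode="same")
    return sums, ma / norm
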