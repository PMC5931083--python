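"""EMMA-style REML variance components and EMMAX-style association scans.

The model is the single-random-effect linear mixed model

    y = X beta + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I).

Variance components are estimated once by restricted maximum likelihood,
profiled over the ratio delta = se^2 / sg^2 via the spectral decomposition
of K projected off the fixed effects (the EMMA trick: each candidate delta
costs O(n) once the eigendecomposition is done).  The per-marker scan then
fixes the variance components (the EMMAX approximation) and performs
generalized least squares through the precomputed rotation, with Wald
t-tests per marker and Bonferroni-corrected significance thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix, PSD_TOL

logger = logging.getLogger(__name__)

LOG_DELTA_BOUNDS = (-10.0, 10.0)  # natural-log bounds of the delta search
DELTA_TOL = 1e-6
N_GRID = 100


@dataclass
class VarianceComponents:
    genetic: float
    residual: float
    delta: float  # residual / genetic
    reml_loglik: float
    delta_identifiable: bool = True

    @property
    def total(self) -> float:
        return self.genetic + self.residual


@dataclass
class AssocResult:
    marker: str
    beta: float
    se: float
    stat: float
    pvalue: float
    n: int


@dataclass
class ScanResult:
    results: list[AssocResult] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)

    def pvalues(self) -> dict[str, float]:
        return {r.marker: r.pvalue for r in self.results}

    def top(self) -> AssocResult:
        return min(self.results, key=lambda r: (r.pvalue, r.marker))


def _check_inputs(y: np.ndarray, X: np.ndarray, K: KinshipMatrix):
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n or len(K.ids) != n:
        raise ValueError("y, X and K dimensions disagree")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; mixed model degenerate")
    Kv = K.values
    w = np.linalg.eigvalsh(Kv)
    if w[0] < -PSD_TOL * max(1.0, w[-1]):
        raise ValueError("kinship matrix is not positive semidefinite")
    return y, X, Kv


def reml_profile(y, X, K: KinshipMatrix):
    """The profiled restricted log-likelihood as a function of log(delta).

    Returns ``(loglik, sigma_g2)``: callables evaluating the restricted
    likelihood and the profiled genetic variance at a given log delta.
    Used internally by :func:`emma_reml` and available for optimizer
    sanity checks.
    """
    y, X, Kv = _check_inputs(y, X, K)
    n = y.size
    q = np.linalg.matrix_rank(X)
    if n <= q:
        raise ValueError("more fixed effects than observations")
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    SKS = S @ Kv @ S
    w, U = np.linalg.eigh((SKS + SKS.T) / 2)
    idx = np.argsort(w)[::-1][: n - q]
    xi = np.clip(w[idx], 0.0, None)
    eta2 = (U[:, idx].T @ y) ** 2
    nq = n - q

    def loglik(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        ss = float(np.sum(eta2 / denom))
        return 0.5 * (
            nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(ss)
            - float(np.sum(np.log(denom)))
        )

    def sigma_g2(log_delta: float) -> float:
        delta = np.exp(log_delta)
        return float(np.sum(eta2 / (xi + delta)) / nq)

    return loglik, sigma_g2


def emma_reml(y, X, K: KinshipMatrix) -> VarianceComponents:
    """REML variance components of the kinship mixed model.

    The restricted likelihood is profiled over delta = se^2/sg^2 using the
    spectral decomposition of S K S (S projecting off the column space of
    X): a coarse grid over log delta in [-10, 10] brackets the optimum,
    followed by bounded 1-D refinement to 1e-6.  When K = I the
    decomposition is flat in delta (only the total variance is
    identified); this is detected and flagged.
    """
    loglik, sigma_g2 = reml_profile(y, X, K)

    def neg_restricted_ll(log_delta: float) -> float:
        return -loglik(log_delta)

    grid = np.linspace(*LOG_DELTA_BOUNDS, N_GRID)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    flat = np.ptp(vals) < 1e-8
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(N_GRID - 1, i + 1)]
    if lo == hi:
        best_logd = grid[i]
    else:
        res = optimize.minimize_scalar(
            neg_restricted_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": DELTA_TOL},
        )
        best_logd = float(res.x)
        if neg_restricted_ll(grid[i]) < res.fun:
            best_logd = grid[i]
    delta = float(np.exp(best_logd))
    sg2 = sigma_g2(best_logd)
    se2 = delta * sg2
    if flat:
        logger.warning("restricted likelihood flat in delta (K ~ identity); "
                       "only the total variance is identified")
    return VarianceComponents(
        genetic=sg2,
        residual=se2,
        delta=delta,
        reml_loglik=-neg_restricted_ll(best_logd),
        delta_identifiable=not flat,
    )


def emmax_scan(y, X, markers, K: KinshipMatrix, vc: VarianceComponents) -> ScanResult:
    """Per-marker GLS association under fixed variance components.

    ``markers`` is a PavMatrix (rows = markers, columns = accessions in
    the order of ``y``) or an equivalent (ids, matrix) pair.  Monomorphic
    markers and markers collinear with the covariates are skipped and
    counted.  P-values are two-sided Wald t-tests with n - p degrees of
    freedom.
    """
    y, X, Kv = _check_inputs(y, X, K)
    n = y.size
    if hasattr(markers, "values") and hasattr(markers, "row_ids"):
        marker_ids = markers.row_ids
        M = markers.values().astype(float)
    else:
        marker_ids, M = markers
        M = np.asarray(M, dtype=float)
    if M.shape != (len(marker_ids), n):
        raise ValueError("marker matrix shape does not match ids / sample size")

    lam, U = np.linalg.eigh(Kv)
    lam = np.clip(lam, 0.0, None)
    wts = 1.0 / np.sqrt(vc.genetic * lam + vc.residual)
    if not np.all(np.isfinite(wts)):
        raise ValueError("degenerate variance components")
    yt = wts * (U.T @ y)
    Xt = wts[:, None] * (U.T @ X)
    Mt = (wts[:, None] * (U.T @ M.T)).T  # markers x n, rotated

    Qx, _ = np.linalg.qr(Xt)
    ry = yt - Qx @ (Qx.T @ yt)
    p = X.shape[1] + 1
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the scan")

    out = ScanResult()
    n_mono = 0
    for mid, row, trow in zip(marker_ids, M, Mt):
        if np.ptp(row) == 0:
            n_mono += 1
            out.skipped[mid] = "monomorphic"
            continue
        rx = trow - Qx @ (Qx.T @ trow)
        sxx = float(rx @ rx)
        if sxx <= 1e-10 * float(trow @ trow):
            out.skipped[mid] = "collinear"
            continue
        beta = float(rx @ ry) / sxx
        rss = float(ry @ ry) - beta**2 * sxx
        sigma2 = max(rss, 0.0) / df
        se = float(np.sqrt(sigma2 / sxx))
        if se == 0:
            out.skipped[mid] = "degenerate"
            continue
        t = beta / se
        pval = float(2 * stats.t.sf(abs(t), df))
        out.results.append(
            AssocResult(marker=mid, beta=beta, se=se, stat=t, pvalue=max(pval, 5e-324), n=n)
        )
    if n_mono:
        logger.info("skipped %d monomorphic markers", n_mono)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha / m."""
    if m < 1:
        raise ValueError("marker count must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
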