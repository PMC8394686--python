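"""Renormalized partial directed coherence (rPDC): frequency-domain causality.

The Fourier transform of the fitted VAR coefficient stack,

    A(w) = I - sum_{r=1..p} Ahat(r) e^{-i w r},

carries the directed frequency-domain structure of the process: the
off-diagonal entry A_kj(w) vanishes (at every w) exactly when j has no
direct influence on k.  rPDC tests that by renormalizing the 2-vector

    Z_kj(w) = (Re A_kj(w), Im A_kj(w))

with the asymptotic covariance of the coefficient estimates,

    V_kj(w) = sum_{l,m=1..p} [Rp^{-1}]_{(l-1)n+j,(m-1)n+j} * Sigma_kk
              * [[cos lw cos mw, cos lw sin mw],
                 [sin lw cos mw, sin lw sin mw]],

giving the statistic lambda_kj(w) = Z' V^{-1} Z.  Under the null of no
influence, N * lambda_kj(w) is asymptotically chi-square with 2 degrees of
freedom (N = number of points entering the fit), so the pointwise critical
value at level alpha is chi2(2, 1-alpha) / N.  At order p = 1 the trigonometric
outer product makes V rank one; a Moore-Penrose pseudo-inverse is used and
the degrees of freedom drop to the rank.

The headline decision rule declares an edge only when the statistic clears
the critical value at *every* grid frequency — conservative, but it matches
how the spectra are read; any-frequency and fraction-of-frequencies rules
are provided as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import CausalGraph
from .var import SingularMatrixError, VARFit

__all__ = [
    "FrequencyGrid",
    "RPDCResult",
    "default_grid",
    "fourier_coefficients",
    "z_vector",
    "z_covariance",
    "compute_rpdc",
    "rpdc_critical_value",
    "rpdc_significance",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing angular frequencies in the open interval (0, pi)."""

    omegas: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omegas, dtype=float)
        if om.ndim != 1 or om.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if np.any(np.diff(om) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if om[0] <= 0 or om[-1] >= np.pi:
            raise ValueError("frequencies must lie strictly inside (0, pi)")
        object.__setattr__(self, "omegas", om)

    def __len__(self) -> int:
        return self.omegas.size


def default_grid(n_freq: int = 64) -> FrequencyGrid:
    """``n_freq`` equally spaced frequencies in (0, pi), endpoints excluded."""
    if n_freq < 1:
        raise ValueError("n_freq must be >= 1")
    k = np.arange(1, n_freq + 1)
    return FrequencyGrid(np.pi * k / (n_freq + 1))


@dataclass(frozen=True)
class RPDCResult:
    """rPDC statistics ``lam[k, j, f]`` (target k, source j, frequency f).

    ``critical`` is the pointwise critical value chi2(dof, 1-alpha)/N already
    divided by the effective sample size ``N``; ``dof`` is 2 except for
    order-1 fits where the estimator covariance has rank 1.
    """

    lam: np.ndarray            # (n, n, F), NaN on the diagonal
    critical: float
    N: int
    alpha: float
    dof: int
    omegas: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.lam.shape[0]


def fourier_coefficients(fit: VARFit, grid: FrequencyGrid) -> np.ndarray:
    """A(w) = I - sum_r Ahat(r) exp(-i w r), shape (F, n, n)."""
    omegas = grid.omegas
    r = np.arange(1, fit.p + 1)
    E = np.exp(-1j * np.outer(omegas, r))            # (F, p)
    return np.eye(fit.n) - np.einsum("fr,rij->fij", E, fit.Ahat)


def z_vector(Aw: np.ndarray, k: int, j: int) -> np.ndarray:
    """Real/imaginary parts of A_kj(w): the tested 2-vector (per frequency)."""
    if k == j:
        raise ValueError("self-influence (k == j) is not defined for rPDC")
    entry = Aw[..., k, j]
    return np.stack([entry.real, entry.imag], axis=-1)


def _source_block(fit: VARFit, j: int) -> np.ndarray:
    """p x p matrix of Rp^{-1} entries ((l-1)n+j, (m-1)n+j), l, m = 1..p."""
    try:
        Rp_inv = np.linalg.inv(fit.Rp)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("lag-covariance matrix Rp is singular") from exc
    idx = j + fit.n * np.arange(fit.p)
    return Rp_inv[np.ix_(idx, idx)]


def _trig_basis(omegas: np.ndarray, p: int) -> np.ndarray:
    """C(w) with rows (cos lw) and (-sin lw) for l = 1..p, shape (F, 2, p).

    These are the real and imaginary parts of e^{-i l w}, so that
    Z_kj(w) = -sum_l Ahat_kj(l) * C[:, l] and the quadratic form pairs the
    coefficient covariance with the estimator's actual orientation.  Writing
    both cross terms with a positive sine (as the displayed formula is often
    typeset) corresponds to the opposite Fourier sign convention; paired
    with Z = (Re, +Im) of the e^{-i w r} transform it breaks the chi-square
    calibration and, at p = 1, manufactures a spurious zero of the statistic
    where Z leaves the covariance's column space.
    """
    lw = np.outer(np.atleast_1d(omegas), np.arange(1, p + 1))
    return np.stack([np.cos(lw), -np.sin(lw)], axis=1)


def z_covariance(fit: VARFit, k: int, j: int, omega: float) -> np.ndarray:
    """Covariance V_kj(w) of the Fourier 2-vector (before the 1/N scaling)."""
    if k == j:
        raise ValueError("self-influence (k == j) is not defined for rPDC")
    H = _source_block(fit, j)
    C = _trig_basis(np.array([omega]), fit.p)[0]      # (2, p)
    return float(fit.SigmaHat[k, k]) * C @ H @ C.T


def rpdc_critical_value(alpha: float, N: int, dof: int = 2) -> float:
    """chi2(dof, 1-alpha) / N: pointwise threshold for lambda = Z' V^{-1} Z."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if N <= 0:
        raise ValueError("N must be positive")
    return float(stats.chi2.ppf(1.0 - alpha, dof)) / N


def compute_rpdc(
    fit: VARFit,
    grid: FrequencyGrid | None = None,
    alpha: float = 0.05,
) -> RPDCResult:
    """Evaluate lambda_kj(w) for every ordered pair k != j on the grid.

    Rank-deficient V (inevitable at p = 1) is inverted with the
    Moore-Penrose pseudo-inverse and the critical value uses the reduced
    degrees of freedom.  ``N`` is the number of points entering the fit,
    T - p.
    """
    if grid is None:
        grid = default_grid()
    n, p = fit.n, fit.p
    omegas = grid.omegas
    F = omegas.size
    Aw = fourier_coefficients(fit, grid)
    C = _trig_basis(omegas, p)                        # (F, 2, p)
    sig = np.diag(fit.SigmaHat)
    lam = np.full((n, n, F), np.nan)
    for j in range(n):
        H = _source_block(fit, j)
        Vbase = np.einsum("fap,pq,fbq->fab", C, H, C)  # (F, 2, 2)
        Vbase_pinv = np.linalg.pinv(Vbase, rcond=1e-12)
        for k in range(n):
            if k == j:
                continue
            Z = z_vector(Aw, k, j)                    # (F, 2)
            quad = np.einsum("fa,fab,fb->f", Z, Vbase_pinv, Z)
            lam[k, j] = quad / sig[k]
    dof = min(2, p)
    N = fit.nobs
    return RPDCResult(
        lam=lam,
        critical=rpdc_critical_value(alpha, N, dof),
        N=N,
        alpha=alpha,
        dof=dof,
        omegas=omegas,
        labels=fit.labels,
    )


def rpdc_significance(
    result: RPDCResult,
    rule: str = "all_frequencies",
    fraction: float = 0.5,
) -> CausalGraph:
    """Threshold the rPDC statistics into a directed graph.

    ``rule`` is ``"all_frequencies"`` (edge present iff the statistic clears
    the critical value at every grid frequency; weight = min lambda),
    ``"any_frequency"`` (at least one frequency; weight = max lambda), or
    ``"fraction"`` (at least ``fraction`` of frequencies; weight = median
    lambda).  Self-edges are excluded.
    """
    if result.omegas.size == 0:
        raise ValueError("empty frequency grid")
    above = result.lam > result.critical
    n = result.n
    edges: dict[tuple[str, str], float] = {}
    for k in range(n):
        for j in range(n):
            if k == j:
                continue
            cells = above[k, j]
            if rule == "all_frequencies":
                present = bool(cells.all())
                weight = float(result.lam[k, j].min())
            elif rule == "any_frequency":
                present = bool(cells.any())
                weight = float(result.lam[k, j].max())
            elif rule == "fraction":
                present = bool(cells.mean() >= fraction)
                weight = float(np.median(result.lam[k, j]))
            else:
                raise ValueError(f"unknown rule {rule!r}")
            if present:
                edges[(result.labels[j], result.labels[k])] = weight
    return CausalGraph(nodes=result.labels, edges=edges)
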