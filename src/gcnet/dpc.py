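"""Directed partial correlation (DPC): time-domain Granger-causal strength.

Raw VAR coefficients carry the measurement units of the channels, which makes
their magnitudes incomparable across channel pairs.  DPC removes the units by
rescaling each coefficient with the residual precision and the cumulative
influence of the source channel:

    pi_ij(h) = Ahat_ij(h) / sqrt(SigmaHat_ii * rho_jj(h)),

    rho_jj(h) = K_jj
              + sum_{v=1..h-1} sum_{k,l} Ahat_kj(v) K_kl Ahat_lj(v)
              + Ahat_ij(h)^2 / SigmaHat_ii,

with ``K = SigmaHat^{-1}``.  The result behaves like a correlation between
X_i(t) and X_j(t-h) with the linear effects of all other channels removed;
for negative lags the convention pi_ij(h) = pi_ij(-h) adds no information and
only positive lags are stored.

Significance is assessed with a percentile bootstrap over amplitude-adjusted
Fourier-transform (AAFT) surrogates: each surrogate keeps every channel's
amplitude distribution exactly and its power spectrum approximately while
randomizing Fourier phases independently per channel, which destroys
cross-channel coupling and therefore realizes the no-causality null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import CausalGraph
from .var import SingularMatrixError, TimeSeriesPanel, VARFit, fit_var

__all__ = [
    "DPCResult",
    "BootstrapCI",
    "compute_dpc",
    "aaft_surrogate",
    "bootstrap_indices",
    "dpc_bootstrap_ci",
    "dpc_significance",
    "dpc_analysis",
]


@dataclass(frozen=True)
class DPCResult:
    """DPC values ``pi[i, j, h-1]`` for target i, source j, lag h = 1..p."""

    pi: np.ndarray            # (n, n, p)
    p: int
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.pi.shape[0]


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval per (target, source, lag) cell.

    ``lo``/``hi`` hold the alpha*B-th and (1-alpha)*B-th order statistics of
    the ``B`` surrogate DPC values (ascending order, 1-based counting).
    """

    lo: np.ndarray            # (n, n, p)
    hi: np.ndarray            # (n, n, p)
    B: int
    alpha: float
    seed: int | None
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.lo > self.hi):
            raise ValueError("interval lower bounds exceed upper bounds")


def compute_dpc(fit: VARFit) -> DPCResult:
    """Rescale fitted VAR coefficients into directed partial correlations."""
    K = fit.precision()               # raises SingularMatrixError if needed
    A = fit.Ahat                      # (p, n, n)
    n, p = fit.n, fit.p
    sig = np.diag(fit.SigmaHat)       # (n,)
    pi = np.empty((n, n, p))
    # base_j accumulates K_jj + sum_{v<h} (A(v)^T K A(v))_jj as h grows
    base = np.diag(K).astype(float).copy()
    for h in range(1, p + 1):
        Ah = A[h - 1]
        # rho_jj(h) additionally holds the target-specific term A_ij(h)^2/S_ii
        rho = base[None, :] + Ah ** 2 / sig[:, None]
        pi[:, :, h - 1] = Ah / np.sqrt(sig[:, None] * rho)
        if h < p:
            base = base + np.einsum("kj,kl,lj->j", Ah, K, Ah)
    if not np.all(np.isfinite(pi)):
        raise FloatingPointError("non-finite DPC values (degenerate fit)")
    return DPCResult(pi=pi, p=p, labels=fit.labels)


# ---------------------------------------------------------------------------
# AAFT surrogates
# ---------------------------------------------------------------------------


def _amplitude_remap(sorted_x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reorder each column of ``sorted_x`` by the ranks of ``reference``.

    Equivalent to sorted_x[ranks(reference)] but with a single argsort:
    scatter the sorted amplitudes onto the reference's sort order.
    """
    order = np.argsort(reference, axis=0, kind="stable")
    out = np.empty_like(sorted_x)
    np.put_along_axis(out, order, sorted_x, axis=0)
    return out


def _phase_randomize(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate Fourier phases uniformly, independently per channel."""
    T = y.shape[0]
    Y = np.fft.rfft(y, axis=0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=Y.shape)
    phases[0] = 0.0                      # keep DC real
    if T % 2 == 0:
        phases[-1] = 0.0                 # keep Nyquist real
    return np.fft.irfft(Y * np.exp(1j * phases), n=T, axis=0)


def aaft_surrogate(
    panel: TimeSeriesPanel,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 100,
    rel_tol: float = 1e-4,
) -> TimeSeriesPanel:
    """Amplitude-adjusted Fourier-transform surrogate of every channel.

    Per channel: (a) remap the data onto a Gaussian sample ordered by the
    data's ranks, (b) phase-randomize its Fourier transform, (c) remap back
    onto the original amplitudes; then iteratively re-impose the original
    amplitude spectrum and re-rank onto the original values until the
    relative spectral mismatch stops improving (by less than ``rel_tol``
    relative, or ``max_iter`` rounds).  The returned channel is always an
    exact permutation of the original channel's values.

    Phases are randomized independently per channel, so any cross-channel
    dependence is destroyed — the surrogate realizes the no-coupling null.
    """
    T = panel.T
    if T < 8:
        raise ValueError("AAFT requires at least 8 time points")
    X = panel.values
    if np.any(np.ptp(X, axis=0) == 0):
        flat = [l for l, r in zip(panel.labels, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant channel(s) {flat}: ranks are undefined")
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(X, axis=0)
    target = np.abs(np.fft.rfft(X, axis=0))
    values = _aaft_draw(X, sorted_x, target, rng, max_iter, rel_tol)
    return TimeSeriesPanel(values, panel.labels)


def _aaft_draw(
    X: np.ndarray,
    sorted_x: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    rel_tol: float,
) -> np.ndarray:
    """One AAFT surrogate given the panel's precomputed sort and spectrum."""
    T = X.shape[0]
    # (a) Gaussianize by rank ordering
    gauss = np.sort(rng.standard_normal(X.shape), axis=0)
    y = _amplitude_remap(gauss, X)
    # (b) randomize phases of the Gaussianized series
    y = _phase_randomize(y, rng)
    # (c) back onto the original amplitude distribution
    s = _amplitude_remap(sorted_x, y)

    # iterative spectrum/amplitude adjustment
    target_norm = np.linalg.norm(target)
    prev = np.inf
    for _ in range(max_iter):
        S = np.fft.rfft(s, axis=0)
        mismatch = np.linalg.norm(np.abs(S) - target) / target_norm
        if prev - mismatch < rel_tol * max(prev, 1e-300):
            break
        prev = mismatch
        mag = np.abs(S)
        phase = np.where(mag > 0, S / np.where(mag > 0, mag, 1.0), 1.0)
        filtered = np.fft.irfft(target * phase, n=T, axis=0)
        s = _amplitude_remap(sorted_x, filtered)
    return s


# ---------------------------------------------------------------------------
# percentile bootstrap
# ---------------------------------------------------------------------------


def bootstrap_indices(B: int, alpha: float) -> tuple[int, int]:
    """Order-statistic indices (1-based) of the percentile interval.

    Returns (alpha*B, (1-alpha)*B), floored when the products are not
    integers; e.g. B=10000, alpha=0.05 gives (500, 9500).
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if B * alpha < 1:
        raise ValueError("B*alpha must be at least 1")
    lo = math.floor(alpha * B)
    hi = math.floor((1.0 - alpha) * B)
    return lo, hi


def dpc_bootstrap_ci(
    panel: TimeSeriesPanel,
    p: int,
    B: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 100,
    max_retries: int = 5,
) -> BootstrapCI:
    """Surrogate-bootstrap confidence intervals for every DPC cell.

    Draws ``B`` AAFT surrogates of the panel (one set shared by all edges),
    fits a VAR[p] to each, computes DPC, and takes per-cell percentile
    endpoints via :func:`bootstrap_indices`.  A surrogate whose fit fails is
    redrawn, up to ``max_retries`` extra attempts.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    lo_idx, hi_idx = bootstrap_indices(B, alpha)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(B)
    n = panel.n
    if panel.T < 8:
        raise ValueError("AAFT requires at least 8 time points")
    X = panel.values
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant channel: ranks are undefined")
    # panel invariants shared by every surrogate draw
    sorted_x = np.sort(X, axis=0)
    target = np.abs(np.fft.rfft(X, axis=0))
    samples = np.empty((B, n, n, p))
    for r in range(B):
        child = children[r]
        for attempt in range(max_retries + 1):
            try:
                values = _aaft_draw(X, sorted_x, target,
                                    np.random.default_rng(child),
                                    max_iter, 1e-4)
                surr = TimeSeriesPanel(values, panel.labels)
                samples[r] = compute_dpc(fit_var(surr, p)).pi
                break
            except (SingularMatrixError, FloatingPointError):
                if attempt == max_retries:
                    raise
                child = child.spawn(1)[0]
    samples.sort(axis=0)
    return BootstrapCI(
        lo=samples[lo_idx - 1],
        hi=samples[hi_idx - 1],
        B=B,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
        labels=panel.labels,
    )


def dpc_significance(result: DPCResult, ci: BootstrapCI) -> CausalGraph:
    """Graph of edges whose DPC falls outside its surrogate interval.

    An edge j -> i is declared present if pi_ij(h) lies outside [lo, hi] at
    one or more lags (no correction across lags or pairs); its weight is the
    largest |pi| over the significant lags.  Self-edges are excluded.
    """
    if result.pi.shape != ci.lo.shape:
        raise ValueError(
            f"result {result.pi.shape} and interval {ci.lo.shape} mismatch"
        )
    if result.labels != ci.labels:
        raise ValueError("result and interval come from different panels")
    outside = (result.pi < ci.lo) | (result.pi > ci.hi)
    n = result.n
    edges: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            sig = outside[i, j]
            if sig.any():
                weight = float(np.max(np.abs(result.pi[i, j][sig])))
                edges[(result.labels[j], result.labels[i])] = weight
    return CausalGraph(nodes=result.labels, edges=edges)


def dpc_analysis(
    panel: TimeSeriesPanel,
    p: int,
    B: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    bonferroni: bool = False,
    max_iter: int = 100,
) -> tuple[DPCResult, BootstrapCI, CausalGraph]:
    """Full DPC pipeline: fit, rescale, bootstrap, threshold.

    With ``bonferroni=True`` the per-cell level is divided by the number of
    lags tested per edge (off by default: the plain per-value test).
    """
    cell_alpha = alpha / p if bonferroni else alpha
    fit = fit_var(panel, p)
    result = compute_dpc(fit)
    ci = dpc_bootstrap_ci(panel, p, B=B, alpha=cell_alpha, seed=seed, max_iter=max_iter)
    return result, ci, dpc_significance(result, ci)
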