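"""Vector autoregressive (VAR) models: definition, simulation, estimation.

A VAR[p] process over ``n`` channels evolves as

    X(t) = sum_{r=1..p} A(r) X(t-r) + eps(t),    eps(t) ~ N(0, Sigma),

with n-by-n coefficient matrices ``A(r)`` and non-singular noise covariance
``Sigma``.  The index convention throughout the package is
``A(r)[i, j]`` = effect of channel ``j`` at lag ``r`` on channel ``i``
(target row, source column), so a directed influence j -> i lives in row i,
column j.

Estimation is ordinary least squares written through the lag-covariance
normal equations: with

    Rp(h, v) = 1/(T-p) * sum_{t=p+1..T} X(t-h) X(t-v)^T,   h, v = 1..p,
    rp(v)    = Rp(0, v),

the coefficient estimates solve ``Ahat = rp Rp^{-1}`` and the residual
covariance is the outer-product average of the least-squares residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "VARModel",
    "TimeSeriesPanel",
    "VARFit",
    "StationarityError",
    "SingularMatrixError",
    "companion_matrix",
    "spectral_radius",
    "simulate_var",
    "lag_covariance",
    "fit_var",
    "select_order",
]

#: Condition-number ceiling above which the lag-covariance matrix is treated
#: as numerically singular.
_MAX_CONDITION = 1e12


class StationarityError(ValueError):
    """Raised when an operation requires a stationary VAR model."""


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when a matrix that must be inverted is numerically singular."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VARModel:
    """A VAR[p] model: coefficient stack ``A`` and noise covariance ``Sigma``.

    Parameters
    ----------
    A : ndarray, shape (p, n, n)
        Coefficient matrices, ``A[r-1][i, j]`` = effect of channel j at lag r
        on channel i.
    Sigma : ndarray, shape (n, n)
        Symmetric positive-definite innovation covariance.
    """

    A: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError(f"A must have shape (p, n, n), got {A.shape}")
        Sigma = np.asarray(self.Sigma, dtype=float)
        n = A.shape[1]
        if Sigma.shape != (n, n):
            raise ValueError(f"Sigma must be {n}x{n}, got {Sigma.shape}")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Sigma", Sigma)

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def is_stationary(self) -> bool:
        return spectral_radius(self) < 1.0


@dataclass(frozen=True)
class TimeSeriesPanel:
    """T x n observation matrix with unique channel labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] < 1:
            raise ValueError("panel must contain at least one time point")
        if not np.all(np.isfinite(values)):
            raise ValueError("panel contains missing or non-finite entries")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {values.shape[1]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def select(self, labels: "list[str] | tuple[str, ...]") -> "TimeSeriesPanel":
        """Sub-panel restricted to ``labels`` (order preserved as given)."""
        idx = [self.labels.index(l) for l in labels]
        return TimeSeriesPanel(self.values[:, idx], tuple(labels))

    def drop(self, labels) -> "TimeSeriesPanel":
        """Sub-panel with the given channels removed."""
        drop = {str(l) for l in labels}
        keep = [l for l in self.labels if l not in drop]
        if not keep:
            raise ValueError("cannot drop every channel")
        return self.select(keep)


@dataclass(frozen=True)
class VARFit:
    """Least-squares VAR estimates together with the moment matrices.

    ``Rp`` is the (p*n, p*n) lag-covariance matrix whose (h, v) block is the
    average of X(t-h) X(t-v)^T, and ``rp`` stacks the cross blocks
    (Rp(0,1), ..., Rp(0,p)) into an (n, p*n) matrix.  ``nobs`` = T - p is the
    number of time points that actually enter the regression.
    """

    p: int
    Ahat: np.ndarray           # (p, n, n)
    SigmaHat: np.ndarray       # (n, n)
    residuals: np.ndarray      # (T - p, n)
    Rp: np.ndarray             # (p n, p n)
    rp: np.ndarray             # (n, p n)
    T: int
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Ahat.shape[1]

    @property
    def nobs(self) -> int:
        """Effective sample size entering the fit (T - p)."""
        return self.T - self.p

    def precision(self) -> np.ndarray:
        """Khat = inverse of the residual covariance."""
        try:
            return np.linalg.inv(self.SigmaHat)
        except np.linalg.LinAlgError as exc:
            raise SingularMatrixError(
                "residual covariance SigmaHat is singular"
            ) from exc


# ---------------------------------------------------------------------------
# model-level operations
# ---------------------------------------------------------------------------


def companion_matrix(model: VARModel) -> np.ndarray:
    """(n p) x (n p) companion form rewriting the VAR[p] as a VAR[1]."""
    n, p = model.n, model.p
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(model.A, axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(model: VARModel) -> float:
    """Largest eigenvalue modulus of the companion matrix.

    The model is stationary iff the result is strictly below 1 (equivalently,
    all roots of the lag polynomial lie outside the unit circle).
    """
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(model)))))


def simulate_var(
    model: VARModel,
    T: int,
    burn_in: int = 500,
    seed: int | np.random.SeedSequence | None = None,
    labels: tuple[str, ...] | None = None,
) -> TimeSeriesPanel:
    """Simulate ``T`` observations from a stationary VAR model.

    The recursion starts from zeros and the first ``burn_in`` samples are
    discarded so the retained stretch is effectively drawn from the
    stationary distribution.  Identical seeds give identical output.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    radius = spectral_radius(model)
    if radius >= 1.0:
        raise StationarityError(
            f"model is not stationary (spectral radius {radius:.4f} >= 1)"
        )
    n, p = model.n, model.p
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.Sigma)
    eps = rng.standard_normal((burn_in + T, n)) @ chol.T
    out = np.zeros((burn_in + T + p, n))
    A = model.A
    for t in range(p, burn_in + T + p):
        acc = eps[t - p]
        for r in range(p):
            acc = acc + A[r] @ out[t - r - 1]
        out[t] = acc
    values = out[p + burn_in:]
    if labels is None:
        labels = tuple(f"X{i + 1}" for i in range(n))
    return TimeSeriesPanel(values, labels)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _lagged_design(values: np.ndarray, p: int) -> np.ndarray:
    """Regressor matrix Z with row t = (X(t-1), ..., X(t-p)), t = p..T-1."""
    T = values.shape[0]
    return np.concatenate([values[p - h: T - h] for h in range(1, p + 1)], axis=1)


def lag_covariance(panel: TimeSeriesPanel, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical lag-covariance matrix ``Rp`` and cross blocks ``rp``.

    Rp(h, v) = 1/(T-p) sum_{t=p+1..T} X(t-h) X(t-v)^T for h, v = 1..p, and
    rp = (Rp(0, 1), ..., Rp(0, p)) with the same normalization.  Returned as
    the (p n, p n) block matrix and the (n, p n) stacked cross blocks.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    T = panel.T
    if T <= p:
        raise ValueError(f"insufficient data: T={T} <= p={p}")
    X = panel.values
    Z = _lagged_design(X, p)
    Y = X[p:]
    denom = T - p
    Rp = Z.T @ Z / denom
    rp = Y.T @ Z / denom
    return Rp, rp


def fit_var(
    panel: TimeSeriesPanel,
    p: int,
    sigma_divisor: str = "T",
) -> VARFit:
    """Least-squares fit of a VAR[p] (no intercept; data assumed zero-mean).

    Parameters
    ----------
    sigma_divisor : {"T", "T-p"}
        Divisor of the residual outer-product sum in the covariance
        estimate.  The default ``"T"`` follows the customary plug-in
        formula written with 1/T; ``"T-p"`` divides by the number of terms
        actually summed.

    Raises
    ------
    SingularMatrixError
        If the lag-covariance matrix is numerically rank deficient; the
        message reports the offending condition number.
    """
    if sigma_divisor not in ("T", "T-p"):
        raise ValueError("sigma_divisor must be 'T' or 'T-p'")
    Rp, rp = lag_covariance(panel, p)
    cond = np.linalg.cond(Rp)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise SingularMatrixError(
            f"lag-covariance matrix Rp is numerically singular "
            f"(condition number {cond:.3e})"
        )
    # Ahat = rp Rp^{-1}; solved as Rp x = rp^T for stability.
    A_stack = scipy.linalg.solve(Rp, rp.T, assume_a="sym").T
    n, T = panel.n, panel.T
    X = panel.values
    Z = _lagged_design(X, p)
    residuals = X[p:] - Z @ A_stack.T
    denom = T if sigma_divisor == "T" else T - p
    SigmaHat = residuals.T @ residuals / denom
    Ahat = np.stack([A_stack[:, (h - 1) * n: h * n] for h in range(1, p + 1)])
    return VARFit(
        p=p, Ahat=Ahat, SigmaHat=SigmaHat, residuals=residuals,
        Rp=Rp, rp=rp, T=T, labels=panel.labels,
    )


def select_order(
    panel: TimeSeriesPanel,
    p_max: int,
    criterion: str = "bic",
    fixed: int | None = None,
) -> int:
    """Choose the VAR order by an information criterion over 1..p_max.

    ``criterion`` is one of ``"aic"``, ``"bic"`` or ``"fixed"``; with
    ``"fixed"`` the configured order ``fixed`` is returned unchanged.  The
    criteria are evaluated as log det(SigmaHat) plus the usual penalty per
    effective observation, each order fitted on its own usable sample.
    """
    if criterion == "fixed":
        if fixed is None:
            raise ValueError("criterion='fixed' requires the fixed order")
        return int(fixed)
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    n = panel.n
    best_p, best_ic = 1, np.inf
    for p in range(1, p_max + 1):
        fit = fit_var(panel, p, sigma_divisor="T-p")
        nobs = fit.nobs
        sign, logdet = np.linalg.slogdet(fit.SigmaHat)
        if sign <= 0:
            continue
        k = p * n * n
        penalty = (2.0 * k if criterion == "aic" else np.log(nobs) * k) / nobs
        ic = logdet + penalty
        if ic < best_ic:
            best_p, best_ic = p, ic
    return best_p
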