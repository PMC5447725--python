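"""Alternating-least-squares estimation of GSCA models.

All J indicators and all P component scores are standardized (mean 0,
variance 1, population 1/N scaling), and the global least-squares criterion

    Phi = SS(ZV - Z W A),   V = [I_J | W],   A = [C | B]  (P x (J+P))

is minimized by alternating two exact conditional updates:

1. given W, each free column of A is an ordinary least-squares regression of
   the corresponding column of ZV on the component scores it may depend on;
2. given A, each component's weight column is the exact minimizer of Phi on
   its pattern support subject to unit variance of the component score.

Writing V = V0 + W D with V0 = [I | 0] and D = [0 | I], the criterion is
Phi = ||Z V0 + Z W (D - A)||^2, which is, for a single weight column w_p with
the others held fixed and theta_p the p-th row of (D - A),

    Phi(w_p) = const + 2 w_p' b_p + (theta_p theta_p') w_p' Z'Z w_p,
    b_p = Z' R_p theta_p',

so under the constraint w_p' Z'Z w_p = N the minimum is attained at the
(negatively scaled) solution of (Z'Z) u = b_p restricted to the support.
Because each half-step is an exact constrained minimizer, Phi is monotone
non-increasing across iterations, normalization included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = [
    "StandardizedData",
    "GscaFit",
    "BootstrapResult",
    "GscaError",
    "NonConvergenceWarning",
    "standardize",
    "fit_gsca",
    "bootstrap_se",
]


class GscaError(ValueError):
    pass


class NonConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class StandardizedData:
    """Column-standardized indicator matrix (population 1/N variance)."""

    Z: np.ndarray
    names: tuple[str, ...]
    n_dropped: int = 0

    @property
    def N(self) -> int:
        return self.Z.shape[0]

    @property
    def J(self) -> int:
        return self.Z.shape[1]

    @property
    def sample_correlation(self) -> np.ndarray:
        """J x J sample correlation matrix S = Z'Z / N."""
        return self.Z.T @ self.Z / self.N


def standardize(raw, names: tuple[str, ...] | None = None) -> StandardizedData:
    """Standardize an N x J table to column mean 0 and variance 1.

    Rows containing missing values are dropped (listwise deletion) before
    standardizing.  Variance uses the population 1/N convention so that each
    standardized column has sum of squares exactly N, matching the algebra of
    the least-squares criterion.

    Parameters
    ----------
    raw
        ``pandas.DataFrame`` or array-like of shape (N, J).
    names
        Column names when ``raw`` is a bare array.
    """
    if isinstance(raw, pd.DataFrame):
        names = tuple(map(str, raw.columns))
        X = raw.to_numpy(dtype=float)
    else:
        X = np.asarray(raw, dtype=float)
        if X.ndim != 2:
            raise GscaError("expected a two-dimensional table")
        if names is None:
            names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
    complete = ~np.isnan(X).any(axis=1)
    n_dropped = int((~complete).sum())
    X = X[complete]
    if X.shape[0] < 4:
        raise GscaError(f"fewer than 4 complete rows (got {X.shape[0]})")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (1/N)
    if np.any(sd <= 0):
        bad = [names[j] for j in np.flatnonzero(sd <= 0)]
        raise GscaError(f"constant column(s): {bad}")
    Z = (X - mu) / sd
    if Z.shape[0] <= Z.shape[1]:
        warnings.warn("N <= J: estimates are defined but unstable", UserWarning)
    return StandardizedData(Z=Z, names=names, n_dropped=n_dropped)


@dataclass
class GscaFit:
    """Converged alternating-least-squares solution.

    ``A_hat`` is the P x (J+P) supermatrix ``[C_hat | B_hat]``; ``V`` the
    J x (J+P) matrix ``[I | W_hat]``; ``Gamma`` the N x P standardized
    component scores; ``residuals`` the N x (J+P) residual matrix of the
    stacked measurement and structural equations; ``r_squared`` the R^2 of
    each of the J+P equations.
    """

    spec: ModelSpec
    W_hat: np.ndarray
    C_hat: np.ndarray
    B_hat: np.ndarray
    Phi_value: float
    Gamma: np.ndarray
    residuals: np.ndarray
    r_squared: np.ndarray
    phi_trace: np.ndarray
    n_iter: int
    converged: bool
    tol: float

    @property
    def A_hat(self) -> np.ndarray:
        return np.hstack([self.C_hat, self.B_hat])

    @property
    def V(self) -> np.ndarray:
        J = self.W_hat.shape[0]
        return np.hstack([np.eye(J), self.W_hat])

    def component_correlations(self, data: StandardizedData) -> np.ndarray:
        """P x P correlation matrix of the component scores, W' S W."""
        return self.W_hat.T @ data.sample_correlation @ self.W_hat


def _initial_weights(spec: ModelSpec) -> np.ndarray:
    W = spec.weight_pattern.astype(float)
    return W / np.sqrt(W.sum(axis=0, keepdims=True))


def fit_gsca(
    data: StandardizedData,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    random_start: bool = False,
) -> GscaFit:
    """Estimate weights, loadings and paths by alternating least squares.

    Parameters
    ----------
    data
        Standardized indicators; column names must match the spec.
    spec
        The model pattern.
    tol
        Convergence threshold on the relative decrease of the criterion.
    max_iter
        Iteration cap; hitting it returns the best iterate with
        ``converged=False`` and a :class:`NonConvergenceWarning`.
    seed, random_start
        With ``random_start=True``, weights are initialized from a seeded
        uniform draw instead of equal weights (multistart support).  The
        default equal-weight start is deterministic.

    Notes
    -----
    After convergence each component's sign is fixed so that the sum of its
    loadings (or, for a component with no loadings, the sum of its weights)
    is positive.  This prevents arbitrary sign flips across bootstrap
    resamples.
    """
    if tuple(data.names) != tuple(spec.indicator_names):
        raise GscaError(
            "data columns do not match spec indicators: "
            f"{data.names} vs {spec.indicator_names}"
        )
    if tol <= 0:
        raise GscaError("tol must be positive")

    Z = data.Z
    N, J = Z.shape
    P = spec.n_components
    Wpat = spec.weight_pattern
    Apat = np.hstack([spec.loading_pattern, spec.path_pattern])  # P x (J+P)

    G = Z.T @ Z  # Gram matrix, = N * S

    if random_start:
        rng = np.random.default_rng(seed)
        W = np.where(Wpat, rng.uniform(0.2, 1.0, size=Wpat.shape), 0.0)
    else:
        W = _initial_weights(spec)
    for p in range(P):
        W[:, p] /= np.sqrt(W[:, p] @ G @ W[:, p] / N)

    D = np.hstack([np.zeros((P, J)), np.eye(P)])
    V0 = np.hstack([np.eye(J), np.zeros((J, P))])

    A = np.zeros((P, J + P))
    phi_trace: list[float] = []
    phi_prev = np.inf
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        Gamma = Z @ W
        # --- update A: per-column OLS of ZV on the permitted components ----
        ZV = np.hstack([Z, Gamma])
        GtG = Gamma.T @ Gamma
        GtZV = Gamma.T @ ZV
        A = np.zeros((P, J + P))
        for t in range(J + P):
            free = np.flatnonzero(Apat[:, t])
            if free.size == 0:
                continue
            sub = GtG[np.ix_(free, free)]
            try:
                coef = np.linalg.solve(sub, GtZV[free, t])
            except np.linalg.LinAlgError:
                raise GscaError(
                    "singular component-score cross-product; indicators in "
                    "overlapping blocks may be collinear"
                ) from None
            A[free, t] = coef

        # --- update W column by column --------------------------------------
        Theta = D - A
        M = V0 + W @ Theta  # residual coefficient matrix: resid = Z @ M
        for p in range(P):
            support = np.flatnonzero(Wpat[:, p])
            theta_p = Theta[p, :]
            c = float(theta_p @ theta_p)
            # R_p = Z @ (M - w_p theta_p); b = Z_S' R_p theta_p'
            Mp = M - np.outer(W[:, p], theta_p)
            b = G[support, :] @ (Mp @ theta_p)
            Gs = G[np.ix_(support, support)]
            # exactly collinear indicators within a block leave the weights
            # underdetermined; the minimum-norm solution still minimizes Phi
            try:
                u = np.linalg.solve(Gs, b)
            except np.linalg.LinAlgError:
                u = np.linalg.pinv(Gs) @ b
            quad = float(u @ Gs @ u)
            if quad <= 0 or c <= 0:
                # b == 0: criterion is flat in w_p under the constraint;
                # keep the current normalized column
                new_wp = W[support, p]
            else:
                new_wp = -u * np.sqrt(N / quad)
            W[:, p] = 0.0
            W[support, p] = new_wp
            M = Mp + np.outer(W[:, p], theta_p)

        phi = float(np.sum((Z @ M) ** 2))
        phi_trace.append(phi)
        if phi_prev < np.inf:
            rel = (phi_prev - phi) / max(phi_prev, 1e-300)
            if rel < tol:
                converged = True
                break
        phi_prev = phi

    if not converged:
        warnings.warn(
            f"ALS did not converge in {max_iter} iterations "
            f"(last Phi={phi_trace[-1]:.6g})",
            NonConvergenceWarning,
        )

    C_hat = A[:, :J].copy()
    B_hat = A[:, J:].copy()

    # sign convention: sum of loadings (or weights) positive per component
    for p in range(P):
        ref = C_hat[p, :].sum() if spec.loading_pattern[p].any() else W[:, p].sum()
        if ref < 0:
            W[:, p] *= -1.0
            C_hat[p, :] *= -1.0
            B_hat[p, :] *= -1.0
            B_hat[:, p] *= -1.0

    A = np.hstack([C_hat, B_hat])
    Gamma = Z @ W
    resid = np.hstack([Z, Gamma]) - Gamma @ A
    phi = float(np.sum(resid**2))
    ss_cols = np.full(J + P, float(N))  # each standardized column has SS = N
    r2 = 1.0 - (resid**2).sum(axis=0) / ss_cols

    return GscaFit(
        spec=spec,
        W_hat=W,
        C_hat=C_hat,
        B_hat=B_hat,
        Phi_value=phi,
        Gamma=Gamma,
        residuals=resid,
        r_squared=r2,
        phi_trace=np.asarray(phi_trace),
        n_iter=it,
        converged=converged,
        tol=tol,
    )


@dataclass
class BootstrapResult:
    """Bootstrap standard errors and percentile intervals.

    ``se_W``/``se_C``/``se_B`` have the shapes of the corresponding
    estimates, with zeros at structural zeros; ``ci_*`` stack the 2.5% and
    97.5% percentile bounds along the last axis.
    """

    n_boot: int
    n_converged: int
    se_W: np.ndarray
    se_C: np.ndarray
    se_B: np.ndarray
    ci_W: np.ndarray
    ci_C: np.ndarray
    ci_B: np.ndarray
    failed: list[int] = field(default_factory=list)


def bootstrap_se(
    data: StandardizedData,
    spec: ModelSpec,
    n_boot: int = 100,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> BootstrapResult:
    """Bootstrap standard errors of all GSCA estimates.

    Rows are resampled with replacement at the original sample size, each
    resample is re-standardized and refit, and standard errors are the
    standard deviations of the estimates over converged resamples.  The
    per-fit sign convention keeps component orientations aligned across
    resamples.  A resample that fails (constant column, non-convergence) is
    recorded in ``failed``; more than 50% failures is an error.
    """
    if n_boot < 2:
        raise GscaError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    N = data.N
    Ws, Cs, Bs = [], [], []
    failed: list[int] = []
    for b in range(n_boot):
        idx = rng.integers(0, N, size=N)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", NonConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                bdata = standardize(data.Z[idx], names=data.names)
                fit = fit_gsca(bdata, spec, tol=tol, max_iter=max_iter)
        except (GscaError, NonConvergenceWarning):
            failed.append(b)
            continue
        Ws.append(fit.W_hat)
        Cs.append(fit.C_hat)
        Bs.append(fit.B_hat)
    n_ok = len(Ws)
    if n_ok < n_boot / 2:
        raise GscaError(
            f"bootstrap failed: {len(failed)}/{n_boot} resamples did not "
            "converge or were degenerate"
        )
    Wa, Ca, Ba = np.asarray(Ws), np.asarray(Cs), np.asarray(Bs)

    def _ci(arr: np.ndarray) -> np.ndarray:
        return np.stack(
            [np.percentile(arr, 2.5, axis=0), np.percentile(arr, 97.5, axis=0)],
            axis=-1,
        )

    return BootstrapResult(
        n_boot=n_boot,
        n_converged=n_ok,
        se_W=Wa.std(axis=0, ddof=1),
        se_C=Ca.std(axis=0, ddof=1),
        se_B=Ba.std(axis=0, ddof=1),
        ci_W=_ci(Wa),
        ci_C=_ci(Ca),
        ci_B=_ci(Ba),
        failed=failed,
    )
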