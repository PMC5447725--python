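"""Confirmatory tetrad analysis (CTA).

A tetrad is a difference of two products of covariances among four distinct
variables, ``tau_ijkl = sigma_ij sigma_kl - sigma_ik sigma_jl``.  Each
4-subset {i < j < k < l} of the J variables yields three distinct tetrads
(the three ways of splitting four indices into two pairs), so there are
``3 * C(J, 4)`` in total.  A tetrad that is zero under a model's implied
correlation matrix is a *vanishing* tetrad — a testable implication of the
model that does not require distributional assumptions.

The test statistic for a model with non-redundant vanishing tetrads
``tau_hat`` (sample values) and estimated asymptotic covariance
``Sigma_tau`` is the quadratic form

    T = n * tau_hat' Sigma_tau^{-1} tau_hat  ~  chi^2_df,   df = #tetrads,

with ``Sigma_tau = (d tau/d sigma) Sigma_S (d tau/d sigma)'`` restricted to
the selected tetrads, where ``Sigma_S`` is the asymptotic covariance matrix
of the sample covariances.  ``Sigma_S`` is estimated distribution-free from
centered fourth moments, so the whole procedure is free of the multivariate
normality assumption; a normal-theory estimator is available for
comparison.  The modified statistic ``T1`` replaces ``Sigma_tau`` by its
diagonal.

Vanishing tetrads are typically linearly redundant (for a one-factor
quadruple, any two of its three vanishing tetrads imply the third), so the
chi-square degrees of freedom must count only a non-redundant subset.
Following the sweep-operator approach, the covariance matrix of the
candidate tetrads is swept in a seeded random order and a tetrad is retained
only when its pivot is numerically nonzero given those already retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .fit import implied_correlation
from .gsca import GscaFit, StandardizedData
from .model import ModelSpec

__all__ = [
    "TetradCatalog",
    "TetradTestResult",
    "UntestableModelError",
    "enumerate_tetrads",
    "tetrad_values",
    "implied_vanishing_set",
    "sigma_S_adf",
    "sigma_S_normal",
    "jacobian_tau_sigma",
    "select_nonredundant",
    "tetrad_test",
    "LARGE_SAMPLE",
    "format_p",
]

#: Sample sizes above this are considered large: the chi-square statistic is
#: inflated by n and single-model rejection becomes uninformative.
LARGE_SAMPLE = 1000

#: Threshold below which an implied tetrad counts as vanishing (correlation
#: scale).  Implied tetrads of the reflective reconstruction vanish to
#: machine precision; 1e-6 guards rounding from iterative fits.
TOL_VANISH = 1e-6

#: Relative pivot threshold for the sweep-based redundancy elimination.
PIVOT_TOL = 1e-8


class UntestableModelError(ValueError):
    """The model implies no vanishing tetrads, so CTA cannot test it."""


@dataclass(frozen=True)
class TetradCatalog:
    """Canonical enumeration of all tetrads over J variables.

    ``quadruples[t]`` is the 4-subset of tetrad ``t`` and ``pairings[t]``
    its pair split ``((a, b), (c, d), (e, f), (g, h))`` meaning
    ``tau_t = sigma_ab sigma_cd - sigma_ef sigma_gh``.  Quadruples are
    lexicographic; within each quadruple {i<j<k<l} the three pairings appear
    in the fixed order

        (ij)(kl) - (ik)(jl),   (ik)(lj) - (il)(kj),   (il)(jk) - (ij)(lk).
    """

    J: int
    quadruples: tuple[tuple[int, int, int, int], ...]
    pairings: tuple[
        tuple[tuple[int, int], tuple[int, int], tuple[int, int], tuple[int, int]], ...
    ]

    @property
    def n_tetrads(self) -> int:
        return len(self.pairings)


def enumerate_tetrads(J: int) -> TetradCatalog:
    """Enumerate the ``3 * C(J, 4)`` tetrads over J variables."""
    if J < 4:
        raise ValueError(f"tetrad analysis requires J >= 4 (got J={J})")
    quadruples = []
    pairings = []
    for i, j, k, l in combinations(range(J), 4):
        quad = (i, j, k, l)
        for split in (
            ((i, j), (k, l), (i, k), (j, l)),
            ((i, k), (l, j), (i, l), (k, j)),
            ((i, l), (j, k), (i, j), (l, k)),
        ):
            quadruples.append(quad)
            pairings.append(split)
    return TetradCatalog(J=J, quadruples=tuple(quadruples), pairings=tuple(pairings))


def tetrad_values(Sigma: np.ndarray, catalog: TetradCatalog) -> np.ndarray:
    """Evaluate every tetrad of the catalog on a symmetric matrix."""
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (catalog.J, catalog.J):
        raise ValueError(f"expected a {catalog.J}x{catalog.J} matrix")
    if np.abs(Sigma - Sigma.T).max() > 1e-10:
        raise ValueError("input matrix is not symmetric")
    p = np.asarray(catalog.pairings)  # (T, 4, 2)
    return (
        Sigma[p[:, 0, 0], p[:, 0, 1]] * Sigma[p[:, 1, 0], p[:, 1, 1]]
        - Sigma[p[:, 2, 0], p[:, 2, 1]] * Sigma[p[:, 3, 0], p[:, 3, 1]]
    )


def implied_vanishing_set(
    Sigma_hat: np.ndarray,
    catalog: TetradCatalog,
    tol_vanish: float = TOL_VANISH,
) -> np.ndarray:
    """Indices of tetrads vanishing under the model-implied matrix."""
    tau = tetrad_values(Sigma_hat, catalog)
    idx = np.flatnonzero(np.abs(tau) < tol_vanish)
    if idx.size == 0:
        raise UntestableModelError(
            "the model implies no vanishing tetrads; CTA cannot evaluate it"
        )
    return idx


# ---------------------------------------------------------------------------
# asymptotic covariance of the sample covariances
# ---------------------------------------------------------------------------


def covariance_pairs(J: int) -> list[tuple[int, int]]:
    """Ordering contract for the sigma vector: column-stacked lower triangle
    excluding the diagonal, i.e. (1,0), (2,0), ..., (2,1), (3,1), ...
    (row > column within each column)."""
    return [(a, b) for b in range(J) for a in range(b + 1, J)]


def sigma_S_adf(data: StandardizedData) -> np.ndarray:
    """Distribution-free estimator of the asymptotic covariance of the
    sample covariances.

    The entry for covariance pairs (g,h) and (i,j) is the centered fourth
    cross-moment minus the product of the two covariances,

        s_{gh,ij} = (1/N) sum_n z_g z_h z_i z_j  -  s_gh s_ij,

    i.e. the covariance of the products z_g z_h — no normality assumption.
    Rows/columns follow :func:`covariance_pairs`.
    """
    Z = data.Z
    N, J = Z.shape
    if N < 10:
        warnings.warn("N < 10: fourth-moment estimates are very noisy", UserWarning)
    pairs = covariance_pairs(J)
    P = np.empty((N, len(pairs)))
    for t, (a, b) in enumerate(pairs):
        P[:, t] = Z[:, a] * Z[:, b]
    m = P.mean(axis=0)
    return P.T @ P / N - np.outer(m, m)


def sigma_S_normal(S: np.ndarray) -> np.ndarray:
    """Normal-theory closed form: entry ((g,h),(i,j)) equals
    ``sigma_gi sigma_hj + sigma_gj sigma_hi`` evaluated at the sample
    matrix."""
    S = np.asarray(S, dtype=float)
    pairs = covariance_pairs(S.shape[0])
    K = len(pairs)
    out = np.empty((K, K))
    for a, (g, h) in enumerate(pairs):
        for c, (i, j) in enumerate(pairs):
            out[a, c] = S[g, i] * S[h, j] + S[g, j] * S[h, i]
    return out


def jacobian_tau_sigma(catalog: TetradCatalog, Sigma: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d tau / d sigma evaluated at ``Sigma``.

    Rows follow the catalog, columns the :func:`covariance_pairs` ordering
    of distinct off-diagonal covariances.  For
    ``tau = sigma_ab sigma_cd - sigma_ef sigma_gh`` the nonzero partials are
    ``d tau/d sigma_ab = sigma_cd``, ``d tau/d sigma_cd = sigma_ab``,
    ``d tau/d sigma_ef = -sigma_gh`` and ``d tau/d sigma_gh = -sigma_ef``,
    so each row has at most four nonzeros.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    J = catalog.J
    pairs = covariance_pairs(J)
    col = {}
    for t, (a, b) in enumerate(pairs):
        col[(a, b)] = t
        col[(b, a)] = t
    jac = np.zeros((catalog.n_tetrads, len(pairs)))
    for t, ((a, b), (c, d), (e, f), (g, h)) in enumerate(catalog.pairings):
        jac[t, col[(a, b)]] += Sigma[c, d]
        jac[t, col[(c, d)]] += Sigma[a, b]
        jac[t, col[(e, f)]] -= Sigma[g, h]
        jac[t, col[(g, h)]] -= Sigma[e, f]
    return jac


# ---------------------------------------------------------------------------
# redundancy elimination by sweeping
# ---------------------------------------------------------------------------


def select_nonredundant(
    vanishing_idx: np.ndarray,
    Sigma_tau_full: np.ndarray,
    seed: int | None = None,
    pivot_tol: float = PIVOT_TOL,
    forced_order: np.ndarray | None = None,
) -> np.ndarray:
    """Select a maximal linearly independent subset of vanishing tetrads.

    The covariance matrix of the candidate tetrads' sample values is swept
    in a seeded random order; a tetrad is retained iff its pivot (its
    conditional variance given the tetrads already retained) exceeds
    ``pivot_tol`` relative to the largest diagonal entry.  The retained set
    has a full-rank covariance matrix and its size equals the numerical rank
    of ``Sigma_tau_full``.

    Parameters
    ----------
    vanishing_idx
        Catalog indices of the candidate (vanishing) tetrads.
    Sigma_tau_full
        Covariance matrix of the candidates' sample tetrad values, in the
        same order as ``vanishing_idx``.
    seed
        Seed for the random sweep order.
    pivot_tol
        Relative pivot threshold separating exact linear dependence from
        noise.
    forced_order
        Optional explicit sweep order (positions into ``vanishing_idx``);
        overrides the random permutation.  Used by the nested-model
        comparison to force subset selections.
    """
    vanishing_idx = np.asarray(vanishing_idx)
    m = vanishing_idx.size
    if m == 0:
        raise UntestableModelError("empty vanishing set")
    Sig = np.asarray(Sigma_tau_full, dtype=float)
    if Sig.shape != (m, m):
        raise ValueError("Sigma_tau_full does not match the vanishing set")
    if forced_order is None:
        order = np.random.default_rng(seed).permutation(m)
    else:
        order = np.asarray(forced_order)
    scale = float(Sig.diagonal().max())
    if scale <= 0:
        raise ValueError("degenerate covariance matrix: all pivots zero")
    keep: list[int] = []
    for pos in order:
        # conditional variance of candidate `pos` given the retained set,
        # computed against the (well-conditioned) retained submatrix rather
        # than a running Schur complement, for numerical stability
        if keep:
            sub = Sig[np.ix_(keep, keep)]
            v = Sig[keep, pos]
            pivot = Sig[pos, pos] - float(v @ np.linalg.solve(sub, v))
        else:
            pivot = Sig[pos, pos]
        if pivot > pivot_tol * scale:
            keep.append(int(pos))
    if not keep:
        raise ValueError("degenerate covariance matrix: all pivots zero")
    keep_sorted = np.sort(np.asarray(keep))
    return vanishing_idx[keep_sorted]


# ---------------------------------------------------------------------------
# the tetrad test
# ---------------------------------------------------------------------------


@dataclass
class TetradTestResult:
    """Single-model CTA result.

    ``vanishing_idx`` are the catalog indices implied zero by the model;
    ``nonredundant_idx`` the selected subset whose count is the chi-square
    df; ``tau_hat`` the sample values of *all* tetrads; ``Sigma_tau`` the
    estimated covariance of the selected sample tetrads.
    """

    statistic: float
    df: int
    p_value: float
    n: int
    vanishing_idx: np.ndarray
    nonredundant_idx: np.ndarray
    tau_hat: np.ndarray
    Sigma_tau: np.ndarray
    use_T1: bool
    catalog: TetradCatalog


def format_p(p: float) -> str:
    """Three-decimal p-value formatting; '0.000' means p < 0.0005."""
    return f"{p:.3f}"


def tetrad_test(
    data: StandardizedData,
    fit: GscaFit,
    spec: ModelSpec | None = None,
    seed: int | None = None,
    use_T1: bool = False,
    tol_vanish: float = TOL_VANISH,
    normal_theory: bool = False,
    _selection: np.ndarray | None = None,
) -> TetradTestResult:
    """Confirmatory tetrad test of a fitted GSCA model.

    Pipeline: implied correlation matrix -> implied vanishing set -> sample
    tetrads and their distribution-free covariance -> sweep-based
    non-redundant selection -> chi-square quadratic form.

    ``_selection`` bypasses the random selection with an explicit
    non-redundant index set (used by the nested comparison).
    """
    if spec is not None and spec is not fit.spec and spec != fit.spec:
        raise ValueError("spec does not match the fitted model")
    catalog = enumerate_tetrads(data.J)
    Sigma_hat = implied_correlation(fit, data)
    vanishing = implied_vanishing_set(Sigma_hat, catalog, tol_vanish)

    S = data.sample_correlation
    tau_hat = tetrad_values(S, catalog)
    Sigma_S = sigma_S_normal(S) if normal_theory else sigma_S_adf(data)
    jac = jacobian_tau_sigma(catalog, S)
    Jv = jac[vanishing]
    Sigma_tau_full = Jv @ Sigma_S @ Jv.T

    if _selection is None:
        selected = select_nonredundant(vanishing, Sigma_tau_full, seed=seed)
    else:
        selected = np.asarray(_selection)
        if not np.isin(selected, vanishing).all():
            raise ValueError("selection contains non-vanishing tetrads")

    pos = np.searchsorted(vanishing, selected)
    Sigma_tau = Sigma_tau_full[np.ix_(pos, pos)]
    t_sel = tau_hat[selected]
    n = data.N
    if use_T1:
        stat = float(n * np.sum(t_sel**2 / Sigma_tau.diagonal()))
    else:
        try:
            sol = np.linalg.solve(Sigma_tau, t_sel)
        except np.linalg.LinAlgError:  # pragma: no cover - selection is full rank
            raise AssertionError("singular covariance after selection") from None
        stat = float(n * t_sel @ sol)
    df = int(selected.size)
    p = float(stats.chi2.sf(stat, df))
    if n > LARGE_SAMPLE:
        warnings.warn(
            f"n={n} is a large sample for a chi-square tetrad test; the "
            "statistic is inflated by n and rejection may be uninformative",
            UserWarning,
        )
    return TetradTestResult(
        statistic=stat,
        df=df,
        p_value=p,
        n=n,
        vanishing_idx=vanishing,
        nonredundant_idx=selected,
        tau_hat=tau_hat,
        Sigma_tau=Sigma_tau,
        use_T1=use_T1,
        catalog=catalog,
    )
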