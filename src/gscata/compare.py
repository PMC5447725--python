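"""Tetrad-nestedness checking and the nested chi-square difference test.

Model B is *tetrad-nested* in model A when B's implied vanishing-tetrad set
is a strict subset of A's.  Only tetrad-nested pairs can be compared: the
difference ``delta_T = T_A - T_B`` of the two tetrad statistics is referred
to a chi-square distribution with ``df_A - df_B`` degrees of freedom, and
rejection means the less restrictive model (B) fits better.

Because vanishing tetrads are redundant, the non-redundant selections are
randomized and the comparison is replicated several times (five by
default).  Within each replication the less-restrictive model's selection
is forced to be a subset of the restrictive model's selection on the shared
vanishing tetrads, which guarantees a valid nested difference with
``delta_df >= 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gsca import GscaFit, StandardizedData, fit_gsca
from .model import ModelSpec
from .tetrads import (
    TetradCatalog,
    TetradTestResult,
    enumerate_tetrads,
    implied_vanishing_set,
    jacobian_tau_sigma,
    select_nonredundant,
    sigma_S_adf,
    sigma_S_normal,
    tetrad_test,
    tetrad_values,
)
from .fit import implied_correlation

__all__ = [
    "NestednessResult",
    "NotNestedError",
    "TetradEquivalenceError",
    "NestedComparisonResult",
    "ComparisonRow",
    "check_nestedness",
    "delta_test",
    "compare_models",
]


class NotNestedError(ValueError):
    """The two models are not tetrad-nested; carries the offending set."""

    def __init__(self, message: str, offending: np.ndarray):
        super().__init__(message)
        self.offending = offending


class TetradEquivalenceError(ValueError):
    """Identical vanishing sets: equivalent by tetrads, not comparable."""


@dataclass(frozen=True)
class NestednessResult:
    nested: bool
    equivalent: bool
    offending: np.ndarray  # tetrads vanishing in the less restrictive model only


def check_nestedness(
    van_restrictive: np.ndarray, van_less: np.ndarray
) -> NestednessResult:
    """Is the less restrictive model tetrad-nested in the restrictive one?

    Nested iff the less restrictive model's vanishing set is a *strict*
    subset of the restrictive model's.  Identical sets are flagged
    equivalent (not comparable by the difference test); otherwise the
    offending tetrads — vanishing in the less restrictive model only — are
    returned.
    """
    r = set(np.asarray(van_restrictive).tolist())
    l = set(np.asarray(van_less).tolist())
    offending = np.array(sorted(l - r), dtype=int)
    if l == r:
        return NestednessResult(nested=False, equivalent=True, offending=offending)
    return NestednessResult(nested=l < r, equivalent=False, offending=offending)


def delta_test(
    t_restrictive: float,
    df_restrictive: int,
    t_less: float,
    df_less: int,
) -> tuple[float, int, float]:
    """Chi-square difference test: returns (delta_T, delta_df, p).

    ``delta_T = T_restrictive - T_less`` referred to the upper tail of
    chi-square with ``df_restrictive - df_less`` degrees of freedom.  A
    negative difference (a finite-sample artifact) is reported as-is with a
    warning and p = 1.
    """
    if df_restrictive <= df_less:
        raise ValueError(
            f"df of the restrictive model must exceed the less restrictive "
            f"model's ({df_restrictive} <= {df_less})"
        )
    if t_restrictive < 0 or t_less < 0:
        raise ValueError("chi-square statistics must be non-negative")
    delta_t = t_restrictive - t_less
    delta_df = df_restrictive - df_less
    if delta_t < 0:
        warnings.warn(
            "negative chi-square difference (finite-sample artifact); p set to 1",
            UserWarning,
        )
        return delta_t, delta_df, 1.0
    return delta_t, delta_df, float(stats.chi2.sf(delta_t, delta_df))


@dataclass(frozen=True)
class ComparisonRow:
    rep: int
    t_restrictive: float
    df_restrictive: int
    p_restrictive: float
    t_less: float
    df_less: int
    p_less: float
    delta_t: float
    delta_df: int
    p_delta: float


@dataclass
class NestedComparisonResult:
    """Replicated nested comparison in the layout of a report table:
    one row per replication with the restrictive model's (T, df, p), the
    less restrictive model's, and the difference block."""

    restrictive: str
    less: str
    nested: bool
    rows: list[ComparisonRow]
    fit_restrictive: GscaFit
    fit_less: GscaFit

    def rejection_rate(self, alpha: float = 0.05) -> float:
        return float(np.mean([row.p_delta < alpha for row in self.rows]))

    def to_table(self) -> str:
        head = (
            f"{'Rep':>3} | {'Chi-square':>10} {'df':>4} {'p':>6} | "
            f"{'Chi-square':>10} {'df':>4} {'p':>6} | "
            f"{'dChi-sq':>9} {'ddf':>4} {'p':>6}"
        )
        lines = [
            f"restrictive: {self.restrictive}   less restrictive: {self.less}",
            head,
            "-" * len(head),
        ]
        for r in self.rows:
            lines.append(
                f"{r.rep:>3} | {r.t_restrictive:>10.1f} {r.df_restrictive:>4} "
                f"{r.p_restrictive:>6.3f} | {r.t_less:>10.1f} {r.df_less:>4} "
                f"{r.p_less:>6.3f} | {r.delta_t:>9.1f} {r.delta_df:>4} "
                f"{r.p_delta:>6.3f}"
            )
        return "\n".join(lines)


def compare_models(
    data: StandardizedData,
    spec_restrictive: ModelSpec,
    spec_less: ModelSpec,
    n_reps: int = 5,
    seed: int | None = None,
    use_T1: bool = False,
    normal_theory: bool = False,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> NestedComparisonResult:
    """Replicated tetrad-nested comparison of two models on the same data.

    Both models are fit by alternating least squares; their implied
    vanishing sets are checked for strict nestedness (``NotNestedError``
    with the offending tetrads otherwise, ``TetradEquivalenceError`` for
    identical sets).  Each replication draws a fresh random non-redundant
    selection for the restrictive model and forces the less-restrictive
    model's selection to be a subset of it, then computes both statistics
    and the chi-square difference.
    """
    if tuple(spec_restrictive.indicator_names) != tuple(spec_less.indicator_names):
        raise ValueError("models must be defined over the same indicators")

    fit_r = fit_gsca(data, spec_restrictive, tol=tol, max_iter=max_iter)
    fit_l = fit_gsca(data, spec_less, tol=tol, max_iter=max_iter)

    catalog = enumerate_tetrads(data.J)
    van_r = implied_vanishing_set(implied_correlation(fit_r, data), catalog)
    van_l = implied_vanishing_set(implied_correlation(fit_l, data), catalog)

    nest = check_nestedness(van_r, van_l)
    if nest.equivalent:
        raise TetradEquivalenceError(
            "the two models imply identical vanishing-tetrad sets: "
            "equivalent by tetrads, not comparable by the difference test"
        )
    if not nest.nested:
        raise NotNestedError(
            f"models are not tetrad-nested: {nest.offending.size} tetrad(s) "
            "vanish in the less restrictive model but not in the "
            f"restrictive one (e.g. catalog indices "
            f"{nest.offending[:5].tolist()})",
            offending=nest.offending,
        )

    # shared ingredients across replications
    S = data.sample_correlation
    tau_hat = tetrad_values(S, catalog)
    Sigma_S = sigma_S_normal(S) if normal_theory else sigma_S_adf(data)
    jac = jacobian_tau_sigma(catalog, S)
    Jr = jac[van_r]
    Sigma_tau_r = Jr @ Sigma_S @ Jr.T

    rng = np.random.default_rng(seed)
    in_less = np.isin(van_r, van_l)
    rows: list[ComparisonRow] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for rep in range(1, n_reps + 1):
            # restrictive model: sweep in an order that visits the shared
            # (less-model) tetrads first, so its selection restricted to the
            # shared tetrads is itself a valid selection for the less model
            shared = np.flatnonzero(in_less)
            extra = np.flatnonzero(~in_less)
            order = np.concatenate(
                [rng.permutation(shared), rng.permutation(extra)]
            )
            sel_r = select_nonredundant(van_r, Sigma_tau_r, forced_order=order)
            sel_l = sel_r[np.isin(sel_r, van_l)]
            if sel_l.size == 0 or sel_r.size <= sel_l.size:
                raise ValueError(
                    "degenerate replication: delta_df = 0 "
                    "(selections coincide on the shared tetrads)"
                )
            res_r = tetrad_test(
                data, fit_r, use_T1=use_T1, normal_theory=normal_theory,
                _selection=sel_r,
            )
            res_l = tetrad_test(
                data, fit_l, use_T1=use_T1, normal_theory=normal_theory,
                _selection=sel_l,
            )
            dt, ddf, pd_ = delta_test(
                res_r.statistic, res_r.df, res_l.statistic, res_l.df
            )
            rows.append(
                ComparisonRow(
                    rep=rep,
                    t_restrictive=res_r.statistic,
                    df_restrictive=res_r.df,
                    p_restrictive=res_r.p_value,
                    t_less=res_l.statistic,
                    df_less=res_l.df,
                    p_less=res_l.p_value,
                    delta_t=dt,
                    delta_df=ddf,
                    p_delta=pd_,
                )
            )

    return NestedComparisonResult(
        restrictive="restrictive",
        less="less-restrictive",
        nested=True,
        rows=rows,
        fit_restrictive=fit_r,
        fit_less=fit_l,
    )
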