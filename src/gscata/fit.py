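"""Descriptive model-fit measures and the model-implied correlation matrix.

FIT is the proportion of the total variance of all indicators and components
explained by the model, ``FIT = 1 - SS(ZV - ZWA)/SS(ZV)``, identically equal
to the average R^2 over the J+P model equations.  AFIT penalizes FIT by the
free-parameter count delta through the degrees-of-freedom ratio d0/d1 with
d0 = N*J and d1 = N*J - delta.  GFI and SRMR measure the discrepancy between
the sample correlation matrix S and the model-implied matrix

    Sigma_hat = C' Phi_gamma C   (unit diagonal),  Phi_gamma = W' S W.

The reflective reconstruction above is the package's definition of the
implied matrix: each block of indicators is reproduced by its component's
loadings, and cross-block correlations by the loadings times the component
correlation, which gives the rank-one cross-block structure that the tetrad
analysis in :mod:`gscata.tetrads` exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gsca import GscaFit, StandardizedData
from .model import ModelSpec

__all__ = [
    "FitIndices",
    "compute_fit",
    "implied_correlation",
    "compute_gfi_srmr",
    "composite_reliability",
    "fit_indices",
    "GFI_GOOD",
    "SRMR_GOOD",
    "RELIABILITY_GOOD",
]

#: Conventional good-fit thresholds: GFI above 0.95, SRMR below 0.08 and
#: composite reliability above 0.70.
GFI_GOOD = 0.95
SRMR_GOOD = 0.08
RELIABILITY_GOOD = 0.70


@dataclass(frozen=True)
class FitIndices:
    FIT: float
    AFIT: float
    GFI: float
    SRMR: float
    rho: dict[str, float]
    delta: int
    d0: int
    d1: int
    T_count: int


def compute_fit(fit: GscaFit, data: StandardizedData) -> tuple[float, float]:
    """Return (FIT, AFIT).

    FIT = 1 - Phi/SS(ZV); the equivalent mean-R^2 form is exposed through
    ``fit.r_squared`` and asserted equal in the test-suite.  AFIT uses
    d0 = N*J and d1 = N*J - delta with delta the number of free entries in
    the weight, loading and path patterns (plus free exogenous
    correlations).
    """
    N = data.N
    J = data.J
    P = fit.spec.n_components
    ss_zv = float(N * (J + P))  # standardized columns: SS = N each
    assert ss_zv > 0
    FIT = 1.0 - fit.Phi_value / ss_zv
    delta = fit.spec.n_free_parameters
    d0 = N * J
    d1 = N * J - delta
    if d1 <= 0:
        raise ValueError("free parameters exceed N*J; AFIT undefined")
    AFIT = 1.0 - (1.0 - FIT) * d0 / d1
    return FIT, AFIT


def implied_correlation(fit: GscaFit, data: StandardizedData) -> np.ndarray:
    """Model-implied correlation matrix Sigma_hat = C' Phi_gamma C.

    ``Phi_gamma = W' S W`` is the component correlation matrix at the
    estimates.  The diagonal is forced to one (each indicator's variance is
    exact by standardization); a numerically indefinite ``Phi_gamma`` is
    clipped at zero eigenvalues with a warning.
    """
    Phi_g = fit.component_correlations(data)
    eig = np.linalg.eigvalsh(Phi_g)
    if eig[0] < -1e-10:
        warnings.warn("component correlation matrix not PSD; clipping", UserWarning)
        lam, Q = np.linalg.eigh(Phi_g)
        Phi_g = Q @ np.diag(np.clip(lam, 0.0, None)) @ Q.T
    Sigma = fit.C_hat.T @ Phi_g @ fit.C_hat
    Sigma = (Sigma + Sigma.T) / 2.0
    np.fill_diagonal(Sigma, 1.0)
    return Sigma


def compute_gfi_srmr(S: np.ndarray, Sigma_hat: np.ndarray) -> tuple[float, float]:
    """GFI and SRMR from the sample and implied correlation matrices.

    GFI = 1 - trace((S - Sigma_hat)^2)/trace(S^2).  The SRMR sum runs over
    the lower triangle including the diagonal, q = 1..j, with the unit
    diagonals contributing zero on the correlation scale:

        SRMR = sqrt( 2 * sum_j sum_{q<=j} ((s_jq - sigma_jq)/sqrt(s_jj s_qq))^2
                     / (J (J+1)) ).
    """
    S = np.asarray(S, dtype=float)
    Sigma_hat = np.asarray(Sigma_hat, dtype=float)
    if S.shape != Sigma_hat.shape or S.shape[0] != S.shape[1]:
        raise ValueError("dimension mismatch between S and Sigma_hat")
    J = S.shape[0]
    D = S - Sigma_hat
    gfi = 1.0 - float(np.trace(D @ D)) / float(np.trace(S @ S))
    d = np.sqrt(np.diag(S))
    scaled = D / np.outer(d, d)
    low = np.tril_indices(J)  # includes diagonal, q = 1..j
    srmr = float(np.sqrt(2.0 * np.sum(scaled[low] ** 2) / (J * (J + 1))))
    return gfi, srmr


def composite_reliability(C_hat: np.ndarray, spec: ModelSpec) -> dict[str, float]:
    """Composite reliability rho_p per reflective block:

        rho_p = (sum_j c_pj)^2 / ((sum_j c_pj)^2 + sum_j (1 - c_pj^2)).

    Components with no loadings (e.g. a second-order component) are skipped.
    """
    out: dict[str, float] = {}
    for p, comp in enumerate(spec.component_names):
        mask = spec.loading_pattern[p]
        if not mask.any():
            continue
        c = C_hat[p, mask]
        num = c.sum() ** 2
        out[comp] = float(num / (num + np.sum(1.0 - c**2)))
    return out


def fit_indices(fit: GscaFit, data: StandardizedData) -> FitIndices:
    """All global indices plus per-component composite reliabilities."""
    FIT, AFIT = compute_fit(fit, data)
    S = data.sample_correlation
    Sigma_hat = implied_correlation(fit, data)
    gfi, srmr = compute_gfi_srmr(S, Sigma_hat)
    rho = composite_reliability(fit.C_hat, fit.spec)
    delta = fit.spec.n_free_parameters
    return FitIndices(
        FIT=FIT,
        AFIT=AFIT,
        GFI=gfi,
        SRMR=srmr,
        rho=rho,
        delta=delta,
        d0=data.N * data.J,
        d1=data.N * data.J - delta,
        T_count=data.J + fit.spec.n_components,
    )
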