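"""Synthetic rating-scale data with the structure of the four archetype
models.

The generator emulates a two-rater social-skills instrument: eight scales
scored 1-4, four rated by teachers and four by parents, with realistic
marginal means and standard deviations.  Latent-Gaussian data are drawn
from the population correlation matrix implied by one of the four model
structures (M0 two correlated factors, M1 the same with a directed path,
M2 a second-order factor, M3 four correlated factors), affinely rescaled to
the target marginals and optionally clipped to the 1-4 scale.  Clipping
induces mild non-normality on purpose: the tetrad machinery is
distribution-free and is exercised in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ECLSK_INDICATORS

__all__ = ["SyntheticConfig", "population_sigma", "generate", "builtin_config"]

#: Printed marginal means and SDs of the eight scales (teacher self-control,
#: interpersonal, externalizing, internalizing; parent self-control, social
#: interaction, sad/lonely, impulsive/overactive).
_TARGET_MOMENTS = {
    "t_self_control": (3.216, 0.623),
    "t_interpersonal": (3.142, 0.656),
    "t_external_prob": (1.721, 0.618),
    "t_internal_prob": (1.539, 0.505),
    "p_self_control": (3.016, 0.495),
    "p_social_interact": (3.432, 0.556),
    "p_sad_lonely": (1.463, 0.388),
    "p_impulsive": (1.869, 0.663),
}

#: Default sample size, matching the motivating study's extract.
DEFAULT_N = 18174


@dataclass(frozen=True)
class SyntheticConfig:
    """Population parameters for one generating structure.

    ``blocks`` maps each factor to its indicators; ``loadings`` gives one
    standardized loading per indicator (|lambda| <= 1); ``factor_corr`` is
    the factor correlation matrix.  For M1 the single path coefficient b
    equals the implied factor correlation of standardized components; for
    M2 the first-order factor correlation is the product of the two
    second-order loadings.
    """

    model_id: str
    n: int
    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    loadings: dict[str, float]
    factor_corr: np.ndarray
    target_means: dict[str, float]
    target_sds: dict[str, float]
    scale_bounds: tuple[float, float] | None = (1.0, 4.0)
    seed: int = 0
    second_order_loadings: tuple[float, float] | None = None
    path_value: float | None = None
    indicator_names: tuple[str, ...] = field(default=ECLSK_INDICATORS)


def population_sigma(config: SyntheticConfig) -> np.ndarray:
    """Population correlation matrix implied by the configuration.

    Within a block ``sigma_ij = lambda_i lambda_j``; across blocks p, q
    ``sigma_ij = lambda_i phi_pq lambda_j`` — the single-factor-per-block,
    rank-one cross-block structure.  Raises if the result is not positive
    definite.
    """
    names = list(config.indicator_names)
    J = len(names)
    P = len(config.blocks)
    Lam = np.zeros((J, P))
    for p, (_, inds) in enumerate(config.blocks):
        for ind in inds:
            Lam[names.index(ind), p] = config.loadings[ind]
    Phi = np.asarray(config.factor_corr, dtype=float)
    if Phi.shape != (P, P):
        raise ValueError(f"factor_corr must be {P}x{P}")
    Sigma = Lam @ Phi @ Lam.T
    np.fill_diagonal(Sigma, 1.0)
    if np.linalg.eigvalsh(Sigma).min() <= 1e-12:
        raise ValueError("implied population correlation matrix is not positive definite")
    return Sigma


def generate(config: SyntheticConfig, clip: bool | None = None) -> pd.DataFrame:
    """Draw an N x J rating-scale table from the configured population.

    Latent Gaussian draws with correlation :func:`population_sigma` are
    rescaled to the target means/SDs; when ``clip`` (default: on when
    ``scale_bounds`` is set) the values are truncated to the bounds, which
    slightly perturbs the marginal moments.  Fixed seed => identical table.
    """
    Sigma = population_sigma(config)
    rng = np.random.default_rng(config.seed)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((config.n, len(config.indicator_names))) @ L.T
    means = np.array([config.target_means[c] for c in config.indicator_names])
    sds = np.array([config.target_sds[c] for c in config.indicator_names])
    X = X * sds + means
    if clip is None:
        clip = config.scale_bounds is not None
    if clip:
        if config.scale_bounds is None:
            raise ValueError("clip requested but no scale bounds configured")
        lo, hi = config.scale_bounds
        X = np.clip(X, lo, hi)
    return pd.DataFrame(X, columns=list(config.indicator_names))


_T, _P = ECLSK_INDICATORS[:4], ECLSK_INDICATORS[4:]


def builtin_config(
    model_id: str,
    n: int = DEFAULT_N,
    seed: int = 0,
    loading: float = 0.8,
) -> SyntheticConfig:
    """Default population configuration for one of the four archetypes.

    All within-block loadings default to 0.8 (composite reliabilities in
    the conventionally good range).  M0 uses a factor correlation of 0.4;
    M1 a standardized regression of 0.367; M2 second-order loadings whose
    product reproduces M0's factor correlation; M3 within-rater factor
    correlations of 0.6 and cross-rater 0.3.
    """
    loadings = {name: loading for name in ECLSK_INDICATORS}
    common = dict(
        n=n,
        seed=seed,
        loadings=loadings,
        target_means={k: v[0] for k, v in _TARGET_MOMENTS.items()},
        target_sds={k: v[1] for k, v in _TARGET_MOMENTS.items()},
    )
    if model_id == "M0":
        return SyntheticConfig(
            model_id="M0",
            blocks=(("T_SS", _T), ("P_SS", _P)),
            factor_corr=np.array([[1.0, 0.4], [0.4, 1.0]]),
            **common,
        )
    if model_id == "M1":
        b = 0.367
        return SyntheticConfig(
            model_id="M1",
            blocks=(("T_SS", _T), ("P_SS", _P)),
            factor_corr=np.array([[1.0, b], [b, 1.0]]),
            path_value=b,
            **common,
        )
    if model_id == "M2":
        a1 = a2 = np.sqrt(0.4)  # product reproduces M0's factor correlation
        return SyntheticConfig(
            model_id="M2",
            blocks=(("T_SS", _T), ("P_SS", _P)),
            factor_corr=np.array([[1.0, a1 * a2], [a1 * a2, 1.0]]),
            second_order_loadings=(a1, a2),
            **common,
        )
    if model_id == "M3":
        phi = np.array(
            [
                [1.0, 0.6, 0.3, 0.3],
                [0.6, 1.0, 0.3, 0.3],
                [0.3, 0.3, 1.0, 0.6],
                [0.3, 0.3, 0.6, 1.0],
            ]
        )
        return SyntheticConfig(
            model_id="M3",
            blocks=(
                ("T_SS1", _T[:2]),
                ("T_SS2", _T[2:]),
                ("P_SS1", _P[:2]),
                ("P_SS2", _P[2:]),
            ),
            factor_corr=phi,
            **common,
        )
    raise ValueError(f"unknown model id {model_id!r}; expected one of M0, M1, M2, M3")
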