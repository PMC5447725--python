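"""Model specification for component-based structural equation models.

A GSCA model has three sub-models: a *weighted relation* model defining each
latent variable as a weighted composite (component) of its indicators,
``gamma = W' z``; a *measurement* model relating indicators to components,
``z = C' gamma + eps``; and a *structural* model of directed paths among
components, ``gamma = B' gamma + zeta``.  A :class:`ModelSpec` records only
the *patterns* (structural zeros) of ``W``, ``C`` and ``B`` together with the
names of indicators and components; numeric values are estimated later.

Models are written in a small lavaan-like line syntax::

    # reflective component of two indicators
    T_SS =~ t_self_control + t_interpersonal
    # directed path between components
    P_SS -> T_SS
    # free correlation between exogenous components
    P_SS ~~ T_SS
    # second-order component over first-order components
    SS =2~ P_SS + T_SS

All measurement blocks are reflective: arrows point from the construct to its
indicators.  Formative blocks are rejected with an explicit error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelSpecError",
    "parse_model",
    "serialize_model",
    "builtin_model",
    "ECLSK_INDICATORS",
]


class ModelSpecError(ValueError):
    """Raised for an invalid or inconsistent model specification."""


#: The eight social-skill rating scales (teacher- and parent-rated, 1-4 scale)
#: used by all built-in models.
ECLSK_INDICATORS = (
    "t_self_control",
    "t_interpersonal",
    "t_external_prob",
    "t_internal_prob",
    "p_self_control",
    "p_social_interact",
    "p_sad_lonely",
    "p_impulsive",
)


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a GSCA model.

    Parameters
    ----------
    indicator_names
        The J observed-variable names, in data-column order.
    component_names
        The P component (latent-variable) names.
    weight_pattern
        J x P boolean array; entry ``(j, p)`` is True when indicator ``j``
        enters component ``p``'s composite (structural zeros of W).
    loading_pattern
        P x J boolean array; structural zeros of the loading matrix C.
    path_pattern
        P x P boolean array; ``(p, q)`` True means a directed path from
        component ``p`` to component ``q`` (structural zeros of B).
    correlate_exogenous
        Whether exogenous components are freely correlated (a two-factor
        model with no paths and a factor correlation is the archetype).
    higher_order
        Tuple of ``(second_order_name, (first_order_names, ...))`` pairs for
        hierarchical components.
    """

    indicator_names: tuple[str, ...]
    component_names: tuple[str, ...]
    weight_pattern: np.ndarray
    loading_pattern: np.ndarray
    path_pattern: np.ndarray
    correlate_exogenous: bool = False
    higher_order: tuple[tuple[str, tuple[str, ...]], ...] = field(default=())

    def __post_init__(self) -> None:
        J, P = len(self.indicator_names), len(self.component_names)
        W = np.asarray(self.weight_pattern, dtype=bool)
        C = np.asarray(self.loading_pattern, dtype=bool)
        B = np.asarray(self.path_pattern, dtype=bool)
        if W.shape != (J, P):
            raise ModelSpecError(f"weight_pattern must be {J}x{P}, got {W.shape}")
        if C.shape != (P, J):
            raise ModelSpecError(f"loading_pattern must be {P}x{J}, got {C.shape}")
        if B.shape != (P, P):
            raise ModelSpecError(f"path_pattern must be {P}x{P}, got {B.shape}")
        object.__setattr__(self, "weight_pattern", W)
        object.__setattr__(self, "loading_pattern", C)
        object.__setattr__(self, "path_pattern", B)
        if len(set(self.indicator_names)) != J:
            raise ModelSpecError("duplicate indicator names")
        if len(set(self.component_names)) != P:
            raise ModelSpecError("duplicate component names")
        if set(self.indicator_names) & set(self.component_names):
            raise ModelSpecError("indicator and component names must be disjoint")
        if not W.any(axis=1).all():
            orphans = [n for n, ok in zip(self.indicator_names, W.any(axis=1)) if not ok]
            raise ModelSpecError(f"indicators in no component: {orphans}")
        if (~W.any(axis=0)).any():
            empty = [n for n, ok in zip(self.component_names, W.any(axis=0)) if not ok]
            raise ModelSpecError(f"components with no indicators: {empty}")
        if B.diagonal().any():
            raise ModelSpecError("self-loop in path pattern")
        if _has_cycle(B):
            raise ModelSpecError("path pattern contains a cycle")
        # reflective blocks: an indicator can only load on a component it
        # belongs to
        if (C & ~W.T).any():
            raise ModelSpecError("loading outside the component's indicator block")

    # -- convenience -------------------------------------------------------

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_names)

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    def indicator_index(self, name: str) -> int:
        return self.indicator_names.index(name)

    def component_index(self, name: str) -> int:
        return self.component_names.index(name)

    @property
    def n_free_parameters(self) -> int:
        """Free-parameter count delta used by the AFIT penalty.

        Counted as #weights + #loadings + #paths, plus the free correlations
        among exogenous components when ``correlate_exogenous`` is set.
        """
        delta = int(self.weight_pattern.sum() + self.loading_pattern.sum()
                    + self.path_pattern.sum())
        if self.correlate_exogenous:
            exo = ~self.path_pattern.any(axis=0)  # no incoming path
            k = int(exo.sum())
            delta += k * (k - 1) // 2
        return delta

    def blocks(self) -> dict[str, list[str]]:
        """Map each component to the indicators in its weight pattern."""
        return {
            comp: [ind for j, ind in enumerate(self.indicator_names)
                   if self.weight_pattern[j, p]]
            for p, comp in enumerate(self.component_names)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelSpec):
            return NotImplemented
        return (
            self.indicator_names == other.indicator_names
            and self.component_names == other.component_names
            and np.array_equal(self.weight_pattern, other.weight_pattern)
            and np.array_equal(self.loading_pattern, other.loading_pattern)
            and np.array_equal(self.path_pattern, other.path_pattern)
            and self.correlate_exogenous == other.correlate_exogenous
            and self.higher_order == other.higher_order
        )

    __hash__ = None  # type: ignore[assignment]


def _has_cycle(adj: np.ndarray) -> bool:
    """Cycle check on a boolean adjacency matrix by repeated source stripping."""
    active = np.ones(adj.shape[0], dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        incoming = adj[np.ix_(idx, idx)].any(axis=0)
        sources = idx[~incoming]
        if sources.size == 0:
            return True
        active[sources] = False
    return False


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_RE_MEASURE = re.compile(rf"^({_NAME})\s*=~\s*(.+)$")
_RE_SECOND = re.compile(rf"^({_NAME})\s*=2~\s*(.+)$")
_RE_PATH = re.compile(rf"^({_NAME})\s*->\s*({_NAME})$")
_RE_CORR = re.compile(rf"^({_NAME})\s*~~\s*({_NAME})$")


def parse_model(text: str) -> ModelSpec:
    """Parse a model-syntax string into a validated :class:`ModelSpec`.

    One statement per line; ``#`` starts a comment.  See the module docstring
    for the four statement forms.
    """
    components: dict[str, list[str]] = {}
    second_order: dict[str, list[str]] = {}
    paths: list[tuple[str, str]] = []
    correlations: list[tuple[str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if m := _RE_MEASURE.match(line):
            name, rhs = m.group(1), m.group(2)
            if name in components or name in second_order:
                raise ModelSpecError(f"line {lineno}: duplicate definition of {name!r}")
            inds = [t.strip() for t in rhs.split("+")]
            if any(not t for t in inds):
                raise ModelSpecError(f"line {lineno}: empty indicator in {name!r}")
            components[name] = inds
        elif m := _RE_SECOND.match(line):
            name, rhs = m.group(1), m.group(2)
            if name in components or name in second_order:
                raise ModelSpecError(f"line {lineno}: duplicate definition of {name!r}")
            second_order[name] = [t.strip() for t in rhs.split("+")]
        elif m := _RE_PATH.match(line):
            paths.append((m.group(1), m.group(2)))
        elif m := _RE_CORR.match(line):
            correlations.append((m.group(1), m.group(2)))
        elif "<~" in line or "<-" in line:
            raise ModelSpecError(
                f"line {lineno}: formative blocks are not supported "
                "(all measurement blocks are reflective)"
            )
        else:
            raise ModelSpecError(f"line {lineno}: cannot parse {line!r}")

    if not components:
        raise ModelSpecError("no components defined")

    indicator_names: list[str] = []
    for inds in components.values():
        for ind in inds:
            if ind in components or ind in second_order:
                raise ModelSpecError(f"{ind!r} is a component, not an indicator")
            if ind not in indicator_names:
                indicator_names.append(ind)

    comp_names = list(components) + list(second_order)
    J, P = len(indicator_names), len(comp_names)
    W = np.zeros((J, P), dtype=bool)
    C = np.zeros((P, J), dtype=bool)
    B = np.zeros((P, P), dtype=bool)

    jidx = {n: j for j, n in enumerate(indicator_names)}
    pidx = {n: p for p, n in enumerate(comp_names)}

    for name, inds in components.items():
        p = pidx[name]
        for ind in inds:
            W[jidx[ind], p] = True
            C[p, jidx[ind]] = True

    # a second-order component is a composite of the union of its first-order
    # components' indicators, with no direct loadings and directed paths to
    # each first-order component
    for name, firsts in second_order.items():
        p = pidx[name]
        for f in firsts:
            if f not in components:
                raise ModelSpecError(
                    f"second-order component {name!r} references unknown "
                    f"first-order component {f!r}"
                )
            for ind in components[f]:
                W[jidx[ind], p] = True
            B[p, pidx[f]] = True

    for a, b in paths:
        for n in (a, b):
            if n not in pidx:
                raise ModelSpecError(f"path references unknown component {n!r}")
        B[pidx[a], pidx[b]] = True

    for a, b in correlations:
        for n in (a, b):
            if n not in pidx:
                raise ModelSpecError(f"correlation references unknown component {n!r}")

    return ModelSpec(
        indicator_names=tuple(indicator_names),
        component_names=tuple(comp_names),
        weight_pattern=W,
        loading_pattern=C,
        path_pattern=B,
        correlate_exogenous=bool(correlations) or not paths,
        higher_order=tuple((n, tuple(f)) for n, f in second_order.items()),
    )


def serialize_model(spec: ModelSpec) -> str:
    """Render a ModelSpec back into the line syntax (round-trips through
    :func:`parse_model`)."""
    second = {n for n, _ in spec.higher_order}
    lines = []
    for p, comp in enumerate(spec.component_names):
        if comp in second:
            continue
        inds = [spec.indicator_names[j] for j in np.flatnonzero(spec.weight_pattern[:, p])]
        lines.append(f"{comp} =~ " + " + ".join(inds))
    for name, firsts in spec.higher_order:
        lines.append(f"{name} =2~ " + " + ".join(firsts))
    ho_paths = {(name, f) for name, firsts in spec.higher_order for f in firsts}
    for p in range(spec.n_components):
        for q in range(spec.n_components):
            if spec.path_pattern[p, q]:
                pair = (spec.component_names[p], spec.component_names[q])
                if pair not in ho_paths:
                    lines.append(f"{pair[0]} -> {pair[1]}")
    if spec.correlate_exogenous:
        exo = [spec.component_names[p] for p in range(spec.n_components)
               if not spec.path_pattern[:, p].any() and spec.component_names[p] not in second]
        for i in range(len(exo)):
            for j in range(i + 1, len(exo)):
                lines.append(f"{exo[i]} ~~ {exo[j]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# built-in models for the eight social-skill scales
# ---------------------------------------------------------------------------

_TEACHER = ECLSK_INDICATORS[:4]
_PARENT = ECLSK_INDICATORS[4:]

_BUILTIN_TEXT = {
    # two correlated factors: teacher-rated and parent-rated social skills
    "M0": (
        f"T_SS =~ {' + '.join(_TEACHER)}\n"
        f"P_SS =~ {' + '.join(_PARENT)}\n"
        "P_SS ~~ T_SS\n"
    ),
    # same measurement model, directed path from parent- to teacher-rated
    "M1": (
        f"T_SS =~ {' + '.join(_TEACHER)}\n"
        f"P_SS =~ {' + '.join(_PARENT)}\n"
        "P_SS -> T_SS\n"
    ),
    # second-order social-skill component over the two first-order factors,
    # with unconstrained paths to each
    "M2": (
        f"T_SS =~ {' + '.join(_TEACHER)}\n"
        f"P_SS =~ {' + '.join(_PARENT)}\n"
        "SS =2~ P_SS + T_SS\n"
    ),
    # four correlated factors: each rater's scales split in two
    "M3": (
        f"T_SS1 =~ {_TEACHER[0]} + {_TEACHER[1]}\n"
        f"T_SS2 =~ {_TEACHER[2]} + {_TEACHER[3]}\n"
        f"P_SS1 =~ {_PARENT[0]} + {_PARENT[1]}\n"
        f"P_SS2 =~ {_PARENT[2]} + {_PARENT[3]}\n"
        "T_SS1 ~~ T_SS2\nT_SS1 ~~ P_SS1\nT_SS1 ~~ P_SS2\n"
        "T_SS2 ~~ P_SS1\nT_SS2 ~~ P_SS2\nP_SS1 ~~ P_SS2\n"
    ),
}


def builtin_model(model_id: str) -> ModelSpec:
    """Return one of the four archetype models (``M0`` .. ``M3``) over the
    eight teacher/parent social-skill scales.

    ``M0``: two correlated factors (teacher, parent).  ``M1``: the same
    measurement model with a directed path parent -> teacher.  ``M2``: a
    second-order component over the two first-order factors.  ``M3``: four
    correlated factors of two indicators each.
    """
    try:
        text = _BUILTIN_TEXT[model_id]
    except KeyError:
        raise ModelSpecError(
            f"unknown model id {model_id!r}; expected one of M0, M1, M2, M3"
        ) from None
    return parse_model(text)
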