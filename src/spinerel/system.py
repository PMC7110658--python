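"""Series/parallel system reliability of the vertebral column.

Structural reading of the column: within one vertebra the cortical shell and
cancellous core share the load path, so the vertebra fails only if both
tissues fail (a parallel pair); likewise the annulus and nucleus within one
disc. A section (vertebra plus its disc) fails if either component fails
(series), and the whole backbone is a series chain of its sections. With
independent component failures:

    parallel:  P_F = prod(P_Fi)
    series:    P_F = 1 - prod(1 - P_Fi)

The series complement-product is evaluated through summed log1p terms so a
33-section chain of probabilities near 1e-6 loses no precision to
cancellation. Independence of component failures is an explicit modelling
assumption throughout; correlated extensions are out of scope.

The system reliability index is the generalized one, beta = -Phi^(-1)(P_f),
the convention under which every published (P_f, beta) reference pair here
round-trips at two decimals.

An exact enumeration oracle over small series/parallel composition trees is
included so every product formula can be checked against a full joint-outcome
sum in tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.special import ndtr, ndtri

from .component import ComponentReliability, Method, component_reliability
from .demand import (
    Condition,
    DemandDistribution,
    LoadCase,
    SpineTopology,
)
from .errors import (
    EmptySystemError,
    EnumerationBoundError,
    ProbabilityRangeError,
    UnknownTokenError,
)
from .materials import (
    DISC_TISSUES,
    VERTEBRA_TISSUES,
    LoadMode,
    TissueKind,
    YieldStrengthDistribution,
)

__all__ = [
    "SectionReliability",
    "SystemResult",
    "parallel_pf",
    "series_pf",
    "disc_pf",
    "vertebra_pf",
    "sectional_pf",
    "backbone_pf",
    "beta_from_pf",
    "pf_from_beta",
    "Comp",
    "Series",
    "Parallel",
    "enumeration_oracle",
    "evaluate_system",
]


def _check_probs(pfs: Sequence[float]) -> None:
    for p in pfs:
        if not 0.0 <= p <= 1.0:
            raise ProbabilityRangeError(f"probability out of [0, 1]: {p}")


def parallel_pf(pfs: Sequence[float]) -> float:
    """Failure probability of a parallel system of independent components:
    all must fail, P_F = prod(P_Fi)."""
    if len(pfs) == 0:
        raise EmptySystemError("parallel system needs at least one component")
    _check_probs(pfs)
    return float(np.prod(pfs))


def series_pf(pfs: Sequence[float]) -> float:
    """Failure probability of a series system of independent components:
    any failure fails the system, P_F = 1 - prod(1 - P_Fi).

    Evaluated as -expm1(sum(log1p(-pf))) so many small terms survive
    floating point intact.
    """
    if len(pfs) == 0:
        raise EmptySystemError("series system needs at least one component")
    _check_probs(pfs)
    if any(p == 1.0 for p in pfs):
        return 1.0
    return float(-np.expm1(np.sum(np.log1p(-np.asarray(pfs, dtype=float)))))


def disc_pf(pf_annulus: float, pf_nucleus: float) -> float:
    """Disc failure: annulus and nucleus share the load path, so both must
    fail — the product of the two."""
    _check_probs((pf_annulus, pf_nucleus))
    return pf_annulus * pf_nucleus


def vertebra_pf(pf_cancellous: float, pf_cortical: float) -> float:
    """Vertebra failure: cancellous core and cortical shell share the load
    path, so both must fail — the product of the two."""
    _check_probs((pf_cancellous, pf_cortical))
    return pf_cancellous * pf_cortical


def sectional_pf(pf_disc: float, pf_vertebra: float) -> float:
    """Section failure: either the disc or the vertebra failing fails the
    section, 1 - (1 - pf_disc)(1 - pf_vertebra)."""
    _check_probs((pf_disc, pf_vertebra))
    return 1.0 - (1.0 - pf_disc) * (1.0 - pf_vertebra)


def beta_from_pf(pf: float) -> float:
    """Generalized reliability index beta = -Phi^(-1)(pf); endpoints map to
    +/- infinity sentinels, values outside [0, 1] raise."""
    if not 0.0 <= pf <= 1.0:
        raise ProbabilityRangeError(f"pf out of [0, 1]: {pf}")
    if pf == 0.0:
        return math.inf
    if pf == 1.0:
        return -math.inf
    return float(-ndtri(pf))


def pf_from_beta(beta: float) -> float:
    """Inverse of :func:`beta_from_pf`: pf = Phi(-beta)."""
    return float(ndtr(-beta))


@dataclass(frozen=True)
class SectionReliability:
    """Failure probabilities of one section and its two component types;
    ``pf_disc`` is None for a section without a disc (then the section pf is
    the vertebra pf alone)."""

    section: str
    pf_disc: float | None
    pf_vertebra: float
    pf_section: float


@dataclass(frozen=True)
class SystemResult:
    """Whole-backbone outcome for one condition and load case."""

    sections: tuple[SectionReliability, ...]
    pf_backbone: float
    beta_backbone: float
    condition: Condition
    load_case: LoadCase
    config_digest: str = ""
    components: tuple[ComponentReliability, ...] = ()

    def summary(self) -> dict:
        return {
            "condition": self.condition.value,
            "body_mass_kg": self.load_case.body_mass,
            "pf_backbone": self.pf_backbone,
            "beta_backbone": self.beta_backbone,
        }


def backbone_pf(sections: Sequence[SectionReliability]) -> tuple[float, float]:
    """Series failure probability over all sections plus its reliability
    index; order of sections is immaterial."""
    if len(sections) == 0:
        raise EmptySystemError("backbone needs at least one section")
    pf = series_pf([s.pf_section for s in sections])
    return pf, beta_from_pf(pf)


# ---------------------------------------------------------------------------
# Exact enumeration oracle

@dataclass(frozen=True)
class Comp:
    """Leaf: an independent component with failure probability pf."""

    pf: float


@dataclass(frozen=True)
class Series:
    children: tuple = ()

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class Parallel:
    children: tuple = ()

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


Node = Union[Comp, Series, Parallel]

_ENUM_MAX_COMPONENTS = 20


def _leaves(node: Node) -> list[Comp]:
    if isinstance(node, Comp):
        return [node]
    return [leaf for child in node.children for leaf in _leaves(child)]


def _fails(node: Node, state: Mapping[int, bool], counter: itertools.count) -> bool:
    if isinstance(node, Comp):
        return state[next(counter)]
    results = [_fails(c, state, counter) for c in node.children]
    return any(results) if isinstance(node, Series) else all(results)


def enumeration_oracle(structure: Node) -> float:
    """Exact system failure probability of a series/parallel composition tree
    of independent components, by full enumeration of the 2^k joint outcomes.

    A deliberately brute-force reference for the product formulas; refuses
    trees with more than 20 components.
    """
    leaves = _leaves(structure)
    k = len(leaves)
    if k == 0:
        raise EmptySystemError("structure has no components")
    if k > _ENUM_MAX_COMPONENTS:
        raise EnumerationBoundError(
            f"{k} components exceed the enumeration bound of {_ENUM_MAX_COMPONENTS}"
        )
    _check_probs([leaf.pf for leaf in leaves])
    total = 0.0
    for outcome in itertools.product((False, True), repeat=k):
        state = dict(enumerate(outcome))
        weight = 1.0
        for leaf, failed in zip(leaves, outcome):
            weight *= leaf.pf if failed else (1.0 - leaf.pf)
        if _fails(structure, state, itertools.count()):
            total += weight
    return total


# ---------------------------------------------------------------------------
# Full-system evaluation from resistance + demand tables

_DISC_COMBINATIONS = ("parallel", "series")


def evaluate_system(
    topology: SpineTopology,
    resistances: Mapping[tuple[TissueKind, LoadMode], YieldStrengthDistribution],
    demands: Mapping[tuple[str, TissueKind, LoadMode], DemandDistribution],
    condition: Condition = Condition.NORMAL,
    load_case: LoadCase | None = None,
    method: Method | str = Method.CLOSED_FORM,
    mc_n: int = 1_000_000,
    seed: int = 0,
    policy: str = "governing",
    disc_combination: str = "parallel",
    config_digest: str = "",
) -> SystemResult:
    """Component -> section -> backbone aggregation for one demand table.

    ``disc_combination`` selects how the two tissues within a disc (and a
    vertebra) combine: ``parallel`` is the shared-load-path product reading
    (default); ``series`` is the alternative either-tissue-fails reading.
    """
    if disc_combination not in _DISC_COMBINATIONS:
        raise UnknownTokenError(
            f"unknown disc_combination {disc_combination!r}; expected {_DISC_COMBINATIONS}"
        )
    within = parallel_pf if disc_combination == "parallel" else series_pf

    components: list[ComponentReliability] = []
    sections: list[SectionReliability] = []
    for sec in topology.sections:
        per_tissue: dict[TissueKind, ComponentReliability] = {}
        tissues = list(VERTEBRA_TISSUES) + (list(DISC_TISSUES) if sec.disc else [])
        for tissue in tissues:
            comp = component_reliability(
                sec.vertebra, tissue, resistances, demands,
                method=method, n=mc_n, seed=seed, policy=policy,
            )
            per_tissue[tissue] = comp
            components.append(comp)
        p_vert = within(
            [per_tissue[TissueKind.CANCELLOUS].pf, per_tissue[TissueKind.CORTICAL].pf]
        )
        p_disc = (
            within([per_tissue[TissueKind.ANNULUS].pf, per_tissue[TissueKind.NUCLEUS].pf])
            if sec.disc
            else None
        )
        p_sec = sectional_pf(0.0 if p_disc is None else p_disc, p_vert)
        sections.append(SectionReliability(sec.vertebra, p_disc, p_vert, p_sec))

    if topology.include_support:
        sections.append(SectionReliability(topology.support_label, None, 0.0, 0.0))

    pf, beta = backbone_pf(sections)
    return SystemResult(
        sections=tuple(sections),
        pf_backbone=pf,
        beta_backbone=beta,
        condition=(
            condition
            if isinstance(condition, Condition)
            else Condition(str(condition).strip().lower())
        ),
        load_case=load_case if load_case is not None else LoadCase(body_mass=0.0),
        config_digest=config_digest,
        components=tuple(components),
    )
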