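"""Per-component failure probability and reliability index.

A component is one tissue of one spinal section. Its strength limit state is
g = R - Q with R the random yield stress (resistance) and Q the random
applied stress (demand); failure is the event g < 0. With R and Q normal and
independent, the reliability index has the closed form

    beta = (mu_R - mu_Q) / sqrt(sigma_R^2 + sigma_Q^2),   P_f = Phi(-beta).

The closed form is the default route. Monte Carlo counting over paired
(R, Q) draws — both truncated below at zero, matching the sampling model —
is the verification route; at the failure probabilities of interest
(1e-5 .. 1e-3) it needs large n, so draws are streamed in batches.
Truncation is ignored by the closed form; a warning is emitted when
mean/std < 3 for any distribution used there, which is where the
approximation could matter (cancellous and nucleus tissue).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .demand import DemandDistribution
from .materials import _coerce_tissue
from .errors import (
    DegenerateDistributionError,
    MissingEntryError,
    UnknownTokenError,
)
from .materials import LoadMode, TissueKind, YieldStrengthDistribution

__all__ = [
    "LimitState",
    "ComponentReliability",
    "Method",
    "beta_closed_form",
    "pf_monte_carlo",
    "deterministic_failure",
    "combine_modes",
    "component_reliability",
    "component_table",
]

#: crude-MC batch size; bounds memory while streaming large n
_MC_BATCH = 1_000_000


class Method(str, enum.Enum):
    CLOSED_FORM = "closed_form"
    MONTE_CARLO = "monte_carlo"


@dataclass(frozen=True)
class LimitState:
    """g = R - Q for one tissue/mode; resistance and demand must agree on
    tissue and mode."""

    resistance: YieldStrengthDistribution
    demand: DemandDistribution

    def __post_init__(self):
        if self.resistance.tissue != self.demand.tissue:
            raise UnknownTokenError(
                f"limit state mixes tissues: {self.resistance.tissue.value} vs "
                f"{self.demand.tissue.value}"
            )
        if self.resistance.mode != self.demand.mode:
            raise UnknownTokenError(
                f"limit state mixes modes: {self.resistance.mode.value} vs "
                f"{self.demand.mode.value}"
            )

    @property
    def tissue(self) -> TissueKind:
        return self.resistance.tissue

    @property
    def mode(self) -> LoadMode:
        return self.resistance.mode


@dataclass(frozen=True)
class ComponentReliability:
    """Failure probability of one section/tissue, both modes combined."""

    section: str
    tissue: TissueKind
    pf_tension: float
    pf_compression: float
    pf: float
    beta: float
    method: Method
    policy: str = "governing"
    mc_n: int | None = None
    mc_stderr: float | None = None
    mc_pf_upper95: float | None = None  # rule-of-three bound when no failures observed
    seed: int | None = None


def _warn_if_truncation_matters(mean: float, std: float, what: str) -> None:
    if std > 0 and mean / std < 3:
        warnings.warn(
            f"{what}: mean/std = {mean / std:.2f} < 3; zero-truncation is "
            f"ignored by the closed form and may bias the result",
            stacklevel=3,
        )


def beta_closed_form(
    mu_R: float, sigma_R: float, mu_Q: float, sigma_Q: float
) -> float:
    """Reliability index for independent normal resistance and demand.

    beta = (mu_R - mu_Q) / sqrt(sigma_R^2 + sigma_Q^2); the corresponding
    failure probability is Phi(-beta). Homogeneous of degree zero: scaling
    all four arguments by the same positive factor leaves beta unchanged.
    """
    var = sigma_R**2 + sigma_Q**2
    if var == 0.0:
        raise DegenerateDistributionError(
            "both standard deviations are zero; use deterministic_failure()"
        )
    _warn_if_truncation_matters(mu_R, sigma_R, "resistance")
    if mu_Q > 0:
        _warn_if_truncation_matters(mu_Q, sigma_Q, "demand")
    return (mu_R - mu_Q) / math.sqrt(var)


def deterministic_failure(mu_R: float, mu_Q: float) -> float:
    """Failure indicator when both distributions are degenerate (std 0):
    pf is 1 if mu_R <= mu_Q else 0."""
    return 1.0 if mu_R <= mu_Q else 0.0


def _truncated_normal_transform(u: np.ndarray, mean: float, std: float) -> np.ndarray:
    """Inverse-CDF transform of uniforms to Normal(mean, std) truncated
    below at 0."""
    if std == 0.0:
        return np.full_like(u, mean)
    lo = ndtr((0.0 - mean) / std)
    return mean + std * ndtri(lo + (1.0 - lo) * u)


def pf_monte_carlo(
    ls: LimitState, n: int, seed: int
) -> tuple[float, float]:
    """Crude Monte Carlo failure probability of one limit state.

    Draws ``n`` independent pairs (R, Q) — R from the truncated-normal
    resistance model, Q normal truncated at zero — and returns the failure
    fraction P(g = R - Q < 0) with its binomial standard error
    sqrt(p(1-p)/n). Deterministic given ``seed``; draws stream in batches so
    memory stays flat at any n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    fails = 0
    remaining = n
    while remaining > 0:
        m = min(remaining, _MC_BATCH)
        # one uniform pair per (R, Q) draw: the estimate is independent of
        # how n is split into batches
        u = rng.random((m, 2))
        r = _truncated_normal_transform(u[:, 0], ls.resistance.mean, ls.resistance.std)
        q = _truncated_normal_transform(u[:, 1], ls.demand.mean, ls.demand.std)
        fails += int(np.count_nonzero(r < q))
        remaining -= m
    p = fails / n
    return p, math.sqrt(p * (1.0 - p) / n)


_POLICIES = ("governing", "series")


def combine_modes(pf_tension: float, pf_compression: float, policy: str = "governing") -> float:
    """Combine the two loading-mode failure probabilities of one component.

    ``governing`` (default) keeps the larger of the two, the convention when
    a principal-stress check reports the governing state; ``series`` treats
    the modes as independent series events, 1 - (1-pf_t)(1-pf_c).
    """
    for p in (pf_tension, pf_compression):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0,1]: {p}")
    if policy == "governing":
        return max(pf_tension, pf_compression)
    if policy == "series":
        return 1.0 - (1.0 - pf_tension) * (1.0 - pf_compression)
    raise UnknownTokenError(f"unknown mode-combination policy {policy!r}; expected {_POLICIES}")


def _beta_from_pf(pf: float) -> float:
    if pf <= 0.0:
        return math.inf
    if pf >= 1.0:
        return -math.inf
    return float(-ndtri(pf))


def _truncated_cdf(x: float, mean: float, std: float) -> float:
    """P(X <= x) for Normal(mean, std) truncated below at 0."""
    lo = ndtr((0.0 - mean) / std)
    if x <= 0.0:
        return 0.0
    return float((ndtr((x - mean) / std) - lo) / (1.0 - lo))


def _mode_pf_closed_form(ls: LimitState) -> float:
    r, q = ls.resistance, ls.demand
    if r.std == 0.0 and q.std == 0.0:
        return deterministic_failure(r.mean, q.mean)
    # a degenerate side admits an exact answer under the truncated sampling
    # model; in particular zero demand can never exceed a truncated resistance
    if q.std == 0.0:
        return _truncated_cdf(q.mean, r.mean, r.std)
    if r.std == 0.0:
        return 1.0 - _truncated_cdf(r.mean, q.mean, q.std)
    return float(ndtr(-beta_closed_form(r.mean, r.std, q.mean, q.std)))


def component_reliability(
    section: str,
    tissue: TissueKind,
    resistances: Mapping[tuple[TissueKind, LoadMode], YieldStrengthDistribution],
    demands: Mapping[tuple[str, TissueKind, LoadMode], DemandDistribution],
    method: Method | str = Method.CLOSED_FORM,
    n: int = 1_000_000,
    seed: int = 0,
    policy: str = "governing",
) -> ComponentReliability:
    """Assemble the mode-combined failure probability of one section/tissue.

    Looks up the resistance and demand entries for both loading modes,
    evaluates each mode's pf by the chosen method, combines them under
    ``policy`` and attaches beta = -Phi^(-1)(pf) (infinite sentinel at
    pf = 0 or 1).
    """
    method = method if isinstance(method, Method) else Method(str(method).strip().lower())
    tissue = _coerce_tissue(tissue)
    mode_pfs: dict[LoadMode, float] = {}
    mc_se: dict[LoadMode, float] = {}
    for mode in LoadMode:
        try:
            r = resistances[(tissue, mode)]
        except KeyError:
            raise MissingEntryError(
                f"no resistance entry for ({tissue.value}, {mode.value})"
            ) from None
        try:
            q = demands[(section, tissue, mode)]
        except KeyError:
            raise MissingEntryError(
                f"no demand entry for ({section}, {tissue.value}, {mode.value})"
            ) from None
        ls = LimitState(r, q)
        if method is Method.CLOSED_FORM:
            mode_pfs[mode] = _mode_pf_closed_form(ls)
        else:
            # distinct stream per mode, derived from the master seed
            sub = np.random.SeedSequence(
                entropy=seed, spawn_key=(1 if mode is LoadMode.TENSION else 2,)
            )
            p, se = pf_monte_carlo(ls, n, int(np.random.default_rng(sub).integers(2**31)))
            mode_pfs[mode], mc_se[mode] = p, se
    pf = combine_modes(mode_pfs[LoadMode.TENSION], mode_pfs[LoadMode.COMPRESSION], policy)
    is_mc = method is Method.MONTE_CARLO
    return ComponentReliability(
        section=section,
        tissue=tissue,
        pf_tension=mode_pfs[LoadMode.TENSION],
        pf_compression=mode_pfs[LoadMode.COMPRESSION],
        pf=pf,
        beta=_beta_from_pf(pf),
        method=method,
        policy=policy,
        mc_n=n if is_mc else None,
        mc_stderr=max(mc_se.values()) if is_mc else None,
        mc_pf_upper95=(3.0 / n if (is_mc and pf == 0.0) else None),
        seed=seed if is_mc else None,
    )


def component_table(
    sections: Iterable[tuple[str, Sequence[TissueKind]]],
    resistances: Mapping[tuple[TissueKind, LoadMode], YieldStrengthDistribution],
    demands: Mapping[tuple[str, TissueKind, LoadMode], DemandDistribution],
    **kwargs,
) -> list[ComponentReliability]:
    """Component reliabilities for every (section, tissue) pair given."""
    return [
        component_reliability(sec, tissue, resistances, demands, **kwargs)
        for sec, tissues in sections
        for tissue in tissues
    ]


def index_resistances(
    entries: Iterable[YieldStrengthDistribution],
) -> dict[tuple[TissueKind, LoadMode], YieldStrengthDistribution]:
    """Key a resistance table by (tissue, mode)."""
    return {(e.tissue, e.mode): e for e in entries}


def index_demands(
    entries: Iterable[DemandDistribution],
) -> dict[tuple[str, TissueKind, LoadMode], DemandDistribution]:
    """Key a demand table by (section, tissue, mode)."""
    return {(e.section, e.tissue, e.mode): e for e in entries}
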