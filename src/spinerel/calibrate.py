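"""Calibration of the synthetic demand scale to a target reliability index.

The synthetic generator fixes only the *relative* stress profile along the
column; the absolute level carries the uncertainty of the unpublished stress
fields it emulates. A single multiplier s on every demand mean and std closes
the gap: the system reliability index beta_sys(s) is continuous and strictly
decreasing in s (each component margin shrinks as demand grows), so the s
matching any attainable target beta is found by bisection on a bracketing
interval.
"""

from __future__ import annotations

from typing import Mapping

from .component import Method, index_demands
from .demand import DemandDistribution, SpineTopology, scale_demands
from .errors import CalibrationBracketError
from .materials import LoadMode, TissueKind, YieldStrengthDistribution
from .system import evaluate_system

__all__ = ["calibrate_demand_scale", "system_beta_at_scale"]

_BRACKET_LO, _BRACKET_HI = 1e-3, 1e3
_BRACKET_LIMIT = 1e12
_MAX_BISECTIONS = 200


def system_beta_at_scale(
    s: float,
    topology: SpineTopology,
    resistances: Mapping[tuple[TissueKind, LoadMode], YieldStrengthDistribution],
    demands: list[DemandDistribution],
    policy: str = "governing",
    disc_combination: str = "parallel",
) -> float:
    """System reliability index with all demands scaled by ``s`` (closed-form
    component route; deterministic)."""
    result = evaluate_system(
        topology,
        resistances,
        index_demands(scale_demands(demands, s)),
        method=Method.CLOSED_FORM,
        policy=policy,
        disc_combination=disc_combination,
    )
    return result.beta_backbone


def calibrate_demand_scale(
    topology: SpineTopology,
    resistances: Mapping[tuple[TissueKind, LoadMode], YieldStrengthDistribution],
    demands: list[DemandDistribution],
    target_beta: float,
    tol: float = 1e-3,
    policy: str = "governing",
    disc_combination: str = "parallel",
) -> float:
    """Find the uniform demand multiplier s such that the system reliability
    index equals ``target_beta`` within ``tol``.

    Bisection on a bracket that expands geometrically (up to 1e12 either way)
    until beta crosses the target; raises
    :class:`~spinerel.errors.CalibrationBracketError` if the target stays out
    of reach. Deterministic.
    """

    def f(s: float) -> float:
        return system_beta_at_scale(
            s, topology, resistances, demands,
            policy=policy, disc_combination=disc_combination,
        ) - target_beta

    lo, hi = _BRACKET_LO, _BRACKET_HI
    f_lo, f_hi = f(lo), f(hi)
    # beta decreases in s: want f(lo) >= 0 >= f(hi)
    while f_lo < 0.0 and lo > 1.0 / _BRACKET_LIMIT:
        lo /= 10.0
        f_lo = f(lo)
    while f_hi > 0.0 and hi < _BRACKET_LIMIT:
        hi *= 10.0
        f_hi = f(hi)
    if f_lo < 0.0 or f_hi > 0.0:
        raise CalibrationBracketError(
            f"target beta {target_beta} not bracketed: beta({lo:g}) = "
            f"{f_lo + target_beta:g}, beta({hi:g}) = {f_hi + target_beta:g}"
        )

    for _ in range(_MAX_BISECTIONS):
        mid = (lo * hi) ** 0.5  # geometric midpoint: s spans decades
        f_mid = f(mid)
        if abs(f_mid) <= 0.25 * tol:
            return mid
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    raise CalibrationBracketError(
        f"bisection did not converge to beta {target_beta} within tolerance {tol}"
    )
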