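"""Synthetic stress-demand generation for the vertebral column.

This module stands in for a finite-element stress analysis: it turns a simple
body-weight load model into per-section, per-tissue applied-stress
distributions (the demand side Q of each strength limit state).

The load model: the spine carries a configurable fraction (50-60%) of body
weight, divided evenly between the 24 articulating vertebrae and accumulated
cranial-to-caudal by static equilibrium, plus a 4.5-5.5 kg head load entering
at the second cervical vertebra. Sectional force divided by a per-tissue
effective cross-sectional area gives a nominal axial stress in MPa. A small
seeded log-normal jitter emulates the scatter of a stress field across
random-property models. A scoliosis curvature profile amplifies demand means
near the inflection points of the lateral curve, where stress concentrates in
the deformed column; the normal profile leaves demands untouched.

Absolute demand levels produced here are nominal: the calibration step
(:mod:`spinerel.calibrate`) rescales them uniformly so the system reliability
index matches a reference value, after which only the relative profile shaped
by this module matters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptySystemError,
    InvalidDistributionError,
    MissingColumnError,
    MissingEntryError,
    UnknownTokenError,
)
from .materials import (
    DISC_TISSUES,
    VERTEBRA_TISSUES,
    LoadMode,
    TissueKind,
    _coerce_mode,
    _coerce_tissue,
    _data_path,
    _read_delimited,
)

__all__ = [
    "Section",
    "SpineTopology",
    "LoadCase",
    "Condition",
    "CurvatureProfile",
    "DemandDistribution",
    "AreaTable",
    "default_topology",
    "builtin_area_table",
    "read_area_table",
    "read_topology",
    "write_topology",
    "read_demand_table",
    "write_demand_table",
    "cumulative_axial_load",
    "nominal_stress",
    "apply_curvature",
    "generate_demand_table",
    "scale_demands",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class Section:
    """One backbone section: a vertebra plus the disc immediately below it
    (``disc`` is None for the last articulating vertebra)."""

    vertebra: str
    disc: str | None = None


@dataclass(frozen=True)
class SpineTopology:
    """Ordered (cranial -> caudal) articulating sections of the column.

    The fused sacral/coccygeal block acts as the fixed support and is not
    load-rated; set ``include_support`` to count it in the series length
    anyway (it then enters the chain as a zero-failure-probability member).
    """

    sections: tuple[Section, ...]
    include_support: bool = False
    support_label: str = "sacrum-coccyx"

    def __post_init__(self):
        labels = [s.vertebra for s in self.sections]
        labels += [s.disc for s in self.sections if s.disc is not None]
        if len(labels) != len(set(labels)):
            raise InvalidDistributionError("topology labels must be unique")
        if not self.sections:
            raise EmptySystemError("topology has no sections")

    @property
    def n(self) -> int:
        """Series length used by the whole-column chain."""
        return len(self.sections) + (1 if self.include_support else 0)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.vertebra for s in self.sections)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MissingEntryError(f"section {label!r} not in topology") from None


def default_topology(include_support: bool = False) -> SpineTopology:
    """C1-C7, T1-T12, L1-L5 with a disc below every vertebra except L5."""
    names = (
        [f"C{i}" for i in range(1, 8)]
        + [f"T{i}" for i in range(1, 13)]
        + [f"L{i}" for i in range(1, 6)]
    )
    sections = []
    for i, v in enumerate(names):
        disc = f"{v}-{names[i + 1]}" if i < len(names) - 1 else None
        sections.append(Section(v, disc))
    return SpineTopology(tuple(sections), include_support=include_support)


@dataclass(frozen=True)
class LoadCase:
    """Standing axial load case: body mass, spine-borne trunk fraction and
    head mass (the head load is applied at C2)."""

    body_mass: float  # kg
    trunk_fraction: float = 0.55  # dimensionless, in [0.50, 0.60]
    head_mass: float = 5.0  # kg, in [4.5, 5.5]
    gravity: float = GRAVITY

    def __post_init__(self):
        if self.body_mass < 0:
            raise InvalidDistributionError(f"body_mass must be >= 0 kg, got {self.body_mass}")
        if not 0.50 <= self.trunk_fraction <= 0.60:
            raise InvalidDistributionError(
                f"trunk_fraction must lie in [0.50, 0.60], got {self.trunk_fraction}"
            )
        if not 4.5 <= self.head_mass <= 5.5:
            raise InvalidDistributionError(
                f"head_mass must lie in [4.5, 5.5] kg, got {self.head_mass}"
            )


class Condition(str, enum.Enum):
    NORMAL = "normal"
    SCOLIOSIS = "scoliosis"


@dataclass(frozen=True)
class CurvatureProfile:
    """Curvature condition of the column.

    For scoliosis, demand means are amplified by a factor
    ``1 + (amplification - 1) * w(d)`` where ``d`` is the section distance to
    the nearest inflection point of the lateral curve and ``w`` is a
    triangular kernel with ``w(0) = 1`` decaying to zero over
    ``decay_width`` sections. The normal profile is the identity.
    """

    condition: Condition = Condition.NORMAL
    inflection_sections: tuple[str, ...] = ()
    amplification: float = 1.0
    decay_width: int = 3

    def __post_init__(self):
        cond = (
            self.condition
            if isinstance(self.condition, Condition)
            else Condition(str(self.condition).strip().lower())
        )
        object.__setattr__(self, "condition", cond)
        object.__setattr__(self, "inflection_sections", tuple(self.inflection_sections))
        if self.decay_width <= 0:
            raise InvalidDistributionError("decay_width must be > 0 sections")
        if cond is Condition.NORMAL:
            if self.amplification != 1.0 or self.inflection_sections:
                raise InvalidDistributionError(
                    "normal profile requires amplification 1 and no inflection sections"
                )
        else:
            if not self.amplification > 1.0:
                raise InvalidDistributionError(
                    "scoliosis profile requires amplification > 1"
                )
            if not self.inflection_sections:
                raise InvalidDistributionError(
                    "scoliosis profile requires at least one inflection section"
                )

    @classmethod
    def normal(cls) -> "CurvatureProfile":
        return cls()

    @classmethod
    def scoliosis(
        cls,
        inflection_sections: Sequence[str] = ("T7", "T12"),
        amplification: float = 2.0,
        decay_width: int = 3,
    ) -> "CurvatureProfile":
        return cls(Condition.SCOLIOSIS, tuple(inflection_sections), amplification, decay_width)


@dataclass(frozen=True)
class DemandDistribution:
    """Normal applied-stress model (MPa) for one section, tissue and mode."""

    section: str
    tissue: TissueKind
    mode: LoadMode
    mean: float
    std: float

    def __post_init__(self):
        object.__setattr__(self, "tissue", _coerce_tissue(self.tissue))
        object.__setattr__(self, "mode", _coerce_mode(self.mode))
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "std", float(self.std))
        if self.mean < 0 or self.std < 0:
            raise InvalidDistributionError(
                f"{self.section}/{self.tissue.value}/{self.mode.value}: "
                f"demand mean and std must be >= 0 MPa"
            )


# ---------------------------------------------------------------------------
# Effective areas

class AreaTable:
    """Per-section, per-tissue effective cross-sectional areas (mm^2)."""

    def __init__(self, areas: Mapping[tuple[str, TissueKind], float]):
        self._areas = {
            (sec, _coerce_tissue(t)): float(a) for (sec, t), a in areas.items()
        }
        for key, a in self._areas.items():
            if not a > 0:
                raise InvalidDistributionError(f"area for {key} must be > 0 mm^2")

    def area(self, section: str, tissue: TissueKind) -> float:
        try:
            return self._areas[(section, _coerce_tissue(tissue))]
        except KeyError:
            raise MissingEntryError(
                f"no effective area for section {section!r}, tissue {tissue!r}"
            ) from None

    def __contains__(self, key) -> bool:
        sec, t = key
        return (sec, _coerce_tissue(t)) in self._areas


_AREA_COLUMNS = {
    TissueKind.CORTICAL: "cortical_area_mm2",
    TissueKind.CANCELLOUS: "cancellous_area_mm2",
    TissueKind.ANNULUS: "annulus_area_mm2",
    TissueKind.NUCLEUS: "nucleus_area_mm2",
}


def read_area_table(path) -> AreaTable:
    """Read a delimited area table (header ``section,...,<tissue>_area_mm2``);
    blank disc-area cells mark sections without a disc."""
    df = _read_delimited(path, ("section",) + tuple(_AREA_COLUMNS.values()))
    areas: dict[tuple[str, TissueKind], float] = {}
    for _, row in df.iterrows():
        for tissue, col in _AREA_COLUMNS.items():
            val = row[col]
            if pd.notna(val):
                areas[(str(row["section"]), tissue)] = float(val)
    return AreaTable(areas)


def builtin_area_table() -> AreaTable:
    """The packaged synthetic area table (see data/areas_synthetic.csv)."""
    return read_area_table(_data_path("areas_synthetic.csv"))


# ---------------------------------------------------------------------------
# Topology and demand-table I/O

def read_topology(path) -> SpineTopology:
    """Read a topology file (header ``order,vertebra,disc``; blank disc cell
    for the last articulating section)."""
    df = _read_delimited(path, ("order", "vertebra", "disc"))
    df = df.sort_values("order")
    sections = tuple(
        Section(str(r["vertebra"]), None if pd.isna(r["disc"]) else str(r["disc"]))
        for _, r in df.iterrows()
    )
    return SpineTopology(sections)


def write_topology(topology: SpineTopology, path) -> None:
    pd.DataFrame(
        {
            "order": range(1, len(topology.sections) + 1),
            "vertebra": [s.vertebra for s in topology.sections],
            "disc": [s.disc if s.disc is not None else "" for s in topology.sections],
        }
    ).to_csv(path, index=False)


def read_demand_table(path) -> list[DemandDistribution]:
    """Read demands from a delimited file, header
    ``section,tissue,mode,mean_mpa,std_mpa`` (same dialect as the resistance
    table). Replaces the synthetic generator when real stress data exist."""
    df = _read_delimited(path, ("section", "tissue", "mode", "mean_mpa", "std_mpa"))
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                DemandDistribution(
                    section=str(row["section"]), tissue=row["tissue"],
                    mode=row["mode"], mean=row["mean_mpa"], std=row["std_mpa"],
                )
            )
        except (InvalidDistributionError, UnknownTokenError) as exc:
            raise type(exc)(f"{path}, row {idx + 1}: {exc}") from None
    return out


def write_demand_table(demands: Iterable[DemandDistribution], path) -> None:
    pd.DataFrame(
        {
            "section": [d.section for d in demands],
            "tissue": [d.tissue.value for d in demands],
            "mode": [d.mode.value for d in demands],
            "mean_mpa": [d.mean for d in demands],
            "std_mpa": [d.std for d in demands],
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Load model

def cumulative_axial_load(
    topology: SpineTopology, load: LoadCase, cumulative: bool = True
) -> dict[str, float]:
    """Axial force (N) carried at each articulating section, cranial -> caudal.

    The spine-borne trunk weight ``trunk_fraction * body_mass * g`` is divided
    evenly into per-vertebra shares that accumulate down the column (section k
    of N carries k shares), so the bottom articulating section carries the
    head load plus the full trunk share. The head load enters at the second
    section (C2) and is carried by every section below. With
    ``cumulative=False`` each section below the first carries the head load
    plus a single share (no accumulation).
    """
    if not topology.sections:
        raise EmptySystemError("topology has no sections")
    n = len(topology.sections)
    trunk = load.trunk_fraction * load.body_mass * load.gravity
    head = load.head_mass * load.gravity
    forces = {}
    for k, sec in enumerate(topology.sections, start=1):
        share = trunk * (k / n) if cumulative else trunk / n
        forces[sec.vertebra] = (head if k >= 2 else 0.0) + share
    return forces


def nominal_stress(
    force: float, section: str, tissue: TissueKind, area_table: AreaTable
) -> float:
    """Nominal axial stress (MPa) = force (N) / effective area (mm^2).

    The same sectional force loads both parallel tissues of a component,
    each through its own effective area.
    """
    return force / area_table.area(section, tissue)


def _amplification_factor(profile: CurvatureProfile, distance: int) -> float:
    # triangular kernel: w(0)=1, linear decay to 0 at decay_width
    w = max(0.0, 1.0 - distance / profile.decay_width)
    return 1.0 + (profile.amplification - 1.0) * w


def apply_curvature(
    demands: Sequence[DemandDistribution],
    profile: CurvatureProfile,
    topology: SpineTopology,
) -> list[DemandDistribution]:
    """Amplify demand means (and stds, preserving the coefficient of
    variation) near the curvature inflection points; identity for the
    normal profile."""
    if profile.condition is Condition.NORMAL:
        return list(demands)
    idx = {lab: i for i, lab in enumerate(topology.labels)}
    for lab in profile.inflection_sections:
        if lab not in idx:
            raise MissingEntryError(f"inflection section {lab!r} not in topology")
    infl = [idx[lab] for lab in profile.inflection_sections]
    out = []
    for d in demands:
        dist = min(abs(idx[d.section] - i) for i in infl)
        f = _amplification_factor(profile, dist)
        out.append(replace(d, mean=d.mean * f, std=d.std * f))
    return out


def scale_demands(
    demands: Sequence[DemandDistribution], s: float
) -> list[DemandDistribution]:
    """Uniformly rescale all demand means and stds by ``s`` (the calibration
    knob; β of every component is strictly decreasing in ``s``)."""
    if not s > 0:
        raise InvalidDistributionError(f"demand scale must be > 0, got {s}")
    return [replace(d, mean=d.mean * s, std=d.std * s) for d in demands]


def generate_demand_table(
    topology: SpineTopology,
    load: LoadCase,
    profile: CurvatureProfile,
    cov: float = 0.10,
    seed: int = 0,
    areas: AreaTable | None = None,
    tension_fraction: float = 0.2,
    jitter_sigma: float = 0.05,
    cumulative: bool = True,
    scale: float = 1.0,
) -> list[DemandDistribution]:
    """Generate one demand distribution per (section, tissue, mode).

    Compression demand means come from the sectional force through the tissue
    areas; tension demand is a configurable baseline fraction of the local
    compression demand (a surrogate for bending/eccentricity, without which
    the two tension limit states would never be exercised). A per-component
    multiplicative log-normal jitter (sigma ``jitter_sigma``) seeded by
    ``seed`` emulates stress-field scatter; it is drawn in a fixed order
    independent of the curvature profile, so normal and scoliosis tables at
    the same seed differ only by the amplification. Finally
    ``std = cov * mean``.

    Deterministic: identical arguments give a bit-identical table.
    """
    if cov < 0:
        raise InvalidDistributionError(f"cov must be >= 0, got {cov}")
    if not 0 <= tension_fraction:
        raise InvalidDistributionError("tension_fraction must be >= 0")
    areas = areas if areas is not None else builtin_area_table()
    forces = cumulative_axial_load(topology, load, cumulative=cumulative)
    rng = np.random.default_rng(seed)

    base: list[DemandDistribution] = []
    for sec in topology.sections:
        force = forces[sec.vertebra]
        tissues = list(VERTEBRA_TISSUES) + (list(DISC_TISSUES) if sec.disc else [])
        for tissue in tissues:
            compression = nominal_stress(force, sec.vertebra, tissue, areas)
            for mode in (LoadMode.TENSION, LoadMode.COMPRESSION):
                mean = compression if mode is LoadMode.COMPRESSION else tension_fraction * compression
                jitter = math.exp(jitter_sigma * rng.standard_normal()) if jitter_sigma > 0 else 1.0
                base.append(
                    DemandDistribution(
                        section=sec.vertebra, tissue=tissue, mode=mode,
                        mean=mean * jitter * scale, std=0.0,
                    )
                )

    shaped = apply_curvature(base, profile, topology)
    return [replace(d, std=cov * d.mean) for d in shaped]
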