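"""Material strength and stiffness parameters of spinal tissues.

The load-bearing tissues of the vertebral column are modelled as four kinds:
the dense cortical shell and porous cancellous core of each vertebra, and the
annulus fibrosus ring and nucleus pulposus core of each intervertebral disc.
Yield stress in each tissue, separately under tension and compression, is
treated as a normal random variable truncated below at zero (a yield stress
cannot be negative; the truncation only matters for the low-margin cancellous
and nucleus entries where mean/std < 3).

Two further tables — orthotropic elastic constants of bone and Prony-series
viscoelastic constants of the disc tissues — are packaged and validated as
metadata for a future stress-analysis stage; no computation in this package
consumes them.

All stresses are in MPa throughout the package; no unit conversion happens
anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .errors import InvalidDistributionError, MissingColumnError, UnknownTokenError

__all__ = [
    "TissueKind",
    "LoadMode",
    "YieldStrengthDistribution",
    "ElasticConstants",
    "PronySeriesConstants",
    "builtin_resistance_table",
    "builtin_elastic_constants",
    "builtin_prony_series",
    "read_resistance_table",
    "write_resistance_table",
    "sample_resistance",
    "truncated_normal_mean",
]


class TissueKind(str, enum.Enum):
    """The four load-bearing tissue kinds of a spinal section."""

    CORTICAL = "cortical"
    CANCELLOUS = "cancellous"
    ANNULUS = "annulus"
    NUCLEUS = "nucleus"

    @property
    def is_vertebral(self) -> bool:
        return self in (TissueKind.CORTICAL, TissueKind.CANCELLOUS)

    @property
    def is_disc(self) -> bool:
        return not self.is_vertebral


#: Tissue pairs forming the parallel load paths of each component type.
VERTEBRA_TISSUES = (TissueKind.CORTICAL, TissueKind.CANCELLOUS)
DISC_TISSUES = (TissueKind.ANNULUS, TissueKind.NUCLEUS)


class LoadMode(str, enum.Enum):
    """Principal-stress loading mode checked against the yield limit."""

    TENSION = "tension"
    COMPRESSION = "compression"


def _coerce_tissue(token) -> TissueKind:
    if isinstance(token, TissueKind):
        return token
    try:
        return TissueKind(str(token).strip().lower())
    except ValueError:
        raise UnknownTokenError(
            f"unknown tissue {token!r}; expected one of "
            f"{[t.value for t in TissueKind]}"
        ) from None


def _coerce_mode(token) -> LoadMode:
    if isinstance(token, LoadMode):
        return token
    try:
        return LoadMode(str(token).strip().lower())
    except ValueError:
        raise UnknownTokenError(
            f"unknown load mode {token!r}; expected one of "
            f"{[m.value for m in LoadMode]}"
        ) from None


@dataclass(frozen=True)
class YieldStrengthDistribution:
    """Normal yield-stress model (MPa) for one tissue under one load mode.

    ``mean``/``std`` are the moments of the *untruncated* normal; sampling
    truncates below at zero, so drawn strengths are never negative.
    """

    tissue: TissueKind
    mode: LoadMode
    mean: float
    std: float
    family: str = field(default="normal-truncated-at-zero", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "tissue", _coerce_tissue(self.tissue))
        object.__setattr__(self, "mode", _coerce_mode(self.mode))
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "std", float(self.std))
        if not self.mean > 0:
            raise InvalidDistributionError(
                f"{self.tissue.value}/{self.mode.value}: mean must be > 0 MPa, "
                f"got {self.mean}"
            )
        if self.std < 0:
            raise InvalidDistributionError(
                f"{self.tissue.value}/{self.mode.value}: std must be >= 0 MPa, "
                f"got {self.std}"
            )
        if self.std >= self.mean:
            raise InvalidDistributionError(
                f"{self.tissue.value}/{self.mode.value}: std {self.std} must be "
                f"< mean {self.mean} (all packaged rows satisfy this)"
            )


@dataclass(frozen=True)
class ElasticConstants:
    """Orthotropic elastic constants of a bone tissue. Metadata only."""

    tissue: TissueKind
    E_xx: float
    E_yy: float
    E_zz: float
    G_xy: float
    G_yz: float
    G_xz: float
    v_xy: float
    v_yz: float
    v_xz: float

    def __post_init__(self):
        object.__setattr__(self, "tissue", _coerce_tissue(self.tissue))
        for name in ("E_xx", "E_yy", "E_zz", "G_xy", "G_yz", "G_xz"):
            if not getattr(self, name) > 0:
                raise InvalidDistributionError(f"{name} must be > 0 MPa")
        for name in ("v_xy", "v_yz", "v_xz"):
            v = getattr(self, name)
            if not 0 < v < 0.5:
                raise InvalidDistributionError(
                    f"{name} must lie in (0, 0.5), got {v}"
                )


@dataclass(frozen=True)
class PronySeriesConstants:
    """Prony-series viscoelastic constants of a disc tissue. Metadata only.

    ``terms`` is a sequence of (g_i, k_i, tau_i): shear weight, bulk weight,
    relaxation time in seconds. Stored and validated, never solved.
    """

    tissue: TissueKind
    E: float
    v: float
    terms: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "tissue", _coerce_tissue(self.tissue))
        if self.tissue not in DISC_TISSUES:
            raise UnknownTokenError(
                f"Prony constants apply to disc tissues only, got {self.tissue.value}"
            )
        object.__setattr__(
            self, "terms", tuple((float(g), float(k), float(t)) for g, k, t in self.terms)
        )
        for g, k, tau in self.terms:
            if not (0 <= g <= 1 and 0 <= k <= 1):
                raise InvalidDistributionError(
                    f"Prony weights must lie in [0, 1], got g={g}, k={k}"
                )
            if not tau > 0:
                raise InvalidDistributionError(f"relaxation time must be > 0 s, got {tau}")


# ---------------------------------------------------------------------------
# Packaged tables

def _data_path(name: str) -> Path:
    return Path(resources.files("spinerel.data").joinpath(name))  # type: ignore[arg-type]


def _sniff_delimiter(path) -> str:
    """Comma or tab, decided from the first non-comment line."""
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_delimited(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with '#' comments; check columns.

    Uses round-trip float parsing so written tables read back bit-exactly.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#",
                     skip_blank_lines=True, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_resistance_table(path) -> list[YieldStrengthDistribution]:
    """Read yield-strength rows from a delimited file.

    Expected header: ``tissue,mode,mean_mpa,std_mpa`` (comma or tab separated,
    ``#`` comment lines allowed). Each row is validated; the offending row is
    named in the error on failure.
    """
    df = _read_delimited(path, ("tissue", "mode", "mean_mpa", "std_mpa"))
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                YieldStrengthDistribution(
                    tissue=row["tissue"], mode=row["mode"],
                    mean=row["mean_mpa"], std=row["std_mpa"],
                )
            )
        except (InvalidDistributionError, UnknownTokenError) as exc:
            raise type(exc)(f"{path}, row {idx + 1}: {exc}") from None
    return out


def write_resistance_table(entries: Iterable[YieldStrengthDistribution], path) -> None:
    """Write yield-strength rows in the same delimited format read back by
    :func:`read_resistance_table` (round-trip identity on valid tables)."""
    df = pd.DataFrame(
        {
            "tissue": [e.tissue.value for e in entries],
            "mode": [e.mode.value for e in entries],
            "mean_mpa": [e.mean for e in entries],
            "std_mpa": [e.std for e in entries],
        }
    )
    df.to_csv(path, index=False)


def builtin_resistance_table() -> list[YieldStrengthDistribution]:
    """The packaged yield-stress table: 8 entries, 4 tissues x 2 modes (MPa)."""
    entries = read_resistance_table(_data_path("yield_strength.csv"))
    assert len(entries) == 8, "packaged table must have 4 tissues x 2 modes"
    return entries


def builtin_elastic_constants() -> list[ElasticConstants]:
    """Packaged orthotropic elastic constants of vertebral bone (metadata)."""
    df = _read_delimited(
        _data_path("elastic_constants.csv"),
        ("tissue", "E_xx_mpa", "E_yy_mpa", "E_zz_mpa",
         "G_xy_mpa", "G_yz_mpa", "G_xz_mpa", "v_xy", "v_yz", "v_xz"),
    )
    return [
        ElasticConstants(
            tissue=r["tissue"],
            E_xx=r["E_xx_mpa"], E_yy=r["E_yy_mpa"], E_zz=r["E_zz_mpa"],
            G_xy=r["G_xy_mpa"], G_yz=r["G_yz_mpa"], G_xz=r["G_xz_mpa"],
            v_xy=r["v_xy"], v_yz=r["v_yz"], v_xz=r["v_xz"],
        )
        for _, r in df.iterrows()
    ]


def builtin_prony_series() -> list[PronySeriesConstants]:
    """Packaged Prony-series constants of the disc tissues (metadata)."""
    df = _read_delimited(
        _data_path("prony_series.csv"),
        ("tissue", "E_mpa", "poisson", "term", "g", "k", "tau_s"),
    )
    out = []
    for tissue, grp in df.groupby("tissue", sort=False):
        grp = grp.sort_values("term")
        out.append(
            PronySeriesConstants(
                tissue=tissue,
                E=float(grp["E_mpa"].iloc[0]),
                v=float(grp["poisson"].iloc[0]),
                terms=tuple(zip(grp["g"], grp["k"], grp["tau_s"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sampling

def sample_resistance(dist: YieldStrengthDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` yield-stress samples (MPa), normal truncated below at zero.

    Sampling uses the inverse-CDF transform of a seeded uniform stream, so the
    same seed yields bit-identical samples. With ``std == 0`` every sample
    equals the mean.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if dist.std == 0.0:
        return np.full(n, dist.mean)
    rng = np.random.default_rng(seed)
    # u uniform on (Phi(alpha), 1) with alpha the standardised truncation point
    alpha = (0.0 - dist.mean) / dist.std
    lo = ndtr(alpha)
    u = lo + (1.0 - lo) * rng.random(n)
    return dist.mean + dist.std * ndtri(u)


def truncated_normal_mean(mean: float, std: float) -> float:
    """Analytic mean of a normal(mean, std) truncated below at zero.

    Provided as the closed-form check for the sampler; delegates to
    scipy's truncated-normal moments.
    """
    if std == 0.0:
        return mean
    a = (0.0 - mean) / std
    return float(truncnorm.mean(a, np.inf, loc=mean, scale=std))
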