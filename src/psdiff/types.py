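"""Domain types shared by every stage of the portal-systemic difference pipeline.

Internal unit conventions (fixed; all conversion happens at the IO boundary):
time in hours, plasma concentration in nmol/L, dose in mg/kg at the interface
and nmol/kg inside the estimators, portal blood flow in mL/min/kg at the
interface and L/h/kg inside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genotype",
    "Route",
    "Site",
    "ConcProfile",
    "CompoundSpec",
    "PhysiologyConfig",
    "SchemaError",
    "DataError",
    "EstimationError",
    "PAPER_SCHEDULE",
]

#: Sparse blood-sampling schedule (hours) used throughout: 5 min to 8 h.
PAPER_SCHEDULE: tuple[float, ...] = (0.083, 0.17, 0.5, 1.0, 2.0, 4.0, 8.0)


class SchemaError(ValueError):
    """An input table is missing required columns."""


class DataError(ValueError):
    """An input table has structurally invalid contents."""


class EstimationError(RuntimeError):
    """A fit or regression could not produce a usable estimate."""


class Genotype(str, enum.Enum):
    WT = "WT"
    BcrpKO = "BcrpKO"
    Mdr1a1bKO = "Mdr1a1bKO"


class Route(str, enum.Enum):
    iv = "iv"
    oral = "oral"


class Site(str, enum.Enum):
    systemic = "systemic"
    portal = "portal"


def _coerce_enum(cls, value, what: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(
            f"unknown {what} {value!r}; expected one of: {allowed}"
        ) from None


@dataclass
class ConcProfile:
    """One concentration-time series for a compound/genotype/route/site arm.

    ``times`` must be strictly increasing (hours); ``concs`` are non-negative
    plasma concentrations in nmol/L. A portal-site profile after intravenous
    dosing is permitted (portal and systemic blood are equivalent once the
    dose is in the central circulation) but flagged as unusual.
    """

    compound: str
    genotype: Genotype
    route: Route
    site: Site
    times: np.ndarray
    concs: np.ndarray
    dose_mg_per_kg: float
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genotype = _coerce_enum(Genotype, self.genotype, "genotype")
        self.route = _coerce_enum(Route, self.route, "route")
        self.site = _coerce_enum(Site, self.site, "site")
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concs.shape:
            raise DataError("times and concs must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise DataError("a profile needs at least 2 time points")
        if self.times.size < 3:
            self.flags.add("short_profile")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise DataError("times must be non-negative")
        if np.any(self.concs < 0):
            raise DataError("concentrations must be non-negative")
        if not self.dose_mg_per_kg > 0:
            raise DataError("dose must be positive")
        if self.site is Site.portal and self.route is Route.iv:
            self.flags.add("iv_portal")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def key(self) -> tuple[str, str, str, str]:
        return (self.compound, self.genotype.value, self.route.value, self.site.value)


@dataclass(frozen=True)
class CompoundSpec:
    """Per-compound constants consumed (not estimated) by the pipeline.

    ``mw_dosed`` is the molar mass of the chemical form actually dosed
    (salt where a salt was weighed out); it converts mg/kg doses to nmol/kg
    so that dose and AUC share a molar scale. ``rb`` is the whole-blood to
    plasma concentration ratio, assumed genotype-independent.
    """

    name: str
    mw_dosed: float
    rb: float
    dose_iv: float
    dose_oral: float

    def __post_init__(self) -> None:
        for attr in ("mw_dosed", "rb", "dose_iv", "dose_oral"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive")


@dataclass(frozen=True)
class PhysiologyConfig:
    """Physiological constants: portal venous blood flow and the default
    sampling schedule.

    The default Qpv of 106.6 mL/min/kg is the literature mouse portal blood
    flow per body weight.
    """

    qpv: float = 106.6
    schedule: tuple[float, ...] = PAPER_SCHEDULE

    def __post_init__(self) -> None:
        if not self.qpv > 0:
            raise ValueError("qpv must be positive")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size and np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")
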