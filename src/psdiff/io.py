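"""Readers and writers for concentration-time study tables and configs.

The study CSV dialect is comma-separated, dot-decimal, UTF-8, with a header
row: compound, genotype, route, site, time_h, conc_nM, dose_mg_per_kg.
Replicate rows at one time point (e.g. several animals per arm) are
arithmetically averaged before analysis, matching how sparse destructive-
sampling studies report mean profiles.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .types import (
    CompoundSpec,
    ConcProfile,
    DataError,
    Genotype,
    PhysiologyConfig,
    Route,
    SchemaError,
    Site,
)

__all__ = ["read_study", "read_study_frame", "write_study", "read_config"]

STUDY_COLUMNS = (
    "compound",
    "genotype",
    "route",
    "site",
    "time_h",
    "conc_nM",
    "dose_mg_per_kg",
)

_GROUP_KEYS = ["compound", "genotype", "route", "site"]


def read_study_frame(df: pd.DataFrame) -> list[ConcProfile]:
    """Build one ConcProfile per (compound, genotype, route, site) group
    from a long-format table, averaging replicates at each time point."""
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"study table is missing columns: {', '.join(missing)}")

    for col, enum_cls in (("genotype", Genotype), ("route", Route), ("site", Site)):
        allowed = {m.value for m in enum_cls}
        bad = set(df[col].astype(str)) - allowed
        if bad:
            raise ValueError(
                f"unknown {col} value(s) {sorted(bad)!r}; "
                f"expected one of: {sorted(allowed)}"
            )

    profiles: list[ConcProfile] = []
    for key, grp in df.groupby(_GROUP_KEYS, sort=True):
        doses = grp["dose_mg_per_kg"].unique()
        if len(doses) != 1:
            raise DataError(f"group {key} mixes doses {sorted(doses)}")
        mean = (
            grp.groupby("time_h", sort=True)["conc_nM"].mean().reset_index()
        )
        profiles.append(
            ConcProfile(
                compound=key[0],
                genotype=key[1],
                route=key[2],
                site=key[3],
                times=mean["time_h"].to_numpy(),
                concs=mean["conc_nM"].to_numpy(),
                dose_mg_per_kg=float(doses[0]),
            )
        )
    return profiles


def read_study(
    path: str | os.PathLike, config: PhysiologyConfig | None = None
) -> list[ConcProfile]:
    """Read a study CSV into ConcProfile objects (``config`` is accepted for
    interface symmetry; the schedule is taken from the data itself)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return read_study_frame(df)


def write_study(profiles: Iterable[ConcProfile], path: str | os.PathLike) -> None:
    """Write profiles back to the study CSV dialect, full float precision."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concs):
            rows.append(
                {
                    "compound": p.compound,
                    "genotype": p.genotype.value,
                    "route": p.route.value,
                    "site": p.site.value,
                    "time_h": repr(float(t)),
                    "conc_nM": repr(float(c)),
                    "dose_mg_per_kg": repr(float(p.dose_mg_per_kg)),
                }
            )
    pd.DataFrame(rows, columns=list(STUDY_COLUMNS)).to_csv(path, index=False)


def read_config(
    path: str | os.PathLike,
) -> tuple[dict[str, CompoundSpec], PhysiologyConfig]:
    """Read a YAML config holding compound constants and physiology.

    Layout::

        physiology:
          qpv_ml_min_kg: 106.6
        compounds:
          ciprofloxacin: {mw_dosed: 331.34, rb: 1.20, dose_iv: 1, dose_oral: 1}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "compounds" not in raw:
        raise SchemaError("config must contain a 'compounds' mapping")
    phys_raw = raw.get("physiology", {}) or {}
    physiology = PhysiologyConfig(qpv=float(phys_raw.get("qpv_ml_min_kg", 106.6)))
    compounds: dict[str, CompoundSpec] = {}
    for name, spec in raw["compounds"].items():
        try:
            compounds[name] = CompoundSpec(
                name=name,
                mw_dosed=float(spec["mw_dosed"]),
                rb=float(spec["rb"]),
                dose_iv=float(spec["dose_iv"]),
                dose_oral=float(spec["dose_oral"]),
            )
        except KeyError as exc:
            raise SchemaError(f"compound {name!r} is missing key {exc}") from None
    return compounds, physiology
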