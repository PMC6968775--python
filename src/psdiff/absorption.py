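"""Core portal-systemic difference estimators: FaFg, bioavailability, Fh.

The apparent fraction of the oral dose reaching the portal blood (the
product FaFg of fraction absorbed and intestinal availability) is obtained
by mass balance over the gut-to-portal-vein boundary: the excess of portal
over systemic plasma exposure, converted to blood with Rb and multiplied by
portal blood flow, equals the amount absorbed::

    FaFg = Qpv * Rb * (AUC_pv - AUC_sys) / Dose

with Qpv in L/h/kg, AUCs in nmol/L*h and Dose in nmol/kg. Bioavailability
F = (AUC_oral/AUC_iv) * (Dose_iv/Dose_oral) and hepatic availability
Fh = F / FaFg close the system, so F = FaFg * Fh by construction.

All fractions are kept on the 0-1 scale internally; percent only in reports.
Supra-unity FaFg (possible with noisy sparse AUCs and near-complete
absorption) is returned as computed and flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .units import qpv_to_L_per_h_per_kg

__all__ = ["AbsorptionSummary", "fafg", "bioavailability", "hepatic_availability"]


@dataclass
class AbsorptionSummary:
    """FaFg, BA, Fh and ka for one compound x genotype."""

    compound: str
    genotype: str
    fafg: float = float("nan")
    ba: float = float("nan")
    fh: float = float("nan")
    ka: float = float("nan")
    mat: float = float("nan")
    flags: set = field(default_factory=set)


def fafg(
    auc_pv: float,
    auc_sys: float,
    rb: float,
    qpv: float,
    dose_oral_nmol_per_kg: float,
    flags: set | None = None,
) -> float:
    """Apparent FaFg from the portal-systemic AUC difference.

    ``qpv`` is in mL/min/kg (converted internally), the AUCs in nmol/L*h and
    the dose in nmol/kg. A negative difference signals an assay or arm
    mismatch: the value is returned as computed with a "nonphysical" flag
    rather than raising, so batch runs surface the diagnosis. Values above 1
    get a "supra_unity" flag.
    """
    if not dose_oral_nmol_per_kg > 0:
        raise ValueError("dose must be positive")
    value = (
        qpv_to_L_per_h_per_kg(qpv) * rb * (auc_pv - auc_sys) / dose_oral_nmol_per_kg
    )
    if flags is not None:
        if value < 0:
            flags.add("nonphysical")
        elif value > 1:
            flags.add("supra_unity")
    return value


def bioavailability(
    auc_oral_sys: float, auc_iv_sys: float, dose_iv: float, dose_oral: float
) -> float:
    """Dose-normalised systemic exposure ratio F (fraction, not percent).

    Doses may be in any common unit (mg/kg as dosed is fine) since only
    their ratio enters.
    """
    if min(auc_oral_sys, auc_iv_sys, dose_iv, dose_oral) <= 0:
        raise ValueError("AUCs and doses must be positive")
    return (auc_oral_sys / auc_iv_sys) * (dose_iv / dose_oral)


def hepatic_availability(ba: float, fafg_value: float) -> float:
    """Hepatic availability Fh = F / FaFg; undefined (NaN) when FaFg = 0."""
    if fafg_value == 0:
        return float("nan")
    return ba / fafg_value
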