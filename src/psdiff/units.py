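"""Unit conversions at the boundary between dosing units and molar PK units."""

from __future__ import annotations

__all__ = ["dose_to_nmol_per_kg", "qpv_to_L_per_h_per_kg"]


def dose_to_nmol_per_kg(dose_mg_per_kg: float, mw_dosed: float) -> float:
    """Convert a dose in mg/kg to nmol/kg via the molar mass of the dosed form.

    mg/kg -> g/kg is 1e-3, g/kg -> mol/kg divides by MW, mol -> nmol is 1e9;
    net factor 1e6/MW.
    """
    if not dose_mg_per_kg > 0:
        raise ValueError("dose must be positive")
    if not mw_dosed > 0:
        raise ValueError("molar mass must be positive")
    return dose_mg_per_kg * 1e6 / mw_dosed


def qpv_to_L_per_h_per_kg(qpv_ml_min_kg: float) -> float:
    """Convert portal blood flow from mL/min/kg to L/h/kg (x60/1000)."""
    if not qpv_ml_min_kg > 0:
        raise ValueError("portal blood flow must be positive")
    return qpv_ml_min_kg * 60.0 / 1000.0
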