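"""Non-compartmental analysis of a single concentration-time profile.

Terminal log-linear regression gives the elimination rate constant lambda_z
(ke) and half-life t1/2 = ln2/lambda_z. AUC and AUMC from time zero to
infinity use the linear trapezoidal rule over the observed points plus the
standard terminal extrapolation tails C_last/lambda_z and
C_last*t_last/lambda_z + C_last/lambda_z**2. For an intravenous bolus the
concentration at time zero, C0, is back-extrapolated log-linearly through the
first two positive points; after oral dosing C(0) = 0.

Derived quantities follow the standard moment identities:
MRT = AUMC/AUC, CLtot = Dose/AUC_iv, Vdss = MRT_iv * CLtot, and
MAT = MRT_oral - MRT_iv.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import ConcProfile, EstimationError, Route
from .units import dose_to_nmol_per_kg

__all__ = [
    "NcaResult",
    "lambda_z",
    "half_life",
    "c0_backextrapolated",
    "auc_aumc_inf",
    "cl_tot",
    "vd_ss",
    "mat",
    "analyze",
]

LN2 = math.log(2.0)


@dataclass
class NcaResult:
    """NCA parameters for one profile; route-inapplicable fields are NaN."""

    compound: str
    genotype: str
    route: str
    site: str
    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_inf: float
    aumc_inf: float
    mrt: float
    cltot: float = float("nan")
    vdss: float = float("nan")
    mat: float = float("nan")
    c0: float = float("nan")
    r_squared: float = float("nan")
    n_terminal_used: int = 0
    flags: set = field(default_factory=set)


def lambda_z(
    profile: ConcProfile, n_terminal: int = 3
) -> tuple[float, dict]:
    """Terminal elimination rate constant from log-linear regression over
    the last ``n_terminal`` positive-concentration points.

    If the requested window contains non-positive concentrations it shrinks
    toward the minimum of 2 positive points. Returns (lambda_z, diagnostics)
    where diagnostics carries r_squared, n_used and the log-intercept.
    """
    if n_terminal < 2:
        raise ValueError("n_terminal must be at least 2")
    pos = profile.concs > 0
    t = profile.times[pos]
    c = profile.concs[pos]
    if t.size < 2:
        raise EstimationError("fewer than 2 positive concentrations")
    n = min(n_terminal, t.size)
    t_win, c_win = t[-n:], c[-n:]
    logc = np.log(c_win)
    slope, intercept = np.polyfit(t_win, logc, 1)
    # tolerance absorbs float noise on exactly-flat profiles
    if slope >= -1e-10:
        raise EstimationError("no terminal decay (non-negative terminal slope)")
    fitted = slope * t_win + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return -float(slope), {
        "r_squared": r2,
        "n_used": int(n),
        "log_intercept": float(intercept),
    }


def half_life(lam: float) -> float:
    """t1/2 = ln2 / lambda_z."""
    if not lam > 0:
        raise ValueError("lambda_z must be positive")
    return LN2 / lam


def c0_backextrapolated(profile: ConcProfile) -> float:
    """Concentration at t=0 for an iv bolus: exp of the intercept of a
    log-linear fit through the first two positive points. Falls back to the
    first observed concentration if the two-point fit is unusable."""
    pos = profile.concs > 0
    t = profile.times[pos]
    c = profile.concs[pos]
    if t.size == 0:
        return 0.0
    if t.size == 1:
        return float(c[0])
    t2, c2 = t[:2], c[:2]
    if c2[1] >= c2[0]:
        # rising head: back-extrapolation would understate C0; use first obs
        return float(c2[0])
    slope = (math.log(c2[1]) - math.log(c2[0])) / (t2[1] - t2[0])
    return float(math.exp(math.log(c2[0]) - slope * t2[0]))


def auc_aumc_inf(
    profile: ConcProfile,
    lam: float | None = None,
    log_trapezoid: bool = False,
) -> tuple[float, float]:
    """AUC and AUMC from 0 to infinity by the trapezoidal rule.

    C(0) is 0 after oral dosing and the back-extrapolated C0 for iv. If the
    last observed concentration is positive, ``lam`` (lambda_z) is required
    for the extrapolation tails. ``log_trapezoid`` switches to the log-linear
    trapezoid on strictly decreasing segments (off by default).
    """
    t = profile.times.copy()
    c = profile.concs.copy()
    if t[0] > 0:
        c0 = c0_backextrapolated(profile) if profile.route is Route.iv else 0.0
        t = np.insert(t, 0, 0.0)
        c = np.insert(c, 0, c0)
    if log_trapezoid:
        auc = aumc = 0.0
        for i in range(t.size - 1):
            dt = t[i + 1] - t[i]
            c1, c2 = c[i], c[i + 1]
            if c1 > 0 and c2 > 0 and c2 < c1:
                k = math.log(c1 / c2) / dt
                auc += (c1 - c2) / k
                aumc += (c1 * t[i] - c2 * t[i + 1]) / k + (c1 - c2) / k**2
            else:
                auc += 0.5 * (c1 + c2) * dt
                aumc += 0.5 * (c1 * t[i] + c2 * t[i + 1]) * dt
    else:
        auc = float(np.trapezoid(c, t))
        aumc = float(np.trapezoid(c * t, t))
    c_last, t_last = float(c[-1]), float(t[-1])
    if c_last > 0:
        if lam is None or not lam > 0:
            raise ValueError(
                "positive last concentration requires lambda_z for the tail"
            )
        auc += c_last / lam
        aumc += c_last * t_last / lam + c_last / lam**2
    return float(auc), float(aumc)


def cl_tot(dose_nmol_per_kg: float, auc_iv: float) -> float:
    """Total body clearance CLtot = Dose / AUC_iv (L/h/kg for molar units)."""
    if not dose_nmol_per_kg > 0 or not auc_iv > 0:
        raise ValueError("dose and AUC must be positive")
    return dose_nmol_per_kg / auc_iv


def vd_ss(aumc_iv: float, auc_iv: float, cl: float) -> float:
    """Steady-state volume of distribution Vdss = (AUMC_iv/AUC_iv) * CLtot."""
    if not aumc_iv > 0 or not auc_iv > 0 or not cl > 0:
        raise ValueError("AUMC, AUC and CL must be positive")
    return aumc_iv / auc_iv * cl


def mat(mrt_oral: float, mrt_iv: float) -> float:
    """Mean absorption time MAT = MRT_oral - MRT_iv (may come out negative
    with noisy sparse data; callers flag rather than clamp)."""
    return mrt_oral - mrt_iv


def analyze(
    profile: ConcProfile,
    n_terminal: int = 3,
    mw_dosed: float | None = None,
    lloq: float = 0.0,
    log_trapezoid: bool = False,
) -> NcaResult:
    """Full NCA for one profile.

    CLtot and Vdss are filled only for iv profiles and only when ``mw_dosed``
    is given (needed to put dose and AUC on the same molar scale). Values at
    or below ``lloq`` are dropped before analysis (default keeps everything).
    """
    flags: set = set(profile.flags)
    if lloq > 0:
        keep = profile.concs > lloq
        if keep.sum() < 2:
            raise EstimationError("fewer than 2 points above LLOQ")
        profile = ConcProfile(
            compound=profile.compound,
            genotype=profile.genotype,
            route=profile.route,
            site=profile.site,
            times=profile.times[keep],
            concs=profile.concs[keep],
            dose_mg_per_kg=profile.dose_mg_per_kg,
        )
        flags.add("lloq_censored")

    i_max = int(np.argmax(profile.concs))
    cmax = float(profile.concs[i_max])
    tmax = float(profile.times[i_max])

    if np.all(profile.concs == 0):
        return NcaResult(
            *profile.key(), cmax=0.0, tmax=tmax, lambda_z=float("nan"),
            t_half=float("nan"), auc_inf=0.0, aumc_inf=0.0, mrt=float("nan"),
            flags=flags | {"all_zero"},
        )

    lam, diag = lambda_z(profile, n_terminal=n_terminal)
    t_half = half_life(lam)
    auc, aumc = auc_aumc_inf(profile, lam, log_trapezoid=log_trapezoid)
    mrt = aumc / auc if auc > 0 else float("nan")

    res = NcaResult(
        *profile.key(),
        cmax=cmax,
        tmax=tmax,
        lambda_z=lam,
        t_half=t_half,
        auc_inf=auc,
        aumc_inf=aumc,
        mrt=mrt,
        r_squared=diag["r_squared"],
        n_terminal_used=diag["n_used"],
        flags=flags,
    )
    if profile.route is Route.iv:
        res.c0 = c0_backextrapolated(profile)
        if mw_dosed is not None:
            dose_nmol = dose_to_nmol_per_kg(profile.dose_mg_per_kg, mw_dosed)
            res.cltot = cl_tot(dose_nmol, auc)
            res.vdss = vd_ss(aumc, auc, res.cltot)
    return res
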