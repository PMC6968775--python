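"""Synthetic study generator for the portal-systemic difference design.

A closed-form recirculatory model produces paired portal and systemic plasma
profiles with known ground truth, so every downstream estimator can be
checked by parameter recovery.

Disposition is one-compartment (volume V, elimination rate ke). After an
intravenous bolus both sites see the same mono-exponential,
C_sys(t) = D_iv/V * exp(-ke t). After oral dosing the absorbed input into
the portal blood is first-order, Ra(t) = FaFg * D_oral * ka * exp(-ka t),
the systemic curve is the Bateman function scaled by hepatic availability,

    C_sys(t) = Fh * FaFg * D_oral/V * ka/(ka-ke) * (exp(-ke t) - exp(-ka t)),

and the portal curve carries the instantaneous flow-dilution excess

    C_pv(t) = C_sys(t) + Ra(t) / (Qpv * Rb)

with Qpv in L/h/kg. This construction makes the mass balance
Qpv * Rb * integral(C_pv - C_sys) = FaFg * D_oral hold exactly in continuous
time, so the FaFg estimator has an analytic oracle; the portal excess is not
given its own mixing compartment.

Observation noise is multiplicative lognormal: C_obs = C * exp(eps) with
eps ~ N(0, sqrt(ln(1 + CV^2))), independent per sample. One integer seed
governs a whole study; per-profile substreams are derived deterministically
from (seed, genotype, route, site, animal), so any arm can be regenerated
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kafit import bateman
from .types import ConcProfile, Genotype, PAPER_SCHEDULE, Route, Site
from .units import dose_to_nmol_per_kg, qpv_to_L_per_h_per_kg

__all__ = ["SimTruth", "simulate_profiles", "simulate_study", "default_truths"]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters for one genotype arm of a simulated study."""

    fafg: float = 0.5          # fraction of oral dose reaching portal blood
    fh: float = 0.7            # hepatic availability
    ke: float = 0.5            # elimination rate constant, 1/h
    ka: float = 2.0            # absorption rate constant, 1/h
    v: float = 2.5             # distribution volume, L/kg
    rb: float = 1.0            # blood/plasma ratio
    qpv: float = 106.6         # portal blood flow, mL/min/kg
    cv_noise: float = 0.10     # residual CV (lognormal)
    seed: int = 0
    schedule: tuple[float, ...] = PAPER_SCHEDULE
    dose_iv: float = 1.0       # mg/kg
    dose_oral: float = 1.0     # mg/kg
    mw: float = 400.0          # g/mol of the dosed form

    def __post_init__(self) -> None:
        if not 0 < self.fafg <= 1.5 or not 0 < self.fh <= 1.5:
            raise ValueError("fractions must lie in (0, 1.5]")
        if min(self.ke, self.ka, self.v, self.rb, self.qpv) <= 0:
            raise ValueError("rates, volume, Rb and Qpv must be positive")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be non-negative")


def default_truths() -> dict[Genotype, SimTruth]:
    """Study conditions for the three genotype arms of a BCRP-substrate-like
    compound: knockout of the apical efflux transporter raises FaFg (to
    complete absorption for BCRP) and modestly lowers clearance."""
    wt = SimTruth()
    return {
        Genotype.WT: wt,
        Genotype.BcrpKO: replace(wt, fafg=1.0, ke=0.4),
        Genotype.Mdr1a1bKO: replace(wt, fafg=0.6, ke=0.45),
    }


def _substream(truth: SimTruth, genotype: Genotype, route: Route, site: Site,
               animal: int) -> np.random.Generator:
    g = list(Genotype).index(genotype)
    r = list(Route).index(route)
    s = list(Site).index(site)
    return np.random.default_rng([int(truth.seed), g, r, s, int(animal)])


def _noise(c: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return c.copy()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return c * np.exp(rng.normal(0.0, sigma, size=c.shape))


def _clean_curves(
    truth: SimTruth, route: Route, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (systemic, portal) concentrations at times t (hours)."""
    if route is Route.iv:
        d = dose_to_nmol_per_kg(truth.dose_iv, truth.mw)
        c_sys = d / truth.v * np.exp(-truth.ke * t)
        return c_sys, c_sys.copy()
    d = dose_to_nmol_per_kg(truth.dose_oral, truth.mw)
    c_sys = bateman(t, truth.ka, truth.ke, truth.fh * truth.fafg * d / truth.v)
    ra = truth.fafg * d * truth.ka * np.exp(-truth.ka * t)
    c_pv = c_sys + ra / (qpv_to_L_per_h_per_kg(truth.qpv) * truth.rb)
    return c_sys, c_pv


def simulate_profiles(
    truth: SimTruth,
    genotype: Genotype | str,
    route: Route | str,
    animal: int = 0,
    compound: str = "simdrug",
) -> tuple[ConcProfile, ConcProfile]:
    """Simulate one animal's (systemic, portal) profile pair for a route.

    For iv dosing the portal profile equals the systemic one up to noise
    (and is flagged by ConcProfile as an unusual iv-portal arm).
    """
    genotype = Genotype(genotype)
    route = Route(route)
    t = np.asarray(truth.schedule, dtype=float)
    c_sys, c_pv = _clean_curves(truth, route, t)
    dose = truth.dose_iv if route is Route.iv else truth.dose_oral
    out = []
    for site, clean in ((Site.systemic, c_sys), (Site.portal, c_pv)):
        rng = _substream(truth, genotype, route, site, animal)
        out.append(
            ConcProfile(
                compound=compound,
                genotype=genotype,
                route=route,
                site=site,
                times=t,
                concs=_noise(clean, truth.cv_noise, rng),
                dose_mg_per_kg=dose,
            )
        )
    return out[0], out[1]


def simulate_study(
    truths: dict[Genotype, SimTruth] | None = None,
    n_animals: int = 2,
    schedule: tuple[float, ...] | None = None,
    compound: str = "simdrug",
) -> pd.DataFrame:
    """Simulate a full study table: per genotype an iv arm (systemic site)
    and an oral arm (portal + systemic sites), ``n_animals`` replicates each.

    Returns a long-format table consumable by :func:`psdiff.io.read_study`
    (replicates average into the arm-mean profile exactly as the pipeline
    expects). Use ``schedule`` to override the sparse default, e.g. a dense
    grid for noise-free oracle checks.
    """
    if truths is None:
        truths = default_truths()
    if not truths:
        raise ValueError("truth set must not be empty")
    if n_animals < 1:
        raise ValueError("n_animals must be at least 1")
    rows = []
    for genotype, truth in truths.items():
        genotype = Genotype(genotype)
        if schedule is not None:
            truth = replace(truth, schedule=tuple(schedule))
        for route in (Route.iv, Route.oral):
            sites = (Site.systemic,) if route is Route.iv else (
                Site.systemic, Site.portal)
            dose = truth.dose_iv if route is Route.iv else truth.dose_oral
            for animal in range(n_animals):
                sys_p, pv_p = simulate_profiles(
                    truth, genotype, route, animal=animal, compound=compound
                )
                by_site = {Site.systemic: sys_p, Site.portal: pv_p}
                for site in sites:
                    prof = by_site[site]
                    for t, c in zip(prof.times, prof.concs):
                        rows.append(
                            {
                                "compound": compound,
                                "genotype": genotype.value,
                                "route": route.value,
                                "site": site.value,
                                "time_h": t,
                                "conc_nM": c,
                                "dose_mg_per_kg": dose,
                            }
                        )
    return pd.DataFrame(rows)
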