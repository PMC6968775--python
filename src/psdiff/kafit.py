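"""First-order absorption rate constant by nonlinear least squares.

The oral systemic profile is fitted with the one-compartment Bateman curve

    C(t) = S * ka/(ka - ke) * (exp(-ke t) - exp(-ka t))

where S lumps F*Dose/V and ke is FIXED from the same arm's intravenous
terminal slope. Fixing ke resolves the flip-flop ambiguity of the Bateman
function (ka and ke are exchangeable on a single oral curve). At ka = ke the
curve degenerates to S * ka * t * exp(-ka t); the implementation uses the
expm1-based form which is continuous through that limit.

Fitting is deterministic multistart Levenberg/TRF least squares; starting
values ka0 in {1/Tmax, 3/Tmax, 10*ke}, first-listed wins ties on SSE, ties
broken toward the smaller ka.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .types import ConcProfile, EstimationError

__all__ = ["AbsorptionFit", "bateman", "fit_ka"]

KA_BOUNDS = (1e-3, 1e3)


@dataclass
class AbsorptionFit:
    ka: float
    scale: float
    ke_fixed: float
    sse: float
    converged: bool
    n_iter: int
    weighting: str = "uniform"
    flags: set = field(default_factory=set)


def bateman(t: np.ndarray, ka: float, ke: float, scale: float) -> np.ndarray:
    """Bateman concentration-time curve, stable through ka -> ke.

    Written as scale*ka*exp(-ke t)*(1-exp(-(ka-ke)t))/(ka-ke); the last
    factor tends to t as ka -> ke, handled with expm1 and an explicit
    equal-rates branch.
    """
    t = np.asarray(t, dtype=float)
    d = ka - ke
    if d == 0.0:
        return scale * ka * t * np.exp(-ka * t)
    with np.errstate(over="ignore"):
        frac = -np.expm1(-d * t) / d
    return scale * ka * np.exp(-ke * t) * frac


def fit_ka(
    profile: ConcProfile,
    ke: float,
    weighting: str = "uniform",
    ka0: float | None = None,
    bounds: tuple[float, float] = KA_BOUNDS,
) -> AbsorptionFit:
    """Fit ka (and the scale S) to an oral systemic profile with ke fixed.

    ``weighting`` is "uniform" (ordinary least squares) or "inverse_pred"
    (weights 1/C_hat, the classical iteratively-reweighted convention for
    assay error proportional to concentration).
    """
    if not ke > 0:
        raise ValueError("ke must be positive")
    if weighting not in ("uniform", "inverse_pred"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t = profile.times
    c = profile.concs
    if t.size < 4:
        raise EstimationError("ka fitting needs at least 4 points")
    i_max = int(np.argmax(c))
    if i_max == t.size - 1 and c[-1] > c[0]:
        raise EstimationError(
            "profile rises to the last sample: no post-peak decay to fit"
        )

    tmax = float(t[i_max]) if t[i_max] > 0 else float(t[max(i_max, 1)])
    starts = [ka0] if ka0 is not None else [1.0 / tmax, 3.0 / tmax, 10.0 * ke]
    starts = [float(np.clip(s, *bounds)) for s in starts]
    cmax = float(c.max())
    eps = 1e-12

    def residuals(x: np.ndarray) -> np.ndarray:
        pred = bateman(t, x[0], ke, x[1])
        r = c - pred
        if weighting == "inverse_pred":
            r = r / np.sqrt(np.maximum(pred, eps * cmax + eps))
        return r

    best = None
    for s in starts:
        s0 = cmax * 2.0  # Bateman peak is below S for ka > ke
        try:
            sol = least_squares(
                residuals,
                x0=[s, s0],
                bounds=([bounds[0], 0.0], [bounds[1], np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        cand = (sse, float(sol.x[0]), float(sol.x[1]), int(sol.nfev))
        if best is None or cand[0] < best[0] - 1e-15 * (1 + best[0]) or (
            abs(cand[0] - best[0]) <= 1e-12 * (1 + best[0]) and cand[1] < best[1]
        ):
            best = cand
    if best is None:
        raise EstimationError("ka fit failed to converge from all starting values")

    sse, ka_hat, scale_hat, nfev = best
    flags: set = set()
    if np.isclose(ka_hat, bounds[0], rtol=1e-6) or np.isclose(
        ka_hat, bounds[1], rtol=1e-6
    ):
        flags.add("ka_at_bound")
    return AbsorptionFit(
        ka=ka_hat,
        scale=scale_hat,
        ke_fixed=ke,
        sse=sse,
        converged=True,
        n_iter=nfev,
        weighting=weighting,
        flags=flags,
    )
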