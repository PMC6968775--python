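"""Transporter contribution scoring across knockout genotypes.

Given a per-genotype triplet of a readout x (either the absorption rate
constant ka or the fraction absorbed FaFg) in wild-type, Bcrp(-/-) and
Mdr1a/1b(-/-) mice, the normalised knockout deltas

    delta_b = x_bcrp - x_wt,   delta_p = x_pgp - x_wt,
    D = x_wt + delta_b + delta_p

define the in vivo absorptive quotient AQ (ka-based) and the rate of
contribution R (FaFg-based):

    AQ_bcrp (or R_bcrp) = delta_b / D,    AQ_pgp (or R_pgp) = delta_p / D.

When both deltas are non-negative the scores lie in [0, 1] and satisfy
score_b + score_p + x_wt/D = 1: the three terms partition the permeability
of the unrestricted (double-unblocked) gut into the BCRP-attributable,
P-gp-attributable and transporter-independent shares. A negative delta
(knockout readout below wild type, as for sulfasalazine's ka) breaks that
interpretation: the raw quotient is still reported, with a not_estimable
flag, matching how such cells are rendered as "-" in summary tables.

The in vitro / in vivo concordance check classifies each (compound,
transporter) pair by a closed 0.4 criterion on both axes into true/false
positive/negative quadrants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "GenotypeTriplet",
    "ContributionResult",
    "Quadrant",
    "IvivcRecord",
    "aq_in_vivo",
    "r_contribution",
    "classify_quadrant",
]

DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class GenotypeTriplet:
    """One readout measured in all three genotypes."""

    wt: float
    bcrp_ko: float
    pgp_ko: float
    kind: Literal["ka", "fafg"] = "fafg"

    def __post_init__(self) -> None:
        vals = (self.wt, self.bcrp_ko, self.pgp_ko)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("triplet values must be finite")
        if self.kind == "ka" and not all(v > 0 for v in vals):
            raise ValueError("ka values must be positive")
        if self.kind == "fafg" and not all(v >= 0 for v in vals):
            raise ValueError("FaFg values must be non-negative")


@dataclass
class ContributionResult:
    aq_bcrp: float = float("nan")
    aq_pgp: float = float("nan")
    r_bcrp: float = float("nan")
    r_pgp: float = float("nan")
    flags: set = field(default_factory=set)

    @property
    def aq_estimable(self) -> bool:
        return "not_estimable_aq" not in self.flags and "zero_denominator_aq" not in self.flags

    @property
    def r_estimable(self) -> bool:
        return "not_estimable_r" not in self.flags and "zero_denominator_r" not in self.flags


def _normalized_deltas(trip: GenotypeTriplet) -> tuple[float, float, set]:
    delta_b = trip.bcrp_ko - trip.wt
    delta_p = trip.pgp_ko - trip.wt
    denom = trip.wt + delta_b + delta_p
    flags: set = set()
    if delta_b < 0:
        flags.add("negative_delta_bcrp")
    if delta_p < 0:
        flags.add("negative_delta_pgp")
    if denom <= 0:
        flags.add("zero_denominator")
        return float("nan"), float("nan"), flags
    return delta_b / denom, delta_p / denom, flags


def aq_in_vivo(ka: GenotypeTriplet) -> ContributionResult:
    """In vivo absorptive quotients (AQ_bcrp, AQ_pgp) from a ka triplet."""
    score_b, score_p, flags = _normalized_deltas(ka)
    out_flags = set()
    if "zero_denominator" in flags:
        out_flags.add("zero_denominator_aq")
    if flags & {"negative_delta_bcrp", "negative_delta_pgp"}:
        out_flags |= flags - {"zero_denominator"}
        out_flags.add("not_estimable_aq")
    return ContributionResult(aq_bcrp=score_b, aq_pgp=score_p, flags=out_flags)


def r_contribution(fafg: GenotypeTriplet) -> ContributionResult:
    """Rates of contribution (R_bcrp, R_pgp) from a FaFg triplet."""
    score_b, score_p, flags = _normalized_deltas(fafg)
    out_flags = set()
    if "zero_denominator" in flags:
        out_flags.add("zero_denominator_r")
    if flags & {"negative_delta_bcrp", "negative_delta_pgp"}:
        out_flags |= flags - {"zero_denominator"}
        out_flags.add("not_estimable_r")
    return ContributionResult(r_bcrp=score_b, r_pgp=score_p, flags=out_flags)


class Quadrant(str, enum.Enum):
    """In vitro (x) vs in vivo (y) concordance classes at the 0.4 criterion."""

    T_pos = "T(+)"
    T_neg = "T(-)"
    F_pos = "F(+)"
    F_neg = "F(-)"


@dataclass
class IvivcRecord:
    compound: str
    transporter: Literal["BCRP", "Pgp"]
    aq_in_vitro: float
    r_in_vivo: float
    quadrant: Quadrant


def classify_quadrant(
    aq_in_vitro: float,
    r_in_vivo: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> Quadrant:
    """Closed-boundary quadrant classification: scores >= threshold count as
    transporter-limited on that axis."""
    if not (math.isfinite(aq_in_vitro) and math.isfinite(r_in_vivo)):
        raise ValueError("cannot classify non-finite scores")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    hi_vitro = aq_in_vitro >= threshold
    hi_vivo = r_in_vivo >= threshold
    if hi_vitro and hi_vivo:
        return Quadrant.T_pos
    if not hi_vitro and not hi_vivo:
        return Quadrant.T_neg
    if hi_vitro:
        return Quadrant.F_pos
    return Quadrant.F_neg
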