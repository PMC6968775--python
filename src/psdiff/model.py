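"""Study-level model objects tying the pipeline stages together.

`PSDifferenceModel` is built from a long-format concentration-time table
plus compound and physiology constants; its `fit()` runs, per compound and
genotype, the non-compartmental analysis of the intravenous arm (terminal
slope, CLtot, Vdss), the portal and systemic oral-arm exposures, the
portal-systemic difference estimate of FaFg, bioavailability and hepatic
availability, and the Bateman fit of the absorption rate constant with ke
fixed from the iv arm. The returned `PSDifferenceResults` carries the
per-profile NCA table, the per-arm absorption summary and the per-compound
transporter-contribution scores, renders text summaries, and classifies
in vitro vs in vivo concordance quadrants.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import absorption, contribution, kafit, nca
from .io import read_study, read_study_frame
from .types import (
    CompoundSpec,
    ConcProfile,
    EstimationError,
    Genotype,
    PhysiologyConfig,
    Route,
    Site,
)
from .units import dose_to_nmol_per_kg

__all__ = ["PSDifferenceModel", "PSDifferenceResults"]

_NCA_COLUMNS = [
    "compound", "genotype", "route", "site", "cmax", "tmax", "lambda_z",
    "t_half", "auc_inf", "aumc_inf", "mrt", "cltot", "vdss", "mat", "c0",
    "r_squared", "n_terminal_used", "flags",
]


class PSDifferenceModel:
    """Portal-systemic difference analysis of one study.

    Parameters
    ----------
    profiles
        Arm-mean concentration-time profiles (one per compound, genotype,
        route, site).
    compounds
        Mapping of compound name to its constants (dosed-form molar mass,
        blood/plasma ratio, doses per route).
    physiology
        Portal blood flow and default schedule.
    """

    def __init__(
        self,
        profiles: list[ConcProfile],
        compounds: dict[str, CompoundSpec],
        physiology: PhysiologyConfig | None = None,
    ) -> None:
        self.profiles = list(profiles)
        self.compounds = dict(compounds)
        self.physiology = physiology or PhysiologyConfig()
        missing = {p.compound for p in self.profiles} - set(self.compounds)
        if missing:
            raise ValueError(f"no CompoundSpec for: {sorted(missing)}")
        self._index: dict[tuple, ConcProfile] = {}
        for p in self.profiles:
            key = (p.compound, p.genotype, p.route, p.site)
            if key in self._index:
                raise ValueError(f"duplicate profile for arm {key}")
            self._index[key] = p

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        compounds: dict[str, CompoundSpec],
        physiology: PhysiologyConfig | None = None,
    ) -> "PSDifferenceModel":
        return cls(read_study_frame(df), compounds, physiology)

    @classmethod
    def from_csv(
        cls,
        path: str | os.PathLike,
        compounds: dict[str, CompoundSpec],
        physiology: PhysiologyConfig | None = None,
    ) -> "PSDifferenceModel":
        return cls(read_study(path), compounds, physiology)

    def _arm(self, compound: str, genotype: Genotype, route: Route,
             site: Site) -> ConcProfile | None:
        return self._index.get((compound, genotype, route, site))

    def fit(
        self,
        n_terminal: int = 3,
        weighting: str = "uniform",
        lloq: float = 0.0,
        log_trapezoid: bool = False,
    ) -> "PSDifferenceResults":
        """Run the full pipeline; arms that cannot be estimated are recorded
        with NaN values and a flag instead of aborting the study."""
        nca_rows: list[dict] = []
        summaries: list[absorption.AbsorptionSummary] = []
        contrib_rows: list[dict] = []

        for comp_name in sorted({p.compound for p in self.profiles}):
            spec = self.compounds[comp_name]
            fafg_by_gt: dict[Genotype, float] = {}
            ka_by_gt: dict[Genotype, float] = {}
            for genotype in Genotype:
                arms = {
                    (r, s): self._arm(comp_name, genotype, r, s)
                    for r, s in [
                        (Route.iv, Site.systemic),
                        (Route.oral, Site.systemic),
                        (Route.oral, Site.portal),
                    ]
                }
                if all(a is None for a in arms.values()):
                    continue
                summary = absorption.AbsorptionSummary(comp_name, genotype.value)

                iv = arms[(Route.iv, Site.systemic)]
                iv_res = None
                if iv is not None:
                    try:
                        iv_res = nca.analyze(
                            iv, n_terminal=n_terminal, mw_dosed=spec.mw_dosed,
                            lloq=lloq, log_trapezoid=log_trapezoid,
                        )
                        nca_rows.append(_nca_row(iv_res))
                    except EstimationError:
                        summary.flags.add("iv_nca_failed")

                po_sys = arms[(Route.oral, Site.systemic)]
                po_res = None
                if po_sys is not None:
                    try:
                        po_res = nca.analyze(
                            po_sys, n_terminal=n_terminal, lloq=lloq,
                            log_trapezoid=log_trapezoid,
                        )
                        nca_rows.append(_nca_row(po_res))
                    except EstimationError:
                        summary.flags.add("oral_nca_failed")

                po_pv = arms[(Route.oral, Site.portal)]
                pv_res = None
                if po_pv is not None:
                    try:
                        pv_res = nca.analyze(
                            po_pv, n_terminal=n_terminal, lloq=lloq,
                            log_trapezoid=log_trapezoid,
                        )
                        nca_rows.append(_nca_row(pv_res))
                    except EstimationError:
                        summary.flags.add("portal_nca_failed")

                if po_res is not None and iv_res is not None:
                    m = nca.mat(po_res.mrt, iv_res.mrt)
                    summary.mat = m
                    if m < 0:
                        summary.flags.add("negative_mat")
                    nca_rows[-1 - (pv_res is not None)]["mat"] = m

                if pv_res is not None and po_res is not None:
                    dose_nmol = dose_to_nmol_per_kg(spec.dose_oral, spec.mw_dosed)
                    summary.fafg = absorption.fafg(
                        pv_res.auc_inf, po_res.auc_inf, spec.rb,
                        self.physiology.qpv, dose_nmol, flags=summary.flags,
                    )
                    fafg_by_gt[genotype] = summary.fafg
                if po_res is not None and iv_res is not None:
                    summary.ba = absorption.bioavailability(
                        po_res.auc_inf, iv_res.auc_inf,
                        spec.dose_iv, spec.dose_oral,
                    )
                    if np.isfinite(summary.fafg) and summary.fafg != 0:
                        summary.fh = absorption.hepatic_availability(
                            summary.ba, summary.fafg
                        )
                if po_sys is not None and iv_res is not None:
                    try:
                        fit = kafit.fit_ka(
                            po_sys, ke=iv_res.lambda_z, weighting=weighting
                        )
                        summary.ka = fit.ka
                        ka_by_gt[genotype] = fit.ka
                        summary.flags |= fit.flags
                    except EstimationError:
                        summary.flags.add("ka_fit_failed")
                summaries.append(summary)

            row: dict = {"compound": comp_name}
            have_all = all(g in fafg_by_gt for g in Genotype)
            if all(g in ka_by_gt for g in Genotype):
                trip = contribution.GenotypeTriplet(
                    ka_by_gt[Genotype.WT], ka_by_gt[Genotype.BcrpKO],
                    ka_by_gt[Genotype.Mdr1a1bKO], kind="ka",
                )
                aq = contribution.aq_in_vivo(trip)
                row.update(aq_bcrp=aq.aq_bcrp, aq_pgp=aq.aq_pgp,
                           aq_flags=sorted(aq.flags))
            if have_all:
                trip = contribution.GenotypeTriplet(
                    fafg_by_gt[Genotype.WT], fafg_by_gt[Genotype.BcrpKO],
                    fafg_by_gt[Genotype.Mdr1a1bKO], kind="fafg",
                )
                r = contribution.r_contribution(trip)
                row.update(r_bcrp=r.r_bcrp, r_pgp=r.r_pgp,
                           r_flags=sorted(r.flags))
            if len(row) > 1:
                contrib_rows.append(row)

        nca_df = pd.DataFrame(nca_rows, columns=_NCA_COLUMNS)
        absorption_df = pd.DataFrame([asdict(s) for s in summaries])
        if not absorption_df.empty:
            absorption_df["flags"] = absorption_df["flags"].map(sorted)
        contrib_df = pd.DataFrame(contrib_rows)
        return PSDifferenceResults(self, nca_df, absorption_df, contrib_df)


def _nca_row(res: nca.NcaResult) -> dict:
    d = asdict(res)
    d["flags"] = sorted(d["flags"])
    return d


class PSDifferenceResults:
    """Fitted results of a portal-systemic difference study.

    Attributes
    ----------
    nca : DataFrame
        One row per analysed profile (Cmax, Tmax, lambda_z, t1/2, AUC, AUMC,
        MRT; CLtot/Vdss/C0 for iv arms; MAT on oral systemic arms).
    absorption : DataFrame
        One row per compound x genotype (FaFg, BA, Fh, ka, MAT, flags).
    contribution : DataFrame
        One row per compound with complete genotype triplets
        (AQ_bcrp/AQ_pgp from ka, R_bcrp/R_pgp from FaFg, flags).
    """

    def __init__(self, model: PSDifferenceModel, nca_df: pd.DataFrame,
                 absorption_df: pd.DataFrame, contrib_df: pd.DataFrame) -> None:
        self.model = model
        self.nca = nca_df
        self.absorption = absorption_df
        self.contribution = contrib_df

    def classify(
        self,
        invitro: pd.DataFrame,
        threshold: float = contribution.DEFAULT_THRESHOLD,
    ) -> pd.DataFrame:
        """Concordance quadrants of in vitro AQ (columns: compound,
        transporter in {BCRP, Pgp}, aq_in_vitro) against this study's fitted
        in vivo R values."""
        r_map: dict[tuple[str, str], float] = {}
        for _, row in self.contribution.iterrows():
            for transporter, col, flags_col in (
                ("BCRP", "r_bcrp", "r_flags"), ("Pgp", "r_pgp", "r_flags"),
            ):
                if col in row and np.isfinite(row.get(col, np.nan)):
                    flags = row.get(flags_col) or []
                    if "not_estimable_r" not in flags:
                        r_map[(row["compound"], transporter)] = row[col]
        records = []
        for _, row in invitro.iterrows():
            key = (row["compound"], row["transporter"])
            if key not in r_map:
                records.append(
                    {"compound": key[0], "transporter": key[1],
                     "aq_in_vitro": row["aq_in_vitro"], "r_in_vivo": np.nan,
                     "quadrant": "not_estimable"}
                )
                continue
            quad = contribution.classify_quadrant(
                row["aq_in_vitro"], r_map[key], threshold=threshold
            )
            records.append(
                {"compound": key[0], "transporter": key[1],
                 "aq_in_vitro": row["aq_in_vitro"], "r_in_vivo": r_map[key],
                 "quadrant": quad.value}
            )
        return pd.DataFrame(records)

    def summary(self, percent: bool = True) -> str:
        """Plain-text summary: PK parameters per arm, absorption fractions
        (as percentages by default, mirroring the usual table layout) and
        contribution scores rounded to two decimals."""
        parts = ["Portal-systemic difference analysis", "=" * 36, ""]
        if not self.nca.empty:
            pk = self.nca.copy()
            for col in ("cmax", "auc_inf", "aumc_inf"):
                pk[col] = pk[col].map(lambda v: float(f"{v:.3g}"))
            for col in ("lambda_z", "t_half", "mrt", "cltot", "vdss", "mat"):
                pk[col] = pk[col].map(lambda v: float(f"{v:.3g}"))
            parts += ["Non-compartmental parameters", pk[
                ["compound", "genotype", "route", "site", "cmax", "tmax",
                 "t_half", "auc_inf", "mrt", "cltot", "vdss", "mat"]
            ].to_string(index=False), ""]
        if not self.absorption.empty:
            ab = self.absorption.copy()
            if percent:
                for col in ("fafg", "ba", "fh"):
                    ab[col] = (ab[col] * 100).map(lambda v: float(f"{v:.3g}"))
                ab = ab.rename(columns={
                    "fafg": "FaFg_%", "ba": "BA_%", "fh": "Fh_%"})
            ab["ka"] = ab["ka"].map(lambda v: float(f"{v:.3g}"))
            parts += ["Absorption summary", ab.drop(columns=["mat"]).to_string(
                index=False), ""]
        if not self.contribution.empty:
            co = self.contribution.copy()
            for col in ("aq_bcrp", "aq_pgp", "r_bcrp", "r_pgp"):
                if col in co:
                    co[col] = co[col].round(2)
            parts += ["Transporter contribution scores", co.to_string(
                index=False), ""]
        return "\n".join(parts)

    def quadrant_report(
        self,
        invitro: pd.DataFrame,
        threshold: float = contribution.DEFAULT_THRESHOLD,
    ) -> str:
        """Text rendering of the concordance classification."""
        table = self.classify(invitro, threshold=threshold)
        lines = [
            f"In vitro AQ vs in vivo R concordance (criterion {threshold})",
            "-" * 52,
        ]
        for _, row in table.iterrows():
            r = row["r_in_vivo"]
            r_txt = f"{r:.2f}" if np.isfinite(r) else "-"
            lines.append(
                f"{row['compound']:<16}{row['transporter']:<6}"
                f"AQ={row['aq_in_vitro']:.2f}  R={r_txt:<6}{row['quadrant']}"
            )
        return "\n".join(lines)

    def plot_quadrants(self, invitro: pd.DataFrame, threshold: float = 0.4,
                       ax=None):
        """Scatter of in vitro AQ vs in vivo R with the criterion lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        table = self.classify(invitro, threshold=threshold)
        markers = {"BCRP": "o", "Pgp": "s"}
        for transporter, grp in table.groupby("transporter"):
            ax.scatter(grp["aq_in_vitro"], grp["r_in_vivo"],
                       marker=markers.get(transporter, "o"), label=transporter)
        ax.axhline(threshold, ls="--", c="grey")
        ax.axvline(threshold, ls="--", c="grey")
        ax.set_xlabel("in vitro AQ (Caco-2)")
        ax.set_ylabel("in vivo R")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend()
        return ax

    def to_csv(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write the three result tables as CSVs; returns name -> path."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in (("nca", self.nca), ("absorption", self.absorption),
                         ("contribution", self.contribution)):
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False)
            paths[name] = path
        return paths
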