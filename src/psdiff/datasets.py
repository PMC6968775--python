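"""Packaged reference datasets.

Small CSVs holding the published summary values for the four model drugs
(ciprofloxacin, nitrofurantoin, topotecan, sulfasalazine) in wild-type,
Bcrp(-/-) and Mdr1a/1b(-/-) mice: per-arm NCA summaries (AUCs, CLtot, Vdss,
ka, FaFg, Fh, BA), the per-compound ka and FaFg triplets with their AQ/R
scores, and the in vitro Caco-2 absorptive quotients used for the
concordance classification. These serve as regression anchors for the
estimators; raw per-animal profiles were never published.

Note the known internal inconsistency of the source tables: the topotecan
wild-type ka is printed as 2.33 in the per-arm table but 3.18 in the triplet
summary; each loader reproduces its own table verbatim.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_config
from .types import CompoundSpec, PhysiologyConfig

__all__ = [
    "load_published_pk",
    "load_published_triplets",
    "load_caco2_aq",
    "load_compound_specs",
]


def _data_path(name: str):
    return resources.files("psdiff").joinpath("data", name)


def load_published_pk() -> pd.DataFrame:
    """Per compound x genotype published NCA/absorption summary values.

    AUCs in nmol/L*h, CLtot in L/h/kg, Vdss in L/kg, ka in 1/h; FaFg, Fh and
    BA as printed percentages.
    """
    with resources.as_file(_data_path("published_pk.csv")) as p:
        return pd.read_csv(p)


def load_published_triplets() -> pd.DataFrame:
    """Per-compound ka (1/h) and FaFg (fraction) genotype triplets together
    with the published AQ and R scores (NaN where rendered as '-')."""
    with resources.as_file(_data_path("published_triplets.csv")) as p:
        return pd.read_csv(p)


def load_caco2_aq() -> pd.DataFrame:
    """In vitro Caco-2 absorptive quotients and the paired in vivo R values
    per (compound, transporter)."""
    with resources.as_file(_data_path("caco2_aq.csv")) as p:
        return pd.read_csv(p)


def load_compound_specs() -> tuple[dict[str, CompoundSpec], PhysiologyConfig]:
    """Compound constants (dosed-form MW, Rb, doses) and physiology config
    for the four model drugs."""
    with resources.as_file(_data_path("compounds.yaml")) as p:
        return read_config(p)
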