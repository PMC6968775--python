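import dataclasses

import numpy as np
import pytest

from psdiff.simulate import SimTruth, default_truths
from psdiff.types import CompoundSpec, ConcProfile

#: uniform dense grid for oracle checks against closed-form integrals;
#: includes t=0 so the step of the portal curve at 0+ is observed
DENSE_SCHEDULE = tuple(np.round(np.arange(0.0, 24.05, 0.05), 10))


@pytest.fixture
def sim_spec() -> dict[str, CompoundSpec]:
    return {"simdrug": CompoundSpec("simdrug", 400.0, 1.0, 1.0, 1.0)}


@pytest.fixture
def noiseless_truths() -> dict:
    return {
        g: dataclasses.replace(t, cv_noise=0.0)
        for g, t in default_truths().items()
    }


@pytest.fixture
def wt_truth() -> SimTruth:
    return default_truths()[list(default_truths())[0]]


def make_profile(times, concs, route="iv", site="systemic", dose=1.0,
                 compound="x", genotype="WT") -> ConcProfile:
    return ConcProfile(
        compound=compound, genotype=genotype, route=route, site=site,
        times=np.asarray(times, float), concs=np.asarray(concs, float),
        dose_mg_per_kg=dose,
    )
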