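"""Recirculatory simulator: analytic identities, determinism, noise model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from psdiff.contribution import GenotypeTriplet, r_contribution
from psdiff.model import PSDifferenceModel
from psdiff.nca import auc_aumc_inf
from psdiff.simulate import SimTruth, default_truths, simulate_profiles, simulate_study
from psdiff.types import CompoundSpec, Genotype
from psdiff.units import dose_to_nmol_per_kg, qpv_to_L_per_h_per_kg

from conftest import DENSE_SCHEDULE


def noiseless(**kw) -> SimTruth:
    return SimTruth(cv_noise=0.0, **kw)


class TestMassBalance:
    def test_portal_excess_integrates_to_absorbed_dose(self):
        # Qpv * Rb * integral(Cpv - Csys) = FaFg * Dose, the design identity
        truth = noiseless(schedule=DENSE_SCHEDULE, fafg=0.5, rb=1.1)
        sys_p, pv_p = simulate_profiles(truth, "WT", "oral")
        lam = truth.ke
        auc_sys, _ = auc_aumc_inf(sys_p, lam)
        auc_pv, _ = auc_aumc_inf(pv_p, lam)
        dose = dose_to_nmol_per_kg(truth.dose_oral, truth.mw)
        absorbed = qpv_to_L_per_h_per_kg(truth.qpv) * truth.rb * (auc_pv - auc_sys)
        assert absorbed == pytest.approx(truth.fafg * dose, rel=2e-2)

    def test_lossless_absorption_gives_unit_bioavailability(self):
        # FaFg = Fh = 1 with equal doses: oral and iv exposures coincide
        truth = noiseless(schedule=DENSE_SCHEDULE, fafg=1.0, fh=1.0)
        oral_sys, _ = simulate_profiles(truth, "WT", "oral")
        iv_sys, _ = simulate_profiles(truth, "WT", "iv")
        auc_oral, _ = auc_aumc_inf(oral_sys, truth.ke)
        auc_iv, _ = auc_aumc_inf(iv_sys, truth.ke)
        assert auc_oral / auc_iv == pytest.approx(1.0, rel=1e-2)

    def test_iv_portal_equals_systemic(self):
        truth = noiseless()
        sys_p, pv_p = simulate_profiles(truth, "WT", "iv")
        np.testing.assert_array_equal(sys_p.concs, pv_p.concs)


class TestDeterminism:
    def test_fixed_seed_reproduces_exactly(self):
        truth = SimTruth(seed=42)
        a_sys, a_pv = simulate_profiles(truth, "WT", "oral")
        b_sys, b_pv = simulate_profiles(truth, "WT", "oral")
        np.testing.assert_array_equal(a_sys.concs, b_sys.concs)
        np.testing.assert_array_equal(a_pv.concs, b_pv.concs)

    def test_substreams_differ_across_arms_and_animals(self):
        truth = SimTruth(seed=42)
        wt, _ = simulate_profiles(truth, "WT", "oral", animal=0)
        other, _ = simulate_profiles(truth, "WT", "oral", animal=1)
        ko, _ = simulate_profiles(truth, "BcrpKO", "oral", animal=0)
        assert not np.array_equal(wt.concs, other.concs)
        assert not np.array_equal(wt.concs, ko.concs)

    def test_study_table_deterministic(self):
        a = simulate_study(n_animals=2)
        b = simulate_study(n_animals=2)
        assert a.equals(b)


class TestStudyDesign:
    def test_profile_count_per_animal_set(self):
        # 3 genotypes x (iv systemic + oral systemic + oral portal)
        df = simulate_study(n_animals=1)
        groups = df.groupby(["genotype", "route", "site"]).ngroups
        assert groups == 9

    def test_default_schedule_is_sparse_sampling_design(self):
        df = simulate_study(n_animals=1)
        times = sorted(df["time_h"].unique())
        assert times == [0.083, 0.17, 0.5, 1.0, 2.0, 4.0, 8.0]

    def test_empty_truth_set_rejected(self):
        with pytest.raises(ValueError):
            simulate_study({}, n_animals=1)


class TestNoiseModel:
    def test_log_residuals_normal_with_declared_sd(self):
        cv = 0.25
        truth = SimTruth(cv_noise=cv, seed=3,
                         schedule=tuple(np.linspace(0.1, 8, 2000)))
        sys_p, _ = simulate_profiles(truth, "WT", "oral")
        clean_sys, _ = simulate_profiles(
            dataclasses.replace(truth, cv_noise=0.0), "WT", "oral")
        resid = np.log(sys_p.concs) - np.log(clean_sys.concs)
        sigma = np.sqrt(np.log(1 + cv**2))
        assert resid.std() == pytest.approx(sigma, rel=0.1)
        assert abs(resid.mean()) < 3 * sigma / np.sqrt(resid.size)
        assert stats.normaltest(resid).pvalue > 0.01


class TestEndToEndRecovery:
    def test_r_scores_from_truth_fafg_dense_noiseless(self, sim_spec):
        # hand algebra on (0.5, 1.0, 0.6): R_bcrp = 0.5/1.1 = 0.4545...
        truths = {
            g: dataclasses.replace(t, cv_noise=0.0)
            for g, t in default_truths().items()
        }
        df = simulate_study(truths, n_animals=1, schedule=DENSE_SCHEDULE)
        res = PSDifferenceModel.from_dataframe(df, sim_spec).fit()
        row = res.contribution.iloc[0]
        assert row.r_bcrp == pytest.approx(0.5 / 1.1, abs=0.01)
        assert row.r_pgp == pytest.approx(0.1 / 1.1, abs=0.01)
        # matches the score computed directly from the truth parameters
        direct = r_contribution(GenotypeTriplet(0.5, 1.0, 0.6))
        assert row.r_bcrp == pytest.approx(direct.r_bcrp, abs=0.01)

    def test_fafg_and_ka_recovery_noiseless_dense(self, sim_spec, noiseless_truths):
        df = simulate_study(noiseless_truths, n_animals=1, schedule=DENSE_SCHEDULE)
        res = PSDifferenceModel.from_dataframe(df, sim_spec).fit()
        ab = res.absorption.set_index("genotype")
        for g, truth in noiseless_truths.items():
            assert ab.loc[Genotype(g).value, "fafg"] == pytest.approx(
                truth.fafg, rel=0.02
            )
            assert ab.loc[Genotype(g).value, "ka"] == pytest.approx(
                truth.ka, rel=1e-4
            )
            assert ab.loc[Genotype(g).value, "fh"] == pytest.approx(
                truth.fh, rel=0.03
            )
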