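"""Safe space and VBE campaigns: CI-rule compliance, monotonicity, seeding."""

import numpy as np
import pytest

from ibupbbm import be_stats
from ibupbbm.population_vbe import ParameterVariability, TrialDesign, default_variability_spec
from ibupbbm.synthetic_data import SyntheticPopulationSpec, generate_pk_dataset
from ibupbbm.vbe_engine import (
    VBECampaign,
    map_safe_space,
    run_vbe_campaign,
    success_rate_vs_power_check,
)


@pytest.fixture(scope="module")
def safe_space(drug, psd_small):
    return map_safe_space(
        6.02, [5.5, 5.7, 5.9, 6.1, 6.3], drug, psd_small,
        design=TrialDesign(n_subjects=24, seed=1),
    )


class TestSafeSpace:
    def test_reference_point_inside(self, safe_space):
        lo, hi = safe_space.safe_interval["R"]
        assert lo <= 6.02 <= hi

    def test_gmr_monotone_in_test_surface_pH(self, safe_space):
        for analyte in ("R", "S", "racemate"):
            g = safe_space.gmr_pct[analyte]
            assert np.all(np.diff(g) >= -1e-6)

    def test_interval_respects_ci_rule_on_grid(self, safe_space):
        lo, hi = safe_space.safe_interval["R"]
        inside = (safe_space.grid_pH >= lo - 1e-9) & (safe_space.grid_pH <= hi + 1e-9)
        ci = safe_space.ci90_pct["R"]
        assert np.all(ci[inside, 0] >= 80.0)
        assert np.all(ci[inside, 1] <= 125.0)

    def test_r_enantiomer_more_discriminative(self, safe_space):
        """The R interval is no wider than the S interval."""
        r_lo, r_hi = safe_space.safe_interval["R"]
        s_lo, s_hi = safe_space.safe_interval["S"]
        assert (r_hi - r_lo) <= (s_hi - s_lo) + 1e-9

    def test_equal_products_gmr_unity(self, drug, psd_small):
        ss = map_safe_space(6.0, [6.0], drug, psd_small)
        assert ss.gmr_pct["R"][0] == pytest.approx(100.0, abs=1e-6)
        lo, hi = ss.safe_interval["R"]
        assert lo <= 6.0 <= hi

    def test_empty_safe_space_is_none_not_error(self, drug, psd_small):
        ss = map_safe_space(6.02, [4.8, 5.0], drug, psd_small)
        assert ss.safe_interval["R"] is None

    def test_larger_cv_shrinks_safe_space(self, drug, psd_small, monkeypatch):
        """Doubling the planning WSV CV widens CIs and shrinks the interval."""
        import ibupbbm.vbe_engine as ve

        grid = [5.5, 5.7, 5.9, 6.1, 6.3]
        base = map_safe_space(6.02, grid, drug, psd_small)
        doubled = {a: 2 * cv for a, cv in ve.INVIVO_WSV_CV.items()}
        monkeypatch.setattr(ve, "INVIVO_WSV_CV", doubled)
        wide_cv = map_safe_space(6.02, grid, drug, psd_small)
        b_lo, b_hi = base.safe_interval["R"]
        if wide_cv.safe_interval["R"] is None:
            return
        w_lo, w_hi = wide_cv.safe_interval["R"]
        assert (w_hi - w_lo) <= (b_hi - b_lo) + 1e-9


class TestCampaign:
    def test_layout_validation(self):
        c = VBECampaign(n_subjects=12, runs=2, replicates=3)
        assert c.n_total == 6
        with pytest.raises(ValueError):
            VBECampaign(n_subjects=12, runs=0, replicates=5)

    def test_seeds_distinct_and_recorded(self):
        c = VBECampaign(n_subjects=12, runs=3, replicates=4, base_seed=7)
        seeds = {c.seed_for(r, k) for r in range(1, 4) for k in range(1, 5)}
        assert len(seeds) == 12

    def test_identical_products_no_wsv_always_pass(self, drug, psd_small):
        spec = {
            name: ParameterVariability(p.central, 0.0, p.lo, p.hi, wsv=p.wsv)
            for name, p in default_variability_spec().items()
        }
        camp = VBECampaign(n_subjects=4, runs=1, replicates=2, base_seed=3)
        res = run_vbe_campaign(camp, 6.02, 6.02, drug, psd_small, variability=spec)
        for analyte in ("R", "S", "racemate"):
            assert res.success_rate_pct[analyte] == 100.0

    def test_hopeless_product_always_fails(self, drug, psd_small):
        camp = VBECampaign(n_subjects=4, runs=1, replicates=2, base_seed=3)
        res = run_vbe_campaign(camp, 4.8, 6.02, drug, psd_small)
        for analyte in ("R", "S"):
            assert res.success_rate_pct[analyte] == 0.0

    def test_per_run_rates_average_to_campaign_rate(self, drug, psd_small):
        camp = VBECampaign(n_subjects=4, runs=2, replicates=2, base_seed=9)
        res = run_vbe_campaign(camp, 6.0, 6.02, drug, psd_small)
        for analyte, per_run in res.per_run_success_pct.items():
            assert np.mean(per_run) == pytest.approx(res.success_rate_pct[analyte])

    def test_campaign_deterministic(self, drug, psd_small):
        camp = VBECampaign(n_subjects=4, runs=1, replicates=2, base_seed=11)
        r1 = run_vbe_campaign(camp, 5.9, 6.02, drug, psd_small)
        r2 = run_vbe_campaign(camp, 5.9, 6.02, drug, psd_small)
        assert r1.records.equals(r2.records)


class TestSuccessVsPower:
    def test_lognormal_trials_match_closed_form_power(self):
        """Trials drawn exactly from the lognormal model succeed at the
        closed-form TOST power rate (self-consistency, n=74, GMR 0.85)."""
        n_trials = 800
        wins = 0
        for k in range(n_trials):
            ds = generate_pk_dataset(
                SyntheticPopulationSpec(n_subjects=74, seed=50_000 + k),
                0.85, 14.89, 20.0,
            )
            lt, lr = ds.paired_logs()
            wins += be_stats.crossover_be(lt, lr).decision
        rate = 100.0 * wins / n_trials
        report = success_rate_vs_power_check(rate, n_trials, 0.85, 14.89, 74)
        assert report["power_inside_binomial_ci"]

    def test_binomial_band_arithmetic(self):
        report = success_rate_vs_power_check(80.0, 100, 0.85, 14.89, 74)
        # ~ +/- 8 points at N=100, p=0.8
        assert report["binomial_ci_lo_pct"] == pytest.approx(70.8, abs=1.0)
        assert report["binomial_ci_hi_pct"] == pytest.approx(87.3, abs=1.0)

    def test_mechanistic_report_smoke(self, drug, psd_small):
        camp = VBECampaign(n_subjects=4, runs=1, replicates=2, base_seed=13)
        res = run_vbe_campaign(camp, 5.9, 6.02, drug, psd_small)
        report = success_rate_vs_power_check(
            res.success_rate_pct["R"], camp.n_total, 0.9, 14.89, camp.n_subjects
        )
        assert set(report) >= {
            "success_rate_pct", "closed_form_power_pct", "discrepancy_pct_points",
        }
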