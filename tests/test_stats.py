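"""Statistical layer: SMDs, Sidak, paired tests, screening, control-knee
selection, mixed-model EMMs, contrasts and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from kneeqmri.cohort import generate_cohort
from kneeqmri.config import SimulationConfig
from kneeqmri.stats import (CovariateScreen, build_analysis_table,
                            compute_change, effect_size_d, estimate_emms,
                            fit_change_model, paired_bilateral_test,
                            pairwise_contrasts_sidak, screen_covariates,
                            select_control_knee, sidak_adjust, smd)


class TestSmd:
    @pytest.mark.parametrize("a, b, expected", [
        ((53.5, 5.5, 14), (51.3, 6.5, 21), 0.36),   # age, older band
        ((68.2, 12.5, 14), (70.2, 11.4, 21), -0.17),  # body mass
        ((24.3, 2.6, 14), (23.7, 4.3, 21), 0.16),   # BMI
    ])
    def test_characteristic_comparisons(self, a, b, expected):
        assert round(smd(*a, *b), 2) == expected

    def test_equal_means_zero(self):
        assert smd(10.0, 2.0, 5, 10.0, 3.0, 7) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            smd(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestSidak:
    def test_closed_form(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625, abs=1e-9)

    def test_boundaries(self):
        assert sidak_adjust(0.0, 3) == 0.0
        assert sidak_adjust(1.0, 3) == 1.0

    def test_monotone_in_p_and_k(self):
        ps = np.linspace(0, 1, 101)
        adj = sidak_adjust(ps, 3)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= ps)
        for p in (0.01, 0.2, 0.7):
            vals = [sidak_adjust(p, k) for k in range(1, 8)]
            assert np.all(np.diff(vals) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.5, 3)


class TestPairedBilateral:
    def test_identical_vectors(self):
        res = paired_bilateral_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.zero_variance

    def test_known_t_statistic(self):
        """Differences {1,2,3,4}: t = 2.5 / (1.2910/2) = 3.873."""
        res = paired_bilateral_test([2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert 0 < res.p < 0.05

    def test_swap_negates_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        r1 = paired_bilateral_test(a, b)
        r2 = paired_bilateral_test(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_qq_export_shape(self, rng):
        res = paired_bilateral_test(rng.normal(size=20), rng.normal(size=20))
        assert set(res.qq.columns) == {"theoretical", "sample"}
        assert len(res.qq) == 20

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="n >= 3"):
            paired_bilateral_test([1.0, 2.0], [1.0, 2.0])


class TestScreenCovariates:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        s = screen_covariates(2.0 * x, x)
        assert s.slope == pytest.approx(2.0, rel=1e-12)
        assert s.p < 1e-10

    def test_constant_covariate_flagged(self):
        s = screen_covariates([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert s.constant_covariate and np.isnan(s.slope)

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="n >= 3"):
            screen_covariates([1.0, 2.0], [0.0, 1.0])

    def test_null_simulation_slope_within_3se(self, rng):
        """Independent covariate: |slope| < 3 SE in at least 95 % of
        replicates."""
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            s = screen_covariates(y, x)
            hits += abs(s.slope) < 3 * s.se
        assert hits / reps >= 0.95


class TestSelectControlKnee:
    def test_even_stratum_balanced(self):
        cfg = SimulationConfig(seed=8)
        cfg.n_per_group = {"ACL": {"20-30": 0, "40-60": 0},
                           "HEA": {"20-30": 12, "40-60": 0}}
        participants, _ = generate_cohort(cfg)
        sel = select_control_knee(participants, seed=1)
        for sex in ("F", "M"):
            ids = [p.id for p in participants if p.sex == sex]
            lefts = sum(sel[i] == "left" for i in ids)
            assert abs(lefts - len(ids) / 2) <= 0.5

    def test_balance_on_default_cohort(self, default_cohort):
        _, participants, _ = default_cohort
        sel = select_control_knee(participants, seed=3)
        hea = [p for p in participants if p.group == "HEA"]
        assert set(sel) == {p.id for p in hea}
        for age_group in ("20-30", "40-60"):
            for sex in ("F", "M"):
                ids = [p.id for p in hea
                       if p.age_group == age_group and p.sex == sex]
                if not ids:
                    continue
                lefts = sum(sel[i] == "left" for i in ids)
                assert lefts in (len(ids) // 2, (len(ids) + 1) // 2)

    def test_deterministic_under_seed(self, default_cohort):
        _, participants, _ = default_cohort
        assert select_control_knee(participants, 7) == \
            select_control_knee(participants, 7)


class TestComputeChange:
    def _measures(self, baseline, followup, measure="thickness", units="mm"):
        rows = []
        for visit, value, day in (("baseline", baseline, 9.0),
                                  ("followup", followup, 11.5)):
            rows.append({"participant_id": "P1", "knee_id": "P1_R",
                         "role": "ACL_in", "group": "ACL", "age_group": "20-30",
                         "sex": "F", "side": "right", "age": 25.0,
                         "visit": visit, "daytime_h": day, "measure": measure,
                         "location": "iLT", "layer": "total", "value": value,
                         "units": units})
        return pd.DataFrame(rows)

    def test_thickness_change_in_micrometers(self):
        out = compute_change(self._measures(2.20, 2.15))
        assert out.change.iloc[0] == pytest.approx(-50.0, abs=1e-9)
        assert out.baseline.iloc[0] == pytest.approx(2200.0)
        assert out.units.iloc[0] == "um"
        assert out.daytime_diff_h.iloc[0] == pytest.approx(2.5)

    def test_identical_visits_zero_change(self):
        out = compute_change(self._measures(2.0, 2.0))
        assert out.change.iloc[0] == 0.0

    def test_t2_change_in_ms(self):
        out = compute_change(self._measures(30.0, 30.8, measure="t2",
                                            units="ms"))
        assert out.change.iloc[0] == pytest.approx(0.8, abs=1e-9)
        assert out.units.iloc[0] == "ms"

    def test_missing_visit_excluded(self):
        m = self._measures(2.0, 2.1)
        m = m[m.visit == "baseline"]
        with pytest.raises(ValueError, match="both visits"):
            compute_change(m)


def _synthetic_change_table(rng, n_per_group=20, means=(0.0, 0.0, 0.0),
                            sd=50.0, paired=False):
    rows = []
    pid = 0
    for g, mu in zip(("ACL_in", "ACL_unin", "HEA"), means):
        for _ in range(n_per_group):
            pid += 1
            rows.append({"participant_id": f"S{pid:03d}", "knee_group": g,
                         "change": rng.normal(mu, sd),
                         "age": rng.uniform(20, 60),
                         "daytime_diff_h": rng.uniform(-6, 6),
                         "baseline": rng.normal(2000, 200)})
    return pd.DataFrame(rows)


def _paired_change_table(rng, truth=(-46.0, -46.0, -13.0), n_acl=34,
                         n_hea=44, tau=40.0, sigma=58.0):
    """The study design: ACL participants contribute both knees through a
    shared intercept, healthy participants one knee."""
    tmap = dict(zip(("ACL_in", "ACL_unin", "HEA"), truth))
    rows = []
    for i in range(n_acl):
        u = rng.normal(0, tau)
        for g in ("ACL_in", "ACL_unin"):
            rows.append({"participant_id": f"A{i}", "knee_group": g,
                         "change": tmap[g] + u + rng.normal(0, sigma),
                         "age": rng.uniform(20, 60),
                         "daytime_diff_h": rng.uniform(-6, 6),
                         "baseline": rng.normal(2000, 200)})
    for i in range(n_hea):
        rows.append({"participant_id": f"H{i}", "knee_group": "HEA",
                     "change": tmap["HEA"] + rng.normal(0, tau)
                     + rng.normal(0, sigma),
                     "age": rng.uniform(20, 60),
                     "daytime_diff_h": rng.uniform(-6, 6),
                     "baseline": rng.normal(2000, 200)})
    return pd.DataFrame(rows)


class TestMixedModelEmms:
    def test_collapsing_case_emms_equal_raw_means(self, rng):
        """No covariates, independent knees: EMMs are the raw group means."""
        tab = _synthetic_change_table(rng, means=(-40.0, -30.0, -10.0))
        fit = fit_change_model(tab, adjust_age=False, adjust_daytime=False,
                               adjust_baseline=False)
        emms = estimate_emms(fit)
        raw = tab.groupby("knee_group").change.mean()
        for _, r in emms.frame.iterrows():
            assert r.emm == pytest.approx(raw[r.group], abs=1e-6)

    def test_covariate_centering_invariance_of_contrasts(self, rng):
        tab = _synthetic_change_table(rng, means=(-40.0, -30.0, -10.0))
        shifted = tab.assign(age=tab.age + 25.0, baseline=tab.baseline + 500.0)
        c1 = pairwise_contrasts_sidak(estimate_emms(fit_change_model(tab)))
        c2 = pairwise_contrasts_sidak(estimate_emms(fit_change_model(shifted)))
        np.testing.assert_allclose(c1.estimate, c2.estimate, atol=1e-6)

    def test_duplicated_data_same_estimates_smaller_se(self):
        """Doubling the cohort (fresh participant ids) leaves the EMMs and
        the variance components unchanged but shrinks their SEs."""
        tab = _paired_change_table(np.random.default_rng(31))
        dup = pd.concat([tab, tab.assign(
            participant_id=tab.participant_id + "b")], ignore_index=True)
        f1, f2 = fit_change_model(tab), fit_change_model(dup)
        assert f1.model_type == f2.model_type == "mixed"
        e1 = estimate_emms(f1).frame.set_index("group")
        e2 = estimate_emms(f2).frame.set_index("group")
        for g in ("ACL_in", "ACL_unin", "HEA"):
            # REML variance components shift marginally, moving the GLS
            # weights; the EMMs agree to a small fraction of their SE
            assert e2.loc[g, "emm"] == pytest.approx(e1.loc[g, "emm"], abs=0.1)
            assert e2.loc[g, "se"] == pytest.approx(
                e1.loc[g, "se"] / np.sqrt(2), rel=0.05)

    def test_null_model_group_effects_near_zero(self, rng):
        """No group effect: every EMM within 3 SE of zero."""
        tab = _synthetic_change_table(rng, n_per_group=40)
        emms = estimate_emms(fit_change_model(tab))
        for _, r in emms.frame.iterrows():
            assert abs(r.emm) < 3 * r.se

    def test_parameter_recovery_with_random_intercepts(self):
        """Paired ACL knees sharing a participant intercept: fixed effects
        recovered within 3 SE of the injected truth."""
        truth = {"ACL_in": -46.0, "ACL_unin": -46.0, "HEA": -13.0}
        fit = fit_change_model(_paired_change_table(np.random.default_rng(77)))
        assert fit.model_type == "mixed"
        assert fit.tau2 >= 0 and fit.sigma2 > 0
        emms = estimate_emms(fit)
        for _, r in emms.frame.iterrows():
            assert abs(r.emm - truth[r.group]) < 3 * r.se

    def test_sidak_at_least_raw_p(self, rng):
        tab = _synthetic_change_table(rng, means=(-60.0, -20.0, 0.0))
        cons = pairwise_contrasts_sidak(estimate_emms(fit_change_model(tab)))
        assert np.all(cons.p_sidak >= cons.p - 1e-15)
        assert np.all(np.isclose(cons.p_sidak, 1 - (1 - cons.p) ** 3))

    def test_contrast_equals_emm_difference(self, rng):
        tab = _synthetic_change_table(rng, means=(-60.0, -20.0, 0.0))
        emms = estimate_emms(fit_change_model(tab))
        cons = pairwise_contrasts_sidak(emms).set_index("contrast")
        assert cons.loc["ACL_in-HEA", "estimate"] == pytest.approx(
            emms.emm("ACL_in") - emms.emm("HEA"), rel=1e-10)

    def test_single_group_rejected(self, rng):
        tab = _synthetic_change_table(rng)
        with pytest.raises(ValueError, match="two knee groups"):
            fit_change_model(tab[tab.knee_group == "HEA"])


class TestEffectSize:
    def test_zero_difference_zero_d(self, rng):
        tab = _synthetic_change_table(rng)
        d, lo, hi = effect_size_d(0.0, tab, "ACL_in", "HEA", n_boot=0)
        assert d == 0.0

    def test_known_ratio(self, rng):
        """EMM difference 33 um over pooled change-SD 57 um: d = 0.579."""
        tab = _synthetic_change_table(rng, n_per_group=30)
        for g in ("ACL_in", "HEA"):
            sel = tab.knee_group == g
            x = tab.loc[sel, "change"]
            tab.loc[sel, "change"] = (x - x.mean()) / x.std(ddof=1) * 57.0
        d, _, _ = effect_size_d(33.0, tab, "ACL_in", "HEA", n_boot=0)
        assert d == pytest.approx(0.579, abs=0.001)

    def test_sign_flips_with_group_order(self, rng):
        tab = _synthetic_change_table(rng)
        d1, _, _ = effect_size_d(20.0, tab, "ACL_in", "HEA", n_boot=0)
        d2, _, _ = effect_size_d(-20.0, tab, "HEA", "ACL_in", n_boot=0)
        assert d1 == pytest.approx(-d2, rel=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        tab = _synthetic_change_table(rng, means=(-60.0, -20.0, 0.0),
                                      n_per_group=30)
        raw_diff = (tab[tab.knee_group == "ACL_in"].change.mean()
                    - tab[tab.knee_group == "HEA"].change.mean())
        d, lo, hi = effect_size_d(raw_diff, tab, "ACL_in", "HEA",
                                  n_boot=300, seed=4)
        assert lo < d < hi


def test_analysis_table_group_structure(analysis_table):
    """34 injured, 34 contralateral and 44 selected healthy knees per
    location; OV rows attached for thickness."""
    ftj = analysis_table[(analysis_table.measure == "thickness")
                         & (analysis_table.location == "FTJ")]
    assert ftj.knee_group.value_counts().to_dict() == \
        {"HEA": 44, "ACL_in": 34, "ACL_unin": 34}
    ov1 = analysis_table[analysis_table.location == "OV1"]
    assert len(ov1) == 112
    # OV1 is the per-knee minimum over the 16 subregional changes
    from kneeqmri.regions import SUBREGIONS
    sub = analysis_table[(analysis_table.measure == "thickness")
                         & analysis_table.location.isin(SUBREGIONS)]
    mins = sub.groupby("knee_id").change.min()
    ov1_vals = ov1.set_index("knee_id").change
    np.testing.assert_allclose(ov1_vals.sort_index(), mins.sort_index(),
                               rtol=1e-12)
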