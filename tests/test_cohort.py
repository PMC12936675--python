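"""Synthetic cohort generator: counts, determinism, truth injection,
forward signal model and rendered geometry."""

import dataclasses

import numpy as np
import pytest

from kneeqmri.cohort import (generate_cohort, qdess_forward,
                             render_knee_image, truth_regional_measures)
from kneeqmri.config import ConfigError, SimulationConfig
from kneeqmri.regions import PLATES, SUBREGIONS
from kneeqmri.t2_mapping import estimate_t2_map, estimate_t2_voxel, summarize_t2


def _noise_free_config(**overrides) -> SimulationConfig:
    zero_changes = {g: {s: 0.0 for s in SUBREGIONS}
                    for g in ("ACL_in", "ACL_unin", "HEA")}
    zero_t2 = {r: {l: {g: 0.0 for g in ("ACL_in", "ACL_unin", "HEA")}
                   for l in ("deep", "superficial")} for r in PLATES}
    base = dict(
        true_change_by_group_and_subregion=zero_changes,
        t2_change_by_group_region_layer=zero_t2,
        sd_baseline_mm=0.0, sd_random_intercept=0.0, sd_residual=0.0,
        sd_t2_baseline_ms=0.0, sd_t2_intercept_ms=0.0,
        sd_t2_residual_ms={"deep": 0.0, "superficial": 0.0},
        beta_age=0.0, beta_daytime=0.0, beta_baseline=0.0,
        noise_sd_signal=0.0)
    base.update(overrides)
    return SimulationConfig(**base).validate()


class TestConfigValidation:
    @pytest.mark.parametrize("field, value, fragment", [
        ("te_ms", 25.0, "te_ms"),
        ("noise_sd_signal", -0.1, "noise_sd_signal"),
        ("voxel_spacing", (0.3, -0.3, 1.5), "voxel_spacing"),
        ("sd_residual", -1.0, "sd_residual"),
    ])
    def test_invalid_field_named_in_error(self, field, value, fragment):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigError, match=fragment):
            cfg.validate()

    def test_missing_subregion_named(self):
        cfg = SimulationConfig()
        del cfg.baseline_thickness_by_subregion["iLT"]
        with pytest.raises(ConfigError, match="iLT"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, tr_ms=18.0)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGenerateCohort:
    def test_published_group_sizes(self):
        """20/23/14/21 per cell gives 78 participants and 156 knees."""
        cfg = SimulationConfig()
        participants, truths = generate_cohort(cfg)
        assert len(participants) == 78
        assert len(truths) == 156
        by_cell = {}
        for p in participants:
            by_cell[(p.group, p.age_group)] = by_cell.get((p.group, p.age_group), 0) + 1
        assert by_cell == {("ACL", "20-30"): 20, ("HEA", "20-30"): 23,
                           ("ACL", "40-60"): 14, ("HEA", "40-60"): 21}

    def test_knee_roles_per_participant(self):
        _, truths = generate_cohort(SimulationConfig())
        roles = {}
        for kt in truths:
            roles.setdefault(kt.participant_id, set()).add(kt.role)
        for pid, rs in roles.items():
            assert rs in ({"ACL_in", "ACL_unin"}, {"HEA_l", "HEA_r"})

    def test_injured_side_only_for_acl(self):
        participants, _ = generate_cohort(SimulationConfig())
        for p in participants:
            assert (p.injured_side == "none") == (p.group == "HEA")

    def test_seeded_determinism(self):
        a = generate_cohort(SimulationConfig(seed=3))
        b = generate_cohort(SimulationConfig(seed=3))
        assert [dataclasses.asdict(p) for p in a[0]] == \
               [dataclasses.asdict(p) for p in b[0]]
        assert [dataclasses.asdict(k) for k in a[1]] == \
               [dataclasses.asdict(k) for k in b[1]]
        c = generate_cohort(SimulationConfig(seed=4))
        assert [dataclasses.asdict(k) for k in c[1]] != \
               [dataclasses.asdict(k) for k in a[1]]

    def test_degenerate_noise_free_case(self):
        """Zero change terms and zero SDs: follow-up equals baseline."""
        _, truths = generate_cohort(_noise_free_config())
        for kt in truths:
            assert kt.thickness_followup_mm == kt.thickness_baseline_mm
            assert kt.t2_followup_ms == kt.t2_baseline_ms

    def test_monte_carlo_change_converges_to_truth(self):
        """Mean generated change approaches the configured group truth."""
        cfg = SimulationConfig(seed=99, beta_age=0.0, beta_daytime=0.0,
                               beta_baseline=0.0)
        cfg.n_per_group = {"ACL": {"20-30": 250, "40-60": 0},
                           "HEA": {"20-30": 0, "40-60": 0}}
        _, truths = generate_cohort(cfg)
        changes = np.array([
            (kt.thickness_followup_mm["iLT"] - kt.thickness_baseline_mm["iLT"]) * 1000
            for kt in truths if kt.role == "ACL_in"])
        assert changes.size == 250
        truth = cfg.true_change_by_group_and_subregion["ACL_in"]["iLT"]
        se = np.sqrt(cfg.sd_random_intercept**2 + cfg.sd_residual**2) / np.sqrt(250)
        assert abs(changes.mean() - truth) < 3 * se


class TestQdessForward:
    def test_closed_form_example(self):
        s1, s2 = qdess_forward(40.0, 20.0, 6.0, 1.0)
        assert s1 == 1.0
        assert s2 == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_long_t2_limit(self):
        _, s2 = qdess_forward(1e9, 20.0, 6.0, 2.5)
        assert s2 == pytest.approx(2.5, rel=1e-6)

    def test_second_echo_always_smaller(self, rng):
        t2 = rng.uniform(5, 200, 100)
        s1, s2 = qdess_forward(t2, 20.0, 6.0, 3.0)
        assert np.all(s2 < s1)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(ValueError, match="t2"):
            qdess_forward(0.0, 20.0, 6.0, 1.0)

    def test_forward_inverse_round_trip(self):
        """Noise-free inversion recovers T2 to <= 1e-9 relative error."""
        t2_grid = np.linspace(10.0, 100.0, 91)
        s1, s2 = qdess_forward(t2_grid, 20.0, 6.0, 1.0)
        est, reason = estimate_t2_voxel(s1, s2, 20.0, 6.0)
        assert np.all(reason == 0)
        assert np.max(np.abs(est - t2_grid) / t2_grid) <= 1e-9


class TestRenderKneeImage:
    def test_uniform_thickness_column_heights(self):
        """2.4 mm truth at 0.15 mm depth spacing: 16 voxels per column."""
        cfg = _noise_free_config(thickness_modulation_mm=0.0)
        cfg.baseline_thickness_by_subregion = {s: 2.4 for s in SUBREGIONS}
        _, truths = generate_cohort(cfg)
        img = render_knee_image(truths[0], cfg, spacing=(0.6, 0.6, 0.15))
        for plate, occ in img.plate_masks.items():
            counts = occ.sum(axis=2)
            assert set(np.unique(counts[counts > 0])) == {16}

    def test_plates_disjoint_and_nonempty(self, default_cohort):
        cfg, _, truths = default_cohort
        img = render_knee_image(truths[0], cfg, spacing=(0.8, 0.8, 0.25))
        total = np.zeros(img.echo1.shape, dtype=int)
        for occ in img.plate_masks.values():
            assert occ.any()
            total += occ
        assert total.max() == 1

    def test_voxelized_thickness_within_half_voxel_of_target(self, default_cohort):
        """Rounding the continuous thickness field to whole voxels never
        moves a column by more than half a slice."""
        cfg, _, truths = default_cohort
        dz = 0.25
        img = render_knee_image(truths[2], cfg, spacing=(0.8, 0.8, dz))
        for plate in img.plate_masks:
            vt = img.voxel_thickness_mm[plate]
            tt = img.target_thickness_mm[plate]
            ok = np.isfinite(vt)
            assert ok.any()
            assert np.nanmax(np.abs(vt[ok] - tt[ok])) <= dz / 2 + 1e-12
        # and the smoothed field stays within the modulation amplitude of
        # the subregional plateaus away from plateau boundaries
        labels = img.atlas_labels["MT"]
        tt = img.target_thickness_mm["MT"]
        center = labels == "cMT"
        truth = truths[2].thickness_baseline_mm["cMT"]
        assert abs(np.nanmedian(tt[center]) - truth) < \
            cfg.thickness_modulation_mm + 0.15

    def test_noise_free_t2_recovery_per_layer(self, default_cohort):
        """The imaging chain returns the configured layer T2 exactly."""
        cfg, _, truths = default_cohort
        cfg_nf = SimulationConfig(**{**dataclasses.asdict(cfg),
                                     "noise_sd_signal": 0.0})
        cfg_nf.age_ranges = {k: tuple(v) for k, v in cfg_nf.age_ranges.items()}
        img = render_knee_image(truths[0], cfg_nf, spacing=(0.8, 0.8, 0.25))
        t2map = estimate_t2_map(img.echo1, img.echo2, img.mask,
                                cfg_nf.tr_ms, cfg_nf.te_ms)
        summary = summarize_t2(t2map)
        for plate in PLATES:
            for layer in ("deep", "superficial"):
                assert summary.get(plate, layer) == pytest.approx(
                    img.true_t2_ms[plate][layer], rel=1e-10)

    def test_subvoxel_thickness_rejected(self):
        cfg = _noise_free_config(thickness_modulation_mm=0.0)
        cfg.baseline_thickness_by_subregion = {s: 0.5 for s in SUBREGIONS}
        _, truths = generate_cohort(cfg)
        with pytest.raises(ValueError, match="finer"):
            render_knee_image(truths[0], cfg, spacing=(0.8, 0.8, 1.5))

    def test_render_determinism(self, default_cohort):
        cfg, _, truths = default_cohort
        a = render_knee_image(truths[1], cfg, spacing=(0.8, 0.8, 0.25),
                              rng=np.random.default_rng(5))
        b = render_knee_image(truths[1], cfg, spacing=(0.8, 0.8, 0.25),
                              rng=np.random.default_rng(5))
        assert np.array_equal(a.echo1, b.echo1)
        assert np.array_equal(a.echo2, b.echo2)


def test_truth_measures_aggregation(default_cohort):
    """Compartment rules: MFTC = MT + cMF, FTJ = (MFTC + LFTC)/2 for
    thickness; unweighted region means for T2."""
    cfg, participants, truths = default_cohort
    m = truth_regional_measures(participants, truths)
    one = m[(m.knee_id == truths[0].knee_id) & (m.visit == "baseline")]
    th = one[one.measure == "thickness"].set_index("location").value
    assert th["MFTC"] == pytest.approx(th["MT"] + th["cMF"], rel=1e-12)
    assert th["LFTC"] == pytest.approx(th["LT"] + th["cLF"], rel=1e-12)
    assert th["FTJ"] == pytest.approx((th["MFTC"] + th["LFTC"]) / 2, rel=1e-12)
    t2 = one[one.measure == "t2"].set_index(["location", "layer"]).value
    for layer in ("total", "deep", "superficial"):
        assert t2["MFTC", layer] == pytest.approx(
            (t2["MT", layer] + t2["cMF", layer]) / 2, rel=1e-12)
        assert t2["FTJ", layer] == pytest.approx(
            np.mean([t2[p, layer] for p in PLATES]), rel=1e-12)
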