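"""Synthetic cohort generator: calibration, GA-effect solver, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from neocardio.cohort import (
    default_calibration,
    generate_cohort,
    read_cohort_csv,
    solve_ga_effect,
    truncnorm_mean_matched,
    write_cohort_csv,
)
from neocardio.config import GeneratorConfig


class TestDefaultCalibration:
    def test_group_sizes(self, default_cfg):
        assert default_cfg.n_preterm == 121
        assert default_cfg.n_term == 134

    def test_gestational_age_distributions(self, default_cfg):
        assert default_cfg.ga_birth["preterm"].mean == 33.9
        assert default_cfg.ga_birth["preterm"].sd == 2.2
        assert default_cfg.ga_birth["term"].mean == 39.4
        assert default_cfg.ga_birth["term"].sd == 1.3

    @pytest.mark.parametrize("group, measure, mean, sd", [
        ("preterm", "lvmi", 18.8, 3.9),
        ("term", "lvmi", 20.7, 3.9),
        ("preterm", "lv_edvi", 16.8, 5.5),
        ("term", "rv_edvi", 14.7, 5.7),
        ("preterm", "rvmi", 16.3, 5.6),
        ("preterm", "ivsd", 0.33, 0.08),
        ("term", "tapse", 0.9, 0.2),
        ("preterm", "lat_e_prime", 6.1, 1.8),
    ])
    def test_birth_echo_cells(self, default_cfg, group, measure, mean, sd):
        n = default_cfg.echo_birth[group][measure]
        assert (n.mean, n.sd) == (mean, sd)

    def test_followup_echo_cells(self, default_cfg):
        assert default_cfg.echo_followup["preterm"]["lv_edvi"].mean == 27.6
        assert default_cfg.echo_followup["term"]["tapse"].mean == 1.5

    def test_config_is_valid_and_round_trips_json(self, default_cfg, tmp_path):
        default_cfg.validate()
        p = tmp_path / "cfg.json"
        default_cfg.to_json(p)
        back = GeneratorConfig.from_json(str(p))
        assert back.ga_effect["lv"].beta == pytest.approx(
            default_cfg.ga_effect["lv"].beta)
        assert back.echo_birth["preterm"]["lvmi"].mean == 18.8

    def test_invalid_configs_rejected(self, default_cfg):
        import dataclasses

        bad = dataclasses.replace(default_cfg, n_preterm=1)
        with pytest.raises(ValueError):
            bad.validate()
        bad = dataclasses.replace(default_cfg)
        bad.covariate_probs = {**bad.covariate_probs,
                               "preterm": {"steroids": 1.4}}
        with pytest.raises(ValueError):
            bad.validate()


class TestSolveGAEffect:
    def test_beta_closed_form(self):
        eff = solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3,
                              121 / 255, -0.49)
        assert eff.beta == pytest.approx((57.8 - 27.3) / (33.9 - 39.4),
                                         rel=1e-12)
        assert eff.beta == pytest.approx(-5.545, abs=1e-3)

    def test_sigma_eps_closed_form(self):
        eff = solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3,
                              121 / 255, -0.49)
        assert eff.sigma_eps == pytest.approx(32.3, abs=0.1)

    def test_group_means_exact(self):
        eff = solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3,
                              121 / 255, -0.49)
        assert eff.alpha + eff.beta * 33.9 == pytest.approx(57.8)
        assert eff.alpha + eff.beta * 39.4 == pytest.approx(27.3)

    def test_equal_means_force_zero_slope(self):
        eff = solve_ga_effect(30.0, 30.0, 33.9, 39.4, 2.2, 1.3, 0.5, -0.5)
        assert eff.beta == 0.0

    def test_sign_conflict_raises(self):
        with pytest.raises(ValueError):
            solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3, 0.5, +0.49)

    def test_r_out_of_range_raises(self):
        with pytest.raises(ValueError):
            solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3, 0.5, -1.0)

    def test_monte_carlo_correlation_oracle(self, rng):
        # brute-force check: simulate the stated mixture model and verify
        # the population correlation and group means
        eff = solve_ga_effect(57.8, 27.3, 33.9, 39.4, 2.2, 1.3,
                              121 / 255, -0.49)
        n = 400_000
        pre = rng.random(n) < 121 / 255
        ga = np.where(pre, rng.normal(33.9, 2.2, n), rng.normal(39.4, 1.3, n))
        d = eff.alpha + eff.beta * ga + rng.normal(0, eff.sigma_eps, n)
        assert np.corrcoef(ga, d)[0, 1] == pytest.approx(-0.49, abs=0.01)
        assert d[pre].mean() == pytest.approx(57.8, abs=0.3)
        assert d[~pre].mean() == pytest.approx(27.3, abs=0.3)


class TestTruncnormMeanMatched:
    def test_matches_target_mean(self):
        loc, sd = truncnorm_mean_matched(33.9, 2.2, 24.0, 37.0)
        from scipy import stats

        a, b = (24.0 - loc) / 2.2, (37.0 - loc) / 2.2
        assert stats.truncnorm.mean(a, b, loc, 2.2) == pytest.approx(33.9,
                                                                     abs=1e-9)
        assert 0 < sd < 2.2  # truncation shrinks the SD

    def test_degenerate_sd(self):
        assert truncnorm_mean_matched(5.0, 0.0, 0.0, 10.0) == (5.0, 0.0)


class TestGenerateCohort:
    def test_counts_and_visit_structure(self, small_cohort, small_cfg):
        sub = small_cohort.subjects
        assert (sub["group"] == "preterm").sum() == small_cfg.n_preterm
        neon = sub[sub["cohort"] == "neonatal"]
        assert len(neon) == small_cfg.n_preterm + small_cfg.n_term
        counts = small_cohort.visits.groupby("subject_id").size()
        assert (counts.loc[neon["subject_id"]] >= 2).all()

    def test_seed_determinism_byte_identical(self, small_cfg, tmp_path):
        a = generate_cohort(small_cfg, 11)
        b = generate_cohort(small_cfg, 11)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(pa, a)
        write_cohort_csv(pb, b)
        assert pa.read_bytes() == pb.read_bytes()
        for key in a.contours:
            np.testing.assert_array_equal(a.contours[key][0].points,
                                          b.contours[key][0].points)

    def test_different_seed_differs(self, small_cfg, small_cohort):
        other = generate_cohort(small_cfg, 8)
        assert not other.visits["lv_mass"].equals(
            small_cohort.visits["lv_mass"])

    def test_rejects_non_integer_seed(self, small_cfg):
        with pytest.raises(TypeError):
            generate_cohort(small_cfg, 1.5)

    def test_ga_ranges_disjoint(self, small_cohort, small_cfg):
        sub = small_cohort.subjects
        pre = sub.loc[sub["group"] == "preterm", "ga_birth"]
        term = sub.loc[sub["group"] == "term", "ga_birth"]
        assert (pre < small_cfg.preterm_cutoff).all()
        assert (term >= small_cfg.preterm_cutoff).all()

    def test_all_measures_strictly_positive(self, small_cohort):
        v = small_cohort.visits
        for col in ("hc", "lv_mass", "rv_mass"):
            assert (v[col].dropna() > 0).all(), col
        post = v[v["stage"].isin(["birth", "followup"])]
        for col in ("weight", "lv_edv", "lv_esv", "rv_edv", "ivsd", "pwd",
                    "tapse"):
            assert (post[col] > 0).all(), col
        assert (post["lv_esv"] < post["lv_edv"]).all()

    def test_birth_pma_consistent(self, small_cohort):
        t = small_cohort.table()
        birth = t[t["stage"] == "birth"]
        np.testing.assert_allclose(birth["pma"],
                                   birth["ga_birth"] + birth["age_days"] / 7.0)

    def test_fetal_visits_in_window_with_1_to_5_scans(self, small_cohort):
        fet = small_cohort.visits[small_cohort.visits["stage"] == "fetal"]
        assert (fet["pma"] >= 15.0).all()
        assert (fet["pma"] <= 40.0).all()
        per = fet.groupby("subject_id").size()
        assert per.between(1, 5).all()

    def test_hc_monotone_per_subject(self, small_cohort):
        for _, grp in small_cohort.visits.groupby("subject_id"):
            g = grp.sort_values("pma")
            assert (np.diff(g["hc"]) > 0).all()

    def test_followup_mass_index_from_ga_effect(self, small_cfg):
        # per-infant percent change equals the linear-GA model draw, so its
        # correlation with GA is strong and negative even at modest n
        from neocardio.echo import derive_table
        from neocardio.pipeline import percent_changes

        cohort = generate_cohort(small_cfg, 3, with_contours=False)
        pct = percent_changes(derive_table(cohort.table()))
        r = np.corrcoef(pct["ga_birth"], pct["dlvmi_pct"])[0, 1]
        assert r < -0.2

    def test_contours_only_for_postnatal_visits(self, small_cohort):
        stages = {k[1] for k in small_cohort.contours}
        assert stages <= {"birth", "followup"}

    def test_csv_round_trip(self, small_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        write_cohort_csv(p, small_cohort)
        back = read_cohort_csv(p)
        assert len(back) == len(small_cohort.visits)
        assert {"subject_id", "stage", "pma", "group", "ga_birth"} <= set(
            back.columns)


@pytest.fixture(scope="module")
def big():
    from neocardio.echo import derive_table

    cfg = default_calibration()
    cfg.n_preterm = cfg.n_term = 8000
    cfg.n_fetal = 0
    cfg.n_fetal_overlap = {"preterm": 0, "term": 0}
    cohort = generate_cohort(cfg, 99, with_contours=False)
    return cfg, derive_table(cohort.table())


class TestCalibrationFidelity:
    """Sample moments of generated cohorts track the configured values."""

    @pytest.mark.parametrize("measure", ["lvmi", "rvmi", "lv_edvi", "lv_esvi",
                                         "rv_edvi", "ivsd", "pwd", "tapse",
                                         "lat_e_prime"])
    @pytest.mark.parametrize("group", ["preterm", "term"])
    def test_birth_means_within_3se(self, big, measure, group):
        cfg, d = big
        sub = d[(d["stage"] == "birth") & (d["group"] == group)]
        target = cfg.echo_birth[group][measure]
        se = target.sd / math.sqrt(len(sub))
        assert abs(sub[measure].mean() - target.mean) < 3 * se, measure

    def test_ga_means_match_printed_values(self, big):
        cfg, d = big
        birth = d[d["stage"] == "birth"]
        for group in ("preterm", "term"):
            ga = birth.loc[birth["group"] == group, "ga_birth"]
            se = cfg.ga_birth[group].sd / math.sqrt(len(ga))
            assert abs(ga.mean() - cfg.ga_birth[group].mean) < 3 * se
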