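"""Synthetic cohort generator: calibration, determinism, ground truth."""

import copy

import numpy as np
import pandas as pd
import pytest

from gaitcausal.synthetic import (
    DEFAULT_LINKS,
    ANCHORS,
    GroundTruth,
    SyntheticConfig,
    dataset_summary,
    generate_cohort,
    true_effect_curve,
    true_effect_range,
    true_total_effect,
    write_outputs,
)


def zeroed_power_links() -> dict:
    links = copy.deepcopy(DEFAULT_LINKS)
    p = links["power"]
    for key in ("mass", "mass2", "speed", "age", "height",
                "gdi_amp", "smc_amp", "dmc_amp", "spasticity_amp", "strength_amp",
                "sd"):
        p[key] = 0.0
    return links


class TestGeneration:
    def test_same_seed_reproduces_exactly(self):
        cfg = SyntheticConfig(n=300, seed=7)
        c1, e1, _ = generate_cohort(cfg)
        c2, e2, _ = generate_cohort(SyntheticConfig(n=300, seed=7))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_marginals_match_published_anchors(self):
        cohort, _, _ = generate_cohort(SyntheticConfig(n=5000, seed=42))
        s = dataset_summary(cohort)["Total"]
        assert s["GDI_median"] == pytest.approx(71.1, abs=3.0)
        assert s["MetPower_median"] == pytest.approx(124.2, abs=10.0)
        assert s["Speed_median"] == pytest.approx(0.79, abs=0.1)
        assert s["DMC_median"] == pytest.approx(83.3, abs=3.0)
        assert s["Age_median"] == pytest.approx(9.3, abs=1.0)

    def test_missingness_rates(self):
        cfg = SyntheticConfig(n=5000, seed=3)
        cohort, _, _ = generate_cohort(cfg)
        for col, rate in cfg.missing_rates.items():
            assert cohort[col].isna().mean() == pytest.approx(rate, abs=0.02)

    def test_gmfcs_proportions(self):
        cohort, _, _ = generate_cohort(SyntheticConfig(n=5000, seed=4))
        frac = cohort["GMFCS"].value_counts(normalize=True)
        assert frac["I"] == pytest.approx(0.307, abs=0.03)
        assert frac["II"] == pytest.approx(0.464, abs=0.03)
        assert frac["III"] == pytest.approx(0.229, abs=0.03)

    def test_gmfcs_severity_gradient(self, small_cohort):
        # more severely involved children walk slower and deviate more
        cohort, _, _ = small_cohort
        med = cohort.groupby("GMFCS")[["Speed", "GDI"]].median()
        assert med.loc["I", "Speed"] > med.loc["III", "Speed"]
        assert med.loc["I", "GDI"] > med.loc["III", "GDI"]

    def test_mar_mechanism_ties_dmc_to_gmfcs(self):
        cohort, _, _ = generate_cohort(
            SyntheticConfig(n=6000, seed=5, missing_mechanism="MAR")
        )
        by_level = cohort.assign(miss=cohort["DMC"].isna()).groupby("GMFCS")["miss"].mean()
        assert by_level["III"] > by_level["I"]
        assert cohort["DMC"].isna().mean() == pytest.approx(0.321, abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n=0)
        with pytest.raises(ValueError):
            SyntheticConfig(missing_mechanism="bogus")
        with pytest.raises(ValueError):
            SyntheticConfig(missing_rates={"DMC": 1.5})

    def test_invalid_link_name_rejected(self):
        links = copy.deepcopy(DEFAULT_LINKS)
        links["gdi"]["link"] = "cubic"
        with pytest.raises(ValueError, match="link"):
            generate_cohort(SyntheticConfig(n=50, seed=1, links=links))


class TestExamTable:
    def test_item_counts_and_scales(self, small_cohort):
        cohort, exams, _ = small_cohort
        per = exams.groupby(["domain", "child"]).size()
        assert (per == 12).all()
        for domain, (lo, hi) in {
            "spasticity": (1, 5), "strength": (1, 5), "smc": (0, 2)
        }.items():
            vals = exams.loc[exams["domain"] == domain, "rating"].dropna()
            assert vals.between(lo, hi).all()

    def test_items_track_cohort_scores(self, small_cohort):
        cohort, exams, _ = small_cohort
        mean_item = (
            exams[exams["domain"] == "spasticity"].groupby("child")["rating"].mean()
        )
        joined = cohort.set_index("child").join(mean_item.rename("item_mean"))
        ok = joined[["Spasticity", "item_mean"]].dropna()
        assert np.corrcoef(ok["Spasticity"], ok["item_mean"])[0, 1] > 0.7

    def test_masked_scores_have_incomplete_exams(self, small_cohort):
        cohort, exams, _ = small_cohort
        masked = cohort.loc[cohort["Spasticity"].isna(), "child"]
        sub = exams[(exams["domain"] == "spasticity") & exams["child"].isin(masked)]
        missing_per_child = sub.groupby("child")["rating"].apply(lambda r: r.isna().any())
        assert missing_per_child.all()


class TestGroundTruth:
    def test_zero_power_coefficients_mean_no_effects(self):
        cfg = SyntheticConfig(n=200, seed=2, links=zeroed_power_links())
        cohort, _, truth = generate_cohort(cfg)
        assert cohort["MetPower"].nunique() == 1
        for factor in ("GDI", "DMC", "SMC", "Spasticity", "Strength"):
            assert true_total_effect(truth, factor, -1.0, 1.0, mc_n=2000) == 0.0

    def test_linear_config_matches_path_rule(self):
        links = copy.deepcopy(DEFAULT_LINKS)
        links["gdi"]["link"] = "linear"
        links["power"]["mass2"] = 0.0
        links["power"]["strength_amp"] = 0.0
        for f in ("gdi", "smc", "dmc", "spasticity"):
            links["power"][f"{f}_link"] = "linear"
        truth = GroundTruth(SyntheticConfig(n=100, seed=1, links=links))

        d_dmc = 6.0 / ANCHORS["DMC"][1]  # intervene 80 -> 86 on DMC
        s, g, p = links["speed"], links["gdi"], links["power"]
        d_speed = s["dmc"] * d_dmc
        d_u = g["dmc"] * d_dmc + g["speed"] * d_speed / ANCHORS["Speed"][1]
        d_gdi = g["amp"] * g["gain"] * d_u
        expected = (
            p["speed"] * d_speed
            + p["gdi_amp"] * p["gdi_gain"] * d_gdi / ANCHORS["GDI"][1]
            + p["dmc_amp"] * p["dmc_gain"] * d_dmc
        )
        got = true_total_effect(truth, "DMC", 80.0, 86.0, mc_n=40_000)
        assert got == pytest.approx(expected, rel=0.05)

    def test_default_ordering_gdi_largest(self, small_cohort):
        cohort, _, truth = small_cohort
        ranges = {
            f: true_effect_range(truth, f, cohort[f], mc_n=8000)
            for f in ("GDI", "SMC", "DMC", "Spasticity", "Strength")
        }
        order = sorted(ranges, key=lambda f: -ranges[f])
        assert order == ["GDI", "SMC", "DMC", "Spasticity", "Strength"]

    def test_effect_curve_shares_exogenous_draws(self, small_cohort):
        _, _, truth = small_cohort
        curve = true_effect_curve(truth, "GDI", [60.0, 71.1, 85.0], mc_n=5000)
        assert curve[0] > curve[1] > curve[2]  # worse gait -> higher power
        eff = true_total_effect(truth, "GDI", 60.0, 85.0, mc_n=5000)
        assert eff == pytest.approx(curve[2] - curve[0], abs=1e-9)

    def test_unknown_factor_rejected(self, small_cohort):
        _, _, truth = small_cohort
        with pytest.raises(KeyError, match="intervene"):
            true_total_effect(truth, "Sex", 0, 1)


class TestSummaryAndOutputs:
    def test_single_child_summary(self):
        cohort, _, _ = generate_cohort(SyntheticConfig(n=1, seed=9))
        s = dataset_summary(cohort)["Total"]
        assert s["GDI_median"] == cohort["GDI"].iloc[0] or np.isnan(s["GDI_median"])
        assert s["n"] == 1

    def test_write_outputs_round_trip(self, tmp_path, small_cohort):
        cohort, exams, truth = small_cohort
        write_outputs(cohort, exams, truth, tmp_path)
        reloaded = pd.read_csv(tmp_path / "cohort.csv")
        assert len(reloaded) == len(cohort)
        assert (tmp_path / "exams.csv").exists()
        assert (tmp_path / "truth.json").exists()
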