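"""Polychoric PCA scores, power conversion, normalisation, readers."""

import numpy as np
import pandas as pd
import pytest

from gaitcausal.cohort_scores import (
    J_PER_ML_O2,
    MUSCLE_GROUPS,
    exam_items_wide,
    inverse_zscore,
    net_metabolic_power,
    polychoric_correlation,
    polychoric_matrix,
    read_cohort,
    read_exams,
    summary_score,
    zscore_factors,
)


def ordinal_pair(rng, rho, n=5000, cuts=(-0.5, 0.5)):
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.digitize(z[:, 0], cuts)
    y = np.digitize(z[:, 1], cuts)
    k = len(cuts) + 1
    tab = np.zeros((k, k))
    np.add.at(tab, (x, y), 1)
    return tab


class TestPolychoric:
    def test_independence_near_zero(self, rng):
        margins = np.array([0.2, 0.5, 0.3])
        tab = np.outer(margins, margins) * 10000
        assert abs(polychoric_correlation(tab)) < 0.03

    def test_perfect_concordance_clips(self):
        assert polychoric_correlation(np.diag([5, 5])) > 0.99

    @pytest.mark.parametrize("rho", [-0.7, 0.0, 0.6])
    def test_latent_recovery(self, rng, rho):
        est = polychoric_correlation(ordinal_pair(rng, rho))
        assert abs(est - rho) < 0.05

    def test_antisymmetry_under_category_reversal(self, rng):
        tab = ordinal_pair(rng, 0.6)
        est = polychoric_correlation(tab)
        flipped = polychoric_correlation(tab[::-1, :])
        assert flipped == pytest.approx(-est, abs=0.02)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="one category"):
            polychoric_correlation(np.array([[10, 5], [0, 0]]))


def make_exams(rng, n=400, loading=0.8, domain="spasticity"):
    """Items driven by one latent severity, long format; returns (exams, latent)."""
    latent = rng.normal(0, 1, n)
    rows = []
    cuts = (-1.0, -0.3, 0.5, 1.3)
    for m in MUSCLE_GROUPS:
        for side in ("L", "R"):
            item = loading * latent + np.sqrt(1 - loading**2) * rng.normal(0, 1, n)
            rating = 1 + (item[:, None] > np.asarray(cuts)).sum(axis=1)
            rows.append(
                pd.DataFrame(
                    {"child": np.arange(n), "domain": domain, "muscle": m,
                     "side": side, "rating": rating.astype(float)}
                )
            )
    return pd.concat(rows, ignore_index=True), latent


class TestSummaryScore:
    def test_recovers_latent_severity(self, rng):
        exams, latent = make_exams(rng, n=2000)
        scores, model = summary_score(exams, "spasticity")
        assert np.corrcoef(scores.to_numpy(), latent)[0, 1] > 0.8
        assert model.variance_explained > 0.5
        assert scores.mean() == pytest.approx(0, abs=1e-9)
        assert scores.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_first_eigenvalue_dominates_single_latent(self, rng):
        exams, _ = make_exams(rng, n=1500)
        corr = polychoric_matrix(exams, domain="spasticity")
        vals = np.linalg.eigvalsh(corr.to_numpy())
        assert vals[-1] / vals.sum() > 0.5
        assert np.all(np.linalg.eigvalsh(corr.to_numpy()) > -1e-10)

    def test_missing_item_gives_missing_score(self, rng):
        exams, _ = make_exams(rng, n=300)
        exams.loc[exams.index[0], "rating"] = np.nan
        victim = exams.loc[exams.index[0], "child"]
        scores, _ = summary_score(exams, "spasticity")
        assert np.isnan(scores.loc[victim])
        assert scores.drop(index=victim).notna().all()

    def test_uniformly_higher_ratings_score_higher(self, rng):
        exams, _ = make_exams(rng, n=300)
        _, model = summary_score(exams, "spasticity")
        wide = exam_items_wide(exams, "spasticity")
        low = wide.iloc[0].copy()
        low[:] = 2.0
        high = low + 1.0
        pair = pd.DataFrame([low, high])
        raw = model.raw_scores(pair)
        assert raw.iloc[1] > raw.iloc[0]

    def test_invariant_to_row_order(self, rng):
        exams, _ = make_exams(rng, n=200)
        shuffled = exams.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s1, _ = summary_score(exams, "spasticity")
        s2, _ = summary_score(shuffled, "spasticity")
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_out_of_scale_rating_rejected(self, rng):
        exams, _ = make_exams(rng, n=100)
        exams.loc[exams.index[0], "rating"] = 9.0
        with pytest.raises(ValueError, match="scale"):
            summary_score(exams, "spasticity")


class TestNetMetabolicPower:
    def test_stated_conversion(self):
        assert net_metabolic_power(10.0, 3.8) == pytest.approx(124.62)
        assert net_metabolic_power(6.2, 0.0) == pytest.approx(124.62)
        assert net_metabolic_power(4.4, 4.4) == 0.0

    def test_linearity_slope(self, rng):
        w = rng.uniform(1, 10, 50)
        r = rng.uniform(0, 1, 50)
        np.testing.assert_allclose(
            net_metabolic_power(w + 1.0, r) - net_metabolic_power(w, r), J_PER_ML_O2
        )
        np.testing.assert_allclose(
            net_metabolic_power(w, r + 1.0) - net_metabolic_power(w, r), -J_PER_ML_O2
        )

    def test_negative_returned_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = net_metabolic_power(1.0, 2.0)
        assert out == pytest.approx(-20.1)
        assert "negative net power" in caplog.text

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError):
            net_metabolic_power(-1.0, 0.0)


class TestZscore:
    def test_standardization_and_spasticity_flip(self, small_cohort):
        cohort, _, _ = small_cohort
        z, meta = zscore_factors(cohort)
        assert z["GDI"].mean() == pytest.approx(0, abs=1e-9)
        assert z["GDI"].std(ddof=1) == pytest.approx(1, abs=1e-9)
        worst = cohort["Spasticity"].idxmax()
        assert z.loc[worst, "Spasticity"] == pytest.approx(z["Spasticity"].min())
        assert meta["Spasticity"]["sign"] == -1.0
        assert meta["GDI"]["sd"] > 0

    def test_round_trip(self, small_cohort):
        cohort, _, _ = small_cohort
        z, meta = zscore_factors(cohort)
        back = inverse_zscore(z, meta)
        for col in meta:
            np.testing.assert_allclose(
                back[col].dropna(), cohort[col].dropna(), atol=1e-9
            )

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"GDI": [70.0] * 5, "Speed": np.arange(5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            zscore_factors(df, ["GDI"])


class TestReaders:
    def test_cohort_csv_with_column_map(self, tmp_path):
        df = pd.DataFrame({"gdi_score": [70.0, 80.0], "sex": ["M", "f"], "child": [1, 2]})
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        out = read_cohort(path, {"GDI": "gdi_score", "Sex": "sex"})
        assert list(out["GDI"]) == [70.0, 80.0]
        assert list(out["Sex"]) == [1, 0]

    def test_cohort_xlsx(self, tmp_path):
        df = pd.DataFrame({"GDI": [71.1], "MetPower": [124.2]})
        path = tmp_path / "c.xlsx"
        df.to_excel(path, index=False)
        out = read_cohort(path)
        assert out.loc[0, "GDI"] == pytest.approx(71.1)

    def test_bad_mapping_named(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="nope"):
            read_cohort(path, {"GDI": "nope"})

    def test_exam_reader_validates(self, tmp_path, rng):
        exams, _ = make_exams(rng, n=20)
        path = tmp_path / "e.csv"
        exams.to_csv(path, index=False)
        assert len(read_exams(path)) == len(exams)
        bad = exams.rename(columns={"rating": "score"})
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="rating"):
            read_exams(path)
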