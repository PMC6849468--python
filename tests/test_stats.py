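"""NUE arithmetic, ANOVA against a summation oracle, correlations, ranking."""

import numpy as np
import pandas as pd
import pytest

from wheatnue.stats import (
    N_INPUT_G,
    correlation_matrix,
    harvest_index,
    nue,
    nue_table,
    outlier_screen,
    paired_condition_correlation,
    rank_report,
    significance_stars,
    timecourse_correlation,
    two_way_anova,
)
from wheatnue.synthetic import TraitTableSpec, generate_trait_table


class TestNue:
    def test_zero_weight_gives_zero(self):
        assert nue(0.0, 0.147) == 0.0

    def test_printed_example(self):
        # top low-N variety: 19.21 g DW on 0.147 g N
        assert nue(19.21, 0.147) == pytest.approx(130.68, abs=0.005)

    def test_linearity(self):
        assert nue(2 * 7.3, 0.147) == pytest.approx(2 * nue(7.3, 0.147))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            nue(1.0, 0.0)

    def test_nue_table_ordering_invariant(self, reference_harvest):
        out = nue_table(reference_harvest)
        assert (out["nue_b"] >= out["nue_g"]).all()
        assert out["harvest_index_pct"].between(0, 100).all()


class TestHarvestIndex:
    def test_grain_equals_biomass_gives_100(self):
        assert harvest_index(5.0, 5.0) == 100.0

    def test_nonpositive_dw_rejected(self):
        with pytest.raises(ValueError):
            harvest_index(1.0, 0.0)

    @pytest.mark.parametrize(
        "n_level,expected,tol", [("optimum", 46.36, 0.05), ("low", 49.41, 0.1)]
    )
    def test_variety_mean_reconstruction(self, reference_harvest, n_level, expected, tol):
        sub = reference_harvest[reference_harvest["n_level"] == n_level]
        his = [harvest_index(gy, dw) for gy, dw in zip(sub["gy_g"], sub["dw_g"])]
        assert np.mean(his) == pytest.approx(expected, abs=tol)


def _oracle_anova(df: pd.DataFrame, trait: str):
    """Direct summation two-way ANOVA oracle for balanced data."""
    grand = df[trait].mean()
    n = len(df)
    a_means = df.groupby("n_level")[trait].mean()
    b_means = df.groupby("variety")[trait].mean()
    cell = df.groupby(["n_level", "variety"])[trait].mean()
    n_a = df.groupby("n_level").size()
    n_b = df.groupby("variety").size()
    n_cell = df.groupby(["n_level", "variety"]).size()
    ss_a = float((n_a * (a_means - grand) ** 2).sum())
    ss_b = float((n_b * (b_means - grand) ** 2).sum())
    ss_cells = float((n_cell * (cell - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = float(((df[trait] - grand) ** 2).sum())
    ss_err = ss_tot - ss_cells
    return ss_a, ss_b, ss_ab, ss_err, ss_tot


@pytest.fixture()
def balanced_2x2():
    rng = np.random.default_rng(7)
    rows = []
    for a in ("low", "optimum"):
        for b in ("X", "Y"):
            mu = 10 + (5 if a == "optimum" else 0) + (2 if b == "Y" else 0)
            for _ in range(6):
                rows.append({"n_level": a, "variety": b, "y": mu + rng.normal(0, 1.5)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    @pytest.mark.parametrize("n_varieties", [2, 15])
    def test_matches_summation_oracle(self, n_varieties):
        table = generate_trait_table(
            TraitTableSpec(n_varieties=n_varieties, n_replicates=5, seed=n_varieties)
        )
        summary = two_way_anova(table, "dw_g")
        ss_a, ss_b, ss_ab, ss_err, ss_tot = _oracle_anova(table, "dw_g")
        aov = summary.table
        assert aov.loc["n_level", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert aov.loc["variety", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert aov.loc["n_level:variety", "sum_sq"] == pytest.approx(ss_ab, rel=1e-9)
        assert aov.loc["residual", "sum_sq"] == pytest.approx(ss_err, rel=1e-9)
        # partition conservation
        total = aov["sum_sq"].sum()
        assert total == pytest.approx(ss_tot, rel=1e-9)
        assert aov["df"].sum() == len(table) - 1

    def test_sed_lsd_formulas(self, balanced_2x2):
        from scipy import stats as sps

        summary = two_way_anova(balanced_2x2, "y")
        n_per_a = len(balanced_2x2) / 2
        assert summary.sed["n_level"] == pytest.approx(np.sqrt(2 * summary.mse / n_per_a))
        t = sps.t.ppf(0.975, summary.df_error)
        assert summary.lsd["n_level"] == pytest.approx(t * summary.sed["n_level"])
        assert summary.cv_pct == pytest.approx(
            100 * np.sqrt(summary.mse) / balanced_2x2["y"].mean()
        )

    def test_pure_n_effect_puts_all_ss_on_n(self):
        rows = [
            {"n_level": a, "variety": b, "y": 1.0 + (3.0 if a == "optimum" else 0.0)}
            for a in ("low", "optimum")
            for b in ("X", "Y")
            for _ in range(3)
        ]
        df = pd.DataFrame(rows)
        summary = two_way_anova(df, "y")
        assert summary.table.loc["variety", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert summary.table.loc["n_level:variety", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert summary.table.loc["n_level", "sum_sq"] > 0

    def test_cv_recovers_known_sigma(self):
        rng = np.random.default_rng(1)
        rows = [
            {"n_level": a, "variety": b, "y": 50 + rng.normal(0, 5)}
            for a in ("low", "optimum")
            for b in ("X", "Y", "Z")
            for _ in range(60)
        ]
        summary = two_way_anova(pd.DataFrame(rows), "y")
        assert summary.cv_pct == pytest.approx(100 * 5 / 50, rel=0.1)

    def test_unbalanced_rejected_with_fallback_hint(self, balanced_2x2):
        unbal = balanced_2x2.iloc[1:]
        with pytest.raises(ValueError, match="allow_unbalanced"):
            two_way_anova(unbal, "y")
        summary = two_way_anova(unbal, "y", allow_unbalanced=True)
        assert summary.mse > 0


class TestCorrelationMatrix:
    def test_closed_form_example(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 3, 2]})
        rep = correlation_matrix(df, ["x", "y"])
        assert rep.r.loc["x", "y"] == pytest.approx(0.5)
        assert rep.r.loc["x", "x"] == 1.0
        assert rep.n.loc["x", "y"] == 3

    def test_symmetry_and_bounds(self):
        table = generate_trait_table(TraitTableSpec(n_varieties=5, n_replicates=6, seed=2))
        traits = ["eb_kpix", "tva_kpix", "mb_g", "dw_g"]
        rep = correlation_matrix(table, traits)
        assert np.allclose(rep.r, rep.r.T)
        assert (rep.r.abs() <= 1 + 1e-12).all().all()
        assert np.allclose(np.diag(rep.r), 1.0)

    def test_affine_invariance(self):
        table = generate_trait_table(TraitTableSpec(n_varieties=5, n_replicates=6, seed=2))
        r1 = correlation_matrix(table, ["eb_kpix", "mb_g"]).r.loc["eb_kpix", "mb_g"]
        table["mb_g"] = 3.0 * table["mb_g"] + 17.0
        r2 = correlation_matrix(table, ["eb_kpix", "mb_g"]).r.loc["eb_kpix", "mb_g"]
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 2, 2, 2]})
        with pytest.warns(UserWarning, match="zero variance"):
            rep = correlation_matrix(df, ["x", "y"])
        assert np.isnan(rep.r.loc["x", "y"])

    def test_target_correlation_recovered_at_desk_scale(self):
        rs = []
        for seed in range(30):
            table = generate_trait_table(
                TraitTableSpec(n_varieties=1, n_replicates=90, seed=seed)
            )
            low = table[table["n_level"] == "low"]
            rep = correlation_matrix(low, ["eb_kpix", "mb_g"])
            rs.append(rep.r.loc["eb_kpix", "mb_g"])
        lo, hi = np.quantile(rs, [0.025, 0.975])
        assert lo <= 0.94 <= hi


class TestTimecourseCorrelation:
    def _study(self, rng, coupled=True):
        rows, hrows = [], []
        for pot in range(40):
            growth = rng.uniform(2, 10)
            for das in (30.0, 40.0, 50.0):
                rows.append(
                    {
                        "pot_id": f"P{pot}",
                        "variety": f"V{pot % 5}",
                        "n_level": "low",
                        "das": das,
                        "eb_kpix": growth * das,
                    }
                )
            hrows.append(
                {
                    "pot_id": f"P{pot}",
                    "dw_g": growth * 50.0 if coupled else rng.uniform(5, 20),
                    "gy_g": growth * 25.0 if coupled else rng.uniform(2, 10),
                }
            )
        return pd.DataFrame(rows), pd.DataFrame(hrows)

    def test_proportional_harvest_gives_unit_correlation(self, rng):
        series, harvest = self._study(rng, coupled=True)
        tc = timecourse_correlation(series, harvest)
        last = tc[(tc["das"] == 50.0)]
        assert np.allclose(last["r"], 1.0)

    def test_shuffled_pots_give_null_correlation(self, rng):
        series, harvest = self._study(rng, coupled=True)
        mean_r = []
        for _ in range(20):
            shuffled = harvest.copy()
            shuffled["pot_id"] = rng.permutation(harvest["pot_id"].to_numpy())
            tc = timecourse_correlation(series, shuffled)
            mean_r.append(tc["r"].mean())
        # averaged over permutations the association vanishes
        assert abs(np.mean(mean_r)) < 2 / np.sqrt(40)

    def test_disjoint_pots_rejected(self, rng):
        series, harvest = self._study(rng)
        harvest["pot_id"] = "other_" + harvest["pot_id"]
        with pytest.raises(ValueError, match="overlapping"):
            timecourse_correlation(series, harvest)


class TestRankReport:
    def test_reference_dw_ranking(self, reference_harvest):
        ranked = rank_report(reference_harvest, "dw_g", "low")
        assert list(ranked["variety"].head(3)) == ["Yitpi", "Excalibur", "Chara"]
        assert ranked["variety"].iloc[-1] == "Drysdale"
        assert ranked["extreme"].iloc[0] == "high"
        assert ranked["extreme"].iloc[-1] == "low"

    def test_permutation_of_input_varieties(self, reference_harvest):
        ranked = rank_report(reference_harvest, "gy_g", "optimum")
        assert sorted(ranked["variety"]) == sorted(reference_harvest["variety"].unique())

    def test_constant_trait_ties_alphabetical(self):
        df = pd.DataFrame(
            {"variety": list("CAB"), "n_level": "low", "x": [1.0, 1.0, 1.0]}
        )
        ranked = rank_report(df, "x", "low")
        assert list(ranked["variety"]) == ["A", "B", "C"]
        assert ranked["tied"].all()


class TestOutlierScreen:
    def test_all_equal_group_unflagged(self):
        df = pd.DataFrame({"g": ["a"] * 5, "x": [4.0] * 5})
        assert not outlier_screen(df, "x", ["g"])["outlier"].any()

    def test_gross_outlier_flagged(self):
        df = pd.DataFrame({"g": ["a"] * 5, "x": [10.0, 11.0, 9.0, 10.0, 100.0]})
        out = outlier_screen(df, "x", ["g"])
        assert list(out["outlier"]) == [False, False, False, False, True]

    def test_small_groups_never_flagged(self):
        df = pd.DataFrame({"g": ["a"] * 3, "x": [1.0, 1.0, 99.0]})
        assert not outlier_screen(df, "x", ["g"])["outlier"].any()

    def test_clean_gaussian_flag_rate_below_1pct(self, rng):
        # group sizes large enough for the MAD scale estimate to stabilise
        rows = []
        for g in range(30):
            for v in rng.normal(0, 1, size=200):
                rows.append({"g": g, "x": v})
        out = outlier_screen(pd.DataFrame(rows), "x", ["g"])
        assert out["outlier"].mean() < 0.01


class TestPairedConditionCorrelation:
    def test_identical_tables_give_unit_r(self, reference_harvest):
        out = paired_condition_correlation(
            reference_harvest, reference_harvest, ["dw_g", "gy_g"]
        )
        assert np.allclose(out["r"], 1.0)
        assert (out["n"] == reference_harvest["variety"].nunique()).all()


def test_significance_star_conventions():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.05) == "*"
    assert significance_stars(0.2) == ""
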