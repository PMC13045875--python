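"""Age/sex adjustment, double-entry correlations, Fisher z, demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twindti.cohort import roster_to_frame
from twindti.twinstats import (
    adjust_age_sex,
    compare_twin_correlations,
    correlation_table,
    demographics_tests,
    round_half_up,
    summarize_metric_correlations,
    twin_correlation,
)


def _frame(n_mz=6, n_dz=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_mz + n_dz):
        zyg = "MZ" if i < n_mz else "DZ"
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append(
            {
                "pair_id": f"p{i}",
                "zygosity": zyg,
                "sex_1": sex,
                "sex_2": sex,
                "age": float(rng.uniform(9, 32)),
                "scanner": "site_A",
                "excluded_reason": "none",
            }
        )
    return pd.DataFrame(rows)


def _table(frame, fn, region="R", metric="FA"):
    rows = []
    for r in frame.itertuples(index=False):
        for t in (1, 2):
            rows.append(
                {
                    "subject_id": f"{r.pair_id}_{t}",
                    "pair_id": r.pair_id,
                    "twin_index": t,
                    "region": region,
                    "metric": metric,
                    "value": fn(r, t),
                }
            )
    return pd.DataFrame(rows)


class TestAdjustment:
    def test_pure_age_effect_residuals_orthogonal(self):
        frame = _frame(20, 20)
        rng = np.random.default_rng(1)
        table = _table(frame, lambda r, t: 2.0 * r.age + rng.normal(0, 0.1))
        resid = adjust_age_sex(table, frame)
        ages = frame.set_index("pair_id")["age"]
        a = ages.loc[resid["pair_id"]].to_numpy()
        assert abs(np.corrcoef(resid["value"], a)[0, 1]) < 1e-10
        assert abs(resid["value"].mean()) < 1e-12

    def test_no_covariate_effect_residuals_are_centered_values(self):
        frame = _frame(20, 20)
        rng = np.random.default_rng(2)
        vals = {}
        table = _table(frame, lambda r, t: vals.setdefault((r.pair_id, t), rng.normal(5, 1)))
        resid = adjust_age_sex(table, frame)
        # residual equals value minus fitted plane; with null effects the fit
        # is essentially the mean, so centering dominates
        assert abs(resid["value"].mean()) < 1e-12
        assert np.corrcoef(resid["value"], table["value"])[0, 1] > 0.99

    def test_missing_covariate_raises(self):
        frame = _frame(4, 4)
        table = _table(frame, lambda r, t: 1.0)
        table.loc[0, "subject_id"] = "ghost_1"
        with pytest.raises(ValueError, match="ghost"):
            adjust_age_sex(table, frame)

    def test_constant_shift_invariance(self):
        """Adjustment then correlation is unchanged by adding a constant."""
        frame = _frame(15, 15)
        rng = np.random.default_rng(3)
        table = _table(frame, lambda r, t: rng.normal(0, 1))
        shifted = table.copy()
        shifted["value"] = shifted["value"] + 100.0
        r1 = twin_correlation(adjust_age_sex(table, frame), frame, "MZ")[0].r
        r2 = twin_correlation(adjust_age_sex(shifted, frame), frame, "MZ")[0].r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestTwinCorrelation:
    def test_identical_twins_give_r_one(self):
        frame = _frame(6, 0)
        rng = np.random.default_rng(4)
        vals = {p: rng.normal() for p in frame["pair_id"]}
        table = _table(frame, lambda r, t: vals[r.pair_id])
        est = twin_correlation(table, frame, "MZ")[0]
        assert est.r == pytest.approx(1.0)
        assert est.n_pairs == 6

    def test_double_entry_invariant_to_twin_order(self):
        frame = _frame(10, 0, seed=5)
        rng = np.random.default_rng(5)
        table = _table(frame, lambda r, t: rng.normal())
        swapped = table.copy()
        flip = swapped["pair_id"].isin({"p0", "p3", "p7"})
        swapped.loc[flip, "twin_index"] = 3 - swapped.loc[flip, "twin_index"]
        r1 = twin_correlation(table, frame, "MZ")[0].r
        r2 = twin_correlation(swapped, frame, "MZ")[0].r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_equals_anova_intraclass_on_random_data(self):
        """Double-entry Pearson == ICC from the stacked 2n-row data."""
        frame = _frame(25, 0, seed=6)
        rng = np.random.default_rng(6)
        shared = {p: rng.normal() for p in frame["pair_id"]}
        table = _table(frame, lambda r, t: shared[r.pair_id] + rng.normal(0, 0.8))
        r = twin_correlation(table, frame, "MZ")[0].r
        wide = table.pivot_table(index="pair_id", columns="twin_index", values="value")
        x, y = wide[1].to_numpy(), wide[2].to_numpy()
        allv = np.concatenate([x, y])
        mu, s2 = allv.mean(), allv.var()
        icc = np.mean((x - mu) * (y - mu)) / s2
        assert r == pytest.approx(icc, abs=1e-12)

    def test_missing_member_drops_pair(self):
        frame = _frame(5, 0)
        rng = np.random.default_rng(7)
        table = _table(frame, lambda r, t: rng.normal())
        table.loc[table["subject_id"] == "p0_2", "value"] = np.nan
        est = twin_correlation(table, frame, "MZ")[0]
        assert est.n_pairs == 4

    def test_too_few_pairs_logged_not_raised(self, caplog):
        frame = _frame(2, 0)
        table = _table(frame, lambda r, t: 1.0 * t)
        with caplog.at_level("WARNING"):
            out = twin_correlation(table, frame, "MZ")
        assert out == []
        assert "complete pairs" in caplog.text


class TestFisherComparison:
    def test_equal_correlations_give_half(self):
        c = compare_twin_correlations(0.5, 33, 0.5, 48)
        assert c.z == 0.0 and c.p == pytest.approx(0.5)

    def test_printed_example_magnitude(self):
        c = compare_twin_correlations(0.81, 33, 0.37, 48)
        assert c.z == pytest.approx(3.13, abs=0.01)
        assert c.p == pytest.approx(8.7e-4, rel=0.05)
        assert c.direction == "MZ>DZ"

    def test_monotone_in_r_mz(self):
        ps = [compare_twin_correlations(r, 33, 0.3, 48).p for r in (0.4, 0.5, 0.6, 0.7)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            compare_twin_correlations(1.0, 33, 0.5, 48)
        with pytest.raises(ValueError):
            compare_twin_correlations(0.5, 3, 0.5, 48)


class TestSummaries:
    def test_single_estimate(self):
        from twindti.twinstats import CorrelationEstimate

        e = CorrelationEstimate("R", "FA", "MZ", 0.42, 10)
        assert summarize_metric_correlations([e]) == (0.42, 0.42, 0.42)

    def test_half_up_rounding(self):
        assert round_half_up(0.705) == 0.71
        assert round_half_up(0.125, 2) == 0.13
        assert summarize_metric_correlations(pd.Series([0.70, 0.71]))[0] == 0.71

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_metric_correlations([])


class TestDemographics:
    def test_identical_ages_t_zero(self):
        frame = _frame(6, 6)
        frame["age"] = 15.0
        d = demographics_tests(frame)
        assert d.t == pytest.approx(0.0)
        assert d.t_p == pytest.approx(1.0)

    def test_proportional_sex_composition_chi2_zero(self):
        rows = []
        for zyg, n in (("MZ", 8), ("DZ", 8)):
            for i in range(n):
                sex = "M" if i < n // 2 else "F"
                rows.append(
                    {"pair_id": f"{zyg}{i}", "zygosity": zyg, "sex_1": sex, "sex_2": sex,
                     "age": 15.0 + i, "scanner": "s", "excluded_reason": "none"}
                )
        d = demographics_tests(pd.DataFrame(rows))
        assert d.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_hand_formula(self):
        rows = []
        comp = {("MZ", "MM"): 18, ("MZ", "FF"): 15, ("DZ", "MM"): 21, ("DZ", "FF"): 17}
        k = 0
        for (zyg, c), n in comp.items():
            for _ in range(n):
                s1, s2 = (c[0], c[1])
                rows.append({"pair_id": f"p{k}", "zygosity": zyg, "sex_1": s1, "sex_2": s2,
                             "age": 15.0 + 0.1 * k, "scanner": "s", "excluded_reason": "none"})
                k += 1
        frame = pd.DataFrame(rows)
        d = demographics_tests(frame)
        obs = np.array([[18, 15], [21, 17]], float)
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        assert d.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-12)

    def test_correlation_table_shape(self, small_cohort):
        _, frame, table = small_cohort
        resid = adjust_age_sex(table, frame)
        corr = correlation_table(resid, frame)
        assert set(corr.columns) == {"region", "metric", "r_mz", "n_mz", "r_dz", "n_dz", "z", "p"}
        assert len(corr) == 16  # 8 regions x 2 metrics
        assert ((corr["p"] >= 0) & (corr["p"] <= 1)).all()
        # p consistent with z
        np.testing.assert_allclose(corr["p"], stats.norm.sf(corr["z"]), rtol=1e-12)
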