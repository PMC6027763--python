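"""Aggregation and statistics: printed-table oracles, SS decompositions,
post-hoc behaviour, normality guard."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tauquant as tq
from tauquant.stats import round_half_away
from tests.conftest import make_measurement_table


# printed one-decimal group means of the bundled 20-case cohort
PRINTED_GROUP_MEANS = {
    "control": {"age": 68.8, "braak_stage": 0.0, "pmd_hours": 45.2, "fixation_weeks": 8.2},
    "I_II": {"age": 82.2, "braak_stage": 1.8, "pmd_hours": 60.0, "fixation_weeks": 18.0},
    "III_IV": {"age": 84.8, "braak_stage": 3.2, "pmd_hours": 56.8, "fixation_weeks": 12.6},
    "V_VI": {"age": 83.2, "braak_stage": 6.0, "pmd_hours": 46.4, "fixation_weeks": 10.2},
}


class TestSummarizeCases:
    EXPECTED = PRINTED_GROUP_MEANS

    def test_reproduces_printed_group_means(self, reference_cases):
        summary = tq.summarize_cases(reference_cases)
        for group, cols in self.EXPECTED.items():
            for col, expected in cols.items():
                assert summary.loc[group, col] == pytest.approx(expected, abs=1e-9), (group, col)

    def test_single_case_group_is_identity(self):
        cases = pd.DataFrame(
            {
                "case_id": ["1"],
                "braak_group": ["control"],
                "age": [70],
                "braak_stage": [0],
                "pmd_hours": [50.0],
                "fixation_weeks": [8.0],
            }
        )
        summary = tq.summarize_cases(cases)
        assert summary.loc["control", "age"] == 70.0

    def test_empty_group_omitted(self, reference_cases, caplog):
        sub = reference_cases[reference_cases["braak_group"] != "V_VI"]
        with caplog.at_level("WARNING"):
            summary = tq.summarize_cases(sub)
        assert "V_VI" not in summary.index
        assert any("V_VI" in r.message for r in caplog.records)


def test_round_half_away_matches_printed_convention():
    assert round_half_away(0.25, 1) == 0.3
    assert round_half_away(-0.25, 1) == -0.3
    assert round_half_away(18.0, 1) == 18.0


class TestAverageMosaics:
    @staticmethod
    def table(pairs):
        rows = []
        for i, values in enumerate(pairs):
            for m, v in enumerate(values):
                rows.append(
                    {
                        "case_id": f"c{i}",
                        "region": "TeCtx",
                        "marker": "ptau",
                        "mosaic": m,
                        "ir_area_percent": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_duplicates_averaged(self):
        out = tq.average_mosaics(self.table([(2.0, 4.0)]))
        assert len(out) == 1 and out["ir_area_percent"].iloc[0] == pytest.approx(3.0)

    def test_singleton_passes_through(self):
        out = tq.average_mosaics(self.table([(5.0,)]))
        assert out["ir_area_percent"].iloc[0] == 5.0

    def test_matches_loop_mean_oracle(self):
        rng = np.random.default_rng(6)
        pairs = [tuple(rng.uniform(0, 10, 2)) for _ in range(200)]
        out = tq.average_mosaics(self.table(pairs)).set_index("case_id")
        for i, (a, b) in enumerate(pairs):
            assert out.loc[f"c{i}", "ir_area_percent"] == (a + b) / 2.0

    def test_triplicates_rejected(self):
        with pytest.raises(ValueError, match="more than two"):
            tq.average_mosaics(self.table([(1.0, 2.0, 3.0)]))


class TestIsocortexMean:
    @staticmethod
    def table(values, regions=tq.ISOCORTEX_REGIONS, tentr=9.0):
        rows = [
            {"case_id": "c", "region": r, "marker": "ptau", "ir_area_percent": v}
            for r, v in zip(regions, values)
        ]
        rows.append(
            {"case_id": "c", "region": "TEntR", "marker": "ptau", "ir_area_percent": tentr}
        )
        return pd.DataFrame(rows)

    def test_mean_of_four_regions(self):
        out = tq.isocortex_mean(self.table([1.0, 2.0, 3.0, 4.0]))
        iso = out[out["region"] == "Isocortex"]
        assert iso["ir_area_percent"].iloc[0] == pytest.approx(2.5)

    def test_equal_regions_are_identity(self):
        out = tq.isocortex_mean(self.table([7.0] * 4))
        assert out[out["region"] == "Isocortex"]["ir_area_percent"].iloc[0] == 7.0

    def test_transentorhinal_never_included(self):
        out = tq.isocortex_mean(self.table([0.0, 0.0, 0.0, 0.0], tentr=100.0))
        assert out[out["region"] == "Isocortex"]["ir_area_percent"].iloc[0] == 0.0

    def test_missing_region_excludes_case(self, caplog):
        t = self.table([1.0, 2.0, 3.0, 4.0])
        t = t[t["region"] != "OcCtx"]
        with caplog.at_level("WARNING"):
            out = tq.isocortex_mean(t)
        assert "Isocortex" not in set(out["region"])
        assert any("OcCtx" in r.message for r in caplog.records)

    def test_matches_per_case_loop_oracle(self):
        rng = np.random.default_rng(7)
        table = make_measurement_table(rng, n=1)
        out = tq.isocortex_mean(table)
        iso = out[out["region"] == "Isocortex"].set_index("case_id")
        for case_id, sub in table.groupby("case_id"):
            expected = sub[sub["region"].isin(tq.ISOCORTEX_REGIONS)]["ir_area_percent"].mean()
            assert iso.loc[case_id, "ir_area_percent"] == pytest.approx(expected, rel=1e-12)


class TestApplyExclusions:
    @staticmethod
    def table():
        rows = [
            {"case_id": "X", "region": r, "marker": m, "ir_area_percent": 1.0}
            for r in tq.REGIONS
            for m in ("ptau", "pThr231")
        ] + [
            {"case_id": "Y", "region": r, "marker": "ptau", "ir_area_percent": 1.0}
            for r in tq.REGIONS
        ]
        return pd.DataFrame(rows)

    def test_marker_scope_removes_only_that_marker(self):
        out = tq.apply_exclusions(self.table(), [tq.ExclusionRule("X", "pThr231", "outlier")])
        x = out[out["case_id"] == "X"]
        assert len(x) == 5 and set(x["marker"]) == {"ptau"}

    def test_empty_rule_list_is_identity(self):
        t = self.table()
        out = tq.apply_exclusions(t, [])
        pd.testing.assert_frame_equal(out, t)

    def test_scope_all_removes_whole_case(self):
        out = tq.apply_exclusions(self.table(), [tq.ExclusionRule("Y", "all", "outlier")])
        assert len(out) == len(self.table()) - 5
        assert "Y" not in set(out["case_id"])

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError, match="unknown case"):
            tq.apply_exclusions(self.table(), [tq.ExclusionRule("Z")])

    def test_original_table_untouched(self):
        t = self.table()
        before = t.copy()
        tq.apply_exclusions(t, [tq.ExclusionRule("Y")])
        pd.testing.assert_frame_equal(t, before)


def two_way_ss_oracle(table):
    """Brute-force balanced two-way sums-of-squares decomposition."""
    y = table["ir_area_percent"].to_numpy()
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    a_means = table.groupby("braak_group")["ir_area_percent"].mean()
    b_means = table.groupby("region")["ir_area_percent"].mean()
    cell_means = table.groupby(["braak_group", "region"])["ir_area_percent"].mean()
    n_a = table.groupby("braak_group").size()
    n_b = table.groupby("region").size()
    n_cell = table.groupby(["braak_group", "region"]).size()
    ss_a = float((n_a * (a_means - grand) ** 2).sum())
    ss_b = float((n_b * (b_means - grand) ** 2).sum())
    ss_cells = float((n_cell * (cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_resid = float(ss_total - ss_cells)
    return ss_a, ss_b, ss_ab, ss_resid, float(ss_total)


class TestTwoWayAnova:
    def test_matches_hand_computed_ss_on_fixed_2x2(self):
        rows = []
        values = {
            ("a1", "b1"): [1.0, 2.0, 3.0],
            ("a1", "b2"): [2.0, 4.0, 6.0],
            ("a2", "b1"): [5.0, 5.0, 8.0],
            ("a2", "b2"): [9.0, 7.0, 11.0],
        }
        for (a, b), ys in values.items():
            for y in ys:
                rows.append({"braak_group": a, "region": b, "ir_area_percent": y})
        table = pd.DataFrame(rows)
        res = tq.two_way_anova(table, posthoc="never")
        ss_a, ss_b, ss_ab, ss_resid, _ = two_way_ss_oracle(table)
        assert res.table.loc["braak_group", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert res.table.loc["region", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert res.table.loc["braak_group:region", "sum_sq"] == pytest.approx(ss_ab, rel=1e-9)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(ss_resid, rel=1e-9)
        assert res.table["df"].sum() == len(table) - 1

    def test_ss_components_sum_to_total_on_random_balanced_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = make_measurement_table(rng, n=int(rng.integers(2, 5)))
            res = tq.two_way_anova(table, posthoc="never")
            ss_a, ss_b, ss_ab, ss_resid, ss_total = two_way_ss_oracle(table)
            assert res.table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)
            assert res.table.loc["braak_group:region", "sum_sq"] == pytest.approx(
                ss_ab, rel=1e-8, abs=1e-10
            )

    def test_null_case_with_identical_cell_means(self):
        """Noise centred to exact zero within every cell: all factor SS vanish."""
        rng = np.random.default_rng(9)
        rows = []
        for g in tq.GROUPS:
            for r in tq.REGIONS:
                noise = rng.normal(0, 1, 50)
                noise -= noise.mean()
                for v in noise:
                    rows.append({"braak_group": g, "region": r, "ir_area_percent": 5.0 + v})
        res = tq.two_way_anova(pd.DataFrame(rows), posthoc="never")
        assert res.table.loc["braak_group", "p"] > 0.99
        assert res.table.loc["region", "p"] > 0.99

    def test_shifted_group_detected_with_high_power(self):
        """+5 SD shift of one group's means: main effect p < 0.001 in >=95/100 runs."""
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            shift = {("V_VI", r): 6.0 for r in tq.REGIONS}
            table = make_measurement_table(rng, n=5, shift=shift)  # noise SD 0.2, +5 SD = +1.0
            res = tq.two_way_anova(table, posthoc="never")
            hits += res.table.loc["braak_group", "p"] < 0.001
        assert hits >= 95

    def test_bonferroni_families_follow_figure_convention(self):
        rng = np.random.default_rng(11)
        shift = {("V_VI", r): 3.0 for r in tq.REGIONS}
        table = make_measurement_table(rng, n=5, shift=shift)
        res = tq.two_way_anova(table, posthoc="always")
        families = {c.family for c in res.post_hoc}
        assert families == {"braak_group_within_region", "region_within_braak_group"}
        stage_family = [c for c in res.post_hoc if c.family == "braak_group_within_region"]
        # 5 regions x C(4,2) stage pairs
        assert len(stage_family) == 5 * 6
        for c in res.post_hoc:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted == pytest.approx(min(1.0, len(stage_family) * c.p_raw)) or \
                c.family != "braak_group_within_region"

    def test_unbalanced_design_uses_type_ii(self):
        rng = np.random.default_rng(12)
        table = make_measurement_table(rng, n=3)
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)  # unbalance one cell
        res = tq.two_way_anova(table, posthoc="never")
        assert not res.balanced and res.ss_type == 2

    def test_deficient_cell_named_in_error(self):
        rng = np.random.default_rng(13)
        table = make_measurement_table(rng, n=2)
        table = table[~((table.braak_group == "V_VI") & (table.region == "TEntR"))]
        with pytest.raises(ValueError, match="V_VI"):
            tq.two_way_anova(table)


class TestOneWayAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        res = tq.one_way_anova({"a": a, "b": b}, posthoc="none")
        from scipy import stats as sps

        t, p = sps.ttest_ind(a, b)
        assert res.table.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.table.loc["group", "p"] == pytest.approx(p, rel=1e-10)

    def test_identical_constant_groups(self):
        res = tq.one_way_anova({"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0]})
        assert res.table.loc["group", "F"] == 0.0
        assert not any(c.significant for c in res.post_hoc)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tq.one_way_anova({"a": [1.0, 2.0], "b": [1.0]})

    def test_newman_keuls_flags_exactly_shifted_group_comparisons(self):
        """Three null groups and one shifted by 10 SD: the three comparisons
        involving the shifted group (and only those) are flagged in >=95/100 runs."""
        rng = np.random.default_rng(0)
        strict = 0
        shifted = {frozenset((f"g{i}", "g3")) for i in range(3)}
        for _ in range(100):
            groups = {f"g{i}": rng.normal(0 if i < 3 else 10, 1, 10) for i in range(4)}
            res = tq.one_way_anova(groups, posthoc="newman_keuls")
            sig = {frozenset((c.level_a, c.level_b)) for c in res.post_hoc if c.significant}
            strict += sig == shifted
        assert strict >= 95

    def test_newman_keuls_not_more_conservative_than_tukey_on_largest_span(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            groups = {g: rng.normal(rng.uniform(-1, 1), 1, 8) for g in "abcd"}
            nk = tq.one_way_anova(groups, posthoc="newman_keuls")
            tk = tq.one_way_anova(groups, posthoc="tukey")
            means = {g: np.mean(v) for g, v in groups.items()}
            lo = min(means, key=means.get)
            hi = max(means, key=means.get)
            pair = frozenset((lo, hi))
            p_nk = next(
                c.p_adjusted for c in nk.post_hoc if frozenset((c.level_a, c.level_b)) == pair
            )
            p_tk = next(
                c.p_adjusted for c in tk.post_hoc if frozenset((c.level_a, c.level_b)) == pair
            )
            assert p_nk == pytest.approx(p_tk, rel=1e-12)

    def test_sealed_subranges_stay_nonsignificant(self):
        """A non-significant span must seal everything nested inside it even if
        a nested q value would cross its own critical value."""
        rng = np.random.default_rng(16)
        for _ in range(50):
            groups = {g: rng.normal(0, 1, 6) for g in "abcd"}
            res = tq.one_way_anova(groups, posthoc="newman_keuls")
            means = {g: np.mean(v) for g, v in groups.items()}
            order = sorted(means, key=means.get)
            sig = {frozenset((c.level_a, c.level_b)) for c in res.post_hoc if c.significant}
            full = frozenset((order[0], order[-1]))
            if full not in sig:
                assert sig == set()  # full range non-significant seals all


class TestFoldChange:
    @staticmethod
    def table(values_by_group):
        rows = []
        for g, vals in values_by_group.items():
            for v in vals:
                rows.append(
                    {
                        "case_id": f"{g}{v}",
                        "braak_group": g,
                        "region": "TeCtx",
                        "marker": "ptau",
                        "ir_area_percent": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_ratio_of_group_means(self):
        fc = tq.fold_change(self.table({"control": [3.0], "V_VI": [9.0]}))
        row = fc[fc["braak_group"] == "V_VI"].iloc[0]
        assert row["fold_change"] == pytest.approx(3.0)

    def test_reference_is_exactly_one(self):
        fc = tq.fold_change(self.table({"control": [3.0, 5.0]}))
        assert fc[fc["braak_group"] == "control"]["fold_change"].iloc[0] == 1.0

    def test_zero_reference_flagged_not_infinite(self):
        fc = tq.fold_change(self.table({"control": [0.0], "V_VI": [2.0]}))
        row = fc[fc["braak_group"] == "V_VI"].iloc[0]
        assert row["undefined"] and np.isnan(row["fold_change"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="control"):
            tq.fold_change(self.table({"V_VI": [2.0]}))


class TestKsNormality:
    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(0)
        passed = sum(tq.ks_normality(rng.normal(0, 1, 1000))[1] > 0.05 for _ in range(100))
        assert passed >= 93

    def test_statistic_matches_ecdf_oracle(self):
        values = np.array([0.0, 0.5, 1.0])
        stat, _ = tq.ks_normality(values)
        from scipy.stats import norm

        z = (np.sort(values) - values.mean()) / values.std(ddof=1)
        cdf = norm.cdf(z)
        n = len(values)
        d_plus = max((np.arange(1, n + 1) / n) - cdf)
        d_minus = max(cdf - np.arange(0, n) / n)
        assert stat == pytest.approx(max(d_plus, d_minus), rel=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tq.ks_normality([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            tq.ks_normality([1.0, 2.0])


@given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None)
def test_sem_matches_definition(values):
    expected = np.std(values, ddof=1) / np.sqrt(len(values))
    assert tq.sem(values) == pytest.approx(expected, rel=1e-12)


@given(
    st.floats(1e-12, 1.0),
    st.integers(1, 60),
)
@settings(max_examples=100, deadline=None)
def test_bonferroni_adjustment_properties(p_raw, m):
    adjusted = min(1.0, m * p_raw)
    assert adjusted >= p_raw
    assert adjusted <= 1.0
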