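"""Fold changes, t-tests, volcano classification, Fisher and ddCq."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmlipid import (
    AnalysisConfig,
    DegenerateStatisticsError,
    QpcrSample,
    class_summaries,
    class_summary,
    classify_direction,
    ddcq_fold_change,
    differential_table,
    direction_fisher,
    format_p,
    ratio_group_change,
    species_fold_change,
    students_ttest,
    volcano_table,
)
from mrmlipid.differential import DOWN, UP, WITHIN

from conftest import make_profile

CFG = AnalysisConfig(reference_group="control")


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


class TestStudentsTTest:
    def test_worked_example(self):
        res = students_ttest([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224744871, abs=1e-6)
        assert res.df == 4
        assert res.p == pytest.approx(0.2878641, abs=1e-4)

    def test_identical_groups(self):
        res = students_ttest([1.0, 2.0], [1.0, 2.0])
        assert res.p == pytest.approx(1.0) or res.t == pytest.approx(0.0)

    def test_antisymmetry(self):
        fwd = students_ttest([1, 2, 3], [2, 3, 5])
        rev = students_ttest([2, 3, 5], [1, 2, 3])
        assert fwd.t == pytest.approx(-rev.t, rel=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)

    def test_zero_variance_equal_means(self):
        res = students_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)
        assert not res.degenerate

    def test_zero_variance_unequal_means(self):
        res = students_ttest([2.0, 2.0], [3.0, 3.0])
        assert res.p == 0.0
        assert res.degenerate

    def test_matches_oracle_on_random_groups(self):
        """Pooled t against the closed-form formula, 1000 random pairs."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0.0, 1.0 + rng.random(), size=na)
            b = rng.normal(rng.random(), 1.0, size=nb)
            got = students_ttest(a, b)
            t, df, p = pooled_t_oracle(a, b)
            assert got.t == pytest.approx(t, abs=1e-12, rel=1e-12)
            assert got.df == df
            assert got.p == pytest.approx(p, abs=1e-12, rel=1e-12)
            assert 0.0 < got.p <= 1.0

    def test_too_small_group(self):
        with pytest.raises(DegenerateStatisticsError):
            students_ttest([1.0], [1.0, 2.0])


class TestSpeciesFoldChange:
    def test_reference_self_comparison_is_100(self, small_profile):
        ref_cols = [s for s in small_profile.values.columns
                    if small_profile.sample_groups[s] == "control"]
        mirrored = small_profile.values[ref_cols]
        renamed = mirrored.copy()
        renamed.columns = [f"def_{i}" for i in range(1, len(ref_cols) + 1)]
        profile = make_profile(
            pd.concat([mirrored, renamed], axis=1).T.to_dict("list"),
            {**{c: "control" for c in ref_cols},
             **{c: "deficient" for c in renamed.columns}})
        fc = species_fold_change(profile, CFG)
        mean_ref = mirrored.mean(axis=1)
        expected = 100.0 * renamed.mean(axis=1).to_numpy() / mean_ref.to_numpy()
        np.testing.assert_allclose(fc["percent_of_reference"], expected,
                                   rtol=1e-12)

    def test_constant_shift(self):
        profile = make_profile(
            {"PC aa C34:1": [2.0, 2.0, 2.0, 2.2, 2.2, 2.2]},
            {"c1": "control", "c2": "control", "c3": "control",
             "d1": "deficient", "d2": "deficient", "d3": "deficient"})
        fc = species_fold_change(profile, CFG)
        assert fc.loc["PC aa C34:1", "percent_of_reference"] \
            == pytest.approx(110.0, abs=1e-9)
        assert fc.loc["PC aa C34:1", "sem_percent"] == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_hand_computed_example(self):
        """ref {1,3}, other {2,4}: ref mean 2, relative {100,200}."""
        profile = make_profile(
            {"PC aa C34:1": [1.0, 3.0, 2.0, 4.0]},
            {"c1": "control", "c2": "control",
             "d1": "deficient", "d2": "deficient"})
        fc = species_fold_change(profile, CFG)
        assert fc.loc["PC aa C34:1", "percent_of_reference"] == 150.0
        assert fc.loc["PC aa C34:1", "sem_percent"] == pytest.approx(50.0)

    def test_zero_reference_mean_flagged(self):
        profile = make_profile(
            {"PC aa C34:1": [0.0, 0.0, 1.0, 2.0]},
            {"c1": "control", "c2": "control",
             "d1": "deficient", "d2": "deficient"})
        fc = species_fold_change(profile, CFG)
        assert np.isnan(fc.loc["PC aa C34:1", "percent_of_reference"])


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "percent, p, sem, expect",
        [
            (106.0, 0.2, 2.0, (UP, False, "n.s.")),
            (101.0, 0.3, 2.0, (WITHIN, False, "n.s.")),
            (95.0, 0.004, 2.0, (DOWN, True, "**")),
            (100.0, 0.5, 0.0, (WITHIN, False, "n.s.")),
            (89.0, 0.0005, 2.0, (DOWN, True, "***")),
            (104.0, 0.04, 2.0, (UP, True, "*")),
        ],
    )
    def test_cases(self, percent, p, sem, expect):
        assert classify_direction(percent, p, sem, CFG) == expect

    def test_partition_and_monotonicity(self):
        directions = [classify_direction(pct, 0.5, 2.0, CFG)[0]
                      for pct in np.linspace(90, 110, 201)]
        order = {DOWN: 0, WITHIN: 1, UP: 2}
        ranks = [order[d] for d in directions]
        assert ranks == sorted(ranks)
        assert set(directions) == {DOWN, WITHIN, UP}


class TestClassSummary:
    def _records(self, percents, sems=None):
        sems = sems if sems is not None else [1.0] * len(percents)
        return pd.DataFrame({
            "species": [f"PC aa C{30 + 2 * i}:0" for i in range(len(percents))],
            "lipid_class": "PC_AA",
            "percent_of_reference": percents,
            "sem_percent": sems,
        })

    def test_all_at_100(self):
        out = class_summary(self._records([100.0, 100.0, 100.0]))
        assert out["mean_percent"] == 100.0
        assert out["p"] == 1.0

    def test_one_sample_t_worked_example(self):
        out = class_summary(self._records([104.0, 105.0, 106.0]))
        assert out["mean_percent"] == pytest.approx(105.0)
        assert out["sem_percent"] == pytest.approx(0.5773503, abs=1e-6)
        assert out["t"] == pytest.approx(8.660254, abs=1e-5)
        assert out["df"] == 2
        assert out["p"] == pytest.approx(0.013, abs=5e-4)
        formatted = (f"{out['mean_percent']:.1f} ± "
                     f"{out['sem_percent']:.1f}% (p = {format_p(out['p'])})")
        assert formatted == "105.0 ± 0.6% (p = 0.013)"

    def test_mean_sem_threshold_is_mean_of_sems(self):
        out = class_summary(self._records([101.0, 99.0], sems=[2.0, 4.0]))
        assert out["mean_sem_threshold"] == 3.0


class TestRatioGroupChange:
    GROUPS = {"c1": "control", "c2": "control", "c3": "control",
              "d1": "deficient", "d2": "deficient", "d3": "deficient"}

    def test_constant_shift(self):
        values = pd.Series([1.0, 1.0, 1.0, 1.02, 1.02, 1.02],
                           index=list(self.GROUPS))
        pct, sem, p = ratio_group_change(values, self.GROUPS, CFG)
        assert pct == pytest.approx(102.0, abs=1e-9)
        assert sem == pytest.approx(0.0, abs=1e-9)

    def test_identical_distributions(self):
        values = pd.Series([1.5] * 6, index=list(self.GROUPS))
        pct, sem, p = ratio_group_change(values, self.GROUPS, CFG)
        assert (pct, p) == (100.0, 1.0)

    def test_matches_hand_oracle(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0.5, 2.0, size=6)
        values = pd.Series(raw, index=list(self.GROUPS))
        pct, sem, p = ratio_group_change(values, self.GROUPS, CFG)
        rel = 100.0 * raw[3:] / raw[:3].mean()
        assert pct == pytest.approx(rel.mean(), rel=1e-12)
        assert sem == pytest.approx(rel.std(ddof=1) / math.sqrt(3), rel=1e-12)
        assert p == pytest.approx(pooled_t_oracle(raw[:3], raw[3:])[2],
                                  rel=1e-9)

    def test_nan_dropped_pairwise(self):
        values = pd.Series([1.0, 1.0, np.nan, 1.1, 1.1, 1.1],
                           index=list(self.GROUPS))
        pct, _, _ = ratio_group_change(values, self.GROUPS, CFG)
        assert pct == pytest.approx(110.0, abs=1e-9)


def fisher_oracle(table):
    """Two-sided Fisher p via scipy (independent of the implementation)."""
    return float(stats.fisher_exact(np.asarray(table), "two-sided")[1])


class TestDirectionFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[1, 0], [0, 1]], 1.0),
            ([[10, 0], [0, 10]], 2.0 / 184756.0),
        ],
    )
    def test_worked_values(self, table, expected):
        assert direction_fisher(table) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margins(self):
        assert direction_fisher([[0, 0], [3, 4]]) == 1.0
        assert direction_fisher([[2, 0], [3, 0]]) == 1.0

    def test_matches_scipy_on_all_small_tables(self):
        """Exhaustive agreement with scipy for margins <= 8."""
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        if (a + b) and (c + d) and (a + c) and (b + d):
                            table = [[a, b], [c, d]]
                            assert direction_fisher(table) == pytest.approx(
                                fisher_oracle(table), rel=1e-9, abs=1e-12), table

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            direction_fisher([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            direction_fisher([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            direction_fisher([[0, 0], [0, 0]])


class TestDdcq:
    def test_identity(self):
        assert ddcq_fold_change([(20.0, 15.0)], [(20.0, 15.0)]) == 1.0

    def test_worked_examples(self):
        assert ddcq_fold_change([(24.0, 15.0)], [(25.0, 15.0)]) == 2.0
        assert ddcq_fold_change([(24.0, 15.0)], [(26.0, 16.0)]) == 2.0

    def test_qpcr_sample_objects(self):
        treated = [QpcrSample(24.0, 15.0)]
        control = [QpcrSample(25.0, 15.0)]
        assert ddcq_fold_change(treated, control) == 2.0

    def test_empty_collection(self):
        with pytest.raises(ValueError):
            ddcq_fold_change([], [(20.0, 15.0)])

    def test_invalid_cq(self):
        with pytest.raises(ValueError):
            QpcrSample(-1.0, 15.0)


class TestDifferentialTable:
    def test_columns_and_classification(self, small_profile):
        out = differential_table(small_profile, CFG)
        assert list(out.columns) == [
            "species", "lipid_class", "percent_of_reference", "sem_percent",
            "t", "df", "p", "p_adj", "direction", "stars"]
        assert len(out) == 6
        assert set(out["direction"]) <= {UP, DOWN, WITHIN}
        assert ((out["p_adj"] >= out["p"]) | np.isclose(out["p_adj"],
                                                        out["p"])).all()

    def test_volcano_table_geometry(self, small_profile):
        diff = differential_table(small_profile, CFG)
        sub = diff[diff["lipid_class"] == "PC_AA"]
        summary = class_summary(sub)
        volc = volcano_table(sub, summary, CFG)
        assert len(volc) == len(sub)
        np.testing.assert_allclose(
            volc["fold_change"], sub["percent_of_reference"] / 100.0)
        thr = summary["mean_sem_threshold"] / 100.0
        assert volc["vline_low"].iloc[0] == pytest.approx(1.0 - thr)
        assert volc["vline_high"].iloc[0] == pytest.approx(1.0 + thr)
        assert (volc["p_threshold"] == 0.05).all()

    def test_volcano_worked_row(self):
        records = pd.DataFrame({
            "species": ["PC aa C34:1"], "lipid_class": ["PC_AA"],
            "percent_of_reference": [110.0], "sem_percent": [2.0],
            "p": [0.01], "direction": [UP], "stars": ["*"]})
        summary = {"mean_sem_threshold": 2.0}
        volc = volcano_table(records, summary, CFG)
        assert volc["fold_change"].iloc[0] == pytest.approx(1.10)
        assert volc["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert volc["vline_low"].iloc[0] == pytest.approx(0.98)
        assert volc["vline_high"].iloc[0] == pytest.approx(1.02)


def test_class_summaries_shape(small_profile):
    diff = differential_table(small_profile, CFG)
    out = class_summaries(diff)
    assert set(out["lipid_class"]) == {"PC_AA", "CAR"}
    assert list(out.columns) == ["lipid_class", "n_species", "mean_percent",
                                 "sem_percent", "p", "mean_sem_threshold"]


def test_format_p_floor():
    assert format_p(0.0004) == "0.000"
    assert format_p(0.0134) == "0.013"
    assert format_p(np.nan) == "NA"


def test_alpha_levels_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(reference_group="control", alpha_levels=(0.01, 0.05))
    with pytest.raises(ValueError):
        AnalysisConfig(reference_group="control", alpha_levels=(1.5,))
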