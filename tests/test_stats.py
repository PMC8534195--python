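"""Statistics: binning, mixed ANOVA vs projection oracle, t / Wilcoxon / Tukey."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from usvkit.stats import (
    bin_counts,
    independent_t,
    mixed_anova,
    oneway_anova_calltypes,
    paired_t,
    proportion_summary,
    wilcoxon_rank_sum,
)

from oracles import projection_mixed_anova, ranksum_exact_p


def _table(rows):
    return pd.DataFrame(rows, columns=["rat_id", "sex", "drug", "epoch", "time_s", "label"])


def _anova_fixture(rng, n_f=8, n_m=8, n_bins=3, effects=True):
    recs = []
    for i in range(n_f + n_m):
        sex = "F" if i < n_f else "M"
        base = rng.normal(0, 2)
        for d in ("VEH", "CNO"):
            for t in range(n_bins):
                mu = 5 + base
                if effects:
                    mu += 2 * (d == "VEH") + 0.8 * t * t + 0.5 * (sex == "F") * t
                recs.append(
                    dict(rat_id=f"r{i:02d}", sex=sex, drug=d, bin=t,
                         count=mu + rng.normal(0, 1 + 0.5 * t))
                )
    return pd.DataFrame(recs)


class TestBinCounts:
    def test_half_open_bin_boundary(self):
        t = _table([("r0", "F", "VEH", "baseline", 600.0, "FM")])
        c = bin_counts(t)
        hit = c[(c["count"] > 0)]
        assert len(hit) == 1 and hit["bin"].iloc[0] == 1  # second 10-min bin

    def test_empty_table_gives_full_zero_index(self):
        t = _table([("r0", "F", "VEH", "baseline", 10.0, "FM")]).iloc[:0]
        rats = pd.DataFrame({"rat_id": ["r0"], "sex": ["F"]})
        c = bin_counts(t, rats=rats, drugs=["VEH"])
        # one rat x one drug x (3 + 6 bins) x 4 labels, all zero
        assert len(c) == (3 + 6) * 4 and c["count"].sum() == 0

    def test_uniform_calls_spread_evenly(self):
        times = np.arange(90) * 20.0  # 90 calls over 30 min
        t = _table([("r0", "F", "VEH", "baseline", s, "FM") for s in times])
        c = bin_counts(t)
        fm_base = c[(c["label"] == "FM") & (c["epoch"] == "baseline")]
        assert list(fm_base.sort_values("bin")["count"]) == [30, 30, 30]

    def test_marginals_match_table(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"r{i}", "F", d, e, rng.uniform(0, 1790 if e == "baseline" else 3590), lab)
            for i in range(3)
            for d in ("VEH", "CNO")
            for e in ("baseline", "post_amph")
            for lab in ("LF", "Flat", "FM", "Trill")
        ]
        t = _table(rows)
        assert bin_counts(t)["count"].sum() == len(t)

    def test_time_outside_epoch_raises(self):
        t = _table([("r0", "F", "VEH", "baseline", 1800.0, "FM")])
        with pytest.raises(ValueError, match="outside"):
            bin_counts(t)


class TestMixedAnova:
    def test_constant_dv_gives_zero_f(self):
        rng = np.random.default_rng(1)
        df = _anova_fixture(rng)
        df["count"] = 7.0
        for r in mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex"):
            assert r.statistic == 0.0

    def test_two_level_within_equals_squared_paired_t(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.7, 1, 12)
        df = pd.DataFrame(
            {"rat_id": [f"r{i}" for i in range(12)] * 2,
             "drug": ["VEH"] * 12 + ["CNO"] * 12,
             "count": np.r_[x, y]}
        )
        res = mixed_anova(df, "count", "rat_id", ("drug",), None)
        t = paired_t(x, y)
        assert res[0].statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert res[0].epsilon == 1.0  # two levels are trivially spherical

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_projection_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_f, n_m = (8, 8) if trial % 2 == 0 else (9, 7)
        df = _anova_fixture(rng, n_f=n_f, n_m=n_m, n_bins=3 if trial < 5 else 6)
        mine = {r.term: r for r in mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex")}
        oracle = projection_mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex")
        for term, (F, df1, df2, eps) in oracle.items():
            r = mine[term]
            assert r.statistic == pytest.approx(F, abs=1e-8), term
            assert r.df_uncorrected == (df1, df2), term
            if eps is not None:
                assert r.epsilon == pytest.approx(eps, abs=1e-8), term
            p_oracle = float(f_dist.sf(F, df1, df2))
            assert r.p_uncorrected == pytest.approx(p_oracle, abs=1e-8), term

    def test_epsilon_bounds(self):
        for trial in range(5):
            rng = np.random.default_rng(200 + trial)
            df = _anova_fixture(rng, n_bins=4)
            for r in mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex"):
                if r.epsilon is not None:
                    q = round(r.df_uncorrected[0])
                    # epsilon lives in [1/q, 1] for a q-df within effect
                    assert 1.0 / max(q, 1) - 1e-12 <= r.epsilon <= 1.0 + 1e-12

    def test_missing_cell_raises(self, rng):
        df = _anova_fixture(rng)
        df = df[~((df["rat_id"] == "r00") & (df["drug"] == "CNO") & (df["bin"] == 2))]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex")

    def test_single_sex_drops_between_with_warning(self, rng):
        df = _anova_fixture(rng, n_f=8, n_m=0)
        with pytest.warns(UserWarning, match="single level"):
            res = mixed_anova(df, "count", "rat_id", ("drug", "bin"), "sex")
        assert all("sex" not in r.term for r in res)


class TestTTests:
    def test_identical_paired_vectors(self):
        r = paired_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_constant_nonzero_differences_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2.0, 3, 4, 5], [1.0, 2, 3, 4])

    def test_paired_matches_closed_form(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        d = x - y
        t_expect = d.mean() / (d.std(ddof=1) / math.sqrt(10))
        assert paired_t(x, y).statistic == pytest.approx(t_expect, rel=1e-12)

    def test_independent_matches_closed_form(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 12)
        sp2 = ((7 * a.var(ddof=1)) + (11 * b.var(ddof=1))) / 18
        t_expect = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 8 + 1 / 12))
        assert independent_t(a, b).statistic == pytest.approx(t_expect, rel=1e-12)


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        r = wilcoxon_rank_sum([1.0, 1, 1, 1], [1.0, 1, 1, 1])
        assert r.p == 1.0 and r.method == "wilcoxon_exact"

    def test_complete_separation_8v8(self):
        a = np.arange(1.0, 9.0)
        b = np.arange(101.0, 109.0)
        r = wilcoxon_rank_sum(a, b)
        # extreme split: both one-sided tails have a single split each
        assert r.statistic == 36.0  # ranks 1..8
        assert r.p == pytest.approx(2.0 * math.factorial(8) ** 2 / math.factorial(16),
                                    rel=1e-12)

    def test_exact_p_matches_enumeration_with_ties(self, rng):
        a = np.round(rng.normal(5, 1, 8), 0)
        b = np.round(rng.normal(6, 1, 8), 0)
        r = wilcoxon_rank_sum(a, b)
        assert r.method == "wilcoxon_exact"
        assert r.p == pytest.approx(ranksum_exact_p(a, b), abs=1e-12)

    def test_normal_approximation_beyond_cutoff(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        r = wilcoxon_rank_sum(a, b)
        assert r.method == "wilcoxon_normal" and 0 <= r.p <= 1

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestOnewayTukey:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame({"label": ["A"] * 4 + ["B"] * 4, "value": [3.0] * 8})
        res, _ = oneway_anova_calltypes(df)
        assert res.statistic == 0.0

    def test_two_groups_equal_squared_t(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(1, 1, 7)
        df = pd.DataFrame({"label": ["A"] * 9 + ["B"] * 7, "value": np.r_[a, b]})
        res, _ = oneway_anova_calltypes(df)
        assert res.statistic == pytest.approx(independent_t(a, b).statistic ** 2, rel=1e-10)

    def test_small_group_dropped_with_warning(self, rng):
        df = pd.DataFrame(
            {"label": ["A"] * 5 + ["B"] * 5 + ["C"], "value": rng.normal(0, 1, 11)}
        )
        with pytest.warns(UserWarning, match="dropped"):
            res, tukey = oneway_anova_calltypes(df)
        assert set(tukey["group_a"]) | set(tukey["group_b"]) == {"A", "B"}

    def test_tukey_flags_shifted_pairs(self):
        hits, runs = 0, 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "label": ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                    "value": np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                                   rng.normal(3, 1, 10)],
                }
            )
            _, tukey = oneway_anova_calltypes(df)
            tk = {frozenset((r.group_a, r.group_b)): r.p < 0.05 for r in tukey.itertuples()}
            correct = (
                tk[frozenset(("A", "C"))] and tk[frozenset(("B", "C"))]
                and not tk[frozenset(("A", "B"))]
            )
            hits += correct
        assert hits >= 95


class TestProportions:
    def test_single_type_gets_proportion_one(self):
        t = _table([("r0", "F", "VEH", "baseline", 10.0 * i, "Trill") for i in range(5)])
        props = proportion_summary(t, "baseline")
        assert props.loc["r0", "Trill"] == 1.0

    def test_uniform_counts(self):
        rows = [
            ("r0", "F", "VEH", "baseline", float(i * 40 + j * 10), lab)
            for i, lab in enumerate(("LF", "Flat", "FM", "Trill"))
            for j in range(4)
        ]
        props = proportion_summary(_table(rows), "baseline")
        assert np.allclose(props.loc["r0"], 0.25)

    def test_rows_sum_to_one(self, rng):
        labs = np.array(["LF", "Flat", "FM", "Trill"])
        rows = [
            (f"r{i}", "F", "VEH", "baseline", float(rng.uniform(0, 1700)),
             labs[rng.integers(0, 4)])
            for i in range(4)
            for _ in range(20)
        ]
        props = proportion_summary(_table(rows), "baseline")
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_rat_excluded_with_warning(self):
        rows = [("r0", "F", "VEH", "baseline", 5.0, "FM"),
                ("r1", "F", "VEH", "post_amph", 5.0, "FM")]
        with pytest.warns(UserWarning, match="excluded"):
            props = proportion_summary(_table(rows), "baseline")
        assert list(props.index) == ["r0"]
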