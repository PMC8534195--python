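"""The full statistical battery over a labeled per-call session table.

Given a table with one row per call (rat_id, sex, drug, epoch, time_s,
label, optionally the four features) this module runs the standard design:

* per call type, mixed ANOVA on 10-min binned counts with within-subject
  Drug and Time factors and a between-subject Sex factor, separately for
  the baseline and post-injection epochs;
* the same for FM and Trill counts combined;
* per call type, paired t test of the last baseline bin against the first
  post-injection bin (vehicle day) — the acute drug response;
* Wilcoxon rank-sum on per-rat call-type proportions, pre vs post
  (vehicle day);
* per call type and feature, paired t of vehicle vs CNO per-rat averages;
* one-way ANOVA with Tukey HSD comparing call types on each feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from usvkit.features import FEATURE_COLUMNS
from usvkit.stats import (
    CALL_TYPES,
    bin_counts,
    mixed_anova,
    oneway_anova_calltypes,
    paired_t,
    proportion_summary,
    wilcoxon_rank_sum,
)


def _anova_rows(results, analysis, label):
    rows = []
    for r in results:
        d = r.as_dict()
        d["analysis"] = analysis
        d["label"] = label
        rows.append(d)
    return rows


def drug_effect_anovas(
    counts: pd.DataFrame,
    labels=CALL_TYPES,
    combine_fm_trill: bool = True,
    epochs=("baseline", "post_amph"),
) -> pd.DataFrame:
    """Mixed Drug x Time (x Sex) ANOVAs on binned counts, per call type.

    Sessions short enough to span a single 10-min bin lose the Time factor
    (Drug-only within design).
    """
    rows = []
    single_sex = counts["sex"].nunique() < 2
    between = None if single_sex else "sex"
    targets: list[tuple[str, pd.DataFrame]] = [
        (lab, counts[counts["label"] == lab]) for lab in labels
    ]
    if combine_fm_trill:
        both = counts[counts["label"].isin(["FM", "Trill"])]
        combined = (
            both.groupby(["rat_id", "sex", "drug", "epoch", "bin"], observed=True)[
                "count"
            ]
            .sum()
            .reset_index()
        )
        combined["label"] = "FM+Trill"
        targets.append(("FM+Trill", combined))
    for epoch in epochs:
        for lab, sub in targets:
            sub_e = sub[sub["epoch"] == epoch]
            if sub_e.empty:
                continue
            within = ("drug", "bin") if sub_e["bin"].nunique() > 1 else ("drug",)
            res = mixed_anova(
                sub_e, dv="count", subject="rat_id", within=within, between=between,
            )
            rows.extend(_anova_rows(res, f"{epoch}_counts", lab))
    out = pd.DataFrame(rows)
    return out


def acute_response_ttests(counts: pd.DataFrame, day: str = "VEH") -> pd.DataFrame:
    """Per type: paired t of last baseline bin vs first post bin (one day)."""
    rows = []
    sub = counts[counts["drug"] == day]
    nb_base = sub[sub["epoch"] == "baseline"]["bin"].max()
    last_base = sub[(sub["epoch"] == "baseline") & (sub["bin"] == nb_base)]
    first_post = sub[(sub["epoch"] == "post_amph") & (sub["bin"] == 0)]
    for lab in CALL_TYPES:
        pre = (
            last_base[last_base["label"] == lab].set_index("rat_id")["count"].sort_index()
        )
        post = (
            first_post[first_post["label"] == lab].set_index("rat_id")["count"].sort_index()
        )
        if pre.empty or not pre.index.equals(post.index):
            continue
        try:
            r = paired_t(post.to_numpy(), pre.to_numpy())
        except ValueError as err:
            warnings.warn(f"acute t-test for {lab}: {err}", UserWarning)
            continue
        d = r.as_dict()
        d["analysis"] = "acute_pre_post_t"
        d["label"] = lab
        rows.append(d)
    return pd.DataFrame(rows)


def proportion_shift_tests(table: pd.DataFrame, day: str = "VEH") -> pd.DataFrame:
    """Wilcoxon rank-sum of per-rat type proportions, baseline vs post."""
    sub = table[table["drug"] == day]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pre = proportion_summary(sub, "baseline")
        post = proportion_summary(sub, "post_amph")
    for lab in CALL_TYPES:
        a = post[lab].dropna().to_numpy() if lab in post else np.empty(0)
        b = pre[lab].dropna().to_numpy() if lab in pre else np.empty(0)
        if a.size == 0 or b.size == 0:
            continue
        r = wilcoxon_rank_sum(a, b)
        d = r.as_dict()
        d["analysis"] = "proportion_pre_vs_post"
        d["label"] = lab
        rows.append(d)
    return pd.DataFrame(rows)


def feature_drug_ttests(table: pd.DataFrame, labels=("FM", "Trill")) -> pd.DataFrame:
    """Paired t of VEH vs CNO per-rat feature averages (post epoch)."""
    if not set(FEATURE_COLUMNS) <= set(table.columns):
        return pd.DataFrame()
    sub = table[table["epoch"] == "post_amph"]
    rows = []
    for lab in labels:
        calls = sub[sub["label"] == lab]
        means = calls.groupby(["rat_id", "drug"], observed=True)[
            list(FEATURE_COLUMNS)
        ].mean()
        for featcol in FEATURE_COLUMNS:
            wide = means[featcol].unstack("drug")
            wide = wide.dropna()
            if wide.shape[0] < 2 or wide.shape[1] < 2:
                continue
            try:
                r = paired_t(wide["VEH"].to_numpy(), wide["CNO"].to_numpy())
            except ValueError as err:
                warnings.warn(f"feature t-test {lab}/{featcol}: {err}", UserWarning)
                continue
            d = r.as_dict()
            d["analysis"] = f"feature_veh_vs_cno:{featcol}"
            d["label"] = lab
            rows.append(d)
    return pd.DataFrame(rows)


def calltype_feature_anovas(table: pd.DataFrame, day: str = "VEH") -> pd.DataFrame:
    """One-way ANOVA + Tukey across call types on per-rat feature means.

    Uses post-injection vehicle-day calls; rats that never emit a type
    simply contribute no observation for it (between-subjects design).
    """
    if not set(FEATURE_COLUMNS) <= set(table.columns):
        return pd.DataFrame()
    sub = table[(table["epoch"] == "post_amph") & (table["drug"] == day)]
    rows = []
    for featcol in FEATURE_COLUMNS:
        means = (
            sub.groupby(["rat_id", "label"], observed=True)[featcol]
            .mean()
            .reset_index()
            .rename(columns={featcol: "value"})
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res, tukey = oneway_anova_calltypes(means)
        except ValueError:
            continue
        d = res.as_dict()
        d["analysis"] = f"calltype_oneway:{featcol}"
        d["label"] = "all"
        rows.append(d)
        for _, tk in tukey.iterrows():
            rows.append(
                {
                    "analysis": f"calltype_tukey:{featcol}",
                    "label": f"{tk.group_a} vs {tk.group_b}",
                    "term": "pairwise",
                    "statistic": tk.mean_diff,
                    "p": tk.p,
                    "method": "tukey_hsd",
                }
            )
    return pd.DataFrame(rows)


def analyze_experiment(
    table: pd.DataFrame,
    baseline_minutes: float = 30.0,
    post_minutes: float = 60.0,
) -> pd.DataFrame:
    """Run the full battery; returns one tidy DataFrame of test results."""
    counts = bin_counts(
        table, baseline_minutes=baseline_minutes, post_minutes=post_minutes
    )
    parts = [
        drug_effect_anovas(counts),
        acute_response_ttests(counts),
        proportion_shift_tests(table),
        feature_drug_ttests(table),
        calltype_feature_anovas(table),
    ]
    parts = [p for p in parts if not p.empty]
    out = pd.concat(parts, ignore_index=True)
    lead = ["analysis", "label", "term", "statistic", "df1", "df2", "epsilon", "p",
            "correction_applied", "method"]
    cols = [c for c in lead if c in out.columns]
    return out[cols + [c for c in out.columns if c not in cols]]
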