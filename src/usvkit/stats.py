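"""Statistical battery for binned call counts and per-call features.

Implements the repeated-measures design used in within-subject drug
studies: counts per 10-min bin analyzed by a mixed ANOVA with
within-subject Drug and Time factors and a between-subject Sex factor,
with Greenhouse-Geisser sphericity correction; paired/independent t tests;
exact Wilcoxon rank-sum on call-type proportions; and one-way ANOVA with
Tukey HSD across call types.

The mixed ANOVA uses the multivariate contrast formulation: for each
within-subject effect an orthonormal contrast of the subject x cell matrix
is regressed on the between-subject design, the univariate F pools the
contrast columns, and the Greenhouse-Geisser epsilon comes from the pooled
covariance of the contrast scores.  Type-III hypotheses via effect coding.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

CALL_TYPES = ("LF", "Flat", "FM", "Trill")


@dataclass
class TestResult:
    """One fitted test: statistic, (possibly fractional) dfs, epsilon, p.

    For within-subject ANOVA terms both the uncorrected and the
    Greenhouse-Geisser-corrected results are kept; ``p`` and ``df`` hold the
    headline values (corrected when ``correction_applied``).
    """

    term: str
    statistic: float
    df: tuple[float, float] | None
    p: float
    epsilon: float | None = None
    correction_applied: bool = False
    p_uncorrected: float | None = None
    p_gg: float | None = None
    df_uncorrected: tuple[float, float] | None = None
    sphericity_p: float | None = None
    method: str = ""

    def as_dict(self) -> dict:
        d1, d2 = self.df if self.df is not None else (math.nan, math.nan)
        return {
            "term": self.term,
            "statistic": self.statistic,
            "df1": d1,
            "df2": d2,
            "epsilon": self.epsilon,
            "p": self.p,
            "correction_applied": self.correction_applied,
            "method": self.method,
        }


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# Binned counts
# ---------------------------------------------------------------------------

EPOCHS = ("baseline", "post_amph")


def n_bins(epoch: str, bin_minutes: float = 10.0, baseline_minutes: float = 30.0,
           post_minutes: float = 60.0) -> int:
    span = baseline_minutes if epoch == "baseline" else post_minutes
    return int(math.ceil(span / bin_minutes))


def bin_counts(
    table: pd.DataFrame,
    bin_minutes: float = 10.0,
    baseline_minutes: float = 30.0,
    post_minutes: float = 60.0,
    labels: tuple[str, ...] = CALL_TYPES,
    rats: pd.DataFrame | None = None,
    drugs: list[str] | None = None,
) -> pd.DataFrame:
    """Quantify calls in 10-min bins per (rat, sex, drug, epoch, bin, label).

    Bin boundaries are half-open ``[start, end)``; the full index is
    produced, so cells with no calls appear as explicit zeros.  Raises if a
    call's in-epoch time falls outside its epoch span.  ``rats`` (a frame
    with rat_id and sex) and ``drugs`` widen the index beyond what the
    table mentions, e.g. for rats that emitted nothing.
    """
    req = {"rat_id", "sex", "drug", "epoch", "time_s", "label"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    spans = {"baseline": baseline_minutes * 60.0, "post_amph": post_minutes * 60.0}
    nb = {e: n_bins(e, bin_minutes, baseline_minutes, post_minutes) for e in EPOCHS}

    t = table["time_s"].to_numpy(dtype=float)
    epoch = table["epoch"].to_numpy()
    for e, span in spans.items():
        bad = (epoch == e) & ((t < 0) | (t >= span))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"call at t={t[i]:.1f}s outside the {e} epoch span [0, {span:.0f}s)"
            )
    binned = table.copy()
    binned["bin"] = (t // (bin_minutes * 60.0)).astype(int)

    if rats is None:
        rats = table[["rat_id", "sex"]].drop_duplicates().sort_values("rat_id")
    if drugs is None:
        drugs = sorted(table["drug"].unique())
    counts = (
        binned.groupby(["rat_id", "drug", "epoch", "bin", "label"], observed=True)
        .size()
        .rename("count")
    )
    frames = []
    for e in EPOCHS:
        idx = pd.MultiIndex.from_product(
            [rats["rat_id"], drugs, [e], range(nb[e]), labels],
            names=["rat_id", "drug", "epoch", "bin", "label"],
        )
        frames.append(counts.reindex(idx, fill_value=0))
    out = pd.concat(frames).reset_index()
    out = out.merge(rats, on="rat_id", how="left")
    return out[["rat_id", "sex", "drug", "epoch", "bin", "label", "count"]]


# ---------------------------------------------------------------------------
# Mixed ANOVA (within x within x between)
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) matrix with orthonormal rows orthogonal to the constant."""
    return linalg.helmert(k, full=False)


def _effect_code(groups: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(groups.unique())
    g = len(levels)
    cols = np.zeros((groups.size, g - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(groups == lev, 1.0, np.where(groups == levels[-1], -1.0, 0.0))
    return cols, levels


def _hypothesis_ss(B: np.ndarray, xtx_inv: np.ndarray, rows: list[int]) -> float:
    L = np.zeros((len(rows), B.shape[0]))
    for i, r in enumerate(rows):
        L[i, r] = 1.0
    LB = L @ B  # (h, q)
    M = L @ xtx_inv @ L.T
    return float(np.trace(LB.T @ np.linalg.solve(M, LB)))


def _gg_epsilon(sigma: np.ndarray) -> float:
    q = sigma.shape[0]
    tr = float(np.trace(sigma))
    ss = float(np.sum(sigma * sigma))
    if ss <= 0:
        return 1.0
    eps = tr * tr / (q * ss)
    return float(min(1.0, max(1.0 / q, eps)))


def _mauchly_p(sigma: np.ndarray, n_error: int) -> float:
    q = sigma.shape[0]
    if q < 2:
        return 1.0
    tr = float(np.trace(sigma))
    det = float(np.linalg.det(sigma))
    if tr <= 0 or det <= 0:
        return 0.0
    w = det / (tr / q) ** q
    chi2 = -(n_error - (2 * q * q + q + 2) / (6.0 * q)) * math.log(w)
    dof = q * (q + 1) // 2 - 1
    return float(sps.chi2.sf(max(chi2, 0.0), dof))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: tuple[str, ...] | str,
    between: str | None = None,
) -> list[TestResult]:
    """Repeated-measures ANOVA with 1-2 within factors and 0-1 between factor.

    ``data`` is long-format with one row per subject x within-cell.  Every
    subject must have every within cell (zeros are data; missing cells raise).
    Returns results for the between main effect, each within main effect and
    interaction, and their interactions with the between factor.  Within
    terms carry a Greenhouse-Geisser epsilon; the correction is applied to
    the headline p when a Mauchly-style sphericity check rejects at 0.05.
    """
    if isinstance(within, str):
        within = (within,)
    if not 1 <= len(within) <= 2:
        raise ValueError("1 or 2 within factors supported")

    wide = data.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    levels = [sorted(data[w].unique()) for w in within]
    full_cols = (
        pd.MultiIndex.from_product(levels, names=list(within))
        if len(within) == 2
        else pd.Index(levels[0], name=within[0])
    )
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        miss = [
            (s, c) for s in wide.index for c in wide.columns if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"missing within-subject cells: {miss[:10]}")
    Y = wide.to_numpy(dtype=float)
    N = Y.shape[0]

    if between is not None:
        grp = data.groupby(subject)[between].agg(lambda s: s.iloc[0]).reindex(wide.index)
        check = data.groupby(subject)[between].nunique()
        if (check > 1).any():
            raise ValueError("between factor varies within a subject")
        if grp.nunique() < 2:
            warnings.warn(
                f"between factor {between!r} has a single level; dropping it", UserWarning
            )
            between = None
    if between is not None:
        Xb, _ = _effect_code(grp)
        X = np.column_stack([np.ones(N), Xb])
        g = Xb.shape[1] + 1
    else:
        X = np.ones((N, 1))
        g = 1
    if N - g < 1:
        raise ValueError("not enough subjects for the between design")
    xtx_inv = np.linalg.inv(X.T @ X)
    between_rows = list(range(1, X.shape[1]))
    # numerical floor: sums of squares at rounding-noise level count as zero
    ss_tol = 1e-12 * max(1.0, float(np.sum(Y * Y)))

    # contrast matrices per within effect over the flattened cell axis
    ks = [len(l) for l in levels]
    effects: list[tuple[str, np.ndarray]] = []
    if len(within) == 1:
        effects.append((within[0], _orthonormal_contrasts(ks[0])))
    else:
        C1 = _orthonormal_contrasts(ks[0])
        C2 = _orthonormal_contrasts(ks[1])
        u1 = np.full((1, ks[0]), 1.0 / math.sqrt(ks[0]))
        u2 = np.full((1, ks[1]), 1.0 / math.sqrt(ks[1]))
        effects.append((within[0], np.kron(C1, u2)))
        effects.append((within[1], np.kron(u1, C2)))
        effects.append((f"{within[0]}:{within[1]}", np.kron(C1, C2)))

    results: list[TestResult] = []

    if between is not None:
        u_all = np.full((1, Y.shape[1]), 1.0 / math.sqrt(Y.shape[1]))
        Z0 = Y @ u_all.T
        B = np.linalg.lstsq(X, Z0, rcond=None)[0]
        E = Z0 - X @ B
        ss_h = _hypothesis_ss(B, xtx_inv, between_rows)
        ss_e = float(np.sum(E * E))
        df1, df2 = float(g - 1), float(N - g)
        if ss_e > ss_tol:
            F = (ss_h / df1) / (ss_e / df2)
        else:
            F = 0.0 if ss_h <= ss_tol else math.inf
        p = float(sps.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
        results.append(
            TestResult(
                term=between, statistic=F, df=(df1, df2), p=p,
                p_uncorrected=p, df_uncorrected=(df1, df2), method="mixed_anova",
            )
        )

    for name, C in effects:
        q = C.shape[0]
        Z = Y @ C.T
        B = np.linalg.lstsq(X, Z, rcond=None)[0]
        E = Z - X @ B
        sigma = (E.T @ E) / (N - g)
        ss_e = float(np.trace(E.T @ E))
        df_e = float(q * (N - g))

        terms = [(name, [0])]
        if between is not None:
            terms.append((f"{name}:{between}", between_rows))
        for term_name, rows in terms:
            ss_h = _hypothesis_ss(B, xtx_inv, rows)
            df_h = float(q * len(rows))
            if ss_e > ss_tol:
                F = (ss_h / df_h) / (ss_e / df_e)
            else:
                F = 0.0 if ss_h <= ss_tol else math.inf
            eps = _gg_epsilon(sigma)
            sph_p = _mauchly_p(sigma, N - g)
            p_unc = float(sps.f.sf(F, df_h, df_e)) if math.isfinite(F) else 0.0
            p_gg = float(sps.f.sf(F, df_h * eps, df_e * eps)) if math.isfinite(F) else 0.0
            applied = q > 1 and sph_p < 0.05
            results.append(
                TestResult(
                    term=term_name,
                    statistic=F,
                    df=(df_h * eps, df_e * eps) if applied else (df_h, df_e),
                    p=p_gg if applied else p_unc,
                    epsilon=eps,
                    correction_applied=applied,
                    p_uncorrected=p_unc,
                    p_gg=p_gg,
                    df_uncorrected=(df_h, df_e),
                    sphericity_p=sph_p,
                    method="mixed_anova",
                )
            )
    return results


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def paired_t(x, y) -> TestResult:
    """Paired t test; raises on zero-variance nonzero differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("paired", 0.0, (float(x.size - 1), math.nan),
                              1.0, method="paired_t")
        raise ValueError("zero variance of nonzero differences: t undefined")
    t, p = sps.ttest_rel(x, y)
    return TestResult("paired", float(t), (float(x.size - 1), math.nan), float(p),
                      method="paired_t")


def independent_t(a, b) -> TestResult:
    """Two-sample t test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult("independent", 0.0, (float(a.size + b.size - 2), math.nan),
                              1.0, method="independent_t")
        raise ValueError("zero within-group variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult("independent", float(t), (float(a.size + b.size - 2), math.nan),
                      float(p), method="independent_t")


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(group_a, group_b, exact_max_n: int = 20) -> TestResult:
    """Wilcoxon rank-sum test (statistic = rank sum of the first group).

    Uses midranks for ties.  With ``n_a + n_b <= exact_max_n`` the two-sided
    p is exact: every assignment of the (tied) midranks to group A is
    enumerated and ``p = 2 min(P(W <= w), P(W >= w))`` capped at 1.  Larger
    samples use the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    w = float(ranks[: a.size].sum())
    n, na = combined.size, a.size

    if n <= exact_max_n:
        total = math.comb(n, na)
        n_le = n_ge = 0
        for idx in itertools.combinations(range(n), na):
            s = ranks[list(idx)].sum()
            if s <= w + 1e-9:
                n_le += 1
            if s >= w - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult("rank_sum", w, None, p, method="wilcoxon_exact")

    mean = na * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = na * (n - na) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult("rank_sum", w, None, 1.0, method="wilcoxon_normal")
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult("rank_sum", w, None, min(1.0, p), method="wilcoxon_normal")


# ---------------------------------------------------------------------------
# One-way ANOVA across call types + Tukey HSD
# ---------------------------------------------------------------------------


def oneway_anova_calltypes(
    values: pd.DataFrame, value_col: str = "value", group_col: str = "label"
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA over call types with Tukey HSD pairwise comparisons.

    ``values`` holds one row per (rat, call type) mean.  Groups with fewer
    than 2 observations are dropped with a warning (not every rat emits
    every call type, so the design is between-subjects and unbalanced;
    Tukey-Kramer handles the unequal ns).
    """
    groups: dict[str, np.ndarray] = {}
    for name, sub in values.groupby(group_col, observed=True):
        v = sub[value_col].to_numpy(dtype=float)
        if v.size < 2:
            warnings.warn(f"group {name!r} has < 2 observations; dropped", UserWarning)
            continue
        groups[str(name)] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    names = list(groups)
    samples = [groups[k] for k in names]
    df1 = float(len(names) - 1)
    df2 = float(sum(len(s) for s in samples) - len(names))

    if np.ptp(np.concatenate(samples)) == 0:  # fully degenerate data
        res = TestResult("call_type", 0.0, (df1, df2), 1.0, method="oneway_anova")
        rows = [
            {"group_a": names[i], "group_b": names[j], "mean_diff": 0.0, "p": 1.0}
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
        return res, pd.DataFrame(rows)

    F, p = sps.f_oneway(*samples)
    res = TestResult("call_type", float(F), (df1, df2), float(p), method="oneway_anova")

    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p": float(hsd.pvalue[i, j]),
            }
        )
    return res, pd.DataFrame(rows)


def proportion_summary(
    table: pd.DataFrame,
    epoch: str,
    labels: tuple[str, ...] = CALL_TYPES,
    group_col: str = "rat_id",
) -> pd.DataFrame:
    """Per-rat call-type proportions within one epoch (rows sum to 1).

    Rats with no calls in the epoch are excluded with a warning.
    """
    sub = table[table["epoch"] == epoch]
    counts = (
        sub.groupby([group_col, "label"], observed=True).size().unstack(fill_value=0)
    )
    all_rats = pd.Index(sorted(table[group_col].unique()), name=group_col)
    counts = counts.reindex(index=all_rats, columns=labels, fill_value=0).fillna(0)
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"no calls in {epoch} for {empty}; excluded", UserWarning)
        counts = counts.loc[totals > 0]
        totals = totals[totals > 0]
    return counts.div(totals, axis=0)
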