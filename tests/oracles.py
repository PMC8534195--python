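"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the mixed-ANOVA
oracle fits an observation-level design matrix and takes type-III RSS
differences; the rank-sum oracle builds the exact null distribution of the
rank-sum statistic by dynamic programming over (doubled, integer) midranks;
the sinuosity oracle integrates the arc length by adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import rankdata


def _ecode(levels, val):
    v = np.zeros(len(levels) - 1)
    for j, lev in enumerate(levels[:-1]):
        if val == lev:
            v[j] = 1
    if val == levels[-1]:
        v[:] = -1
    return v


def projection_mixed_anova(df: pd.DataFrame, dv, subject, within, between):
    """Split-plot ANOVA by observation-level type-III projections.

    Returns {term: (F, df1, df2, epsilon)} for the same terms the package
    reports; epsilon comes from the eigenvalues of the contrast-projected
    pooled cell covariance (None for between terms).
    """
    w1, w2 = within
    subs = sorted(df[subject].unique())
    l1, l2 = sorted(df[w1].unique()), sorted(df[w2].unique())
    a, b = len(l1), len(l2)
    grp = {s: df[df[subject] == s][between].iloc[0] for s in subs}
    glevels = sorted(set(grp.values()))
    g, N = len(glevels), len(subs)
    subs_by_g = {gl: [s for s in subs if grp[s] == gl] for gl in glevels}

    rows, ys = [], []
    for _, r in df.iterrows():
        s = r[subject]
        S = _ecode(glevels, grp[s])
        D = _ecode(l1, r[w1])
        T = _ecode(l2, r[w2])
        DT = np.kron(D, T)
        sub_block = [
            _ecode(subs_by_g[gl], s) if grp[s] == gl else np.zeros(len(subs_by_g[gl]) - 1)
            for gl in glevels
        ]
        U = np.concatenate(sub_block)
        rows.append(
            dict(S=S, D=D, T=T, SD=np.kron(S, D), ST=np.kron(S, T), DT=DT,
                 SDT=np.kron(S, DT), U=U, UD=np.kron(U, D), UT=np.kron(U, T))
        )
        ys.append(r[dv])
    y = np.asarray(ys, float)
    names = ["S", "D", "T", "SD", "ST", "DT", "SDT", "U", "UD", "UT"]
    blocks = {nm: np.array([r[nm] for r in rows]) for nm in names}

    def rss(cols):
        X = np.column_stack([np.ones(len(y))] + cols)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return float(np.sum((y - X @ beta) ** 2))

    rss_full = rss([blocks[nm] for nm in names])
    ss = {nm: rss([blocks[k] for k in names if k != nm]) - rss_full for nm in names}
    dfs = dict(S=g - 1, D=a - 1, T=b - 1, SD=(g - 1) * (a - 1), ST=(g - 1) * (b - 1),
               DT=(a - 1) * (b - 1), SDT=(g - 1) * (a - 1) * (b - 1), U=N - g,
               UD=(a - 1) * (N - g), UT=(b - 1) * (N - g))
    df_res = (a - 1) * (b - 1) * (N - g)

    # pooled within-group covariance of the subject x cell matrix, for epsilon
    wide = df.pivot_table(index=subject, columns=[w1, w2], values=dv)
    cols = pd.MultiIndex.from_product([l1, l2])
    Y = wide.reindex(columns=cols).to_numpy(float)
    V = np.zeros((a * b, a * b))
    for gl in glevels:
        sel = [i for i, s in enumerate(wide.index) if grp[s] == gl]
        sub = Y[sel]
        dev = sub - sub.mean(axis=0)
        V += dev.T @ dev
    V /= N - g

    from scipy.linalg import helmert

    C1, C2 = helmert(a, full=False), helmert(b, full=False)
    u1 = np.full((1, a), a ** -0.5)
    u2 = np.full((1, b), b ** -0.5)

    def eig_eps(C):
        lam = np.linalg.eigvalsh(C @ V @ C.T)
        lam = np.clip(lam, 0, None)
        if lam.sum() <= 0:
            return 1.0
        return float(min(1.0, max(1.0 / len(lam), lam.sum() ** 2 / (len(lam) * (lam**2).sum()))))

    eps = {
        w1: eig_eps(np.kron(C1, u2)),
        w2: eig_eps(np.kron(u1, C2)),
        f"{w1}:{w2}": eig_eps(np.kron(C1, C2)),
    }

    def F(h, e_ss, e_df):
        return (ss[h] / dfs[h]) / (e_ss / e_df)

    out = {
        between: (F("S", ss["U"], dfs["U"]), dfs["S"], dfs["U"], None),
        w1: (F("D", ss["UD"], dfs["UD"]), dfs["D"], dfs["UD"], eps[w1]),
        f"{w1}:{between}": (F("SD", ss["UD"], dfs["UD"]), dfs["SD"], dfs["UD"], eps[w1]),
        w2: (F("T", ss["UT"], dfs["UT"]), dfs["T"], dfs["UT"], eps[w2]),
        f"{w2}:{between}": (F("ST", ss["UT"], dfs["UT"]), dfs["ST"], dfs["UT"], eps[w2]),
        f"{w1}:{w2}": (
            (ss["DT"] / dfs["DT"]) / (rss_full / df_res), dfs["DT"], df_res,
            eps[f"{w1}:{w2}"],
        ),
        f"{w1}:{w2}:{between}": (
            (ss["SDT"] / dfs["SDT"]) / (rss_full / df_res), dfs["SDT"], df_res,
            eps[f"{w1}:{w2}"],
        ),
    }
    return out


def ranksum_exact_p(a, b) -> float:
    """Exact two-sided rank-sum p by DP over the doubled-midrank multiset."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    combined = np.concatenate([a, b])
    ranks2 = np.round(2 * rankdata(combined)).astype(int)  # doubled midranks
    w2 = int(ranks2[: a.size].sum())
    na, n = a.size, combined.size
    # dist[k][s] = number of k-subsets of the ranks seen so far with doubled sum s
    max_s = int(ranks2.sum())
    dist = np.zeros((na + 1, max_s + 1), dtype=float)
    dist[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(na, n), 0, -1):
            dist[k, r:] += dist[k - 1, : max_s + 1 - r]
    pmf = dist[na]
    total = pmf.sum()
    p_le = pmf[: w2 + 1].sum() / total
    p_ge = pmf[w2:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def sinusoid_arclength_sinuosity(amp_bins: float, cycles: float, n_frames: int) -> float:
    """Quadrature sinuosity of y = amp * sin(2 pi cycles x / L) over L frames."""
    L = float(n_frames)
    om = 2 * np.pi * cycles / L

    def integrand(x):
        return np.sqrt(1.0 + (amp_bins * om * np.cos(om * x)) ** 2)

    path, _ = integrate.quad(integrand, 0.0, L, limit=200)
    return path / L
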