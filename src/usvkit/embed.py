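"""2-D embedding of the four-feature call space and cluster composition.

The four acoustic parameters have incommensurate units, so features are
z-scored before UMAP.  Cluster structure in the 2-D projection is
summarized with k-means (default k = 3) and per-cluster call-type / sex
composition tables; a silhouette profile over k = 2..6 is available for
choosing k.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from usvkit.features import FEATURE_COLUMNS


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant feature column(s) {np.flatnonzero(~keep).tolist()} "
            "before standardization",
            UserWarning,
        )
    return (X[:, keep] - mu[keep]) / sd[keep]


def embed_features(
    X,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """UMAP projection of a feature matrix to 2-D (deterministic per seed)."""
    import umap

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a 2-D matrix with at least 10 calls")
    Z = _standardize(X)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, X.shape[0] - 1),
        min_dist=min_dist,
        random_state=int(seed),
        n_jobs=1,
    )
    coords = np.asarray(reducer.fit_transform(Z), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    # identical inputs get identical outputs: collapse duplicate feature
    # rows onto the coordinates of their first occurrence
    _, first, inverse = np.unique(Z, axis=0, return_index=True, return_inverse=True)
    coords = coords[first[inverse]]
    return coords


def embed_table(
    table: pd.DataFrame,
    seed: int,
    feature_cols: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Embed a per-call table; returns a copy with ``x`` and ``y`` columns."""
    cols = feature_cols or FEATURE_COLUMNS
    coords = embed_features(table[cols].to_numpy(), seed, **kwargs)
    out = table.copy()
    out["x"] = coords[:, 0]
    out["y"] = coords[:, 1]
    return out


def assign_clusters(coords: np.ndarray, k: int = 3, seed: int = 0) -> np.ndarray:
    """k-means cluster ids on 2-D coordinates, relabeled contiguously by size."""
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds the number of calls ({coords.shape[0]})")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw = km.fit_predict(coords)
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def cluster_composition(
    embedded: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    by: tuple[str, ...] = ("label", "sex"),
) -> dict[str, pd.DataFrame]:
    """Per-cluster composition of the embedded calls.

    Returns ``{"assignments": table-with-cluster, "<col>": cluster x level
    proportion table, ...}``; each composition row sums to 1.
    """
    coords = embedded[["x", "y"]].to_numpy()
    cl = assign_clusters(coords, k=k, seed=seed)
    out: dict[str, pd.DataFrame] = {}
    tab = embedded.copy()
    tab["cluster"] = cl
    out["assignments"] = tab
    for col in by:
        if col not in tab.columns:
            continue
        counts = tab.groupby(["cluster", col], observed=True).size().unstack(fill_value=0)
        out[col] = counts.div(counts.sum(axis=1), axis=0)
    return out


def silhouette_profile(coords: np.ndarray, ks=range(2, 7), seed: int = 0) -> pd.Series:
    """Silhouette score of the k-means partition for each candidate k."""
    from sklearn.metrics import silhouette_score

    scores = {}
    for k in ks:
        cl = assign_clusters(coords, k=k, seed=seed)
        scores[k] = float(silhouette_score(coords, cl))
    return pd.Series(scores, name="silhouette")


def plot_embedding(embedded: pd.DataFrame, color_by: str = "label", path=None):
    """Scatter plot of the embedding colored by a categorical column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, sub in embedded.groupby(color_by, observed=True):
        ax.scatter(sub["x"], sub["y"], s=4, label=str(name), alpha=0.6)
    ax.legend(markerscale=3)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
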