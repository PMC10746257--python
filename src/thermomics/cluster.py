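"""RNA/protein fold-change integration and profile clustering.

Per-gene log2 fold changes from the two layers are z-scored within each
layer, projected by PCA (SVD), and clustered on Euclidean distances with
Ward linkage (the ward.D2 criterion: Lance-Williams on squared distances,
heights square-rooted).  The number of clusters is picked by the elbow of
the within-cluster sum of squares curve (maximal second difference), with
the full curve returned so a caller can override k.  Cluster profiles are
summarised as per-condition medians and interquartile ranges.  Also here:
pairwise-complete Pearson correlations and PCA-based replicate outlier
flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster

from .de import OmicsMatrix

__all__ = [
    "ClusterAssignment",
    "pairwise_correlation",
    "zscore_rows",
    "cluster_genes",
    "cluster_profiles",
    "flag_outliers",
    "plot_cluster_profiles",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series                # gene -> 1..k
    k: int
    wss_curve: pd.Series             # k -> within-cluster sum of squares
    linkage_matrix: np.ndarray
    n_pcs: int
    explained_variance: np.ndarray
    n_imputed: int = 0


def pairwise_correlation(
    a: pd.DataFrame, b: pd.DataFrame | None = None, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation between columns.

    Returns ``(r, n)`` where ``n`` counts the complete pairs used; cells
    with fewer than ``min_pairs`` complete pairs are NaN.
    """
    if b is None:
        b = a
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    n = pd.DataFrame(index=a.columns, columns=b.columns, dtype=int)
    for ca in a.columns:
        x = a[ca]
        for cb in b.columns:
            y = b[cb]
            mask = x.notna() & y.notna()
            n.loc[ca, cb] = int(mask.sum())
            if mask.sum() < min_pairs:
                r.loc[ca, cb] = np.nan
                continue
            xv = x[mask].to_numpy(dtype=float)
            yv = y[mask].to_numpy(dtype=float)
            if xv.std() == 0 or yv.std() == 0:
                r.loc[ca, cb] = np.nan
            else:
                r.loc[ca, cb] = float(np.corrcoef(xv, yv)[0, 1])
    return r, n


def zscore_rows(
    fc: pd.DataFrame, per_layer: bool = True
) -> tuple[pd.DataFrame, list]:
    """Z-score each gene's condition vector (per layer when the columns
    carry a (condition, layer) MultiIndex); zero-variance rows dropped.

    Returns the z-scored frame and the list of dropped gene ids.
    """
    if per_layer and isinstance(fc.columns, pd.MultiIndex):
        layers = fc.columns.get_level_values("layer").unique()
        blocks = []
        bad: set = set()
        for layer in layers:
            sub = fc.xs(layer, axis=1, level="layer", drop_level=False)
            mu = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=0)
            bad |= set(sub.index[(sd == 0) & sub.notna().any(axis=1)])
            blocks.append(sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0))
        z = pd.concat(blocks, axis=1)[fc.columns]
    else:
        mu = fc.mean(axis=1)
        sd = fc.std(axis=1, ddof=0)
        bad = set(fc.index[sd == 0])
        z = fc.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    dropped = sorted(bad)
    return z.drop(index=dropped), dropped


def _wss(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def cluster_genes(
    z: pd.DataFrame,
    k_range: range | list[int] = range(2, 9),
    n_pcs: int | str = "auto",
    max_missing: float = 0.5,
    k_override: int | None = None,
) -> ClusterAssignment:
    """Ward-linkage clustering of gene profiles with elbow k selection.

    Genes missing more than ``max_missing`` of their features are
    dropped; remaining missing entries are zero-imputed after z-scoring
    (zero is the profile mean, so imputation is neutral).  ``n_pcs`` =
    "auto" keeps the fewest components explaining >= 90% variance.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    if max(k_range) > len(z) - 1 or min(k_range) < 2:
        raise ValueError("k_range must lie within [2, n_genes - 1]")

    frac_missing = z.isna().mean(axis=1)
    kept = z[frac_missing <= max_missing]
    n_imputed = int(kept.isna().to_numpy().sum())
    x = kept.fillna(0.0).to_numpy(dtype=float)

    x_centered = x - x.mean(axis=0)
    _u, s, vt = np.linalg.svd(x_centered, full_matrices=False)
    var = s**2 / max(len(x) - 1, 1)
    explained = var / var.sum() if var.sum() > 0 else var
    if n_pcs == "auto":
        cum = np.cumsum(explained)
        npc = int(np.searchsorted(cum, 0.90) + 1)
    else:
        npc = min(int(n_pcs), len(s))
    scores = x_centered @ vt[:npc].T

    lm = linkage(scores, method="ward")
    heights = lm[:, 2]
    if np.any(np.diff(heights) < -1e-8):
        raise AssertionError("ward merge heights are not nondecreasing")

    ks = list(range(min(k_range) - 1, max(k_range) + 2))
    ks = [k for k in ks if 1 <= k <= len(kept)]
    wss = {k: _wss(scores, fcluster(lm, t=k, criterion="maxclust")) for k in ks}
    curve = pd.Series(wss).sort_index()

    if k_override is not None:
        k_best = int(k_override)
    else:
        best, k_best = -np.inf, k_range[0]
        for k in k_range:
            if k - 1 in wss and k + 1 in wss:
                d2 = wss[k - 1] - 2 * wss[k] + wss[k + 1]
                if d2 > best:
                    best, k_best = d2, k
    raw = fcluster(lm, t=k_best, criterion="maxclust")
    # relabel clusters contiguously by first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return ClusterAssignment(
        labels=pd.Series(labels, index=kept.index, name="cluster"),
        k=int(k_best),
        wss_curve=curve,
        linkage_matrix=lm,
        n_pcs=npc,
        explained_variance=explained,
        n_imputed=n_imputed,
    )


def cluster_profiles(
    assignment: ClusterAssignment, z: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster, per-column median and IQR of the z-scored profiles."""
    rows = []
    for lab in sorted(assignment.labels.unique()):
        members = assignment.labels.index[assignment.labels == lab]
        sub = z.loc[z.index.intersection(members)]
        med = sub.median(axis=0)
        q1 = sub.quantile(0.25, axis=0)
        q3 = sub.quantile(0.75, axis=0)
        for col in z.columns:
            cond, layer = col if isinstance(col, tuple) else (col, "value")
            rows.append(
                {"cluster": int(lab), "condition": cond, "layer": layer,
                 "n_genes": len(sub), "median": float(med[col]),
                 "iqr": float(q3[col] - q1[col])}
            )
    return pd.DataFrame(rows)


def flag_outliers(values: OmicsMatrix, c: float = 3.5) -> pd.DataFrame:
    """Advisory replicate outlier flags from PCA of log-transformed values.

    Samples are scored on the first two principal components of
    ``log2(x + 1)``; within each condition with >= 3 replicates, a
    replicate is flagged when its distance to the condition centroid
    exceeds ``c`` times the median absolute deviation of the
    within-condition distances.
    """
    logged = np.log2(values.values.fillna(0.0).to_numpy(dtype=float).T + 1.0)
    x = logged - logged.mean(axis=0)
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[:2].T
    frame = pd.DataFrame(scores, index=values.values.columns, columns=["pc1", "pc2"])
    frame["condition"] = values.design.loc[frame.index, "condition"].to_numpy()

    rows = []
    for cond, sub in frame.groupby("condition"):
        if len(sub) < 3:
            for sample in sub.index:
                rows.append({"sample": sample, "condition": cond,
                             "distance": np.nan, "flagged": False,
                             "note": "fewer than 3 replicates"})
            continue
        centroid = sub[["pc1", "pc2"]].mean(axis=0)
        d = np.sqrt(((sub[["pc1", "pc2"]] - centroid) ** 2).sum(axis=1))
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        for sample in sub.index:
            flagged = bool(mad > 0 and d[sample] - med > c * mad)
            rows.append({"sample": sample, "condition": cond,
                         "distance": float(d[sample]), "flagged": flagged,
                         "note": ""})
    return pd.DataFrame(rows).set_index("sample")


def plot_cluster_profiles(profiles: pd.DataFrame, path=None):
    """Basic median/IQR profile plot, one panel per cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted(profiles["cluster"].unique())
    fig, axes = plt.subplots(len(clusters), 1, figsize=(6, 2 * len(clusters)),
                             squeeze=False, sharex=True)
    for ax, lab in zip(axes[:, 0], clusters):
        sub = profiles[profiles["cluster"] == lab]
        for layer, lsub in sub.groupby("layer"):
            xs = np.arange(len(lsub))
            ax.plot(xs, lsub["median"], marker="o", label=str(layer))
            ax.fill_between(xs, lsub["median"] - lsub["iqr"] / 2,
                            lsub["median"] + lsub["iqr"] / 2, alpha=0.2)
            ax.set_xticks(xs)
            ax.set_xticklabels(lsub["condition"], rotation=45)
        ax.set_ylabel(f"cluster {lab}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
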