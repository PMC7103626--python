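"""Z-score normalization, hierarchical clustering and track export.

Samples are clustered on their DMR read-count profiles: each region row is
Z-scored (population SD), pairwise city-block distances are computed
between sample columns, and complete-linkage agglomeration builds the
tree shown in the heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist


@dataclass
class ClusterResult:
    """Agglomeration output for n samples: n-1 merges.

    ``linkage_matrix`` is in scipy format (children, height, size); sample
    labels are sorted lexicographically before clustering so ties break
    deterministically.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    zscores: pd.DataFrame
    constant_rows: pd.Index
    metric: str = "cityblock"
    method: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-row (x - mean) / population SD; constant rows become all-zero.

    Returns (Z matrix, index of constant rows). Constant rows are kept so
    heatmap dimensions stay stable; they carry no clustering signal.
    """
    if matrix.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (x - mean) / sd
    z[constant] = 0.0
    flagged = matrix.index[constant]
    if len(flagged):
        warnings.warn(f"{len(flagged)} constant row(s) set to zero Z-scores", stacklevel=2)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def hcluster(
    z: pd.DataFrame,
    metric: str = "cityblock",
    method: str = "complete",
) -> ClusterResult:
    """Cluster sample columns of a Z-score matrix.

    Columns are sorted by label before linkage, making the agglomeration
    order (and hence ties) deterministic.
    """
    if z.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    if z.isna().to_numpy().any():
        raise ValueError("missing values in Z matrix")
    z = z[sorted(z.columns)]
    d = pdist(z.to_numpy().T, metric=metric)
    lm = linkage(d, method=method)
    return ClusterResult(
        labels=list(z.columns), linkage_matrix=lm, zscores=z,
        constant_rows=pd.Index([]), metric=metric, method=method,
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize the merge tree as Newick with ultrametric branch lengths.

    A node merged at height h sits at depth h/2 from the leaves, so each
    branch length is (parent height - child height) / 2; two samples at
    distance d yield "(A:d/2,B:d/2);".
    """
    lm = result.linkage_matrix
    n = len(result.labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(lm[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = (parent_h - height(node)) / 2.0
        if node < n:
            return f"{result.labels[node]}:{bl:.10g}"
        left, right = int(lm[node - n, 0]), int(lm[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = n + lm.shape[0] - 1
    h = height(root)
    left, right = int(lm[-1, 0]), int(lm[-1, 1])
    return f"({render(left, h)},{render(right, h)});"


def export_dendrogram(result: ClusterResult, path: str | None = None) -> str:
    """Newick string of the tree; optionally written to a file."""
    nwk = to_newick(result)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(nwk + "\n")
    return nwk


def plot_heatmap(result: ClusterResult, path: str) -> None:
    """Z-score heatmap with columns in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.leaf_order()
    z = result.zscores[order]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(order)), 6))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{z.shape[0]} DMRs (Z-score)")
    fig.colorbar(im, ax=ax, shrink=0.6, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_locus_track(
    counts: pd.DataFrame,
    catalog,
    contig: str,
    start: int,
    end: int,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-site scores over an interval, one row per catalog site.

    ``counts`` has one row per catalog site (indexed by site id) and one
    column per sample. With ``groups`` given, columns are replaced by
    per-group means. Empty intervals yield an empty table with a warning.
    """
    ids = catalog.sites_in_interval(contig, start, end)
    if len(ids) == 0:
        warnings.warn(f"no catalog sites in {contig}:{start}-{end}", stacklevel=2)
    sub = counts.loc[ids]
    if groups is not None:
        sub = pd.DataFrame({g: sub[m].mean(axis=1) for g, m in groups.items()}, index=sub.index)
    pos = catalog.sites.loc[ids, "cpg_pos"]
    out = pd.DataFrame({"chrom": contig, "start": pos, "end": pos + 1})
    out = pd.concat([out.reset_index(drop=True), sub.reset_index(drop=True)], axis=1)
    return out
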