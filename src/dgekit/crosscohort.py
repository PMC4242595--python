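"""Cross-cohort DEG comparison and two-way hierarchical clustering.

Overlap between deregulated-gene lists is tested with the hypergeometric
upper tail over a shared detection universe.  Expression profiles are
clustered with average linkage on the uncentered Pearson dissimilarity
(1 - similarity), the metric of Cluster 3.0: the similarity is a cosine
about zero, computed with root-mean-square scaling instead of
mean-centered deviations, so profiles proportional to each other score 1
regardless of offset structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

__all__ = [
    "OverlapResult",
    "Dendrogram",
    "overlap_test",
    "uncentered_pearson",
    "hierarchical_cluster",
    "cluster_heat_export",
    "read_cdt",
    "cut_clusters",
]


@dataclass(frozen=True)
class OverlapResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap_size: int
    p_value: float


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric upper-tail significance of a gene-list overlap.

    p = P(X >= |a ∩ b|) for X ~ Hypergeom(|universe|, |a|, |b|).
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    stray = (a | b) - universe
    if stray:
        raise ValueError(f"elements outside universe: {sorted(stray)[:10]}")
    k = len(a & b)
    # survival function of k-1 gives P(X >= k); scipy evaluates the
    # log-space hypergeometric pmf internally
    p = float(hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return OverlapResult(len(universe), len(a), len(b), k, min(max(p, 0.0), 1.0))


def direction_stratified_overlap(up_a, down_a, up_b, down_b, universe) -> dict[str, OverlapResult]:
    """Up-with-up, down-with-down, and combined overlap tests."""
    return {
        "up": overlap_test(up_a, up_b, universe),
        "down": overlap_test(down_a, down_b, universe),
        "combined": overlap_test(set(up_a) | set(down_a),
                                 set(up_b) | set(down_b), universe),
    }


def uncentered_pearson(profile_x, profile_y) -> float:
    """Uncentered Pearson similarity: s = (1/n) sum (x_i/sx)(y_i/sy),
    with sx, sy the root-mean-square about zero.  Lies in [-1, 1]."""
    x = np.asarray(profile_x, dtype=np.float64)
    y = np.asarray(profile_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("profiles must be equal-length 1-D vectors of length >= 2")
    sx = np.sqrt(np.mean(x * x))
    sy = np.sqrt(np.mean(y * y))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("uncentered correlation undefined for an all-zero vector")
    s = float(np.mean((x / sx) * (y / sy)))
    return float(np.clip(s, -1.0, 1.0))


def uncentered_dissimilarity_matrix(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise d = 1 - uncentered Pearson over matrix rows."""
    m = np.asarray(matrix, dtype=np.float64)
    norms = np.sqrt(np.mean(m * m, axis=1))
    if np.any(norms == 0.0):
        bad = np.nonzero(norms == 0.0)[0]
        raise ValueError(f"all-zero rows at indices {bad.tolist()}")
    scaled = m / norms[:, None]
    sim = np.clip(scaled @ scaled.T / m.shape[1], -1.0, 1.0)
    d = 1.0 - sim
    iu = np.triu_indices(m.shape[0], k=1)
    return np.maximum(d[iu], 0.0)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy-format linkage plus leaf labels."""

    linkage_matrix: np.ndarray  # (n-1, 4): idx1, idx2, height, size
    labels: list[str]
    leaf_order: list[int]
    linkage: str = "average"
    metric: str = "uncentered"

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def hierarchical_cluster(matrix: pd.DataFrame, axis: int | str = 0,
                         linkage: str = "average",
                         metric: str = "uncentered") -> Dendrogram:
    """Agglomerative clustering of matrix rows (axis=0) or columns (axis=1).

    Dissimilarity d = 1 - uncentered Pearson; average (UPGMA) linkage.
    On equal merge heights scipy's ordering resolves ties by the lowest
    pair index, which is deterministic for a fixed input.
    """
    if axis in ("columns", "cols", 1):
        matrix = matrix.T
    elif axis not in ("rows", "index", 0):
        raise ValueError("axis must be 0/'rows' or 1/'columns'")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if matrix.isna().any().any():
        raise ValueError("missing values are not supported")
    if metric == "uncentered":
        d = uncentered_dissimilarity_matrix(matrix.to_numpy())
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        d = pdist(matrix.to_numpy())
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return Dendrogram(
        linkage_matrix=Z,
        labels=[str(l) for l in matrix.index],
        leaf_order=[int(i) for i in leaves],
        linkage=linkage,
        metric=metric,
    )


def cut_clusters(dendro: Dendrogram, k: int) -> pd.Series:
    """Flat cluster labels from cutting the tree into k clusters."""
    labels = hierarchy.fcluster(dendro.linkage_matrix, t=k, criterion="maxclust")
    return pd.Series(labels, index=dendro.labels, name="cluster")


def _write_tree(dendro: Dendrogram, path: Path, prefix: str) -> None:
    """Cluster 3.0-style tree file: NODE, child1, child2, similarity."""
    n = len(dendro.labels)
    lines = []
    for i, (a, b, height, _) in enumerate(dendro.linkage_matrix):
        a, b = int(a), int(b)
        name_a = f"{prefix}{a}X" if a < n else f"NODE{a - n + 1}X"
        name_b = f"{prefix}{b}X" if b < n else f"NODE{b - n + 1}X"
        lines.append(f"NODE{i + 1}X\t{name_a}\t{name_b}\t{1.0 - height:.6f}")
    path.write_text("\n".join(lines) + "\n")


def cluster_heat_export(matrix: pd.DataFrame, row_dendro: Dendrogram,
                        col_dendro: Dendrogram | None, outdir: str | Path,
                        basename: str = "clustered") -> dict[str, str]:
    """Write the matrix reordered by dendrogram leaf order plus tree files.

    Emits TreeView-compatible files: ``<basename>.cdt`` (reordered
    matrix, with GENE/ARRY identifiers), ``<basename>.gtr`` (row tree)
    and, for two-way clustering, ``<basename>.atr`` (column tree).
    Returns the mapping of file kinds to paths.
    """
    if list(matrix.index) != [str(l) for l in row_dendro.labels] and \
       [str(i) for i in matrix.index] != row_dendro.labels:
        raise ValueError("row dendrogram was not built from this matrix")
    if col_dendro is not None and [str(c) for c in matrix.columns] != col_dendro.labels:
        raise ValueError("column dendrogram was not built from this matrix")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    row_order = row_dendro.leaf_order
    col_order = col_dendro.leaf_order if col_dendro is not None else list(range(matrix.shape[1]))
    reordered = matrix.iloc[row_order, col_order]

    files: dict[str, str] = {}
    cdt = outdir / f"{basename}.cdt"
    with cdt.open("w") as fh:
        cols = "\t".join(str(c) for c in reordered.columns)
        fh.write(f"GID\tNAME\t{cols}\n")
        fh.write("AID\t\t" + "\t".join(f"ARRY{j}X" for j in col_order) + "\n")
        for i, (name, row) in zip(row_order, reordered.iterrows()):
            vals = "\t".join(f"{v:.6f}" for v in row.to_numpy())
            fh.write(f"GENE{i}X\t{name}\t{vals}\n")
    files["cdt"] = str(cdt)

    gtr = outdir / f"{basename}.gtr"
    _write_tree(row_dendro, gtr, "GENE")
    files["gtr"] = str(gtr)
    if col_dendro is not None:
        atr = outdir / f"{basename}.atr"
        _write_tree(col_dendro, atr, "ARRY")
        files["atr"] = str(atr)
    return files


def read_cdt(path: str | Path) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Re-import an exported .cdt: (matrix, row leaf order, column leaf order)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    columns = header[2:]
    aid = lines[1].split("\t")[2:]
    col_order = [int(a[4:-1]) for a in aid]
    names, row_order, data = [], [], []
    for line in lines[2:]:
        parts = line.split("\t")
        row_order.append(int(parts[0][4:-1]))
        names.append(parts[1])
        data.append([float(v) for v in parts[2:]])
    return pd.DataFrame(data, index=names, columns=columns), row_order, col_order
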