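"""Hierarchical clustering of behavioral profiles.

Profiles (rows = treatments, columns = the ten behaviors, values = deltas vs
the vehicle control in pp) are clustered agglomeratively with complete
linkage on a weighted Euclidean dissimilarity in the convention of the
Cluster 3.0 program the field uses:

    d(x, y) = sum_i w_i (x_i - y_i)^2 / sum_i w_i

summed over the features defined in both rows (pairwise missing-value
handling with weight renormalisation), *without* a square root — the merge
order is what matters and this is the convention tree-viewer files encode.
The optomotor columns carry weight 0.5 ("Eweight"), the activity columns 1.
No centering, scaling or other transform is applied before clustering.

Additive-inverse rows (every delta negated) act as hypothetical compounds
with opposite neural effects: the inverse of a profile from one functional
class is expected to join the cluster of the opposite class.

Cluster cohesion is reported as the mean pairwise Pearson correlation of the
member profiles, a reconstruction of the per-cluster correlation values
printed next to published dendrogram boxes (whose exact formula is not
stated); minimum pairwise correlation is available as a conservative
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MEASURES, OMR_MEASURES

#: Cluster-3.0 "Eweight": optomotor responses count half
DEFAULT_OMR_WEIGHT = 0.5


class ClusteringError(ValueError):
    """Degenerate matrix or invalid cut parameter."""


def default_weights(columns: Sequence[str] = tuple(MEASURES)) -> np.ndarray:
    return np.array([DEFAULT_OMR_WEIGHT if c in OMR_MEASURES else 1.0
                     for c in columns])


@dataclass
class FeatureMatrix:
    """Profiles-by-behaviors matrix with per-column weights.

    ``data`` keeps NaN for undefined deltas; every row must have at least one
    defined value and the matrix at least two rows.
    """

    data: pd.DataFrame
    column_weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.column_weights is None:
            self.column_weights = default_weights(self.data.columns)
        self.column_weights = np.asarray(self.column_weights, dtype=float)
        if len(self.column_weights) != self.data.shape[1]:
            raise ClusteringError("one weight per column required")
        if (self.column_weights <= 0).any():
            raise ClusteringError("weights must be positive")
        if self.data.shape[0] < 2:
            raise ClusteringError("need at least two profiles to cluster")
        if self.data.index.has_duplicates:
            raise ClusteringError("duplicate row labels")
        if self.data.isna().all(axis=1).any():
            raise ClusteringError("every row needs at least one defined value")

    @property
    def labels(self) -> list[str]:
        return list(self.data.index)


def from_profiles(profiles: pd.DataFrame,
                  extra_rows: Optional[pd.DataFrame] = None,
                  invert: Sequence[str] = (),
                  column_weights: Optional[np.ndarray] = None) -> FeatureMatrix:
    """Build a FeatureMatrix from a screen profile table.

    ``profiles`` is either a ``delta_*`` table from
    :func:`larvascreen.screen_stats.profile_screen` (indexed by the ``label``
    column) or already a plain label-by-measure delta table. ``extra_rows``
    appends reference profiles (e.g. compounds from prior experiments);
    ``invert`` lists labels whose additive inverse should be appended as
    hypothetical profiles. Values pass through untransformed.
    """
    if "label" in profiles.columns:
        data = profiles.set_index("label")[[f"delta_{m}" for m in MEASURES]]
        data.columns = MEASURES
    else:
        data = profiles.loc[:, list(MEASURES)].copy()
    if extra_rows is not None:
        data = pd.concat([data, extra_rows.loc[:, list(MEASURES)]])
    for label in invert:
        data = pd.concat([data, additive_inverse(data.loc[label]).to_frame().T])
    return FeatureMatrix(data=data, column_weights=column_weights)


def additive_inverse(profile: pd.Series) -> pd.Series:
    """Hypothetical opposite profile: every defined delta negated, missing
    values kept missing, label suffixed ``-inv``."""
    out = -profile
    out.name = f"{profile.name}-inv"
    return out


def weighted_euclidean(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weight-normalised mean squared difference over mutually defined
    features (no square root)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    defined = ~(np.isnan(x) | np.isnan(y))
    if not defined.any():
        raise ClusteringError("no mutually defined features")
    wd = w[defined]
    return float(np.sum(wd * (x[defined] - y[defined]) ** 2) / np.sum(wd))


def distance_matrix(matrix: FeatureMatrix) -> np.ndarray:
    values = matrix.data.to_numpy(dtype=float)
    n = len(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = weighted_euclidean(values[i], values[j],
                                                   matrix.column_weights)
    return d


@dataclass
class LinkageTree:
    """Binary merge list over the matrix rows.

    Leaves are numbered 0..n-1 in row order; internal nodes n, n+1, ... in
    merge order. Each merge is (node_id, left_child, right_child, height).
    """

    labels: list[str]
    merges: list[tuple[int, int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[3] for m in self.merges])

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order by depth-first traversal."""
        children = {node: (left, right) for node, left, right, _ in self.merges}
        root = self.merges[-1][0] if self.merges else 0
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = children[node]
                stack.extend([right, left])
        return order

    def cut(self, k: Optional[int] = None, height: Optional[float] = None,
            ) -> list[list[int]]:
        """Flat clusters (lists of leaf indices) by cluster count or height."""
        if (k is None) == (height is None):
            raise ClusteringError("give exactly one of k or height")
        if k is not None:
            if not 1 <= k <= self.n_leaves:
                raise ClusteringError(f"k must lie in 1..{self.n_leaves}")
            applied = self.merges[:self.n_leaves - k]
        else:
            applied = [m for m in self.merges if m[3] <= height]
        members: dict[int, list[int]] = {i: [i] for i in range(self.n_leaves)}
        for node, left, right, _ in applied:
            members[node] = members.pop(left) + members.pop(right)
        return sorted(members.values(), key=lambda leaves: min(leaves))


def complete_linkage(matrix: FeatureMatrix) -> LinkageTree:
    """Agglomerative complete-linkage clustering on the weighted distances.

    Ties in the minimum inter-cluster distance are broken deterministically
    toward the lexicographically smallest pair of cluster representative
    labels (the alphabetically first member label of each cluster).
    """
    labels = matrix.labels
    d = distance_matrix(matrix)
    n = len(labels)
    active: dict[int, int] = {i: i for i in range(n)}  # node id -> matrix row
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    # grow d as merges happen: row/col per node id
    dist = np.full((2 * n - 1, 2 * n - 1), np.inf)
    dist[:n, :n] = d
    merges: list[tuple[int, int, int, float]] = []
    next_id = n
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dd = dist[a, b]
                pair_key = tuple(sorted((rep[a], rep[b])))
                if best is None or dd < best[0] - 1e-12 or (
                        abs(dd - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (dd, pair_key, a, b)
        dd, _, a, b = best
        left, right = (a, b) if rep[a] <= rep[b] else (b, a)
        merges.append((next_id, left, right, float(dd)))
        for other in active:
            if other not in (a, b):
                dist[next_id, other] = dist[other, next_id] = max(dist[a, other],
                                                                  dist[b, other])
        rep[next_id] = min(rep[a], rep[b])
        del active[a], active[b]
        active[next_id] = next_id
        next_id += 1
    return LinkageTree(labels=labels, merges=merges)


@dataclass
class ClusterReport:
    members: list[str]
    cohesion: float  # mean pairwise Pearson correlation; nan for singletons
    size: int


def cohesion(data: pd.DataFrame, statistic: str = "mean") -> float:
    """Mean (or minimum) pairwise Pearson correlation over member profiles,
    each pair correlated over its mutually defined behaviors."""
    values = data.to_numpy(dtype=float)
    n = len(values)
    if n < 2:
        return float("nan")
    corrs = []
    for i in range(n):
        for j in range(i + 1, n):
            defined = ~(np.isnan(values[i]) | np.isnan(values[j]))
            xi, xj = values[i][defined], values[j][defined]
            if defined.sum() < 2 or xi.std() == 0 or xj.std() == 0:
                continue
            corrs.append(float(np.corrcoef(xi, xj)[0, 1]))
    if not corrs:
        return float("nan")
    return float(np.mean(corrs) if statistic == "mean" else np.min(corrs))


def extract_clusters(matrix: FeatureMatrix, tree: LinkageTree,
                     k: Optional[int] = None, height: Optional[float] = None,
                     statistic: str = "mean") -> list[ClusterReport]:
    """Flat clusters with cohesion scores, largest first."""
    groups = tree.cut(k=k, height=height)
    reports = []
    for leaves in groups:
        members = [tree.labels[i] for i in leaves]
        reports.append(ClusterReport(
            members=members,
            cohesion=cohesion(matrix.data.iloc[leaves], statistic=statistic),
            size=len(members)))
    return sorted(reports, key=lambda r: (-r.size, r.members[0]))


# ---------------------------------------------------------------------------
# Cluster-3.0-compatible files (CDT + GTR) for tree-viewer programs
# ---------------------------------------------------------------------------

def write_cdt_gtr(matrix: FeatureMatrix, tree: LinkageTree, cdt_path, gtr_path) -> None:
    """Write the clustered data table and gene-tree files.

    The CDT lists rows in dendrogram leaf order with GIDs ``GENE{i}X`` (i =
    original row index); the EWEIGHT row carries the column weights. The GTR
    lists one merge per line as ``NODE{k}X  child  child  score`` with the
    merge height as the score.
    """
    order = tree.leaf_order()
    columns = list(matrix.data.columns)
    with open(cdt_path, "w") as fh:
        fh.write("\t".join(["GID", "UNIQID", "NAME", "GWEIGHT"] + columns) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] +
                           [f"{w:g}" for w in matrix.column_weights]) + "\n")
        values = matrix.data.to_numpy(dtype=float)
        for i in order:
            label = tree.labels[i]
            cells = ["" if np.isnan(v) else f"{v:.6g}" for v in values[i]]
            fh.write("\t".join([f"GENE{i}X", label, label, "1"] + cells) + "\n")

    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < tree.n_leaves else f"NODE{idx - tree.n_leaves + 1}X"

    with open(gtr_path, "w") as fh:
        for node, left, right, height in tree.merges:
            fh.write("\t".join([node_name(node), node_name(left), node_name(right),
                                f"{height:.6g}"]) + "\n")


def read_cdt(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Parse a CDT file back into (data in leaf order, weights, GIDs)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        columns = header[4:]
        eweight = fh.readline().rstrip("\n").split("\t")
        weights = np.array([float(v) for v in eweight[4:]])
        gids, labels, rows = [], [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            gids.append(cells[0])
            labels.append(cells[1])
            rows.append([float(v) if v else np.nan for v in cells[4:]])
    data = pd.DataFrame(rows, index=pd.Index(labels, name="label"), columns=columns)
    return data, weights, gids


def read_gtr(path) -> list[tuple[str, str, str, float]]:
    with open(path) as fh:
        out = []
        for line in fh:
            node, left, right, score = line.rstrip("\n").split("\t")
            out.append((node, left, right, float(score)))
    return out
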