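"""Interaction-profile clustering and consensus analysis.

Genes (or sgRNAs) are clustered by average-linkage agglomeration on the
Pearson distance (1 - Pearson correlation) between their interaction
profiles.  Flat clusters are cut at fixed distance thresholds: 0.55 for
high-confidence functional clusters and 0.8 for broader "system" groupings.
A consensus clustering across several maps divides each map by its global
score standard deviation, concatenates the normalized maps side by side
(n x kn for k maps) and clusters the short axis; the resulting tree is a
universal ordering applicable to every individual map.

When correlating two profiles, the matrix cells involving either of the two
entities themselves (the self/partner cells, which hold control rather than
profile signal) are excluded from both vectors; masked (filtered) cells are
imputed as 0, the null value on the z scale — for clustering only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .gi import GIMatrix

#: default flat-cut thresholds (Pearson distance)
CLUSTER_CUT = 0.55
SYSTEM_CUT = 0.8


def _profile_matrix(m) -> pd.DataFrame:
    """Accept a GIMatrix/DGIMatrix or a plain square DataFrame."""
    if hasattr(m, "interaction_scores"):
        return m.interaction_scores
    return m


def _pairwise_pearson_distance(
    x: np.ndarray, exclude: list[np.ndarray]
) -> np.ndarray:
    """Condensed 1 - Pearson distances between rows of ``x``.

    ``exclude[i]`` lists column positions dropped from both vectors whenever
    row i takes part in a correlation (its self/partner cells).
    """
    n = x.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=float)
    k = 0
    col_mask = np.ones(x.shape[1], dtype=bool)
    for i in range(n - 1):
        for j in range(i + 1, n):
            col_mask[:] = True
            col_mask[exclude[i]] = False
            col_mask[exclude[j]] = False
            xi = x[i, col_mask]
            xj = x[j, col_mask]
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            denom = np.sqrt((xi * xi).sum() * (xj * xj).sum())
            r = (xi * xj).sum() / denom if denom > 0 else np.nan
            out[k] = 1.0 - r
            k += 1
    return out


def correlation_distance(
    m, exclude_self: bool = True, impute: float = 0.0
) -> pd.DataFrame:
    """Square Pearson-distance matrix between interaction profiles.

    Rows whose profile has zero variance (after imputation of masked cells)
    are excluded with a warning; the distance would be undefined for them.
    """
    profiles = _profile_matrix(m)
    if len(profiles) < 3:
        raise ValueError("need at least 3 entities to build a distance matrix")
    x = profiles.to_numpy(dtype=float)
    x = np.where(np.isnan(x), impute, x)
    labels = list(profiles.index)
    variable = x.std(axis=1) > 0
    if not variable.all():
        dropped = [l for l, v in zip(labels, variable) if not v]
        warnings.warn(
            f"excluding zero-variance profiles from clustering: {dropped}",
            stacklevel=2,
        )
        x = x[variable]
        labels = [l for l, v in zip(labels, variable) if v]
    if exclude_self:
        col_index = profiles.columns
        exclude = [np.flatnonzero(col_index == lbl) for lbl in labels]
    else:
        exclude = [np.empty(0, dtype=int) for _ in labels]
    condensed = _pairwise_pearson_distance(x, exclude)
    dist = squareform(condensed, checks=False)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class ClusterModel:
    """Average-linkage tree over interaction profiles."""

    linkage: np.ndarray
    labels: list[str]
    assignments: dict[float, pd.Series] = field(default_factory=dict)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, threshold: float) -> pd.Series:
        """Flat clusters whose cophenetic merge height is <= threshold.

        Cluster ids are renumbered 1..k in order of first appearance along
        the label list, so identical trees always yield identical labels.
        """
        raw = hierarchy.fcluster(self.linkage, t=threshold, criterion="distance")
        relabel: dict[int, int] = {}
        out = np.empty_like(raw)
        for i, c in enumerate(raw):
            out[i] = relabel.setdefault(c, len(relabel) + 1)
        s = pd.Series(out, index=self.labels, name="cluster")
        self.assignments[threshold] = s
        return s

    def cut_table(self, thresholds: tuple[float, ...] = (CLUSTER_CUT, SYSTEM_CUT)) -> pd.DataFrame:
        return pd.DataFrame({t: self.cut(t) for t in thresholds})

    def plot_dendrogram(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        hierarchy.dendrogram(self.linkage, labels=self.labels, ax=ax, **kwargs)
        ax.set_ylabel("Pearson distance")
        return ax


def hierarchical_cluster(dist: pd.DataFrame) -> ClusterModel:
    """Average-linkage agglomeration of a square distance matrix."""
    condensed = squareform(dist.to_numpy(), checks=False)
    if np.isnan(condensed).any():
        raise ValueError("distance matrix contains NaN")
    z = hierarchy.linkage(condensed, method="average")
    return ClusterModel(linkage=z, labels=list(dist.index))


def cut_clusters(model: ClusterModel, threshold: float) -> pd.Series:
    return model.cut(threshold)


@dataclass
class ConsensusMatrix:
    """Per-map SD-normalized scores concatenated along the condition axis."""

    matrix: pd.DataFrame  # genes x MultiIndex (condition, gene)
    conditions: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def block(self, condition: str) -> pd.DataFrame:
        return self.matrix[condition]


def build_consensus_matrix(maps: list[GIMatrix]) -> ConsensusMatrix:
    """Normalize each map by its score SD and concatenate horizontally.

    All maps must share the gene universe; each block is divided by the
    standard deviation of its off-diagonal scores so the blocks contribute
    on a common scale.
    """
    if len(maps) < 2:
        raise ValueError("consensus requires at least 2 maps")
    first = _profile_matrix(maps[0])
    genes = first.index
    blocks = []
    conditions = []
    for k, m in enumerate(maps):
        profiles = _profile_matrix(m)
        if set(profiles.index) != set(genes):
            raise ValueError("maps do not share a gene universe")
        profiles = profiles.loc[genes, genes]
        vals = profiles.to_numpy(dtype=float).copy()
        off = ~np.eye(len(genes), dtype=bool)
        sd = np.nanstd(vals[off])
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("map has zero score variance; cannot normalize")
        cond = getattr(m, "condition", None) or f"map{k + 1}"
        block = profiles / sd
        block.columns = pd.MultiIndex.from_product([[cond], genes])
        blocks.append(block)
        conditions.append(cond)
    if len(set(conditions)) != len(conditions):
        conditions = [f"{c}#{i + 1}" for i, c in enumerate(conditions)]
        for b, c in zip(blocks, conditions):
            b.columns = pd.MultiIndex.from_product([[c], genes])
    matrix = pd.concat(blocks, axis=1)
    return ConsensusMatrix(matrix=matrix, conditions=conditions)


def consensus_cluster(
    maps: list[GIMatrix], impute: float = 0.0
) -> tuple[ConsensusMatrix, ClusterModel]:
    """Build the consensus matrix and cluster its rows.

    Per-pair correlations exclude the two entities' self/partner columns in
    every condition block; masked cells are imputed as 0 for clustering.
    """
    cm = build_consensus_matrix(maps)
    x = cm.matrix.to_numpy(dtype=float)
    x = np.where(np.isnan(x), impute, x)
    labels = list(cm.matrix.index)
    gene_cols = cm.matrix.columns.get_level_values(1).to_numpy()
    exclude = [np.flatnonzero(gene_cols == lbl) for lbl in labels]
    condensed = _pairwise_pearson_distance(x, exclude)
    if np.isnan(condensed).any():
        raise ValueError("consensus distance undefined for a zero-variance profile")
    z = hierarchy.linkage(condensed, method="average")
    return cm, ClusterModel(linkage=z, labels=labels)


@dataclass
class FidelityResult:
    """Same-gene vs different-gene sgRNA profile correlations."""

    same_gene: pd.Series  # (sgrna_i, sgrna_j) -> Pearson r
    different_gene: pd.Series
    median_same: float
    median_different: float


def sgrna_fidelity(
    m,
    gene_map: pd.Series,
    n_different: int | None = None,
    seed: int = 0,
) -> FidelityResult:
    """Clustering-fidelity metric at the sgRNA level.

    Correlates interaction profiles of every pair of sgRNAs targeting the
    same gene, and of a random matched-size sample of different-gene pairs,
    excluding each pair's self/partner columns.  Accepts an sgRNA-level
    GIMatrix, a ConsensusMatrix built from sgRNA-level maps, or a DataFrame.
    """
    if isinstance(m, ConsensusMatrix):
        profiles = m.matrix
        gene_cols = profiles.columns.get_level_values(1).to_numpy()
    else:
        profiles = _profile_matrix(m)
        gene_cols = profiles.columns.to_numpy()
    profiles = profiles.loc[[s for s in profiles.index if s in gene_map.index]]
    x = profiles.to_numpy(dtype=float)
    x = np.where(np.isnan(x), 0.0, x)
    labels = list(profiles.index)
    pos = {lbl: i for i, lbl in enumerate(labels)}
    exclude = {lbl: np.flatnonzero(gene_cols == lbl) for lbl in labels}

    def corr(a: str, b: str) -> float:
        mask = np.ones(x.shape[1], dtype=bool)
        mask[exclude[a]] = False
        mask[exclude[b]] = False
        xa = x[pos[a], mask]
        xb = x[pos[b], mask]
        xa = xa - xa.mean()
        xb = xb - xb.mean()
        denom = np.sqrt((xa * xa).sum() * (xb * xb).sum())
        return float((xa * xb).sum() / denom) if denom > 0 else np.nan

    by_gene: dict[str, list[str]] = {}
    for s in labels:
        by_gene.setdefault(gene_map[s], []).append(s)
    same_pairs = [
        (a, b)
        for sgrnas in by_gene.values()
        if len(sgrnas) >= 2
        for i, a in enumerate(sgrnas)
        for b in sgrnas[i + 1 :]
    ]
    if not same_pairs:
        raise ValueError("no gene has >= 2 sgRNAs in the profile matrix")
    rng = np.random.default_rng(seed)
    n_diff = n_different if n_different is not None else max(len(same_pairs), 100)
    diff_pairs: set[tuple[str, str]] = set()
    guard = 0
    while len(diff_pairs) < n_diff and guard < 100 * n_diff:
        i, j = rng.integers(0, len(labels), 2)
        guard += 1
        if i == j or gene_map[labels[i]] == gene_map[labels[j]]:
            continue
        diff_pairs.add(tuple(sorted((labels[i], labels[j]))))

    same = pd.Series({p: corr(*p) for p in same_pairs}).dropna()
    diff = pd.Series({p: corr(*p) for p in sorted(diff_pairs)}).dropna()
    return FidelityResult(
        same_gene=same,
        different_gene=diff,
        median_same=float(same.median()),
        median_different=float(diff.median()),
    )
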