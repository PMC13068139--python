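"""Ontology-level compression, coordination, and enrichment analyses.

Gene-level maps are compressed to cluster-by-cluster ("ontology") matrices by
averaging the pairwise interaction scores between (or within) consensus
clusters.  Differencing the environmental and reference ontology matrices
highlights inter-module rewiring; coordination profiles correlate a query
cluster's ontology-level profile with every other cluster per condition,
tracking which modules move together in each environment.

Two enrichment utilities support interpretation: binned enrichment of
interaction strength for known protein-protein interaction (PPI) scores, and
an iterative hypergeometric gene-set enrichment that removes the top term's
genes between rounds, yielding mutually exclusive terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gi import GIMatrix


@dataclass
class OntologyMatrix:
    """Cluster-by-cluster mean interaction scores."""

    scores: pd.DataFrame  # clusters x clusters, symmetric
    members: dict[str, list[str]]  # cluster -> member genes
    condition: str = ""

    @property
    def clusters(self) -> list[str]:
        return list(self.scores.index)

    def profile(self, cluster, exclude=()) -> pd.Series:
        """The cluster's row with itself (and any ``exclude``) removed."""
        drop = {cluster, *exclude}
        keep = [c for c in self.scores.index if c not in drop]
        return self.scores.loc[cluster, keep]


def compress_to_ontology(
    m: GIMatrix | pd.DataFrame, clusters: pd.Series, condition: str | None = None
) -> OntologyMatrix:
    """Average a gene-level matrix within/between clusters.

    Cell (C1, C2) is the mean score over all gene pairs (g1 in C1, g2 in C2)
    with g1 != g2; masked pairs are omitted from the mean.  For singleton
    clusters the diagonal falls back to the gene's own diagonal entry so that
    all-singleton compression reproduces the gene-level matrix exactly.
    """
    profiles = m.interaction_scores if hasattr(m, "interaction_scores") else m
    genes = profiles.index
    missing = [g for g in genes if g not in clusters.index]
    if missing:
        raise ValueError(f"genes without a cluster assignment: {missing[:5]}")
    assign = clusters.reindex(genes)
    members: dict[str, list[str]] = {}
    for g, c in assign.items():
        members.setdefault(str(c), []).append(g)
    for c, mem in members.items():
        if not mem:
            raise ValueError(f"cluster {c!r} is empty")
    labels = sorted(members, key=lambda c: genes.get_loc(members[c][0]))
    x = profiles.to_numpy(dtype=float)
    n = len(labels)
    out = np.full((n, n), np.nan)
    idx = {c: profiles.index.get_indexer(members[c]) for c in labels}
    for i, ci in enumerate(labels):
        for j in range(i, n):
            cj = labels[j]
            block = x[np.ix_(idx[ci], idx[cj])]
            if i == j:
                if len(idx[ci]) == 1:
                    val = block[0, 0]
                else:
                    off = ~np.eye(len(idx[ci]), dtype=bool)
                    vals = block[off]
                    val = np.nanmean(vals) if not np.isnan(vals).all() else np.nan
            else:
                val = np.nanmean(block) if not np.isnan(block).all() else np.nan
            out[i, j] = out[j, i] = val
    cond = condition if condition is not None else getattr(m, "condition", "")
    return OntologyMatrix(
        scores=pd.DataFrame(out, index=labels, columns=labels),
        members=members,
        condition=cond,
    )


@dataclass
class OntologyDifferential:
    """Elementwise difference of two ontology matrices plus edge calls."""

    diff: pd.DataFrame
    gained: list[tuple[str, str]]
    lost: list[tuple[str, str]]
    threshold: float


def ontology_differential(
    env: OntologyMatrix, ref: OntologyMatrix, threshold: float
) -> OntologyDifferential:
    """Difference matrix with gained/lost inter-cluster edges.

    An edge (C1, C2) is *gained* when ``|env|`` exceeds ``threshold`` while
    ``|ref|`` does not, and *lost* in the converse case.
    """
    if set(env.scores.index) != set(ref.scores.index):
        raise ValueError("ontology matrices have different cluster sets")
    r = ref.scores.loc[env.scores.index, env.scores.columns]
    diff = env.scores - r
    gained, lost = [], []
    labels = list(env.scores.index)
    for i, c1 in enumerate(labels):
        for c2 in labels[i + 1 :]:
            e = env.scores.at[c1, c2]
            b = r.at[c1, c2]
            if np.isnan(e) or np.isnan(b):
                continue
            if abs(e) > threshold and abs(b) <= threshold:
                gained.append((c1, c2))
            elif abs(b) > threshold and abs(e) <= threshold:
                lost.append((c1, c2))
    return OntologyDifferential(diff=diff, gained=gained, lost=lost, threshold=threshold)


def coordination_profile(
    query_cluster: str, maps: dict[str, OntologyMatrix]
) -> pd.DataFrame:
    """Correlation of the query cluster with every other cluster, per map.

    For each condition, Pearson correlation between the query's ontology-level
    profile and each other cluster's profile, excluding the two clusters' own
    cells from both vectors.  Rows: other clusters; columns: conditions.
    """
    out = {}
    for cond, om in maps.items():
        if query_cluster not in om.scores.index:
            raise ValueError(f"query cluster {query_cluster!r} absent from {cond!r}")
        others = [c for c in om.clusters if c != query_cluster]
        vals = {}
        for other in others:
            keep = [c for c in om.clusters if c not in (query_cluster, other)]
            a = om.scores.loc[query_cluster, keep].to_numpy(dtype=float)
            b = om.scores.loc[other, keep].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                vals[other] = np.nan
                continue
            vals[other] = float(stats.pearsonr(a[ok], b[ok]).statistic)
        out[cond] = pd.Series(vals)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# PPI enrichment
# ---------------------------------------------------------------------------


@dataclass
class PPITable:
    """Known protein-protein interaction scores in [0, 1] per gene pair.

    Absent pairs mean no known interaction and score 0.
    """

    scores: dict[tuple[str, str], float]

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def escore(self, a: str, b: str) -> float:
        return self.scores.get(self._key(a, b), 0.0)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PPITable":
        scores = {}
        for a, b, s in zip(df["gene_a"], df["gene_b"], df["escore"]):
            scores[cls._key(a, b)] = float(s)
        return cls(scores)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PPITable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene_a": a, "gene_b": b, "escore": s}
            for (a, b), s in sorted(self.scores.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PPIEnrichment:
    table: pd.DataFrame  # per-bin stats
    chi2: float
    p_value: float
    global_mean_escore: float


def ppi_enrichment(
    m: GIMatrix, ppi: PPITable, n_bins: int = 10, scheme: str = "quantile"
) -> PPIEnrichment:
    """Enrichment of known PPIs among strong interactions.

    Unique unordered gene pairs are binned by absolute interaction score
    (quantile bins by default, equal-width with ``scheme="width"``); each
    bin's mean PPI escore (absent pairs count 0) is normalized by the global
    mean escore.  A chi-square test uses the same bins with pairs classified
    interacting/not-interacting by any detected PPI; bins whose expected
    interacting count falls below 5 are merged with their neighbor.
    """
    pairs = m.pairs_long()
    if pairs.empty:
        raise ValueError("no scored gene pairs")
    abs_score = pairs["score"].abs()
    esc = np.array(
        [ppi.escore(a, b) for a, b in zip(pairs["entity_a"], pairs["entity_b"])]
    )
    covered = sum(
        1 for a, b in zip(pairs["entity_a"], pairs["entity_b"])
        if PPITable._key(a, b) in ppi.scores
    )
    if covered == 0:
        raise ValueError("PPI table covers no pair of the matrix universe")
    global_mean = float(esc.mean())
    if global_mean == 0:
        raise ValueError("all PPI escores are zero; enrichment undefined")
    if scheme == "quantile":
        bins = pd.qcut(abs_score, q=n_bins, labels=False, duplicates="drop")
    elif scheme == "width":
        bins = pd.cut(abs_score, bins=n_bins, labels=False)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    df = pd.DataFrame(
        {"bin": bins, "abs_score": abs_score, "escore": esc, "interacting": esc > 0}
    )
    per_bin = (
        df.groupby("bin")
        .agg(
            n_pairs=("escore", "size"),
            mean_abs_score=("abs_score", "mean"),
            mean_escore=("escore", "mean"),
            n_interacting=("interacting", "sum"),
        )
        .reset_index()
    )
    per_bin["enrichment"] = per_bin["mean_escore"] / global_mean

    # chi-square over merged bins (expected interacting count >= 5)
    frac = df["interacting"].mean()
    merged: list[list[float]] = []
    acc_n = acc_i = 0
    for _, row in per_bin.iterrows():
        acc_n += int(row["n_pairs"])
        acc_i += int(row["n_interacting"])
        if frac * acc_n >= 5 and (1 - frac) * acc_n >= 5:
            merged.append([acc_i, acc_n - acc_i])
            acc_n = acc_i = 0
    if acc_n:
        if merged:
            merged[-1][0] += acc_i
            merged[-1][1] += acc_n - acc_i
        else:
            merged.append([acc_i, acc_n - acc_i])
    if len(merged) < 2 or frac in (0.0, 1.0):
        chi2, p = float("nan"), float("nan")
        warnings.warn("too few usable bins for a chi-square test", stacklevel=2)
    else:
        chi2, p, _, _ = stats.chi2_contingency(np.asarray(merged))
    return PPIEnrichment(
        table=per_bin, chi2=float(chi2), p_value=float(p), global_mean_escore=global_mean
    )


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        clipped = {}
        outside = 0
        for name, members in self.sets.items():
            kept = frozenset(members) & self.universe
            outside += len(members) - len(kept)
            clipped[name] = kept
        if outside:
            warnings.warn(
                f"dropped {outside} gene-set members outside the universe",
                stacklevel=2,
            )
        self.sets = clipped

    @classmethod
    def read_gmt(cls, path: str | Path, universe=None) -> "GeneSetCollection":
        """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
        sets: dict[str, frozenset[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        if universe is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets=sets, universe=frozenset(universe))

    def write_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([name, "na", *sorted(members)])
            for name, members in self.sets.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def iterative_enrichment(
    genes: set[str],
    gsc: GeneSetCollection,
    n_iter: int = 10,
    min_neglogp: float = 6.0,
) -> pd.DataFrame:
    """Iterative hypergeometric gene-set enrichment with top-term removal.

    Each round tests every set against the current hit list (hypergeometric
    upper tail over the declared universe), applies Benjamini-Hochberg across
    sets, records the most enriched term, removes its member genes from the
    hit list and repeats — up to ``n_iter`` rounds or until the hit list (or
    the overlap) is exhausted.  ``significant`` flags terms whose
    ``-log10`` adjusted p reaches ``min_neglogp``; successive terms' removed
    gene sets are pairwise disjoint by construction.
    """
    hits = set(genes) & gsc.universe
    if hits != set(genes):
        warnings.warn("hit genes outside the universe were ignored", stacklevel=2)
    m_universe = len(gsc.universe)
    names = sorted(gsc.sets)
    rows = []
    for iteration in range(1, n_iter + 1):
        if not hits:
            break
        n_hits = len(hits)
        pvals, overlaps = [], []
        for name in names:
            members = gsc.sets[name]
            k = len(members & hits)
            p = stats.hypergeom.sf(k - 1, m_universe, len(members), n_hits)
            pvals.append(p)
            overlaps.append(k)
        if max(overlaps) == 0:
            break
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        order = sorted(
            range(len(names)), key=lambda i: (adj[i], pvals[i], names[i])
        )
        top = order[0]
        removed = sorted(gsc.sets[names[top]] & hits)
        neglogp = float(-np.log10(max(adj[top], 1e-300)))
        rows.append(
            {
                "iteration": iteration,
                "term": names[top],
                "p_value": float(pvals[top]),
                "adj_p_value": float(adj[top]),
                "neglog10_adj_p": neglogp,
                "significant": neglogp >= min_neglogp,
                "n_overlap": overlaps[top],
                "genes_removed": tuple(removed),
            }
        )
        hits -= set(removed)
    return pd.DataFrame(rows)
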