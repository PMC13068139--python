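"""Genetic-interaction scoring from dual-guide phenotypes.

For each query sgRNA, the expected phenotype of a pair is modelled as a
quadratic function of the partner's single-sgRNA phenotype, fitted by
ordinary least squares over every construct containing the query.  The
interaction score of a construct is the residual from the query's model,
z-normalized by the standard deviation of the query's residuals over its
ntc-paired constructs (the query's null distribution).  Scores for an
unordered sgRNA pair average all available measurements — each cassette
orientation scored under each of the two queries, up to four per replicate —
and replicates are averaged last, which makes the score matrix exactly
symmetric.  Gene-level scores average all sgRNA-pair scores for the gene
pair; ntc sgRNAs are carried through as size-1 pseudo-genes so the gene-ntc
control distribution is computed identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryDesign
from .phenotypes import Channel, ConstructPhenotypes, SinglePhenotypes

#: minimum partners for the quadratic model; below this a line is fitted
MIN_QUADRATIC = 5
#: absolute minimum partners for any model
MIN_POINTS = 3
#: minimum ntc residuals required to estimate a query's null spread
MIN_NTC_RESIDUALS = 2


def fit_query_model(
    partner_singles: np.ndarray, pair_phenotypes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of pair phenotype vs partner single phenotype for one query.

    Returns ``(coefficients, residuals)``; coefficients are ascending
    ``(c0, c1, c2)`` with ``c2 == 0`` when only a line could be fitted
    (fewer than 5 points).  Raises ``ValueError`` below 3 points.
    """
    x = np.asarray(partner_singles, dtype=float)
    y = np.asarray(pair_phenotypes, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} partners to fit a query model")
    deg = 2 if len(x) >= MIN_QUADRATIC else 1
    coef = np.polynomial.polynomial.polyfit(x, y, deg)
    if deg == 1:
        coef = np.append(coef, 0.0)
    residuals = y - np.polynomial.polynomial.polyval(x, coef)
    return coef, residuals


@dataclass
class GIMatrix:
    """A symmetric interaction-score matrix at sgRNA or gene level.

    ``scores`` spans targeting entities *and* ntc entities (ntc sgRNAs, or
    size-1 ntc pseudo-genes at gene level); ``interaction_scores`` is the
    targeting block and ``control_scores`` the targeting-vs-ntc values whose
    spread sets the significance threshold.
    """

    level: str  # "sgrna" or "gene"
    condition: str
    channel: Channel
    scores: pd.DataFrame
    n_obs: pd.DataFrame
    is_ntc: pd.Series  # per matrix label

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must be square with matching labels")

    def _ntc_mask(self) -> np.ndarray:
        return self.is_ntc.reindex(self.scores.index).to_numpy(dtype=bool)

    @property
    def targeting(self) -> pd.Index:
        return self.scores.index[~self._ntc_mask()]

    @property
    def ntc_labels(self) -> pd.Index:
        return self.scores.index[self._ntc_mask()]

    @property
    def interaction_scores(self) -> pd.DataFrame:
        t = self.targeting
        return self.scores.loc[t, t]

    @property
    def control_scores(self) -> pd.Series:
        """Targeting-vs-ntc scores (the gene-ntc / sgRNA-ntc controls)."""
        block = self.scores.loc[self.targeting, self.ntc_labels]
        s = block.stack(future_stack=True).dropna()
        s.index.names = ["entity", "ntc"]
        return s

    def control_sd(self, ddof: int = 1) -> float:
        return float(self.control_scores.std(ddof=ddof))

    def pairs_long(self) -> pd.DataFrame:
        """Upper-triangle (i < j) long table of targeting pair scores."""
        t = list(self.targeting)
        m = self.scores.loc[t, t].to_numpy()
        n = self.n_obs.reindex(index=t, columns=t).to_numpy()
        iu, ju = np.triu_indices(len(t), k=1)
        df = pd.DataFrame(
            {
                "entity_a": np.asarray(t, dtype=object)[iu],
                "entity_b": np.asarray(t, dtype=object)[ju],
                "score": m[iu, ju],
                "n_obs": n[iu, ju],
            }
        )
        return df.dropna(subset=["score"]).reset_index(drop=True)

    def write_tsv(self, prefix) -> None:
        """Write the square matrix and a long-format pair table."""
        self.scores.to_csv(f"{prefix}_matrix.tsv", sep="\t")
        self.pairs_long().to_csv(f"{prefix}_pairs.tsv", sep="\t", index=False)


def _score_one_replicate(
    values: pd.Series,
    singles: pd.Series,
    library: LibraryDesign,
) -> pd.DataFrame:
    """Score every construct under each of its queries for one replicate.

    Returns a long table (sgrna_lo, sgrna_hi, z) with one row per
    (construct, query) measurement.
    """
    con = library.constructs
    is_ntc = library.sgrnas["is_ntc"]
    a = con["sgrna_a"].to_numpy()
    b = con["sgrna_b"].to_numpy()
    y_all = values.reindex(con.index).to_numpy()

    recs_lo: list[np.ndarray] = []
    recs_hi: list[np.ndarray] = []
    recs_z: list[np.ndarray] = []
    for q in library.sgrna_ids:
        # constructs containing q; self-pair counted once (partner = q)
        in_a = a == q
        in_b = (b == q) & ~in_a
        rows = np.flatnonzero(in_a | in_b)
        if len(rows) == 0:
            continue
        partners = np.where(in_a[rows], b[rows], a[rows])
        x = singles.reindex(partners).to_numpy()
        y = y_all[rows]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() == 0:  # query fully filtered in this condition
            continue
        if ok.sum() < MIN_POINTS:
            warnings.warn(f"query {q!r}: fewer than {MIN_POINTS} usable partners", stacklevel=2)
            continue
        rows, partners, x, y = rows[ok], partners[ok], x[ok], y[ok]
        _, resid = fit_query_model(x, y)
        ntc_partner = is_ntc.reindex(partners).to_numpy()
        ntc_resid = resid[ntc_partner]
        if len(ntc_resid) < MIN_NTC_RESIDUALS:
            warnings.warn(f"query {q!r}: no usable ntc residuals, excluded", stacklevel=2)
            continue
        sd = float(np.std(ntc_resid, ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            warnings.warn(f"query {q!r}: degenerate ntc residual spread, excluded", stacklevel=2)
            continue
        z = resid / sd
        lo = np.minimum(np.full(len(rows), q, dtype=object), partners)
        hi = np.maximum(np.full(len(rows), q, dtype=object), partners)
        recs_lo.append(lo)
        recs_hi.append(hi)
        recs_z.append(z)
    if not recs_z:
        return pd.DataFrame(columns=["sgrna_lo", "sgrna_hi", "z"])
    return pd.DataFrame(
        {
            "sgrna_lo": np.concatenate(recs_lo),
            "sgrna_hi": np.concatenate(recs_hi),
            "z": np.concatenate(recs_z),
        }
    )


def score_sgrna_gis(
    cp: ConstructPhenotypes,
    singles: SinglePhenotypes,
    library: LibraryDesign | None = None,
    channel: Channel = "gamma",
    condition: str | None = None,
) -> GIMatrix:
    """Score sgRNA-level genetic interactions for one phenotype channel.

    Reference maps score the gamma channel; treated/environmental maps score
    ``tau:<condition>``.  Per replicate, each unordered sgRNA pair averages
    up to four measurements (two orientations x two query models); replicate
    scores are averaged last.
    """
    library = library or cp.library
    values = cp.channel_values(channel)
    single_vals = singles[channel]
    if condition is None:
        condition = (
            cp.reference_condition if channel == "gamma" else channel.split(":", 1)[1]
        )

    ids = library.sgrna_ids
    per_rep_scores = []
    per_rep_counts = []
    for rep in values.columns:
        long = _score_one_replicate(values[rep], single_vals[rep], library)
        if long.empty:
            continue
        g = long.groupby(["sgrna_lo", "sgrna_hi"])["z"]
        per_rep_scores.append(g.mean())
        per_rep_counts.append(g.size())
    if not per_rep_scores:
        raise ValueError("no scorable constructs in any replicate")
    score = pd.concat(per_rep_scores, axis=1).mean(axis=1)
    n_obs = pd.concat(per_rep_counts, axis=1).sum(axis=1)

    scores = pd.DataFrame(np.nan, index=ids, columns=ids)
    counts = pd.DataFrame(0, index=ids, columns=ids)
    lo = score.index.get_level_values(0)
    hi = score.index.get_level_values(1)
    scores.values[
        scores.index.get_indexer(lo), scores.columns.get_indexer(hi)
    ] = score.to_numpy()
    scores.values[
        scores.index.get_indexer(hi), scores.columns.get_indexer(lo)
    ] = score.to_numpy()
    counts.values[
        counts.index.get_indexer(lo), counts.columns.get_indexer(hi)
    ] = n_obs.to_numpy()
    counts.values[
        counts.index.get_indexer(hi), counts.columns.get_indexer(lo)
    ] = n_obs.to_numpy()

    return GIMatrix(
        level="sgrna",
        condition=condition,
        channel=channel,
        scores=scores,
        n_obs=counts,
        is_ntc=library.sgrnas["is_ntc"].copy(),
    )


def gene_level_gis(sg: GIMatrix, library: LibraryDesign) -> GIMatrix:
    """Aggregate an sgRNA-level matrix to gene level.

    The gene-pair score is the unweighted mean of all available sgRNA-pair
    scores for that gene pair (with two guides per gene, up to four unordered
    sgRNA pairs, i.e. eight ordered constructs).  ntc sgRNAs become size-1
    pseudo-genes, yielding gene-ntc control scores by the same averaging.
    """
    if sg.level != "sgrna":
        raise ValueError("input must be an sgRNA-level matrix")
    gene_of = library.gene_of
    labels = list(dict.fromkeys(gene_of.reindex(sg.scores.index)))
    long = _upper_long(sg.scores, sg.n_obs)
    ga = long["i"].map(gene_of)
    gb = long["j"].map(gene_of)
    lo = np.minimum(ga, gb)
    hi = np.maximum(ga, gb)
    grouped = long.assign(lo=lo, hi=hi).groupby(["lo", "hi"])
    mean = grouped["score"].mean()
    n = grouped["n"].sum()

    scores = pd.DataFrame(np.nan, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    li = scores.index.get_indexer(mean.index.get_level_values(0))
    hj = scores.columns.get_indexer(mean.index.get_level_values(1))
    scores.values[li, hj] = mean.to_numpy()
    scores.values[hj, li] = mean.to_numpy()
    counts.values[li, hj] = n.to_numpy()
    counts.values[hj, li] = n.to_numpy()

    is_ntc_gene = pd.Series(
        [bool(library.sgrnas["is_ntc"].get(lbl, False)) for lbl in labels],
        index=labels,
    )
    return GIMatrix(
        level="gene",
        condition=sg.condition,
        channel=sg.channel,
        scores=scores,
        n_obs=counts,
        is_ntc=is_ntc_gene,
    )


def _upper_long(scores: pd.DataFrame, n_obs: pd.DataFrame) -> pd.DataFrame:
    """Upper triangle (including diagonal) of a symmetric matrix, long form."""
    labels = np.asarray(scores.index, dtype=object)
    m = scores.to_numpy()
    n = n_obs.to_numpy()
    iu, ju = np.triu_indices(len(labels), k=0)
    df = pd.DataFrame(
        {"i": labels[iu], "j": labels[ju], "score": m[iu, ju], "n": n[iu, ju]}
    )
    return df.dropna(subset=["score"]).reset_index(drop=True)


def call_high_confidence(m: GIMatrix, n_sd: float = 4.0) -> pd.DataFrame:
    """High-confidence interaction calls.

    A pair is significant iff ``|score|`` strictly exceeds ``n_sd`` times the
    standard deviation of the control (entity-ntc) score distribution.
    Positive scores are buffering; negative are synthetic sick.
    """
    ctrl = m.control_scores
    if ctrl.empty:
        raise ValueError("matrix has no control scores; cannot set a threshold")
    threshold = n_sd * float(ctrl.std(ddof=1))
    calls = m.pairs_long()
    calls["sign"] = np.where(calls["score"] > 0, "buffering", "synthetic_sick")
    calls["significant"] = calls["score"].abs() > threshold
    calls.attrs["threshold"] = threshold
    calls.attrs["n_sd"] = n_sd
    calls.attrs["control_sd"] = threshold / n_sd if n_sd else float("nan")
    return calls
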