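"""Construct- and single-sgRNA-level growth phenotypes.

Phenotypes are log2 read enrichments relative to the median of the ntc-ntc
(double non-targeting) constructs, per cumulative population doubling:

* gamma — final untreated vs T0, divided by d_u;
* tau   — final treated vs T0, divided by d_t;
* rho   — final treated vs final untreated, divided by (d_u - d_t): the
  drug-specific component of the phenotype, used for nominating-screen hits.

Processing order: each sample's counts are rescaled to a common depth (the
mean sample total — the identity when depths are equal, and exactly
cancelling any per-sample scaling), low-coverage sgRNAs are flagged on the
raw counts (median construct count < 35 in either cassette position in any
sample of a condition), a pseudocount of 10 is added, and the ratios above
are formed.  The three formulas satisfy the identity
``rho * (d_u - d_t) == tau * d_t - gamma * d_u`` construct by construct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import LibraryDesign
from .simulate import _normalize_doublings, sample_label

Channel = str  # "gamma", "tau:<condition>" or "rho:<condition>"


def parse_sample_columns(columns) -> pd.DataFrame:
    """Split sample labels ``<condition>_<replicate>`` into parts.

    T0 samples use the reserved condition label ``T0``.
    """
    rows = []
    for c in columns:
        if "_" not in c:
            raise ValueError(f"sample label {c!r} is not <condition>_<replicate>")
        cond, rep = c.rsplit("_", 1)
        rows.append({"sample": c, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


def filter_constructs(
    counts: pd.DataFrame,
    library: LibraryDesign,
    min_median: int = 35,
) -> dict[str, set[str]]:
    """Flag low-coverage sgRNAs per condition.

    An sgRNA is flagged in a condition iff the median raw read count of the
    constructs carrying it in position A — or, separately, in position B — is
    strictly below ``min_median`` in any sample belonging to that condition
    (the shared T0 samples belong to every condition).  Every construct
    containing a flagged sgRNA is excluded from that condition's downstream
    analysis.
    """
    meta = parse_sample_columns(counts.columns)
    conditions = [c for c in meta["condition"].unique() if c != "T0"]
    med_a = counts.groupby(library.constructs["sgrna_a"]).median()
    med_b = counts.groupby(library.constructs["sgrna_b"]).median()
    flags: dict[str, set[str]] = {}
    t0_samples = list(meta.index[meta["condition"] == "T0"])
    for cond in conditions:
        samples = t0_samples + list(meta.index[meta["condition"] == cond])
        bad = (med_a[samples] < min_median).any(axis=1) | (
            med_b[samples] < min_median
        ).any(axis=1)
        flags[cond] = set(bad.index[bad])
    return flags


@dataclass
class ConstructPhenotypes:
    """Per-construct, per-replicate gamma/tau/rho values with filter flags."""

    gamma: pd.DataFrame  # constructs x replicates, reference arm
    tau: dict[str, pd.DataFrame]  # condition -> constructs x replicates
    rho: dict[str, pd.DataFrame]
    flagged_sgrnas: dict[str, set[str]]  # condition -> flagged sgRNA ids
    rho_undefined: set[str]  # conditions where d_u == d_t
    library: LibraryDesign = field(repr=False)
    reference_condition: str = "reference"
    doublings: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    @property
    def replicates(self) -> list[str]:
        return list(self.gamma.columns)

    @property
    def conditions(self) -> list[str]:
        return [self.reference_condition, *self.tau]

    def construct_mask(self, condition: str) -> pd.Series:
        """True for constructs excluded in ``condition`` (flagged sgRNA in
        either position)."""
        bad = self.flagged_sgrnas.get(condition, set())
        con = self.library.constructs
        return con["sgrna_a"].isin(bad) | con["sgrna_b"].isin(bad)

    def channel_values(self, channel: Channel, filtered: bool = True) -> pd.DataFrame:
        """Phenotype table for a channel, with excluded constructs as NaN.

        ``channel`` is ``"gamma"`` (reference arm), ``"tau:<cond>"`` or
        ``"rho:<cond>"``.  rho masks constructs flagged in either arm.
        """
        if channel == "gamma":
            vals, conds = self.gamma, [self.reference_condition]
        elif channel.startswith("tau:"):
            cond = channel.split(":", 1)[1]
            vals, conds = self.tau[cond], [cond]
        elif channel.startswith("rho:"):
            cond = channel.split(":", 1)[1]
            vals, conds = self.rho[cond], [cond, self.reference_condition]
        else:
            raise KeyError(f"unknown channel {channel!r}")
        if not filtered:
            return vals.copy()
        mask = pd.Series(False, index=vals.index)
        for c in conds:
            mask |= self.construct_mask(c)
        out = vals.copy()
        out[mask] = np.nan
        return out

    def channel_for(self, condition: str) -> Channel:
        """The growth channel scored for a condition arm: gamma for the
        reference, tau for treated arms."""
        if condition == self.reference_condition:
            return "gamma"
        return f"tau:{condition}"

    def to_long(self) -> pd.DataFrame:
        """Long-format table: construct, replicate, channel, value, filtered."""
        frames = []
        channels = ["gamma"] + [f"tau:{c}" for c in self.tau] + [
            f"rho:{c}" for c in self.rho
        ]
        for ch in channels:
            raw = self.channel_values(ch, filtered=False)
            masked = self.channel_values(ch, filtered=True)
            long = raw.stack(future_stack=True).rename("value").reset_index()
            long.columns = ["construct_id", "replicate", "value"]
            long.insert(2, "channel", ch)
            long["filtered"] = (
                masked.isna() & raw.notna()
            ).stack(future_stack=True).to_numpy()
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def compute_construct_phenotypes(
    counts: pd.DataFrame,
    library: LibraryDesign,
    doublings: dict,
    reference_condition: str | None = None,
    pseudocount: float = 10,
    min_median: int = 35,
    target_depth: float | None = None,
) -> ConstructPhenotypes:
    """Compute gamma (and tau/rho for treated arms) per construct, per
    replicate.

    ``doublings`` maps ``(condition, replicate)`` (or nested
    ``{condition: {replicate: d}}``) to cumulative population doublings.
    The first non-T0 condition in column order is the reference arm unless
    given explicitly.  rho for an arm whose doublings equal the reference's
    is undefined and flagged rather than computed.

    ``target_depth`` is the common total each sample is rescaled to before
    the pseudocount is added; it defaults to the mean sample total (the
    identity when depths are equal).  With an explicit fixed value, gamma is
    exactly invariant to rescaling any sample's counts; with the default the
    pseudocount's relative weight tracks the observed depths.
    """
    meta = parse_sample_columns(counts.columns)
    conditions = [c for c in meta["condition"].unique() if c != "T0"]
    if not conditions:
        raise ValueError("counts table has no final-timepoint samples")
    if reference_condition is None:
        reference_condition = conditions[0]
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in counts")
    replicates = sorted(meta["replicate"].unique())
    doublings = _normalize_doublings(doublings)
    for cond in conditions:
        for rep in replicates:
            if (cond, rep) not in doublings:
                raise ValueError(f"doublings missing entry for {(cond, rep)}")
            if doublings[(cond, rep)] <= 0:
                raise ValueError("doublings must be positive")

    counts = counts.reindex(library.constructs.index)
    ntc_pairs = library.is_ntc_construct()
    if not ntc_pairs.any():
        raise ValueError("no ntc-ntc constructs: cannot form the phenotype normalizer")

    # depth normalization: rescale every sample to a common total
    totals = counts.sum(axis=0)
    if target_depth is None:
        target_depth = float(totals.mean())
    scaled = counts * (target_depth / totals)
    flags = filter_constructs(counts, library, min_median=min_median)

    p = scaled + pseudocount
    ntc_median = p.loc[ntc_pairs].median(axis=0)
    rel = p / ntc_median  # construct abundance relative to the ntc median

    def log2_ratio(c_num: str, c_den: str, rep: str) -> pd.Series:
        num = rel[sample_label(c_num, rep)]
        den = rel[sample_label(c_den, rep)]
        return np.log2(num / den)

    gamma = pd.DataFrame(
        {
            rep: log2_ratio(reference_condition, "T0", rep)
            / doublings[(reference_condition, rep)]
            for rep in replicates
        }
    )
    tau: dict[str, pd.DataFrame] = {}
    rho: dict[str, pd.DataFrame] = {}
    rho_undefined: set[str] = set()
    for cond in conditions:
        if cond == reference_condition:
            continue
        tau[cond] = pd.DataFrame(
            {
                rep: log2_ratio(cond, "T0", rep) / doublings[(cond, rep)]
                for rep in replicates
            }
        )
        cols = {}
        for rep in replicates:
            d_u = doublings[(reference_condition, rep)]
            d_t = doublings[(cond, rep)]
            if d_u == d_t:
                cols[rep] = pd.Series(np.nan, index=counts.index)
                rho_undefined.add(cond)
            else:
                cols[rep] = log2_ratio(cond, reference_condition, rep) / (d_u - d_t)
        rho[cond] = pd.DataFrame(cols)
    if rho_undefined:
        warnings.warn(
            f"rho undefined (d_u == d_t) for conditions: {sorted(rho_undefined)}",
            stacklevel=2,
        )

    return ConstructPhenotypes(
        gamma=gamma,
        tau=tau,
        rho=rho,
        flagged_sgrnas=flags,
        rho_undefined=rho_undefined,
        library=library,
        reference_condition=reference_condition,
        doublings=doublings,
    )


@dataclass
class SinglePhenotypes:
    """Single-sgRNA phenotypes: the mean over all unfiltered ntc-paired
    constructs of that sgRNA, in both cassette orientations (with 13 ntc
    guides this is up to 26 independent measurements per sgRNA)."""

    values: dict[Channel, pd.DataFrame]  # channel -> sgRNA x replicate means
    n_measurements: dict[Channel, pd.DataFrame]

    def __getitem__(self, channel: Channel) -> pd.DataFrame:
        return self.values[channel]

    @property
    def gamma(self) -> pd.DataFrame:
        return self.values["gamma"]


def _ntc_paired_means(
    values: pd.DataFrame, library: LibraryDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean phenotype of each sgRNA over its ntc-paired constructs."""
    is_ntc = library.sgrnas["is_ntc"]
    con = library.constructs
    a_ntc = con["sgrna_a"].map(is_ntc).to_numpy()
    b_ntc = con["sgrna_b"].map(is_ntc).to_numpy()
    # attribute each construct with an ntc partner to its query sgRNA; a
    # construct of two ntcs contributes to both (once when a == b)
    rows, queries = [], []
    idx_b = np.flatnonzero(b_ntc)
    rows.extend(idx_b)
    queries.extend(con["sgrna_a"].to_numpy()[idx_b])
    idx_a = np.flatnonzero(a_ntc & (con["sgrna_a"] != con["sgrna_b"]).to_numpy())
    rows.extend(idx_a)
    queries.extend(con["sgrna_b"].to_numpy()[idx_a])
    v = values.iloc[rows]
    grouper = pd.Index(queries, name="sgrna_id")
    means = v.groupby(grouper).mean()
    n = v.notna().groupby(grouper).sum()
    means = means.reindex(library.sgrnas.index)
    n = n.reindex(library.sgrnas.index).fillna(0).astype(int)
    return means, n


def single_sgrna_phenotypes(
    cp: ConstructPhenotypes, library: LibraryDesign | None = None
) -> SinglePhenotypes:
    """Estimate single-sgRNA phenotypes for every channel of ``cp``."""
    library = library or cp.library
    channels = ["gamma"] + [f"tau:{c}" for c in cp.tau] + [
        f"rho:{c}" for c in cp.rho if c not in cp.rho_undefined
    ]
    values: dict[Channel, pd.DataFrame] = {}
    n_meas: dict[Channel, pd.DataFrame] = {}
    for ch in channels:
        means, n = _ntc_paired_means(cp.channel_values(ch), library)
        dead = n.sum(axis=1) == 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} sgRNAs have no usable ntc-paired constructs "
                f"for channel {ch}",
                stacklevel=2,
            )
        values[ch] = means
        n_meas[ch] = n
    return SinglePhenotypes(values=values, n_measurements=n_meas)


def call_nominating_hits(
    rho_singles: pd.DataFrame,
    library: LibraryDesign,
    rho_cut: float = 0.2,
    p_cut: float = 0.02,
) -> pd.DataFrame:
    """Nominating-screen hit calls from sgRNA-level rho phenotypes.

    Per gene, the sgRNA-level rho values (pooled across replicates) are
    compared to the pooled ntc sgRNA rho distribution by a two-sided
    Mann-Whitney U test; a gene is a hit iff ``|mean rho| > rho_cut`` (strict)
    and ``p < p_cut``.

    Parameters
    ----------
    rho_singles : pandas.DataFrame
        sgRNA x replicate single-phenotype rho values
        (``SinglePhenotypes["rho:<cond>"]``).
    """
    ntc_vals = (
        rho_singles.loc[library.ntc_sgrnas].to_numpy().ravel()
    )
    ntc_vals = ntc_vals[~np.isnan(ntc_vals)]
    if len(ntc_vals) < 2:
        raise ValueError("need >= 2 ntc rho values for the null distribution")
    gene_of = library.sgrnas["gene"]
    rows = []
    for gene in library.genes:
        sgrnas = library.sgrnas.index[(gene_of == gene) & ~library.sgrnas["is_ntc"]]
        vals = rho_singles.loc[sgrnas].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            warnings.warn(f"gene {gene!r}: no surviving sgRNA rho values", stacklevel=2)
            continue
        u = stats.mannwhitneyu(vals, ntc_vals, alternative="two-sided")
        mean_rho = float(np.mean(vals))
        rows.append(
            {
                "gene": gene,
                "mean_rho": mean_rho,
                "p_value": float(u.pvalue),
                "n_sgrna_values": len(vals),
                "hit": bool(abs(mean_rho) > rho_cut and u.pvalue < p_cut),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
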