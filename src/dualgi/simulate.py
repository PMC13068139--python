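"""Pooled dual-guide screen simulator with known ground truth.

The growth model is the exact inverse of the gamma estimator: each construct's
abundance grows as ``initial * 2**(phenotype * doublings)``, where the
phenotype (log2 enrichment relative to the ntc median, per population
doubling) is the sum of the two single-sgRNA effects plus any planted
gene-pair interaction for that condition.  Sequencing is multinomial sampling
of the final abundances at a configurable depth.  Because ntc constructs have
phenotype exactly 0, the downstream estimator recovers the planted phenotypes
by algebra, not convention.

Conditions are arms of one screen sharing the T0 sample: the first condition
listed is the untreated reference (scored on the gamma channel downstream);
any additional conditions are treated/environmental arms (tau channel), whose
single-sgRNA effects are gamma plus a per-gene drug modifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .library import LibraryDesign

Pair = tuple[str, str]


def default_doublings(
    conditions: list[str],
    n_replicates: int = 2,
    reference_doublings: float = 8.0,
    treated_doublings: float = 5.0,
) -> dict[tuple[str, str], float]:
    """Cumulative population doublings per (condition, replicate).

    Defaults emulate a ~9-day pooled growth screen where drug treatment slows
    growth (fewer cumulative doublings in the treated arms), which is what
    gives the drug-specific rho phenotype a nonzero denominator d_u - d_t.
    """
    reps = [f"R{i}" for i in range(1, n_replicates + 1)]
    out: dict[tuple[str, str], float] = {}
    for i, cond in enumerate(conditions):
        d = reference_doublings if i == 0 else treated_doublings
        for r in reps:
            out[(cond, r)] = d
    return out


@dataclass
class SimTruth:
    """Ground truth underlying a simulated screen.

    Attributes
    ----------
    single_effects : pandas.DataFrame
        sgRNA x condition phenotypes per doubling (gamma for the reference
        condition, tau for treated arms).  ntc rows are exactly 0.
    interactions : dict
        ``(condition, geneA, geneB) -> gi`` with ``geneA < geneB``; the
        additive deviation (phenotype-per-doubling units) applied to every
        construct pairing the two genes in that condition.
    rewired : dict
        condition -> frozenset of gene pairs whose interaction differs from
        the reference (the planted differential interactions).
    doublings : dict
        ``(condition, replicate) -> cumulative population doublings``.
    """

    single_effects: pd.DataFrame
    interactions: dict[tuple[str, str, str], float]
    rewired: dict[str, frozenset[Pair]]
    doublings: dict[tuple[str, str], float]
    conditions: list[str]
    gene_effects: pd.Series = field(repr=False, default=None)
    drug_modifiers: pd.DataFrame = field(repr=False, default=None)

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def replicates(self) -> list[str]:
        return sorted({r for _, r in self.doublings})

    def interaction(self, gene_a: str, gene_b: str, condition: str) -> float:
        if gene_a == gene_b:
            return 0.0
        key = (condition, *sorted((gene_a, gene_b)))
        return self.interactions.get(key, 0.0)

    def planted_pairs(self, condition: str | None = None) -> set[Pair]:
        condition = condition or self.reference
        return {(a, b) for c, a, b in self.interactions if c == condition}

    def construct_phenotypes(
        self, library: LibraryDesign, condition: str
    ) -> pd.Series:
        """True per-doubling phenotype of every construct in ``condition``."""
        s = self.single_effects[condition]
        gene = library.gene_of
        a = library.constructs["sgrna_a"]
        b = library.constructs["sgrna_b"]
        phen = a.map(s).to_numpy() + b.map(s).to_numpy()
        ga, gb = a.map(gene), b.map(gene)
        is_ntc = library.sgrnas["is_ntc"]
        targeting_pair = (~a.map(is_ntc)) & (~b.map(is_ntc)) & (ga != gb).to_numpy()
        idx = np.flatnonzero(targeting_pair.to_numpy())
        gi = np.zeros(len(phen))
        for i in idx:
            gi[i] = self.interaction(ga.iloc[i], gb.iloc[i], condition)
        return pd.Series(phen + gi, index=library.constructs.index, name=condition)

    # -- I/O --------------------------------------------------------------
    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.single_effects.to_csv(
            directory / "truth_single_effects.tsv", sep="\t", index_label="sgrna_id"
        )
        rows = [
            {
                "condition": c,
                "gene_a": a,
                "gene_b": b,
                "gi_true": v,
                "rewired": int((a, b) in self.rewired.get(c, frozenset())),
            }
            for (c, a, b), v in sorted(self.interactions.items())
        ]
        pd.DataFrame(rows).to_csv(
            directory / "truth_interactions.tsv", sep="\t", index=False
        )
        dbl = pd.DataFrame(
            [
                {"condition": c, "replicate": r, "doublings": d}
                for (c, r), d in sorted(self.doublings.items())
            ]
        )
        dbl.to_csv(directory / "truth_doublings.tsv", sep="\t", index=False)


def simulate_truth(
    library: LibraryDesign,
    effect_sd: float = 0.1,
    frac_interacting: float = 0.1,
    gi_effect_sd: float = 0.3,
    conditions: tuple[str, ...] = ("reference", "treated"),
    rewiring_frac: float = 0.0,
    doublings: dict | None = None,
    seed: int = 0,
    *,
    sgrna_scatter: float = 0.2,
    drug_effect_sd: float | None = None,
    gi_magnitude: float | None = None,
    drug_modifiers: dict[str, float] | None = None,
) -> SimTruth:
    """Draw single-gene effects and planted interactions for a screen.

    Parameters
    ----------
    effect_sd : float
        SD of the gene-level growth effect (per doubling).  Both sgRNAs of a
        gene share the gene-level mean, with sgRNA-level scatter of
        ``sgrna_scatter * effect_sd`` around it.
    frac_interacting : float
        Fraction of distinct gene pairs given a nonzero interaction in the
        reference condition (``floor(frac * C(G, 2))`` pairs).
    gi_effect_sd : float
        SD of planted interaction values when drawn Normal; if
        ``gi_magnitude`` is given, interactions instead have that fixed
        magnitude with a random sign.
    rewiring_frac : float
        Fraction of planted interactions redrawn independently in each
        non-reference condition — the planted differential interactions.
    drug_effect_sd : float, optional
        SD of the per-gene drug modifier added to gamma to form tau in
        treated arms; defaults to ``0.5 * effect_sd``.
    drug_modifiers : dict, optional
        gene -> modifier override applied in every treated arm (other genes
        draw from the Normal above).
    """
    if not 0 <= frac_interacting <= 1:
        raise ValueError("frac_interacting must be in [0, 1]")
    if not 0 <= rewiring_frac <= 1:
        raise ValueError("rewiring_frac must be in [0, 1]")
    conditions = list(conditions)
    if doublings is None:
        doublings = default_doublings(conditions)
    doublings = _normalize_doublings(doublings)
    have = {c for c, _ in doublings}
    missing = [c for c in conditions if c not in have]
    if missing:
        raise ValueError(f"conditions missing a doublings entry: {missing}")
    if any(d <= 0 for d in doublings.values()):
        raise ValueError("doublings must be > 0")
    if drug_effect_sd is None:
        drug_effect_sd = 0.5 * effect_sd

    rng = np.random.default_rng(seed)
    genes = library.genes
    reference = conditions[0]

    gene_eff = pd.Series(rng.normal(0.0, effect_sd, len(genes)), index=genes)
    single = pd.DataFrame(
        0.0, index=library.sgrnas.index, columns=conditions, dtype=float
    )
    targeting = ~library.sgrnas["is_ntc"]
    gamma = library.sgrnas.loc[targeting, "gene"].map(gene_eff)
    gamma = gamma + rng.normal(0.0, sgrna_scatter * effect_sd, len(gamma))
    single.loc[targeting, reference] = gamma

    drug = pd.DataFrame(0.0, index=genes, columns=conditions[1:], dtype=float)
    for cond in conditions[1:]:
        drug[cond] = rng.normal(0.0, drug_effect_sd, len(genes))
        if drug_modifiers:
            for g, v in drug_modifiers.items():
                drug.loc[g, cond] = v
        mod = library.sgrnas.loc[targeting, "gene"].map(drug[cond])
        single.loc[targeting, cond] = single.loc[targeting, reference] + mod

    def draw_gi(n: int) -> np.ndarray:
        if gi_magnitude is not None:
            return rng.choice([-1.0, 1.0], size=n) * gi_magnitude
        return rng.normal(0.0, gi_effect_sd, n)

    all_pairs = list(combinations(genes, 2))
    n_int = int(np.floor(frac_interacting * len(all_pairs)))
    interactions: dict[tuple[str, str, str], float] = {}
    rewired: dict[str, frozenset[Pair]] = {}
    chosen: list[Pair] = []
    if n_int > 0:
        picked = rng.choice(len(all_pairs), size=n_int, replace=False)
        chosen = [all_pairs[i] for i in sorted(picked)]
        values = draw_gi(n_int)
        for (a, b), v in zip(chosen, values):
            interactions[(reference, a, b)] = float(v)
    for cond in conditions[1:]:
        n_rw = int(np.floor(rewiring_frac * n_int))
        rw: set[Pair] = set()
        if n_rw > 0:
            picked = rng.choice(n_int, size=n_rw, replace=False)
            rw = {chosen[i] for i in picked}
        new_vals = draw_gi(len(rw))
        it = iter(new_vals)
        for a, b in chosen:
            if (a, b) in rw:
                interactions[(cond, a, b)] = float(next(it))
            else:
                interactions[(cond, a, b)] = interactions[(reference, a, b)]
        rewired[cond] = frozenset(rw)

    return SimTruth(
        single_effects=single,
        interactions=interactions,
        rewired=rewired,
        doublings=doublings,
        conditions=conditions,
        gene_effects=gene_eff,
        drug_modifiers=drug,
    )


def _normalize_doublings(doublings: dict) -> dict[tuple[str, str], float]:
    """Accept {(cond, rep): d} or {cond: {rep: d}} and return the flat form."""
    out: dict[tuple[str, str], float] = {}
    for k, v in doublings.items():
        if isinstance(k, tuple):
            out[k] = float(v)
        elif isinstance(v, dict):
            for r, d in v.items():
                out[(k, r)] = float(d)
        else:
            raise ValueError("doublings must map (condition, replicate) -> value")
    return out


def sample_label(condition: str, replicate: str) -> str:
    return f"{condition}_{replicate}"


def simulate_counts(
    library: LibraryDesign,
    truth: SimTruth,
    depth: int = 2_000_000,
    abundance_sd_log: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the read-count table of the screen described by ``truth``.

    Each replicate draws an independent lognormal initial abundance per
    construct (independent transductions); each sample — T0 and the final
    timepoint of every condition arm — is a multinomial draw of exactly
    ``depth`` reads from the arm's abundance profile.

    Columns are labelled ``T0_<rep>`` and ``<condition>_<rep>``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    n = len(library.constructs)
    reps = truth.replicates
    phen = {
        c: truth.construct_phenotypes(library, c).to_numpy()
        for c in truth.conditions
    }
    cols: dict[str, np.ndarray] = {}
    for rep in reps:
        if abundance_sd_log > 0:
            a0 = rng.lognormal(0.0, abundance_sd_log, n)
        else:
            a0 = np.ones(n)
        cols[sample_label("T0", rep)] = rng.multinomial(depth, a0 / a0.sum())
        for cond in truth.conditions:
            d = truth.doublings[(cond, rep)]
            w = a0 * np.exp2(phen[cond] * d)
            cols[sample_label(cond, rep)] = rng.multinomial(depth, w / w.sum())
    order = [sample_label("T0", r) for r in reps] + [
        sample_label(c, r) for c in truth.conditions for r in reps
    ]
    counts = pd.DataFrame(cols, index=library.constructs.index.copy())[order]
    counts.columns.name = "sample"
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="construct_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="construct_id")
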