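"""Model/results facade over the screen-analysis pipeline.

`GIScreen` is constructed from the raw ingredients of a dual-guide screen —
a read-count table, the library design and the per-arm population doublings —
and `fit()` runs the full pipeline (phenotypes, filters, single-sgRNA
estimates, per-condition sgRNA- and gene-level interaction matrices,
high-confidence calls), returning a `GIScreenResults` that carries the
estimates, their null distributions and a `summary()` table.  Differential
maps between two fitted conditions (or two fitted screens) hang off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gi as gi_mod
from . import phenotypes as ph
from . import rewiring
from .library import LibraryDesign
from .simulate import read_counts


class GIScreen:
    """A dual-sgRNA CRISPRi screen ready for interaction mapping.

    Parameters
    ----------
    counts : pandas.DataFrame
        Constructs x samples read counts; columns ``T0_<rep>`` and
        ``<condition>_<rep>``.
    library : LibraryDesign
    doublings : dict
        ``(condition, replicate) -> cumulative population doublings`` (or
        nested ``{condition: {replicate: d}}``).
    reference_condition : str, optional
        The untreated arm (gamma channel); defaults to the first final
        condition in column order.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library: LibraryDesign,
        doublings: dict,
        reference_condition: str | None = None,
    ) -> None:
        self.counts = counts
        self.library = library
        self.doublings = doublings
        self.reference_condition = reference_condition

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        library_dir: str | Path,
        doublings: dict,
        reference_condition: str | None = None,
    ) -> "GIScreen":
        return cls(
            read_counts(counts_path),
            LibraryDesign.read_tsv(library_dir),
            doublings,
            reference_condition,
        )

    def fit(
        self,
        pseudocount: float = 10,
        min_median: int = 35,
        n_sd: float = 4.0,
    ) -> "GIScreenResults":
        """Run the pipeline and return the fitted results."""
        cp = ph.compute_construct_phenotypes(
            self.counts,
            self.library,
            self.doublings,
            reference_condition=self.reference_condition,
            pseudocount=pseudocount,
            min_median=min_median,
        )
        singles = ph.single_sgrna_phenotypes(cp, self.library)
        sgrna_gi: dict[str, gi_mod.GIMatrix] = {}
        gene_gi: dict[str, gi_mod.GIMatrix] = {}
        calls: dict[str, pd.DataFrame] = {}
        for cond in cp.conditions:
            channel = cp.channel_for(cond)
            sg = gi_mod.score_sgrna_gis(cp, singles, self.library, channel=channel)
            sgrna_gi[cond] = sg
            gene = gi_mod.gene_level_gis(sg, self.library)
            gene_gi[cond] = gene
            calls[cond] = gi_mod.call_high_confidence(gene, n_sd=n_sd)
        return GIScreenResults(
            model=self,
            phenotypes=cp,
            singles=singles,
            sgrna_gi=sgrna_gi,
            gene_gi=gene_gi,
            calls=calls,
            n_sd=n_sd,
        )


@dataclass
class GIScreenResults:
    """Fitted interaction maps of a screen, one per condition arm."""

    model: GIScreen = field(repr=False)
    phenotypes: ph.ConstructPhenotypes = field(repr=False)
    singles: ph.SinglePhenotypes = field(repr=False)
    sgrna_gi: dict[str, gi_mod.GIMatrix]
    gene_gi: dict[str, gi_mod.GIMatrix]
    calls: dict[str, pd.DataFrame]
    n_sd: float = 4.0

    @property
    def conditions(self) -> list[str]:
        return list(self.gene_gi)

    @property
    def reference_condition(self) -> str:
        return self.phenotypes.reference_condition

    def differential(
        self,
        env_condition: str,
        ref_condition: str | None = None,
        n_sd: float = 5.0,
        reference_results: "GIScreenResults | None" = None,
    ) -> rewiring.DGIMatrix:
        """Differential map (eGI - GI) with high-confidence calls attached.

        ``reference_results`` allows an unmatched reference from another
        fitted screen; by default the reference arm of this screen is used.
        """
        ref_res = reference_results or self
        ref_condition = ref_condition or ref_res.reference_condition
        d = rewiring.compute_dgi(
            self.gene_gi[env_condition], ref_res.gene_gi[ref_condition]
        )
        rewiring.call_high_confidence_dgi(
            d, self.calls[env_condition], ref_res.calls[ref_condition], n_sd=n_sd
        )
        return d

    def summary(self) -> str:
        """Human-readable per-condition summary of the fitted maps."""
        lib = self.model.library
        lines = [
            "Dual-sgRNA GI screen fit",
            "=" * 60,
            f"sgRNAs: {len(lib.sgrna_ids)} "
            f"({len(lib.targeting_sgrnas)} targeting, {len(lib.ntc_sgrnas)} ntc); "
            f"constructs: {len(lib.constructs)}",
            f"replicates: {', '.join(self.phenotypes.replicates)}; "
            f"reference arm: {self.reference_condition}",
            "-" * 60,
        ]
        header = (
            f"{'condition':<16}{'channel':<12}{'filtered':<10}"
            f"{'ctrl SD':<9}{'pos':<6}{'neg':<6}"
        )
        lines.append(header)
        for cond in self.conditions:
            calls = self.calls[cond]
            sig = calls[calls["significant"]]
            n_pos = int((sig["score"] > 0).sum())
            n_neg = int((sig["score"] < 0).sum())
            ctrl_sd = self.gene_gi[cond].control_sd()
            n_filt = len(self.phenotypes.flagged_sgrnas.get(cond, set()))
            lines.append(
                f"{cond:<16}{self.phenotypes.channel_for(cond):<12}"
                f"{n_filt:<10}{ctrl_sd:<9.3f}{n_pos:<6}{n_neg:<6}"
            )
        lines.append("-" * 60)
        lines.append(
            f"high-confidence threshold: |score| > {self.n_sd:g} SD of the "
            "gene-ntc control distribution"
        )
        return "\n".join(lines)

    def plot_score_distribution(self, condition: str, ax=None, bins: int = 60):
        """Histogram of gene-pair scores with the control distribution and
        the significance thresholds overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        m = self.gene_gi[condition]
        pairs = m.pairs_long()["score"]
        ctrl = m.control_scores
        ax.hist(pairs, bins=bins, density=True, alpha=0.6, label="gene pairs")
        ax.hist(ctrl, bins=bins, density=True, alpha=0.6, label="gene-ntc controls")
        thr = self.calls[condition].attrs["threshold"]
        for t in (-thr, thr):
            ax.axvline(t, color="k", ls="--", lw=0.8)
        ax.set_xlabel("interaction score (z)")
        ax.set_ylabel("density")
        ax.set_title(condition)
        ax.legend()
        return ax
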