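"""Dual-sgRNA library designs.

A pooled dual-guide CRISPRi library places one sgRNA in each of two cassette
positions; every ordered pair (a, b) over the sgRNA set — including self-pairs
(a, a) and pairings with non-targeting controls (ntc) — is a distinct
construct.  A library of S sgRNAs therefore has S**2 constructs before any
cloning dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: gene label shared by all non-targeting control sgRNAs
NTC_GENE = "ntc"

#: separator between the position-A and position-B sgRNA ids in a construct id
CONSTRUCT_SEP = "|"


@dataclass
class LibraryDesign:
    """A dual-sgRNA library: the sgRNA roster and the construct table.

    Parameters
    ----------
    sgrnas : pandas.DataFrame
        Indexed by ``sgrna_id`` with columns ``gene`` (str) and ``is_ntc``
        (bool).  ntc sgRNAs carry ``gene == "ntc"``.
    constructs : pandas.DataFrame
        Indexed by ``construct_id`` with columns ``sgrna_a`` and ``sgrna_b``
        (the position-A and position-B sgRNA ids).
    """

    sgrnas: pd.DataFrame
    constructs: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.sgrnas.index.has_duplicates:
            raise ValueError("duplicate sgRNA ids in library")
        if self.constructs.index.has_duplicates:
            raise ValueError("duplicate construct ids in library")
        known = set(self.sgrnas.index)
        referenced = set(self.constructs["sgrna_a"]) | set(self.constructs["sgrna_b"])
        missing = referenced - known
        if missing:
            raise ValueError(f"constructs reference unknown sgRNAs: {sorted(missing)[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.sgrnas.index)

    @property
    def ntc_sgrnas(self) -> list[str]:
        return list(self.sgrnas.index[self.sgrnas["is_ntc"]])

    @property
    def targeting_sgrnas(self) -> list[str]:
        return list(self.sgrnas.index[~self.sgrnas["is_ntc"]])

    @property
    def genes(self) -> list[str]:
        """Targeting genes, in order of first appearance."""
        g = self.sgrnas.loc[~self.sgrnas["is_ntc"], "gene"]
        return list(dict.fromkeys(g))

    @property
    def gene_of(self) -> pd.Series:
        """Map sgrna_id -> gene (ntc sgRNAs map to their own id, acting as
        size-1 pseudo-genes for control-distribution bookkeeping)."""
        gene = self.sgrnas["gene"].copy()
        gene[self.sgrnas["is_ntc"]] = self.sgrnas.index[self.sgrnas["is_ntc"]]
        return gene

    def is_ntc_construct(self) -> pd.Series:
        """Boolean per construct: both positions carry an ntc sgRNA."""
        ntc = self.sgrnas["is_ntc"]
        return (
            self.constructs["sgrna_a"].map(ntc) & self.constructs["sgrna_b"].map(ntc)
        )

    # -- I/O --------------------------------------------------------------
    def write_tsv(self, directory: str | Path) -> None:
        """Write ``sgrnas.tsv`` (sgrna_id, gene, is_ntc) and
        ``constructs.tsv`` (construct_id, sgrna_a, sgrna_b)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sg = self.sgrnas.copy()
        sg["is_ntc"] = sg["is_ntc"].astype(int)
        sg.to_csv(directory / "sgrnas.tsv", sep="\t", index_label="sgrna_id")
        self.constructs.to_csv(
            directory / "constructs.tsv", sep="\t", index_label="construct_id"
        )

    @classmethod
    def read_tsv(cls, directory: str | Path) -> "LibraryDesign":
        directory = Path(directory)
        sg = pd.read_csv(directory / "sgrnas.tsv", sep="\t", index_col="sgrna_id")
        sg["is_ntc"] = sg["is_ntc"].astype(bool)
        con = pd.read_csv(
            directory / "constructs.tsv", sep="\t", index_col="construct_id"
        )
        return cls(sg, con)


def construct_id(sgrna_a: str, sgrna_b: str) -> str:
    return f"{sgrna_a}{CONSTRUCT_SEP}{sgrna_b}"


def make_library(
    genes: list[str],
    sgrnas_per_gene: int = 2,
    n_ntc: int = 13,
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> LibraryDesign:
    """Build an all-by-all dual-sgRNA library design.

    The sgRNA roster contains ``sgrnas_per_gene`` guides per gene plus
    ``n_ntc`` non-targeting controls; the construct set is every ordered pair
    of sgRNAs (self-pairs included).  ``dropout_fraction`` removes a uniformly
    random fraction of constructs, emulating cloning attrition.

    Raises
    ------
    ValueError
        On duplicate gene names, empty gene list, or invalid parameters.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in library design")
    if sgrnas_per_gene < 1:
        raise ValueError("sgrnas_per_gene must be >= 1")
    if n_ntc < 0:
        raise ValueError("n_ntc must be >= 0")
    if not 0 <= dropout_fraction < 1:
        raise ValueError("dropout_fraction must be in [0, 1)")

    ids, gene_col, ntc_col = [], [], []
    for g in genes:
        for i in range(1, sgrnas_per_gene + 1):
            ids.append(f"{g}_sg{i}")
            gene_col.append(g)
            ntc_col.append(False)
    for i in range(1, n_ntc + 1):
        ids.append(f"ntc_{i}")
        gene_col.append(NTC_GENE)
        ntc_col.append(True)
    sgrnas = pd.DataFrame({"gene": gene_col, "is_ntc": ntc_col}, index=pd.Index(ids, name="sgrna_id"))

    s = len(ids)
    a = np.repeat(np.arange(s), s)
    b = np.tile(np.arange(s), s)
    if dropout_fraction > 0:
        rng = np.random.default_rng(seed)
        n_drop = int(np.floor(dropout_fraction * s * s))
        keep = np.ones(s * s, dtype=bool)
        keep[rng.choice(s * s, size=n_drop, replace=False)] = False
        a, b = a[keep], b[keep]
    id_arr = np.asarray(ids, dtype=object)
    sga, sgb = id_arr[a], id_arr[b]
    cid = np.char.add(np.char.add(sga.astype(str), CONSTRUCT_SEP), sgb.astype(str))
    constructs = pd.DataFrame(
        {"sgrna_a": sga, "sgrna_b": sgb}, index=pd.Index(cid, name="construct_id")
    )

    lib = LibraryDesign(sgrnas, constructs)
    if n_ntc > 0 and not lib.is_ntc_construct().any():
        warnings.warn(
            "dropout removed every ntc-ntc construct; phenotype normalization "
            "will not be possible with this design",
            stacklevel=2,
        )
    return lib
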