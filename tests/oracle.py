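"""Brute-force reimplementation of the interaction scoring, used as an
independent oracle in tests.

Deliberately written in the most literal way possible: explicit loops over
queries and constructs, an explicit least-squares design matrix, dictionary
accumulation of pair measurements.  No code is shared with the package
implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_sgrna_scores(
    values: pd.DataFrame,
    singles: pd.DataFrame,
    library,
) -> pd.DataFrame:
    """sgRNA-level interaction scores computed from first principles.

    values : constructs x replicates phenotypes (NaN = excluded)
    singles : sgRNA x replicates single phenotypes
    Returns the symmetric sgRNA x sgRNA score matrix (replicate-averaged).
    """
    is_ntc = dict(library.sgrnas["is_ntc"])
    per_rep: list[dict[tuple[str, str], float]] = []
    for rep in values.columns:
        measurements: dict[tuple[str, str], list[float]] = {}
        for q in library.sgrna_ids:
            xs, ys, partners = [], [], []
            for cid, row in library.constructs.iterrows():
                a, b = row["sgrna_a"], row["sgrna_b"]
                if a != q and b != q:
                    continue
                partner = b if a == q else a
                x = singles.at[partner, rep]
                y = values.at[cid, rep]
                if np.isnan(x) or np.isnan(y):
                    continue
                xs.append(x)
                ys.append(y)
                partners.append(partner)
            if len(xs) < 3:
                continue
            x_arr = np.array(xs)
            y_arr = np.array(ys)
            deg = 2 if len(xs) >= 5 else 1
            design = np.vander(x_arr, deg + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(design, y_arr, rcond=None)
            fitted = design @ coef
            resid = y_arr - fitted
            ntc_resid = [r for r, p in zip(resid, partners) if is_ntc[p]]
            if len(ntc_resid) < 2:
                continue
            sd = np.std(ntc_resid, ddof=1)
            if sd <= 0:
                continue
            for r, p in zip(resid, partners):
                key = tuple(sorted((q, p)))
                measurements.setdefault(key, []).append(r / sd)
        per_rep.append({k: float(np.mean(v)) for k, v in measurements.items()})

    keys = sorted({k for d in per_rep for k in d})
    ids = library.sgrna_ids
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    for k in keys:
        vals = [d[k] for d in per_rep if k in d]
        out.at[k[0], k[1]] = out.at[k[1], k[0]] = float(np.mean(vals))
    return out


def brute_force_gene_scores(
    sgrna_scores: pd.DataFrame, library
) -> pd.DataFrame:
    """Gene-level aggregation by explicit enumeration of sgRNA pairs."""
    gene_of = dict(library.gene_of)
    labels = list(dict.fromkeys(gene_of[s] for s in sgrna_scores.index))
    acc: dict[tuple[str, str], list[float]] = {}
    ids = list(sgrna_scores.index)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            v = sgrna_scores.at[a, b]
            if np.isnan(v):
                continue
            key = tuple(sorted((gene_of[a], gene_of[b])))
            acc.setdefault(key, []).append(float(v))
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (ga, gb), vals in acc.items():
        out.at[ga, gb] = out.at[gb, ga] = float(np.mean(vals))
    return out
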