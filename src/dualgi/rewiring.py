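"""Differential genetic interactions (dGIs) between two gene-level maps.

A dGI is the elementwise difference of an environmental map and a reference
map (eGI - GI) per gene pair; pairs masked in either map stay masked.  High-
confidence dGIs must exceed ``n_sd`` (default 5) standard deviations of the
gene-ntc dGI control distribution *and* reach significance in at least one of
the two original maps — the exclusion rule that removes large differences
between two sub-threshold scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gi import GIMatrix


@dataclass
class DGIMatrix:
    """Elementwise difference of an environmental and a reference GIMatrix."""

    scores: pd.DataFrame  # full symmetric difference (targeting + ntc labels)
    is_ntc: pd.Series
    env_condition: str
    ref_condition: str
    calls: pd.DataFrame | None = field(default=None, repr=False)

    def _ntc_mask(self) -> np.ndarray:
        return self.is_ntc.reindex(self.scores.index).to_numpy(dtype=bool)

    @property
    def targeting(self) -> pd.Index:
        return self.scores.index[~self._ntc_mask()]

    @property
    def interaction_scores(self) -> pd.DataFrame:
        t = self.targeting
        return self.scores.loc[t, t]

    @property
    def control_scores(self) -> pd.Series:
        """Gene-ntc dGI values: the matched difference of gene-ntc scores."""
        ntc = self.scores.index[self._ntc_mask()]
        s = self.scores.loc[self.targeting, ntc].stack(future_stack=True).dropna()
        s.index.names = ["entity", "ntc"]
        return s

    def pairs_long(self) -> pd.DataFrame:
        t = list(self.targeting)
        m = self.scores.loc[t, t].to_numpy()
        iu, ju = np.triu_indices(len(t), k=1)
        df = pd.DataFrame(
            {
                "entity_a": np.asarray(t, dtype=object)[iu],
                "entity_b": np.asarray(t, dtype=object)[ju],
                "dgi": m[iu, ju],
            }
        )
        return df.dropna(subset=["dgi"]).reset_index(drop=True)


def compute_dgi(egi: GIMatrix, gi: GIMatrix) -> DGIMatrix:
    """Subtract the reference map from the environmental map.

    Both inputs must be gene level and share (at least part of) a gene
    universe; the difference is taken over the label intersection, and a pair
    masked in either map is masked (NaN) in the output.
    """
    for m, name in ((egi, "environmental"), (gi, "reference")):
        if m.level != "gene":
            raise ValueError(f"{name} map must be gene level")
    common = egi.scores.index.intersection(gi.scores.index)
    if len(common.difference(egi.ntc_labels)) == 0:
        raise ValueError("gene universes of the two maps are disjoint")
    diff = egi.scores.loc[common, common] - gi.scores.loc[common, common]
    return DGIMatrix(
        scores=diff,
        is_ntc=egi.is_ntc.reindex(common),
        env_condition=egi.condition,
        ref_condition=gi.condition,
    )


def call_high_confidence_dgi(
    d: DGIMatrix,
    egi_calls: pd.DataFrame,
    gi_calls: pd.DataFrame,
    n_sd: float = 5.0,
) -> pd.DataFrame:
    """High-confidence dGI calls with the original-significance exclusion.

    ``egi_calls`` / ``gi_calls`` come from :func:`dualgi.gi.call_high_confidence`
    on the two original maps (at their own thresholds).  A pair is a dGI iff
    ``|dGI|`` strictly exceeds ``n_sd * sd(control dGIs)`` and the pair was
    significant in at least one original map.  The calls table is also stored
    on ``d.calls``.
    """
    ctrl = d.control_scores
    if ctrl.empty:
        raise ValueError("dGI matrix has no control values; cannot set a threshold")
    threshold = n_sd * float(ctrl.std(ddof=1))
    calls = d.pairs_long()

    def sig_lookup(orig: pd.DataFrame) -> set[tuple[str, str]]:
        sig = orig[orig["significant"]]
        return {
            tuple(sorted(p)) for p in zip(sig["entity_a"], sig["entity_b"])
        }

    sig_any = sig_lookup(egi_calls) | sig_lookup(gi_calls)
    keys = [tuple(sorted(p)) for p in zip(calls["entity_a"], calls["entity_b"])]
    calls["exceeds_threshold"] = calls["dgi"].abs() > threshold
    calls["supported_by_original"] = [k in sig_any for k in keys]
    calls["significant"] = calls["exceeds_threshold"] & calls["supported_by_original"]
    calls["sign"] = np.where(calls["dgi"] > 0, "gained_positive", "gained_negative")
    calls.attrs["threshold"] = threshold
    calls.attrs["n_sd"] = n_sd
    d.calls = calls
    return calls


def unmatched_reference_check(
    dgi_matched: DGIMatrix,
    dgi_unmatched: DGIMatrix,
    n_sd: float = 5.0,
) -> dict[str, float]:
    """Robustness check: correlate dGIs computed against two references.

    Returns the Pearson correlation over all shared gene pairs and over the
    union of pairs significant in either dGI set (from their stored calls if
    present, otherwise by the ``n_sd`` control threshold alone).
    """
    a = _pair_series(dgi_matched)
    b = _pair_series(dgi_unmatched)
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("fewer than two shared gene pairs between the dGI sets")
    r_all = float(stats.pearsonr(a.loc[common], b.loc[common]).statistic)

    sig = _significant_pairs(dgi_matched, n_sd) | _significant_pairs(dgi_unmatched, n_sd)
    sig_idx = [p for p in common if p in sig]
    r_sig = float("nan")
    if len(sig_idx) >= 2:
        r_sig = float(stats.pearsonr(a.loc[sig_idx], b.loc[sig_idx]).statistic)
    return {
        "r_all_pairs": r_all,
        "r_significant_pairs": r_sig,
        "n_all_pairs": len(common),
        "n_significant_pairs": len(sig_idx),
    }


def _pair_series(d: DGIMatrix) -> pd.Series:
    long = d.pairs_long()
    idx = pd.Index(
        [tuple(sorted(p)) for p in zip(long["entity_a"], long["entity_b"])]
    )
    return pd.Series(long["dgi"].to_numpy(), index=idx)


def _significant_pairs(d: DGIMatrix, n_sd: float) -> set[tuple[str, str]]:
    if d.calls is not None:
        sig = d.calls[d.calls["significant"]]
    else:
        threshold = n_sd * float(d.control_scores.std(ddof=1))
        long = d.pairs_long()
        sig = long[long["dgi"].abs() > threshold]
    return {tuple(sorted(p)) for p in zip(sig["entity_a"], sig["entity_b"])}


def dgi_long_table(
    d: DGIMatrix, egi: GIMatrix, gi: GIMatrix, egi_calls=None, gi_calls=None
) -> pd.DataFrame:
    """Combined long-format export: (pair, gi, egi, dgi, significance flags)."""
    out = d.pairs_long().rename(columns={"entity_a": "gene_a", "entity_b": "gene_b"})
    eg = egi.scores
    g = gi.scores
    out["egi"] = [eg.at[a, b] for a, b in zip(out["gene_a"], out["gene_b"])]
    out["gi"] = [g.at[a, b] for a, b in zip(out["gene_a"], out["gene_b"])]

    def flag(calls):
        if calls is None:
            return pd.Series(False, index=out.index)
        sig = {
            tuple(sorted(p))
            for p in zip(
                calls.loc[calls["significant"], "entity_a"],
                calls.loc[calls["significant"], "entity_b"],
            )
        }
        return pd.Series(
            [tuple(sorted(p)) in sig for p in zip(out["gene_a"], out["gene_b"])],
            index=out.index,
        )

    out["egi_significant"] = flag(egi_calls)
    out["gi_significant"] = flag(gi_calls)
    if d.calls is not None:
        dsig = {
            tuple(sorted(p))
            for p in zip(
                d.calls.loc[d.calls["significant"], "entity_a"],
                d.calls.loc[d.calls["significant"], "entity_b"],
            )
        }
        out["dgi_significant"] = [
            tuple(sorted(p)) in dsig for p in zip(out["gene_a"], out["gene_b"])
        ]
    return out
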