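"""Shared fixtures: small simulated screens used across the suite.

All screens are generated at import-time-fixed seeds so every test run sees
identical data; the heavier fitted screens are session-scoped.
"""

from __future__ import annotations

import warnings

import pytest

import dualgi as dg

import matplotlib

matplotlib.use("Agg")


@pytest.fixture(scope="session")
def small_library() -> dg.LibraryDesign:
    """20 genes x 2 sgRNAs + 5 ntc -> 45 sgRNAs, 2025 constructs."""
    return dg.make_library([f"G{i:02d}" for i in range(1, 21)], 2, 5)


@pytest.fixture(scope="session")
def null_screen(small_library):
    """Two untreated-like arms, no interactions, no drug effects: the null
    calibration screen (20 genes, 5 ntc, depth 2e6, 2 replicates)."""
    lib = small_library
    doublings = dg.default_doublings(["refA", "refB"], 2, 8.0, 8.0)
    truth = dg.simulate_truth(
        lib,
        effect_sd=0.1,
        frac_interacting=0.0,
        conditions=("refA", "refB"),
        doublings=doublings,
        seed=11,
        drug_effect_sd=0.0,
    )
    counts = dg.simulate_counts(lib, truth, depth=2_000_000, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = dg.GIScreen(counts, lib, truth.doublings).fit()
    return truth, counts, results


@pytest.fixture(scope="session")
def planted_screen():
    """30 genes x 2 sgRNAs + 8 ntc with planted interactions, half rewired
    in the treated arm (depth 2e6, d=8 both arms)."""
    lib = dg.make_library([f"G{i:02d}" for i in range(1, 31)], 2, 8)
    doublings = dg.default_doublings(["reference", "treated"], 2, 8.0, 8.0)
    truth = dg.simulate_truth(
        lib,
        effect_sd=0.1,
        frac_interacting=0.1,
        gi_effect_sd=0.3,
        conditions=("reference", "treated"),
        rewiring_frac=0.5,
        doublings=doublings,
        seed=1,
    )
    counts = dg.simulate_counts(lib, truth, depth=2_000_000, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = dg.GIScreen(counts, lib, truth.doublings).fit()
    return lib, truth, counts, results


@pytest.fixture(scope="session")
def drug_screen():
    """Small screen with a treated arm growing slower than the untreated one
    (d_u=8 vs d_t=5), so rho is defined; one gene gets a strong protective
    drug modifier for hit-calling tests."""
    lib = dg.make_library([f"G{i:02d}" for i in range(1, 13)], 2, 13)
    doublings = dg.default_doublings(["untreated", "drug"], 2, 8.0, 5.0)
    truth = dg.simulate_truth(
        lib,
        effect_sd=0.05,
        frac_interacting=0.0,
        conditions=("untreated", "drug"),
        doublings=doublings,
        seed=21,
        drug_effect_sd=0.02,
        drug_modifiers={"G03": -0.5},
    )
    counts = dg.simulate_counts(lib, truth, depth=1_000_000, seed=22)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cp = dg.compute_construct_phenotypes(counts, lib, truth.doublings)
        singles = dg.single_sgrna_phenotypes(cp, lib)
    return lib, truth, cp, singles
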