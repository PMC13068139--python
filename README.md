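# dualgi

Genetic-interaction (GI) mapping and condition-specific rewiring analysis
for pooled dual-sgRNA CRISPRi screens.

## The problem

A dual-guide CRISPRi screen knocks down every pair of genes in a focused
library and reads out fitness by deep sequencing of the construct cassettes
before and after a growth period. Two genes *interact* when the double
perturbation's phenotype deviates from the expectation set by the two single
perturbations — more deleterious than expected (synthetic sick/lethal,
negative score) or less (buffering/epistatic, positive score). Running the
same library under an environmental perturbation (a drug, nutrient
deprivation) yields an environmental GI map (eGI), and the per-pair
difference eGI − GI (a *differential* GI, dGI) quantifies how the genetic
network is rewired by that environment — a gene-by-gene-by-environment
interaction.

`dualgi` implements the full analysis stack for such screens, plus a
simulator that generates read counts with known single-gene effects and
planted, condition-specific interactions, so every stage is testable against
ground truth.

## The method

**Phenotypes.** For a construct with reads R and ntc-ntc (double
non-targeting control) median N, per-replicate growth phenotypes are log2
enrichments per cumulative population doubling d:

    gamma = log2[(R_F/N_F) / (R_0/N_0)] / d_u          (untreated arm)
    tau   = log2[(R_T/N_T) / (R_0/N_0)] / d_t          (treated arm)
    rho   = log2[(R_T/N_T) / (R_F/N_F)] / (d_u - d_t)  (drug-specific)

Counts are depth-normalized, sgRNAs with a median construct count below 35
in either cassette position are excluded per condition, and a pseudocount of
10 is added. Single-sgRNA phenotypes average each guide's pairings with all
ntc guides in both orientations (26 measurements per sgRNA with 13 ntc).

**Interaction scores.** For each query sgRNA, the expected pair phenotype is
a quadratic function of the partner's single phenotype (ordinary least
squares over all constructs containing the query). A construct's interaction
is its residual from the query model, z-normalized by the standard deviation
of the query's ntc-pair residuals. Scores average over both cassette
orientations and both query models (up to 4 measurements per sgRNA pair per
replicate), then over replicates; gene-level scores average all sgRNA-pair
scores. Calls exceed 4 SD of the gene-ntc control distribution; dGI calls
exceed 5 SD of the gene-ntc dGI distribution *and* must be significant in at
least one of the two original maps.

**Network structure.** Profiles are clustered by average linkage on the
Pearson distance (1 − r), with flat cuts at 0.55 (functional clusters) and
0.8 (system-level groupings). A consensus clustering SD-normalizes k maps
and concatenates them into an n × kn matrix before clustering the short
axis. Cluster-level ("ontology") matrices, their differentials, coordination
profiles, PPI-bin enrichment and iterative gene-set enrichment support
higher-level interpretation.

## Worked example

```python
import dualgi as dg

lib = dg.make_library([f"GENE{i:02d}" for i in range(1, 21)],
                      sgrnas_per_gene=2, n_ntc=5)
truth = dg.simulate_truth(
    lib, effect_sd=0.1, frac_interacting=0.1, gi_effect_sd=0.3,
    conditions=("reference", "treated"), rewiring_frac=0.5,
    doublings=dg.default_doublings(["reference", "treated"], 2, 8.0, 8.0),
    seed=1,
)
counts = dg.simulate_counts(lib, truth, depth=2_000_000, seed=2)

res = dg.GIScreen(counts, lib, truth.doublings).fit()
print(res.summary())
```

```
Dual-sgRNA GI screen fit
============================================================
sgRNAs: 45 (40 targeting, 5 ntc); constructs: 2025
replicates: R1, R2; reference arm: reference
------------------------------------------------------------
condition       channel     filtered  ctrl SD  pos   neg
reference       gamma       0         0.631    12    14
treated         tau:treated 0         0.674    13    15
------------------------------------------------------------
high-confidence threshold: |score| > 4 SD of the gene-ntc control distribution
```

The 20-gene library yields 45 sgRNAs and 45² = 2025 constructs; the fit
finds 26 and 28 high-confidence interactions in the two arms (the simulation
planted 19 interacting gene pairs, each contributing up to 8 constructs).
The differential map then isolates the planted rewiring:

```python
d = res.differential("treated")          # eGI - GI with 5-SD calls
print(int(d.calls["significant"].sum())) # -> 11 high-confidence dGIs
```

The strongest dGI (GENE03–GENE13, score −36.1) corresponds to a planted
interaction that flipped from +0.11 to −0.25 phenotype units per doubling
between the arms. Clustering and fidelity metrics hang off the same objects:

```python
model = dg.hierarchical_cluster(dg.correlation_distance(res.gene_gi["reference"]))
clusters = model.cut(0.55)
fid = dg.sgrna_fidelity(
    res.sgrna_gi["reference"].scores.loc[lib.targeting_sgrnas,
                                         lib.targeting_sgrnas],
    lib.gene_of,
)
```

A `dualgi` console command exposes the same pipeline
(`dualgi simulate`, `phenotype`, `score`, `dgi`, `cluster`).

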