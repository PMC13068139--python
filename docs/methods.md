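# Methods

This note documents the models, estimators, defaults and numerical choices
behind `dualgi`, and what the simulator does and does not emulate.

## Growth phenotype model

Each dual-sgRNA construct is assumed to grow exponentially with a fitness
expressed as a log2 enrichment per cumulative population doubling, measured
relative to the median of the double non-targeting (ntc-ntc) constructs:

- `gamma = log2[(R_F/N_F)/(R_0/N_0)] / d_u` for the untreated arm,
- `tau` analogously for a treated arm against the shared T0,
- `rho = log2[(R_T/N_T)/(R_F/N_F)] / (d_u - d_t)` for the drug-specific
  component. The denominator is the *difference* in cumulative doublings:
  rho is the enrichment between the two final arms per doubling of growth
  advantage, which is dimensionally consistent with gamma and tau and
  yields the exact identity `rho·(d_u - d_t) = tau·d_t - gamma·d_u`,
  asserted construct-by-construct in the tests. When the two arms happen to
  have equal doublings, rho is undefined and flagged rather than computed.

Processing order: depth normalization → coverage filter → pseudocount →
ratios.

- **Depth normalization.** Every sample's counts are rescaled to a common
  total (`target_depth`), by default the mean sample total. The ratio
  formulas are scale-free except through the pseudocount, so this choice
  only sets the pseudocount's relative weight. With a fixed explicit
  `target_depth`, gamma is exactly invariant to rescaling any sample; with
  the data-driven default the invariance is exact at pseudocount 0 and
  approximate otherwise. No data-driven target can be exactly invariant,
  because scaling one sample moves any symmetric function of the totals.
- **Coverage filter** (`min_median=35`): an sgRNA is excluded from a
  condition when the median raw count of its constructs in either cassette
  position falls below 35 in any sample of that condition (T0 samples count
  toward every condition). All constructs containing an excluded sgRNA are
  masked in that condition. rho masks the union of both arms' exclusions.
- **Pseudocount** (`10`): added to the depth-normalized counts of every
  construct, including the ntc-ntc constructs that form the normalizer, so
  all ratios are finite and the most depleted constructs shrink toward the
  null rather than diverging. The shrinkage is visible in the round-trip
  test: a construct depleted ~100-fold at 10M reads recovers its phenotype
  to ~0.05 per doubling rather than exactly.

Single-sgRNA phenotypes are the mean over the guide's ntc pairings in both
orientations (26 measurements per sgRNA with the canonical 13 ntc guides).
Nominating-screen hits are genes with `|mean rho| > 0.2` (strict) and a
two-sided Mann-Whitney p < 0.02 of the gene's sgRNA-level rho values
against the pooled ntc rho distribution; the gene's sgRNA values are pooled
across replicates.

## Interaction scoring

For each query sgRNA and replicate, the expected phenotype of a pair is a
quadratic OLS fit of pair phenotype against the partner's single phenotype
over all constructs containing the query (self-pair included once, with the
query's own single phenotype as the partner value). Fewer than 5 usable
partners degrade the fit to a line; fewer than 3 exclude the query. The fit
is unweighted.

A construct's score under a query is its residual divided by the standard
deviation (ddof=1) of the query's residuals over its ntc-paired constructs.
Using the *residual* spread — rather than the raw phenotype spread of the
query-ntc population — makes the null distribution centered by
construction; queries with fewer than 2 ntc residuals, or a degenerate
spread, are excluded.

Averaging order: per replicate, all measurements of an unordered sgRNA pair
(two orientations × two query models, up to 4) are averaged; replicate
scores are averaged last, and pairs observed in only one replicate keep the
surviving replicate's value (`n_obs` records multiplicity). This makes the
score matrix exactly symmetric. Gene-level scores are the unweighted mean of
the gene pair's sgRNA-pair scores; ntc sgRNAs are carried through as size-1
pseudo-genes, so the gene-ntc control distribution is produced by the same
code path. Control distributions exclude ntc-ntc pairs.

Reference arms are scored on the gamma channel, treated arms on tau; rho is
reserved for nominating-screen hit calling.

**Thresholds.** High-confidence interactions strictly exceed 4 standard
deviations of the gene-ntc control scores. Differential interactions
(eGI − GI over the intersection of unfiltered pairs; masked pairs stay
masked) strictly exceed 5 SD of the gene-ntc dGI distribution — the matched
difference of the two maps' gene-ntc scores — and must additionally be
significant in at least one of the original maps. The strict inequality at
the boundary is a documented convention. No multiple-testing correction is
applied; the SD thresholds *are* the error control.

## Clustering

Profile distance is 1 − Pearson correlation between two entities' score
rows, with both entities' own columns excluded from both vectors (those
cells hold self/control signal, not profile signal) and masked cells imputed
as 0 — the null value on the z scale — for clustering only. Zero-variance
profiles are excluded with a warning. Agglomeration is average linkage
(scipy), whose merge heights are monotone and whose ordering is
deterministic for fixed input; flat cuts at Pearson distance 0.55
(functional clusters) and 0.8 (system groupings) use the cophenetic
criterion, so cuts at tighter thresholds always refine looser ones. Cluster
ids are renumbered by order of appearance for run-to-run stability.

Consensus clustering divides each map by the SD of its off-diagonal scores,
concatenates the k normalized maps into an n × kn matrix and clusters the
short axis, excluding each entity's self columns in every block. The
resulting tree is a universal ordering applicable to each individual map.
The construction is invariant to map order and to duplicating a map.

sgRNA-level clustering fidelity compares Pearson correlations of same-gene
sgRNA profile pairs against a random matched sample of different-gene pairs
(seeded), reporting both distributions and their medians.

## Ontology-level analysis

Cluster-by-cluster matrices average all distinct-gene pairs within/between
clusters, omitting masked cells; for singleton clusters the diagonal falls
back to the gene's own diagonal entry so that all-singleton compression is
exactly the identity. Differential ontology matrices label an inter-cluster
edge *gained* when only the environmental magnitude exceeds the supplied
threshold and *lost* in the converse case. Coordination profiles correlate a
query cluster's ontology-level profile with every other cluster per
condition, excluding both clusters' cells.

PPI enrichment bins unique unordered gene pairs by absolute score (10
quantile bins by default; equal-width optional), scores each bin by its mean
PPI escore (absent pairs count 0) over the global mean, and runs a
chi-square on interacting/not-interacting counts per bin, merging adjacent
bins until expected counts reach 5. Gene-set enrichment is a local
hypergeometric upper-tail test with Benjamini-Hochberg adjustment across
sets, applied iteratively: the top term's genes are removed from the hit
list between rounds (10 rounds by default), so reported terms are pairwise
disjoint; terms are flagged significant at −log10 adjusted p ≥ 6. This
replaces a web-service wrapper with a statistically equivalent,
self-contained implementation.

## Simulator

The generator inverts the gamma model exactly: construct abundance grows as
`a0 · 2^(phenotype · d)` where the phenotype is the sum of the two guides'
single effects plus any planted gene-pair interaction for that condition,
and each sample is a multinomial draw of exactly `depth` reads. Because ntc
phenotypes are exactly 0, the estimator's correctness is a matter of
algebra, testable by round-trip.

Defaults and what they emulate:

- `effect_sd = 0.1` per-doubling gene effects, with sgRNA-level scatter of
  20% of `effect_sd` around the gene mean — same-gene guides correlate
  strongly but not perfectly.
- `frac_interacting = 0.1` of gene pairs receive an interaction drawn
  Normal(0, `gi_effect_sd = 0.3`); an optional fixed-magnitude mode
  (`gi_magnitude`) plants constant-strength interactions with random signs.
  Interactions act at gene level and are inherited by all four sgRNA pairs
  (eight ordered constructs) of the pair.
- `rewiring_frac` of the planted interactions are redrawn independently in
  each non-reference condition; these are the planted differential
  interactions. Treated-arm singles are gamma plus a per-gene drug modifier
  (SD defaulting to half of `effect_sd`), so rho is meaningfully nonzero.
- Initial abundances are lognormal with `abundance_sd_log = 0.8` (natural
  log), putting roughly 90% of constructs within a 16-fold abundance range —
  a realistic cloning dispersion.
- `make_library` builds every ordered sgRNA pair including self-pairs
  (S² constructs for S guides) with optional uniform dropout emulating
  cloning attrition.

Not modeled: sequencing error, cassette recombination between positions,
transduction MOI and selection dynamics, UMI collapse, or read mapping —
the simulator starts at the counts table.

Simulation sizes used in the tests and the acceptance script (20–30 genes ×
2 sgRNAs, 5–13 ntc, depth 2×10⁶, two replicates, 8 population doublings)
were chosen as the smallest screens at which the pipeline's calibration and
recovery behavior is stable; the published-scale combinatorics (639 guides,
408,321 constructs) are exercised for the library stage, where they are
cheap. For differential-map simulations both arms use matched doublings:
the per-query z scale is inversely proportional to the phenotype noise,
which depends on the doubling number, so unequal doublings would make
conserved interactions cancel imperfectly in the subtraction — a scale
effect that per-map SD thresholds absorb but that would blur the
rewired-vs-conserved comparison the simulations are designed to probe.

What passing tests show — and do not show — about real data: the suite
demonstrates internal correctness (estimator algebra, oracle equivalence,
exact symmetries), calibration of the SD thresholds under the generator's
null, and recovery of planted effects under the generator's noise model.
Real screens add overdispersion, guide-specific efficacy differences,
chromatin-dependent CRISPRi activity and batch structure that the
multinomial/lognormal model does not capture; threshold calibration on real
data rests on the empirical gene-ntc distributions, not on these
simulations.

## Numerical choices

- OLS fits use `numpy.polynomial.polyfit`; the in-test oracle uses an
  explicit Vandermonde design with `lstsq` — agreement to 1e-9 is asserted.
- Standard deviations of control distributions use ddof=1 throughout.
- Score-level replicate averaging (rather than phenotype-level pooling) was
  chosen so replicate concordance of scores is measurable; pairs missing in
  one replicate keep the other's score.
- Boundary convention: all significance inequalities are strict.
- Ties in agglomeration follow scipy's deterministic merge order.
- The gene-ntc control SD at gene level averages fewer measurements per
  entry than gene-gene scores (2 vs up to 4 sgRNA pairs), making the
  threshold slightly conservative; the null false-call rate measured in the
  acceptance script reflects this.
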