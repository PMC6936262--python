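# Methods

## The plasticity score

For gene *g* with log2 fold changes *FC*<sub>*g,c*</sub> across conditions
*c*, the score is `GEP(g) = log2(mean_c FC²)` over the gene's non-missing
conditions. Squaring makes the score direction-free (up- and down-regulation
count equally); averaging pools evidence across conditions; the final log2
corrects the strong right skew of mean squared fold changes. The score is
invariant to condition order and to sign flips of individual fold changes.

Conventions and edge cases:

- **Log base.** Base 2 throughout, including the expression-broadness
  threshold on log(TPM+1) (the literature often leaves the base unstated;
  at the 0.1 cutoff the choice is immaterial for typical TPM values but is
  fixed here for reproducibility).
- **Missing data.** Fold changes may be missing; a gene is scored over its
  observed conditions only and must have at least `min_conditions` of them
  — default `max(10, 25% of conditions)`, capped at the matrix width so
  small studies remain scoreable. Dropped genes are counted and reported.
- **Undefined scores.** A gene whose observed fold changes are all exactly
  zero has log2(0) undefined; it is excluded (with a reported count) rather
  than floored with an arbitrary epsilon, which would place a fake value at
  a data-dependent rank.
- **Percentile normalization.** `(average rank − 0.5) / n × 100` with
  average ranks for ties: symmetric (mean 50), order preserving, and
  tie-stable.
- **Operon genes.** Polycistronic genes share a promoter, so comparing
  their plasticity is not meaningful; the fold-change reader accepts a
  blacklist applied at read time.

### Null, stability, and cell-specific scores

The randomized null shuffles the gene labels of each condition column
independently (each condition's value multiset is preserved exactly) and
rescores. The stability curve subsamples *n* conditions without
replacement, rescores, and Pearson-correlates with the full-data score;
at the full condition set r = 1 identically. Per-cell-group scores reuse
the same machinery on metadata-defined condition subsets, compared by
Spearman correlation over genes scored in every group. All resampling takes
an explicit seed.

The plasticity variant for baseline (normal-condition) expression builds
fold changes as `log2((TPM + 1) / row mean (TPM + 1))` — the pseudo-count
handles zero expression — and feeds them to the same scorer.

## Property profiling

Gene-set contrasts use the two-sided Mann–Whitney U against all other
scored genes. Orthologue conservation uses Spearman correlation over
one-to-one pairs only (ids appearing more than once per species are
dropped by the reader). Ontology profiles propagate each gene's annotations
to all ancestor terms (the ontology must be acyclic) and retain terms with
20–500 propagated genes — below 20 the term mean is noisy, above 500 the
term is uninformatively broad; the cross-species term correlation joins on
terms retained in both species. Disease-burden binning sorts genes by score
ascending into consecutive bins (default 100 genes; a final partial bin is
kept and flagged rather than silently dropped) and reports the per-bin mean
burden plus a Spearman trend over bin indices. Gene-set enrichment is a
hypergeometric upper tail with BH correction across the collections tested;
the default "high-plasticity" foreground is the top 10% of the ranking.

## Motif analysis

**Scanning.** Motif hits use the log2 likelihood-ratio score
`Σ log2(p_pos,base / bg_base)` with a 1e-4 probability floor on zero matrix
entries (avoids −∞). The null score distribution of a background k-mer is
computed exactly by dynamic programming after quantizing per-position
scores to 1/1000 bit; a placement is a hit when the tail probability of its
score is below `match_p` (default 1e-4, the FIMO-style criterion) on either
strand. Default window: −200..+100 around the TSS (−99..0 for TATA-style
scans). Windows are clamped at sequence ends with a warning; genes with
more than 10% non-ACGT bases are skipped. The scanner is checked against
exhaustive enumeration of all k-mers for small motifs.

**Association screen.** Per motif, a two-sided Mann–Whitney between genes
with and without the motif, direction by median difference, BH across all
motifs in one screen invocation (the correction family is one species'
screen); significant iff q < 0.01. Features with fewer than 20 genes on
either side are reported untested rather than forced through an unpowered
test. Multi-sample responses (e.g. expression level across samples) switch
to the consistency rule below.

**Class collapsing.** Significant motifs in the same cluster merge;
clusters from different taxonomic groups sharing a motif id merge
transitively (union–find with deterministic smallest-id roots). A class's
per-species direction is the common sign of its members, else
"inconsistent". Gene-level class presence is the OR over member motifs.
Merging happens only through provided cluster tables; no quantitative
matrix-similarity threshold is invented.

**Stepwise AIC.** Gaussian linear model of the score on class indicators,
`AIC = n ln(RSS/n) + 2(k+1)`, bidirectional search from the full model
(one best add-or-drop move per iteration, deterministic id-order
tie-break). Note the textbook property that AIC retains a truly null
predictor with probability P(χ²₁ > 2) ≈ 16%; the tests assert at this
calibrated level.

**Interaction typing.** With strata neither / only-1 / only-2 / both
(each ≥ 20 genes), B = median(neither) and e_i = median(only-i) − B, the
expected joint location is B + e1 + e2. Additivity is tested on the median
interaction contrast `med(both) − med(only1) − med(only2) + med(neither)`
with a studentized bootstrap (200 resamples per stratum, seeded): this is a
deliberate design choice over a location-shift rank test of the both
stratum against `neither + (e1+e2)`, because treating the estimated e1+e2
as exact ignores three medians' sampling error and misclassifies a large
fraction of genuinely additive pairs. Calls: **additive** if the contrast
is indistinguishable from zero (p ≥ 0.05); **enhancement** if a
same-direction pair overshoots e1+e2 significantly in the same direction;
**dominance of i** if an opposite-direction pair's both stratum is
indistinguishable from only-i (Mann–Whitney p ≥ 0.05) yet distinguishable
from only-j; otherwise **undetermined**. These decision rules are a
reconstruction from the published prose — the original supplementary rule
table is not available — and are stated here prominently as such.

**Co-occurrence.** Per unordered pair of directed classes, a 2×2 Fisher
exact test of joint presence (enriched/depleted at p < 0.05 by odds-ratio
side), then Fisher comparisons of enriched:depleted counts between
same-direction and opposite-direction pairs and of each against all pairs;
degenerate margins are reported undetermined rather than tested.

## Binding and histone screens

Peaks (BED, optionally pre-filtered to peak p < 1e-4) are assigned to genes
through per-chromosome interval trees: promoter windows are strand-aware
(default −500..+500 of the TSS; for minus-strand genes the TSS is the
interval end), gene bodies span TSS–TES, and one base pair of overlap
suffices. A factor or mark passes the consistency screen iff it was assayed
in ≥ 4 samples and is BH-significant with the majority direction in ≥ 80%
of them ("at least 80%" and "more than three" are read as ≥ 0.8 and ≥ 4;
both configurable). A supporting sample must be both significant and
majority-direction — the published criteria list the clauses separately
without stating their per-sample combination, so this conjunction is a
documented reconstruction. The BH family is all factor × sample tests in
one screen invocation.

The loop-anchor analysis labels promoters as anchor / loop-interior /
outside, compares plasticity between anchor and loop genes, and re-runs the
bound-vs-unbound test using only peaks outside loop spans. The default
anchor-vs-loop comparison is an unpaired Mann–Whitney; a signed-rank
variant (rank-order pairing) is selectable, since the published analysis
cites a signed-rank test without describing a pairing scheme. The
mark-combination test stratifies marked genes by the number of distinct
gene-body marks and compares strata pairwise with BH.

## Perturbation validation

Probe matrices collapse to genes by discarding multi-gene probes and
averaging same-gene probes. The eligibility filter calls differential
expression per genotype between the two conditions (two-sample t, BH
q < 0.01; a simplified empirical-Bayes moderated t with pooled prior
variance and 4 prior df is selectable in the spirit of limma, which itself
is out of scope) and requires that more than 60% of the union of DE genes
be DE with the same sign in both genotypes. Genes whose replicate variance
is exactly zero are called DE iff their mean difference is nonzero. Note
that a strong genuine shrink (k ≪ 1) legitimately pulls mutant genes out
of the DE set and lowers the shared fraction: the filter is designed to
catch programme rewiring and is conservative under strong magnitude
effects.

The magnitude comparison computes |mean log2 expression difference| between
conditions per genotype, takes the top 20% of genes by magnitude within
each genotype (stable sort, gene-id tie-break; whether the original ranking
was control-only is unstated, so per-genotype ranking with an
intersection-based paired analysis is used), and reports: an unpaired
Mann–Whitney between the two top sets; on the co-directional intersection a
Wilcoxon signed-rank test, the lower:higher magnitude counts, a Fisher
exact test of that split against an equal split `[[⌈n/2⌉, ⌊n/2⌋]]`, and an
exact binomial alternative alongside. Swapping genotype labels inverts the
counts exactly (ties are excluded from both sides). The verdict requires
the median shift to match the expected direction with Fisher p < 0.001.

## Synthetic data

Each gene has a latent dispersion σ_g; its fold change per condition is
N(0, σ_g), so E[(log2FC)²] = σ_g² and the expected score is 2·log2 σ_g.
Regulatory effects are therefore planted as additive shifts on log2 σ_g:
motif effects δ_m at promoter occupancy 0.3, factor and mark association
shifts at target rate 0.3, gene-level noise N(0, 0.5), base log2 σ = 0.
Defaults encode the standard study conditions: five promoting (+0.5) and
three repressing (−0.5) motifs, one promoting and one repressing factor
(±0.5), two repressive marks (−0.5), and a loss-of-function shrink k = 0.5.
Enhancement is planted by scaling the pair sum (boost × (δ1+δ2) when both
present); dominance by overriding the loser's δ. Promoters are uniform
background with the motif consensus embedded at a random in-window position
on a random strand; binding samples flip each gene's target label
independently at the label-noise rate (0.5 = binding independent of truth);
perturbation experiments draw a control condition effect β_g ~ N(0, σ_g)
and give mutants k·β_g plus replicate noise (SD 0.1). All generators are
deterministic given their seed and regenerate byte-identical files.

What the generator does **not** emulate: heavy-tailed condition effects
(available behind the Normal default but not used in benchmarks), linkage
between neighbouring genes, platform/batch structure, probe-level noise,
realistic genome coordinates, or peak-width variation. Passing benchmarks
therefore demonstrate correctness and calibration of the statistics under
the stated generative model, not performance on real atlas/ENCODE-scale
data — the published headline numbers (species correlations, motif counts,
specific ratios) depend on those external datasets and are out of scope.

## Benchmark sizes and calibration notes

The acceptance benchmarks use: 50×20 matrices for the score oracle; 100
seeds of 100×30 exchangeable matrices for the null; 100 runs of 200 genes ×
300 conditions with 20 subsamples per grid point for stability; 100 seeds
of 1000 genes × 50 null motifs (type I) and 5000 genes with one +0.5 motif
at 30% occupancy (power); 50 seeds of 2000-gene, ~25%-strata interaction
simulations; 100 seeds of 10-sample consistency screens at 5% label noise;
60 seeds of 2000-gene perturbation experiments at k ∈ {0.5, 1}; and 200
random peaks × 100 genes for assignment fidelity — sizes chosen to keep
every Monte-Carlo estimate's standard error well below its acceptance
margin.

One structural point about the null benchmark: because the permutation null
preserves each condition's value multiset exactly, the observed and null
score samples share their underlying values, and the two-sample KS test
between them is conservative by construction (p-values concentrate near 1
under exchangeability). The meaningful calibration property — the null is
never spuriously rejected on exchangeable data — is what the benchmark
asserts and reports; a uniform KS p-value distribution is not attainable
in this design and should not be expected.

## Known limitations

- Interaction rules and the per-sample support conjunction are
  reconstructions (flagged above); alternative readings are configurable
  but not benchmarked.
- The PWM null quantizes scores at 1/1000 bit; hit/miss decisions for
  scores whose exact tail probability lies within quantization error of
  `match_p` can differ from the unquantized rule.
- The moderated t is a fixed-prior simplification, not an estimate of the
  prior df from the data.
- The stepwise search refits OLS per candidate move; it is intended for
  tens of motif classes, not thousands of features.
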