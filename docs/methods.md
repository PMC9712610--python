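# Methods

This note documents the models, parameter choices and numerical
contracts behind `macatlas`, and what the synthetic benchmark does and
does not establish about real data.

## Copy-number rulers

The proteomic ruler assumes the total mass of histones equals the mass
of DNA per cell. `RulerParams.dna_mass_per_cell` defaults to
5.5e-12 g, a diploid mouse genome; it is a plain configuration constant
(no genome parsing). Two signal models are exposed:
`mass_proportional` for raw MS intensity and `mole_proportional` for
iBAQ, the default, since iBAQ is proportional to molar amount. Both are
exactly invariant to a per-sample global rescaling of the signal — this
is asserted under random rescalings in the tests, not assumed. The two
modes agree exactly when intensity = iBAQ × peptide count with peptide
count proportional to molecular weight; on realistic data they agree
only approximately (log-log r > 0.9 on the benchmark atlas).

Theoretical peptide counting uses the canonical convention: fully
tryptic fragments, cleavage C-terminal to K/R but not before P (Keil
rule), zero missed cleavages, length 7–30. Only the length window is
method-defining; the Keil rule and zero missed cleavages are the
standard iBAQ digestion convention.

The RNA ruler takes the ribosome count as the **median** of detected
ribosomal-protein copies rather than a sum: the 1:1
protein-per-ribosome stoichiometry makes every paralog an independent
estimate, and the median is robust to paralog dropout. Constants:
rRNA molar mass per ribosome 2.2e6 g/mol, rRNA = 80% of total RNA
mass, mRNA = 4% of total RNA mass, mean mRNA molar mass
340 g/mol × 1800 nt. The mRNA mass fraction and mean length are
order-of-magnitude literature values and are explicitly overridable;
the parameterization is mass-based because "total RNA" is naturally a
mass in this calibration. Conservation (`Σ copies = N_mRNA`) holds
exactly by construction; absolute mRNA copies inherit the uncertainty
of these constants, while ranks do not.

## Concordance

Correlations between layers use replicate means ("average copy
numbers"); a per-replicate mode would only add exchangeable noise.
Gene-wise Spearman p-values for n ≤ 12 populations come from the exact
permutation null, computed once per n by dynamic programming over
subsets of assigned ranks (the distribution of Σd² over all n!
permutations; 2^n × max(Σd²) table, milliseconds at n = 12). Ties fall
back to the asymptotic approximation. At n = 12 the exact two-sided p
of r = 0.57 is 0.0556 — the conventional operating threshold
|r| > 0.57 therefore sits just above the 5% point, and the smallest
strictly significant value is ≈ 0.587.

Quadrant classification is total and deterministic: "high" means
≥ cutoff on both axes (the tie rule is stated because medians often
coincide with data points); genes never detected in the source layer
get mean expression −∞ and always classify as "low". Auto cutoffs are
the median mean-expression over the gene set and half the number of
samples.

## Co-expression modules

Unsigned adjacency `|cor|^β` on log10 copies. Correlations are Pearson
on pairwise-complete observations; genes detected in fewer than 25% of
samples are excluded from the network, and a correlation supported by
fewer than half of the samples (floor 8) is set to 0 — chance
correlations estimated on tiny overlaps approach ±1, and a power-12
adjacency amplifies them into spurious topological overlap that glues
unrelated genes to modules.

The soft threshold is chosen as the smallest power whose scale-free
fit R² (signed, negative-slope convention; log10 p(k) vs log10 k over
10 equal-width connectivity bins) reaches 0.85, otherwise the argmax
with a warning. Note that at extreme powers almost any correlation
structure drifts toward apparent scale-freeness, so the scan is most
informative over moderate powers.

Module detection: TOM similarity
`t_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`t_ii = 1`, average-linkage clustering on `1 − TOM`, and a **static**
cut at 0.995 × the tallest merge height; clusters below the minimum
size (30) fall into module 0. The static cut replaces the dynamic
hybrid tree cut: with a strong-module/flat-background structure the
background joins the tree just below height 1 while modules condense
far lower, so a single relative cut separates them; the quantile is
exposed for data without that separation. Eigengenes are the first
principal component of the module's row-standardized expression
(missing values imputed at the gene mean for the decomposition only),
sign-fixed to correlate positively with members. Module–trait
statistics use per-population indicator traits; each module is matched
to its argmax trait and dropped below moduleTraitCor 0.5; GS and MM are
absolute pairwise-complete Pearson correlations, filtered at
GS ≥ 0.6, MM ≥ 0.5.

## TF specificity and regulon activity

A TF is specific to a population when its replicate-mean expression
(detection in ≥ 2 replicates required) is at least 5× the median of
its expression over the **other** populations, with non-detections
entering the median as 0. Leave-one-out is the deliberate reading of
the specificity intent — comparing a population against a median that
includes itself dilutes the contrast at small P — and `include_self`
restores the alternative. Zero-vs-zero never calls; a positive focal
mean against an all-zero median calls at any fold. When module
statistics are supplied, the TF must additionally be a GS/MM-filtered
member of a module matched to that population.

CSPS is the relative entropy (bits) of fractional expression against
the uniform null, `Σ f log2(fP)` with 0·log 0 = 0, bounded by
[0, log2 P]. Values within 1e-12 of zero are snapped to exactly 0 so a
uniform vector scores 0 despite floating-point residue.

ctmTF calling scores each specific TF's regulon by the mean
population-level z-score (log10 of replicate-mean copies + 1, with
undetected populations as zero; genes with zero variance across
populations are dropped) and compares it against B = 1000 size-matched
draws **from all quantified proteins** (not TFs only), without
replacement, under a mandatory seed. The call criterion is
observed > max(null) — a max-of-B test whose per-test false-positive
rate is 1/(B+1) ≈ 1e-3; an empirical p is reported alongside. Whether
the z-score should run over populations or over all samples is
genuinely open; population-level is the contract here, matching the
replicate-mean convention used everywhere else.

## Crosstalk networks

Both 1.5× rules (tissue-specific ligands, cell-specific TFs) compare
the focal value against the arithmetic mean **including** the focal
tissue/population, with non-detections as 0; a leave-one-out flag is
provided. Pathway "intermediates" are operationalized as pathway
members minus the ligand tier; the enrichment universe N is the cell
matrix's gene space, draws n are the proteins detected in the focal
population (presence in ≥ 2 replicates), and the hypergeometric upper
tail is left uncorrected (a Benjamini–Hochberg variant is available but
off by default, since the gating on receptors and specific TFs already
constrains calls). Receptor "detection" likewise means presence in ≥ 2
replicates. Edges assemble tier-wise and the link count is the edge
count; by construction every node is reachable from a ligand.

## Differential expression, clustering, PCA

The t-test runs on log10 copies (variance stabilization across a
7-decade dynamic range) while the fold change is a ratio of linear
means; the scale convention is documented because results differ
slightly between scales. No multiple-testing correction enters the
call (the dual rule gates on fold change ≥ 5, which dominates the
error control); a BH-adjusted column is emitted for transparency.
Clustering and PCA operate on log10(x+1) with missing set to 0 — a
completeness requirement of distance computations, never applied to
testing. Presence/absence calls require detection in *all* replicates
of one group (CV ≤ 0.6) and none in the other.

## The synthetic atlas

Defaults are the benchmark conditions: 12 populations × 3 replicates,
2000 genes, 8 planted modules of 100 genes, 2 specific TFs per moduled
population with 20-gene regulons sampled from the home module, 10
histone and 30 ribosomal-protein genes, 8 tissues with 3 specific
ligands each, replicate noise σ(ln) = 0.2, per-sample MS scale scatter
0.2 decades.

Abundances are lognormal throughout (multiplicative biology; all
analyses operate in log space). Baseline protein copies are uniform in
log10 over [2, 9] — 7 decades; no per-population abundance law is
implied by the domain, and uniform-in-log is the maximally
noncommittal choice. mRNA log-copies are an affine compression of
protein log-copies (slope 5/7, so transcripts span 5 decades) shifted
by log10(8000) with 0.35 decades of gene-wise scatter, which pins the
mean protein/mRNA copy ratio at 8000. Planted entities (module genes,
TFs, ligands, receptors) are placed in the well-detected mid-range,
symmetric about the dynamic-range center so the copy-ratio statistic
stays unbiased. Histone copies are drawn under the exact constraint
Σ copies·MW = m_DNA·N_A, making the ruler invertible; ribosomal
proteins share one copy number (3e6, a typical mammalian ribosome
count's order of magnitude).

Detection is Bernoulli per value with logistic probability in log10
abundance, independent across replicates, so identification frequency
carries information. The protein midpoint (4.5) makes a population
detect roughly two thirds of the gene universe, matching the
identification depth typical of deep label-free profiles of sorted
primary cells; the RNA midpoint (−0.4) leaves transcripts below ~1
copy per cell partially undetected.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: peptide-level structure and shared-peptide
inference; correlated (batch-like) noise beyond the per-sample global
scale; regulon overlap between TFs; genes whose protein and mRNA are
decoupled (the two layers are tied through a single per-gene ratio, so
"missing transcripts with detected protein" are essentially absent from
fixtures and that branch of the concordance logic is exercised on
constructed toys); and real pathway topology (planted pathways are
membership sets).

Benchmark problem sizes were chosen so the full suite runs in well
under a minute of generator time and a few seconds of network algebra:
module recovery on 2000 genes × 36 samples, permutation nulls at
B = 1000, 200 simulated null regulons, a 2000-gene no-effect DEP
simulation. On this benchmark the pipeline achieves planted-module
ARI ≈ 0.92 with 100% of planted genes passing the GS/MM filter, exact
recovery of planted specific TFs, ctmTFs, tissue ligands and active
pathways, zero false ctmTF calls over 200 null regulons, and resident
pairs' crosstalk link counts strictly above recruited pairs' — each of
these is recomputed, not cited, by `tests/test_acceptance.py`.

## Known limitations

* The exact Spearman null covers untied data up to n = 12; ties and
  larger n use the asymptotic approximation.
* The static tree cut assumes modules separate from background below
  the top of the dendrogram; heavily nested module structure would
  need the quantile tuned or a dynamic cut.
* Distance-based operations (clustering, PCA) are sensitive to
  zero-filled missing values when detection is far from complete;
  population structure in sparse matrices is better assessed on
  replicate-mean or filtered gene sets.
* Absolute mRNA copy numbers scale linearly with the assumed mRNA mass
  fraction and mean transcript length; only ranks and ratios are
  calibration-free.
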