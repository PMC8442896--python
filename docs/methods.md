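# Methods

This package implements a pipeline for detecting sex chromosomes in a
radiation of closely related species from paired male/female genomes and
sexed replicate transcriptomes, and for reconstructing how those sex
chromosomes evolved along a time-calibrated phylogeny. This note documents
the statistical procedures, the parameters that matter, the synthetic-data
model used for validation, and the numerical choices made where the design
was genuinely open.

## Variant-level preparation

Genotypes arrive as VCF v4.2 with `GT`, `GQ` and `DP` FORMAT fields; a
sample panel TSV maps each individual to species, tribe and sex. Before any
scan:

1. **Indel-proximity masking.** SNPs within *w* bp of an indel are removed,
   with *w* = 2 for 1-bp indels, 3 for 3-bp, 5 for 4–5-bp and 10 for larger
   indels; the masked interval is `[pos − w, pos + span + w]` where `span`
   is the indel's reference-allele length. A 2-bp indel has no stated width
   in this size ladder; we interpolate to *w* = 3 so that widths are
   monotone in indel size. Indel records themselves are dropped. The
   operation is idempotent.
2. **Genotype masking.** Calls with `GQ` < 20 or `DP` < 4 become missing.
3. **Site retention.** Sites with more than 50% missing calls, more than
   two alleles, or no non-reference allele among retained calls are
   removed.
4. **Reference re-anchoring.** At sites where no retained individual
   carries the reference allele, the first alternative becomes the
   reference and genotypes are recoded. After this step every retained
   site has at least one reference-allele carrier.

The indel mask runs before genotype-level masking; the two filters commute
for SNP retention but the stated order fixes the missingness denominator.
Unplaced scaffolds are carried as an `UNPLACED` pseudo-chromosome and
excluded from per-LG calls. Phasing and imputation are not performed: the
scans operate on unphased genotypes, and the haplotype extraction step
derives phased X/Y haplotypes directly from the male-het/female-hom rule.

## WGS accumulation scan (A2)

Each site is classified per species from its designated male/female pair:
**XY** if the male is heterozygous and the female homozygous, **ZW**
mirrored, **noinfo** if either call is missing, and **nosex** otherwise.
The opposite-homozygote configuration (male and female homozygous for
different alleles) carries no heterogamety information and is scored nosex.
When a species contributes more than two genomes, the first-listed pair is
used for classification; the extras still enter the clustering step.

Class counts are summed over all species of a tribe in 10-kb windows
sliding by 2 kb (grid anchored at position 1; trailing partial windows kept
when they contain a site). Expected per-window counts are the genome-wide
mean class fractions — the mean over windows of per-window fractions among
called (non-noinfo) species-sites — multiplied by the window's called-site
count. Windows are designated XY when observed XY exceeds and observed ZW
falls below expectation (ZW mirrored), ambiguous when both exceed
(discarded), nosex otherwise.

Designated windows are tested with a 2×3 exact test (Freeman–Halton, an
in-package log-space enumeration over tables with the observed margins) of
observed vs rounded expected counts over {XY, ZW, nosex}; above 10,000
total counts the test falls back to Pearson's χ² on the same table.

**Permutation thresholds.** Within each tribe the per-species class labels
are shuffled over the fixed site positions 100 times; each permutation
re-runs the window pipeline and records the largest species-normalized
|XY−ZW| difference and the smallest window p-value. The largest difference
over permutations becomes the tribe's retention threshold. Permutation
p-values are computed with the vectorized χ² variant: the quantity the
pipeline consumes downstream is the difference threshold, while window
retention applies a fixed −log₁₀(p) > 20 cutoff to the observed windows'
exact-test p-values, so the permutation p is diagnostic only. This keeps a
full 100-permutation scan of a 10-species tribe under ~5 s.

Retained windows must beat both thresholds; windows overlapping the masked
regions (a protocadherin tandem-array region at 21.36–21.93 Mb of LG02
that attracts cross-mapping, all of repeat-rich LG03, and the unplaced
pseudo-LG) are dropped. Overlapping retained windows merge into regions;
region direction comes from the minimum-p window, ties broken toward the
larger |XY−ZW| difference.

**Species attribution.** Individual genotypes over region sites are
clustered with divisive hierarchical clustering (DIANA, implemented here:
the object with the greatest average dissimilarity seeds a splinter group
that attracts objects closer to it than to the remainder) on Gower
dissimilarities, which for all-categorical genotype vectors reduce to the
mismatch fraction over jointly called sites. A species joins a region's
call when its individuals separate by sex at the 2-cluster cut and its
within-region XY−ZW difference matches the region direction; species with
fewer than 10 informative region sites are flagged and not called. A call
is emitted only when at least two species of the tribe share the
signature.

## Association scan (A1)

Per biallelic SNP, a Cochran–Armitage trend test of genotype dosage
against sex (the score form, n·r², χ² with 1 df). A mixed-model
association with kinship correction would be the field-standard tool on
real cohorts; the synthetic cohorts carry no population structure, and the
decisive step of this route is the downstream genotype clustering, so the
trend test is used and documented as a simplification. Monomorphic sites
report p = 1; the statistic is invariant under ref/alt relabeling.

Selected SNPs are either the top-k (k = 100) most associated (broad
signals) or all SNPs with −log₁₀(p) > 3 (narrow peaks). Because selection
at these cohort sizes carries scattered false positives, genotype
inspection is focused on the associated region: only SNPs on LGs holding
at least 25% of the selection are clustered (mirroring inspection of the
sex-associated regions rather than of isolated SNPs; this also retains
multi-LG fusion signals). Individuals are clustered with the same
Gower/DIANA engine; a species is called XY when the fraction of selected
SNPs at which its male is heterozygous and its female homozygous exceeds
0.8 (configurable; ZW mirrored) and its individuals separate by sex.

## Transcriptome scan (A3)

Input is a per-SNP allele read-count table over typically 3 male and 3
female replicates. SNPs on mitochondrial or unplaced sequence are removed.
Per SNP, a two-sided Fisher exact test on sex-pooled ref/alt counts stands
in for a replicate-aware differential test — the decisive filters are the
downstream zero-count rules — and Benjamini–Hochberg adjustment retains
SNPs at adjusted p ≤ 0.05. A SNP is **XY** when its variant allele has
zero reads in every female and at least one read in at least two males
(ZW mirrored).

XY−ZW differences are accumulated in 10-kb nonoverlapping windows. The
Tukey outlier rule (diff > Q3 + 1.5·IQR) runs over all windows holding at
least one retained SNP — classified or not — so the genome-wide landscape
of expressed, test-passing variation anchors the threshold. The mirrored
low tail (diff < Q1 − 1.5·IQR) flags ZW-dominated windows so
female-heterogametic systems are detectable symmetrically; `one_sided=True`
restores the literal high-tail-only rule. Quantiles use linear
interpolation (type 7).

Heterogamety is decided over outlier windows (at least 3 required) by a
paired two-sided Wilcoxon signed-rank test of per-window XY vs ZW counts;
a significant result (p < 0.05) assigns the system to the side with the
larger total. Candidate LGs are those whose length-normalized count of
system-matching SNPs in outlier windows exceeds both Q3 + 3·IQR of the
per-LG distribution and the mean + 1 SD ("higher than the standard
deviation" is read as mean + 1·SD, since comparing a count to an SD alone
is units-inconsistent; a literal mode is available). An empty candidate
set reports the system with the LG unassigned. The LG-level outlier rule
needs a realistic number of LGs (~20+) to be meaningful; with very few
LGs the quantile cutoffs degenerate.

## Call integration

Per-approach calls merge into a **permissive** set (everything, with
conflicts resolved: same LG merges evidence; different LGs with one
heterogamety form a fusion-compatible multi-LG call; contradictory
heterogamety is flagged, resolving toward the A3-supported system) and a
**stringent** set that removes calls whose only evidence is the WGS
accumulation scan, prunes A2-only LGs from multi-LG calls, and drops
heterogamety-conflicted species. Literature-known systems can be injected
with evidence tag `literature`. The stringent set is always a subset of
the permissive set at the species level.

## Phylogenetic reconstruction

States (recruited LGs, or heterogamety) are coded as a tips × states
probability matrix; species without information receive the uniform row.
Mk models with equal (ER), symmetric (SYM) or all-different (ARD) rates
are fitted by maximum likelihood: Felsenstein pruning with soft tip priors
and L-BFGS-B on log-rates, with each richer model initialized from the
simpler fit (guaranteeing the nested log-likelihood ordering) and minimum
AIC selecting the model; AIC ties below 1e-6 go to the simpler model. The
root prior is uniform over states, consistent with the equal-probability
tip coding; a stationary-distribution option exists. The all-identical-tip
limit drives rates to the lower bound with log-likelihood → log(1/k)
(the uniform root prior's mass on the observed state).

**Stochastic maps.** Node states are drawn from conditional posteriors
(root from prior × partial likelihood, children conditional on parents);
branch histories are endpoint-conditioned CTMC paths sampled by
uniformization with Ω = 1.05·max|Qᵢᵢ| (jump count from the
Poisson-weighted power series of R = I + Q/Ω, jump chain by
forward-filtering/backward-sampling over powers of R, virtual jumps
discarded). Every component consumes a `numpy` Generator seeded from one
root seed, so runs are byte-reproducible.

**Turnovers.** Each LG is reconstructed as an independent binary
(yes/no) trait, accommodating tips in several states (fusions). The
along-branch posterior (fraction of maps in the state, on a 100-point
grid per branch, linearly interpolated) is walked root-ward from each tip
in the state; the first crossing below 0.5 is the turnover (gain) point.
Events on a shared branch are deduplicated; losses are not counted. A path
whose posterior never drops below 0.5 yields a single root-edge event
flagged `root_or_earlier` rather than being dropped, preserving gain
counts.

**Rates.** The turnover rate is events per lineage-million-years:
n_events divided by the total branch length of the tree. Under this
denominator one event is expected between two species that diverged
t = 1/(2·rate) ago (two lineages accumulate 2·rate·t events after their
split); a tree-height denominator is available as a config alternative.

**Heterogamety transitions** run the same machinery over {XY, ZW}
(optionally {XY, ZW, NonGSD}); each per-state gain point is labeled with
its origin state (the majority state at the rootward end of the event
branch), giving directed XY→ZW / ZW→XY counts, ages and a rate.
Literature-driven transitions can be injected. A cross-tabulation labels
each LG turnover heterogamety-preserving or -changing from the
heterogamety posterior on either side of the event point and lists
heterogamety changes unaccompanied by an LG change. Direction-wise ages
are compared with a two-sided Mann–Whitney U test (exact for small
samples; the test choice is ours, as only a p-value convention was
given).

**Recruitment randomization.** Each of 10,000 simulations drops n 10-kb
windows uniformly on the genome (LG probability ∝ length) and records the
containing LG; the reported quantity is the fraction of simulations with
at least the observed number of never-recruited LGs, plus the per-LG
recruitment distribution. The observed-never count is a user input (the
source analyses count it in two slightly different ways).

**pGLS.** Generalized least squares with Brownian-motion covariance
(C_ij = shared root-to-MRCA path length), closed-form GLS estimate and a
t-test on the slope. On a star phylogeny this reduces exactly to OLS,
which is the test oracle.

## Differentiation and haplotypes

The sex-differentiated region of a called species is sized on 10-kb
nonoverlapping windows: a window on a called LG qualifies when its count
of system-matching sex-specific SNPs strictly exceeds twice the mean over
all genome windows (empty windows included in the mean — the count-based
reading, not a per-bp rate). Qualifying windows give the cumulative
length, coordinate range and proportion of the LG; differentiation is
related to system age (the turnover point) by pGLS.

X/Y haplotypes are extracted at sites XY-classified in at least one focal
species with under 10% missing data across included individuals: for each
focal male the allele shared with its female is the presumed X and the
other the presumed Y (order-invariant in the input genotype encoding);
all other individuals contribute both alleles in seeded-random order,
explicitly marked unphased by their `h1`/`h2` ids. Trees over haplotypes
use neighbor-joining on Hamming distances ignoring N (negative branch
lengths clamped to zero) — a deliberate stand-in for full ML inference
with ascertainment correction, since the property of interest is
topological grouping of Y haplotypes, not branch-length fidelity.

## Synthetic data

The generators plant known truth so every stage is testable end to end.

* **WGS cohorts**: one male + one female genome per species, sites uniform
  per LG, background genotypes i.i.d. across individuals — heterozygous
  with probability `background_het` (default 0.2, a diversity typical of
  a young radiation's segregating sites), otherwise homozygous reference
  (80%) or alternative (20%). Inside a planted region a fraction *d*
  (differentiation) of sites is fully sex-specific for that species.
  Validation cohorts use 10 species, 5 LGs of 2 Mb, 2000 sites per LG and
  a 1-Mb planted region shared by the tribe — the tribe-shared geometry
  the WGS scans assume — with 2% missingness.
* **RNA counts**: typically 3+3 replicates; background SNPs uniform on the
  genome with sex-balanced Poisson(depth/2) allele counts; 5% of
  background SNPs are sex-*biased* (0.8/0.2 allele-proportion split
  between sexes), emulating allele-specific expression differences that
  pass the per-SNP test without being sex-exclusive; planted sex-exclusive
  SNPs (10% of SNPs at *d* = 1) cluster into 20 gene-sized (2-kb) blocks
  inside the region, because transcriptome SNPs concentrate in expressed
  genes. Heterogametic replicates draw Poisson(depth) variant reads with
  at least two nonzero enforced; the homogametic sex has zero.
* **Trait histories**: exact continuous-time Markov simulation along the
  tree, with every change recorded.

What the generators deliberately omit — linkage disequilibrium,
recombination maps, population structure, read-level noise, expression
variation across tissues — bounds what passing tests show: recovery
results certify the statistical logic of the pipeline on its stated
assumptions, not robustness to mapping artifacts or structure-driven
confounding in real cohorts.

## Problem sizes used in validation

Recovery suites run 20 seeds per condition (50 for rate recovery), with
the cohort geometry above; stochastic-map checks use 300–4000 maps on 4–16
tip trees; the recruitment test uses its standard 10,000 simulations.
These sizes give stable pass/fail behavior at conventional Monte-Carlo
tolerances while keeping the full suite fast.

## Known limitations

* The association scan omits population-structure correction by design;
  on structured real data it would need to be replaced by a mixed model.
* The per-SNP pooled exact test in the RNA route ignores replicate-level
  overdispersion.
* Turnover detection on a half-tree clade is fundamentally ambiguous for
  a symmetric 2-state model (the mirror history has equal likelihood);
  recovery guarantees apply to nested minority clades.
* The 2×3 exact test enumerates O(n²) tables; very large windows fall
  back to χ².
* The permissive/stringent conflict policy codifies a case-by-case
  narrative; every resolution is logged in the call notes.
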