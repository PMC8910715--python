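# Methods

## Study design being modelled

A recessive dwarf line serves as the recurrent (maternal) parent of a
backcross programme: F₁ plants are backcrossed to it for eight generations,
and the BC₈ population segregates ~1:1 tall:dwarf at the causal locus
because each generation's carried-forward parent is a heterozygote. The
pipeline maps the locus by pooled resequencing of phenotypic extremes and
profiles the same contrast with RNA-seq, hormone panels and qPCR.

## Synthetic cohort generator

**Genetics.** Haplotypes are parental-origin vectors over a marker map
(`False` = recurrent "M", `True` = donor "P"). Meiosis follows the Haldane
(no-interference) map function: between adjacent markers separated by
d cM, a crossover occurs with probability r = (1 − e^(−2d/100))/2. The map
is constant per chromosome (default 2 cM/Mb, a typical genome-wide average
for *B. napus*; no published map is assumed). The default genome is a
two-chromosome stand-in — A01 (24 Mb, causal locus at 3.21 Mb) and a null
chromosome A02 (27 Mb) — with markers every 15 kb approximating the density
of informative SNPs after filtering. Simulations over the whole genome
would only replicate A02 many times over at a large constant cost.

**Backcrossing.** Each of the `population_size` (default 965) BC₈
individuals is an independent lineage: one plant per generation, crossed to
the recurrent parent, with the intermediate parent required to be
heterozygous at the causal locus (rejection sampling of gametes). Final
offspring are unselected, giving the 1:1 segregation. Independent lineages
make per-individual BC₈ genotypes i.i.d., which is both how large backcross
populations are actually produced (many plants per generation) and exactly
the genotype distribution the null-threshold simulation assumes; descent
through a single lineage would instead give every offspring the same
residual donor blocks. Heterozygosity at unlinked markers decays as (1/2)ⁿ.

**Phenotype.** Dwarf iff homozygous recurrent at the causal marker. The
trait is described as polygenic in origin, but bulk construction needs an
unambiguous genotype–phenotype rule; a single major recessive locus is the
simplest model consistent with the 1:1 bulk design. (A liability-scale
polygenic term was considered and left out: it would only blur bulk
membership without changing any estimand.)

**Pool sequencing.** Per marker and pool: total depth ~ Poisson(mean depth;
defaults 46 tall / 57 dwarf), maternal-allele reads ~ Binomial(depth, pool
'M' frequency). Sequencing error is off by default and not modelled
further. Zero-depth rows are flagged missing and propagate as missing —
never imputed.

**Expression.** Counts ~ NB(mean = library size × lognormal abundance,
dispersion α = 0.05; α = 0 degenerates to Poisson). A fraction (default
0.10) of genes is differentially expressed with |log₂FC| ~ U[1, 3]; DE
genes inside the candidate region are up-regulated in dwarf with
probability 0.99, elsewhere 0.64 (the genome-wide up:down ratio of the
design being emulated). Libraries default to 1M fragments — a deliberate
scale-down from real RNA-seq depth that keeps the suite fast while leaving
per-gene counts realistic.

**Hormones and qPCR.** Class totals (12 IAA compounds ≈ 2600 ng/g total,
4 GA ≈ 8, ABA ≈ 150, SL ≈ 2, 8 CK ≈ 5, ETH ≈ 20, 5 BR ≈ 3) are split evenly
over member compounds; replicates are lognormal around the group mean with
the configured dwarf/tall class ratios (IAA ×1.5, GA ×0.6, ABA ×0.7, others
×1). qPCR Ct values are reference Ct − log₂(relative expression) + Gaussian
noise, so zero-noise data invert exactly under 2^−ΔΔCt.

**What the generator does not emulate:** read-level artefacts (mapping
error, GC bias, duplicates), linkage disequilibrium with unmodelled
structural variation, genuinely polygenic phenotypes, compound-specific
hormone variation within a class, and amplification-efficiency differences
in qPCR. Passing tests therefore demonstrate the pipeline's correctness and
calibration under the stated sampling models, not robustness to those
artefacts.

## The scan

SNP-index = M/(M+P) per pool (missing if depth 0), Δ = dwarf − tall.
Informative SNPs are biallelic, parent-polymorphic sites with both pool
depths in [10, 200] (configurable; standard QTL-seq practice, as the
original filtering criteria are not stated).

**Loess.** Tricube-weighted local-linear fit over physical bp, per
chromosome, span 0.1 of the chromosome's SNPs (k nearest neighbours form a
contiguous window since positions are sorted; the weighted line is solved
in closed form). Degree 1 reproduces linear signals exactly; chromosomes
with fewer than five usable SNPs are skipped with a warning. Because the
fit is linear in the responses, the smoother is also materialised as a
sparse matrix to smooth thousands of simulated null tracks cheaply.

**Null thresholds.** The no-QTL null draws each pool member from the BC₈
genotype distribution (independent lineages over the same marker map, so
donor segments have realistic lengths), then binomial reads at each depth
on a small grid. A design point worth recording: per-marker quantiles of
raw Δ are useless in a BC₈, because at most markers both pools are fixed
for the recurrent allele and the null Δ distribution is an atom at zero —
its 95% quantile is 0 and thresholding degenerates. The threshold is
therefore the (confidence-level) quantile of the **genome-wide maximum of
the loess-smoothed Δ** across null replicates (1,000 by default), i.e. a
family-wise threshold in the spirit of permutation thresholds in QTL
mapping. Thresholds are forced monotone non-increasing in depth (read noise
only shrinks with coverage), which also irons out Monte-Carlo jitter; per
SNP the table is interpolated at the smaller of the two pool depths
(conservative).

**Interval calling.** Maximal runs of consecutive SNPs with smoothed
Δ ≥ threshold; runs on a chromosome closer than 100 kb are merged, then
runs with fewer than 10 supporting SNPs are dropped. Endpoints are the
first and last supporting SNP positions (1-based inclusive; BED exports are
0-based half-open). Total span is the union length in Mb, rounded half-up
to two decimals. With the default design the called interval is wide —
after eight backcrosses the donor segment dragged along with the selected
locus keeps smoothed Δ elevated over much of the chromosome — so recovery
is measured as "causal position inside a called interval", not interval
width.

## Differential expression

The test is fully specified so results are reproducible from the count
matrix alone: median-of-ratios size factors (median over all-nonzero genes
of count/geometric mean, used as computed); per-gene group means of
normalised counts; pooled method-of-moments dispersion
α = max(0, (s² − μ̄)/μ̄²) with s² the pooled within-group variance and μ̄ the
mean of the two group means; log₂FC = log₂((μ_d+0.5)/(μ_t+0.5)); Wald
z = ln-FC / SE with SE² = (1/n_t)(1/μ_t′ + α) + (1/n_d)(1/μ_d′ + α), the
primed means carrying the same 0.5 pseudo-count so all-zero groups never
divide by zero; two-sided normal p; Benjamini–Hochberg padj. The moment
estimator's truncation at zero makes the test mildly conservative on
Poisson data (empirical type-I ≈ 0.035 at p ≤ 0.05 with 3-vs-3 replicates),
which the calibration suite checks against the 0.05 ± 0.02 band.

DEG rules: FPKM = count/((length/10³)(library/10⁶)); genes with FPKM < 1 in
*any* sample are excluded before testing (read literally; an "all samples"
variant is available since the phrasing is ambiguous); the rest are up/down
at |log₂FC| ≥ 1 and padj ≤ 0.05, direction always dwarf relative to tall.
K-means (k = 6, k-means++, best of 10 restarts, explicit seed) runs on
per-gene z-scores of log₂(FPKM+1); clusters are relabelled 1..k by
decreasing centroid dwarf−tall difference so numbering is deterministic and
low labels mean up-in-dwarf.

## Hormones

Unweighted OLS calibration lines (1/x weighting available); concentrations
invert the line, flooring negatives at zero with a below-LOQ flag. Group
comparison uses the Welch unequal-variance t with Satterthwaite df — the
robust reading of "Student's t-test" for n = 3 with no variance information
(a pooled-variance flag exists). Two constant, unequal groups return p = 0
rather than an error so noiseless simulations flow through. Fold-change
ranges pair replicates by index (how the published 1.41–1.66 range was
formed is not stated; this is the documented assumption). Stars: * p < 0.05,
** p < 0.01.

## Association

Gene–interval membership is any-overlap (≥ 1 bp, 1-based inclusive;
containment-of-start available). Tallies report up/down/ns/filtered per
interval and over the de-duplicated union; percentages are rounded half-up
to two decimals. Enrichment over user-supplied gene sets is the upper-tail
hypergeometric P(X ≥ k) with BH adjustment across sets; the universe
defaults to all genes passing the FPKM filter.

## Numerical and interface choices

- All randomness flows through `numpy.random.Generator` seeds; every
  generator is bit-reproducible given (config, seed).
- Missing values (zero-depth indices, filtered genes' padj) propagate as
  NaN/NA, never as 0.
- Configuration rejects unknown keys; runs log the package version, a
  config hash and the seed.
- Native tables are TSV with documented headers; VCF input uses per-sample
  AD with the maternal=REF orientation declared in config, since M/P
  depends on which parent matches the reference.

## Problem sizes

The default simulated genome (two chromosomes, ~3,400 markers), 100-cohort
recovery/calibration suites, 1,000-replicate threshold simulation and
2,000-gene expression matrices were chosen so a full test run and the
acceptance script each finish in a few minutes on a single CPU while
keeping all Monte-Carlo tolerances comfortably resolvable.

## Known limitations

- Interval endpoints are SNP positions; no sub-interval deconvolution of
  multiple linked QTL is attempted.
- The threshold table conditions on pool sizes, generation number and the
  marker map; it must be re-simulated if any of those change.
- The NB Wald test with moment dispersion is self-contained by design; it
  is not expected to reproduce any particular external DE tool's gene list.
- Hormone classes are compared on totals; compound-level multiplicity is
  reported per compound without cross-compound correction.
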