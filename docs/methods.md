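# Methods

This note documents the models, defaults, and numerical choices behind
`bulkseg`, and what the synthetic validation does and does not establish.

## Population model (simdata)

**Breeding scheme.** Each family is simulated gamete-by-gamete through
F₁ → BC₁ … BC₆ → one selfing. Every backcross crosses the current line to a
fully recurrent-parent gamete; the selfing draws two independent gametes from
the BC₆F₁. Meiosis follows the **Haldane model**: the crossover count per
chromosome is Poisson with mean equal to the map length in Morgans, crossover
positions are uniform in physical coordinates (uniform recombination rate),
and there is no interference. Chromatids are tracked as donor-origin
intervals, so a family's genotype is a set of half-open donor segments per
homolog; SNP dosages (0/1/2) are read off the segment structure.

**Neutral expectation.** The F₁ transmits donor material with expectation ½
and each backcross halves it, so an unselected BC₆F₂ carries a donor dose
fraction of 2⁻⁷ ≈ 0.0078 on average — which also means an unselected locus
segregates in almost no family. Real introgression programs select carriers
each generation. `SimConfig.retain_qtl` (default on) models this: during
each backcross the transmitted gamete is conditioned (by resampling) on
carrying the donor allele at every planted QTL. The BC₆F₁ is then
heterozygous at the QTL and the BC₆F₂ segregates 1:2:1 there, matching the
null allele frequency of ½ used by the scan's confidence envelope. With an
empty QTL list the switch is inert and transmission is fully neutral; the
neutral-expectation and calibration checks use that mode.

**Phenotypes.** Additive model per trait:
`trait = baseline + Σ_q dose_q · a_q/2 + N(0, σ_env)`, so the two QTL
homozygotes differ by exactly the stated effect `a_q` (in cN/tex for fiber
strength). Fiber length shares the QTL effects through a genetic-correlation
factor (0.6) and a unit conversion (0.48 mm per cN/tex), with independent
environmental noise. Defaults place the **segregating population** at the
observed study scale — strength mean ≈ 33.7 cN/tex, SD ≈ 2.46; length mean
≈ 29.6 mm, SD ≈ 1.18 — hence the all-recurrent baselines are 31.25 cN/tex
and 28.9 mm (every family carries the retained QTL at mean dose 1). The
default major QTL (A10:21,400,000, the centre of the interval the analysis
is designed to recover, effect 4.9 cN/tex) explains ≈ 50% of the strength
variance against σ_env = 1.74.

**Sequencing readout.** Per site and sample: depth ~ Poisson(μ) with μ = 20
(parents) or 30 (bulks); donor reads ~ Binomial(depth, f′) where f′ is the
true pool donor frequency perturbed by a symmetric per-read error rate
(default 0.1%, which is what gives the SNP-index < 0.5 filter something to
do); a zero-depth draw makes the site missing for that sample. Parents are
fixed at frequencies 0 and 1. The default genome is four 60-Mb, 1-Morgan
chromosomes (one named A10) with a differential SNP every 50 kb — large
enough for realistic window statistics, small enough that a full study run
takes well under a second.

**What the generator does not emulate:** tetraploid homoeolog collapse or
mismapping, indels, read-level artifacts, selection on the polygenic
background, or non-uniform recombination. Passing tests therefore show the
*statistic* behaves correctly under its own sampling assumptions, not that
those assumptions hold in any particular sequencing experiment.

## Phenotype summaries and bulks (phenotyping)

Skewness and kurtosis are the adjusted Fisher–Pearson estimators with
sample-size bias correction (scipy's `bias=False`, the convention of
mainstream statistics packages). Skewness needs n ≥ 3, kurtosis n ≥ 4, and
both need SD > 0; otherwise they are flagged undefined rather than NaN. The
normality screen passes iff |skew| < 1 **and** |kurt| < 1 — strict
inequalities, a heuristic rather than a formal test. Bulk rules use strict
comparisons (boundary values stay unassigned) and conjunction over both
traits; high thresholds must exceed low ones, so the bulks are disjoint by
construction. `select_extreme_by_rank` (sum of per-trait z-scores, stable
ties) provides fixed-size bulks when exact 20/12 pools are wanted.
Multi-site phenotype averaging is a documented pre-step: equal-weight mean
per family before the table is read.

## VCF polarization (variantio)

The donor allele at a site is defined by the parents, never by REF/ALT: a
site is informative when each parent's major allele holds ≥ 90% of its reads
(configurable purity) and the two major alleles differ. Multi-allelic and
indel records are dropped; every drop is counted by reason, and
kept + dropped equals records read. Swapping the two parents' roles flips
every donor allele, mapping SNP-index x → 1 − x and Δ → −Δ downstream.
BED output is 0-based half-open (1-based inclusive [s, e] → (s−1, e));
all internal coordinates are 1-based inclusive, matching VCF.

## The scan (bsacore)

**Filters.** Reasons are assessed in order — `low_index_both` (index < 0.5
in both pools), `low_depth` (depth < 5 in either pool), `missing_in_pool` —
and the first that holds is recorded. The asymmetric both/either reading is
deliberate: an index below 0.5 in only one pool is precisely the association
signal sought, while one shallow pool already makes Δ unreliable. Both
clauses are switchable (`index_rule`, `depth_rule`) for sensitivity
analysis. Comparisons are NaN-aware, so a missing pool falls through to
`missing_in_pool`.

**Windows.** 1 Mb windows at 100 kb step, tiling from position 1 and
truncated at the chromosome end; unweighted means over member sites; windows
with fewer than 10 sites are flagged missing and excluded from calling. The
window geometry is configurable; the defaults reflect that candidate-region
boundaries in this kind of scan are conventionally reported at round 100-kb
resolution.

**Null envelope.** Default method is depth-aware null simulation (the
QTL-seq convention): per replicate, each pool's allele frequency is
Binomial(2n, ½)/2n with n = 20 and 12 families (the finite-bulk sampling of
a site segregating 1:2:1 after selfing a heterozygote), then donor reads are
Binomial(depth, frequency). 10,000 replicates; two-sided (α/2, 1−α/2)
empirical quantiles with the **nearest-rank** (inverse-ECDF) definition;
envelopes computed once per rounded window depth pair and attached per
window. A site-wise label-permutation alternative
(`permutation_null_envelope`) gives a single genome-wide band. Calling is
one-sided positive by default (donor alleles raising the trait enrich HC1);
negative and two-sided modes exist. Adjacent or overlapping significant
windows merge when separated by at most one step; a region's span is
end − start and its peak window has the largest |mean Δ|.

**A numerical caveat.** At shallow depths the null Δ lives on a coarse
lattice (spacing 1/depth). Where the exact CDF at a lattice atom lies within
Monte-Carlo noise of the target level (e.g. depths (5,3) at 99%), the
nearest-rank quantile of 10,000 draws legitimately flips a whole atom, so
oracle comparisons are made only where the quantile is statistically
identifiable — margin > 4 ECDF standard errors, decided analytically from
the exact distribution before any sampling. The envelope is computed for a
single site at the window's mean depth but applied to a window *mean*, which
makes calling conservative (window means have smaller variance); the
measured false-positive window fraction at 99% is accordingly well below
0.01.

## Gene extraction and enrichment (annotate)

Region membership is 1-based inclusive. Default candidate classes are
nonsynonymous, stop-gain and stop-loss. Enrichment is the hypergeometric
upper tail P(X ≥ k) with Benjamini–Hochberg adjustment across tested terms;
terms absent from the selection are not reported. For a handful of candidate
genes, classification (term tallies per namespace) is the more appropriate
summary and is the default output; testing is optional. The default
background is all genes carrying any effect annotation, keeping the analysis
self-contained.

## Validation design and problem sizes

The acceptance battery uses the study conditions throughout: 184 families,
bulks 20/12, 30× pools, the default 4 × 60 Mb genome. Calibration uses 50
populations with **zero-effect retained loci** (one per chromosome):
segregating sites without phenotypic effect, the only informative no-QTL
null for a selected introgression population — a fully neutral BC₆F₂ has
essentially no site with pool frequency near ½, so every locus is filtered
and the false-positive rate would be vacuously zero. Recovery uses 50
populations with the default major QTL. The SNP-index noise check compares
the mean absolute deviation of observed indexes from true pool frequencies
against the **exact** binomial expectation E|X/d − f| (pmf enumeration per
site); note the folded-distribution identity MAD ≈ √(2/π)·SD means an
SD-formula reference would sit 20% below the MAD by construction. The
neutral backcross check (2,000 families) verifies the 2⁻⁷ dosage
expectation within 3 standard errors.

## Known limitations

- Diploid segment bookkeeping on an allotetraploid's subgenome coordinates:
  homoeologous cross-mapping is not modelled, so real cotton data will show
  noisier parental purity than the simulator.
- The null envelope conditions on segregating sites; in a population where a
  region segregates in only a subset of families the envelope is mildly
  conservative there.
- Region width reflects linkage drag under segment retention; the peak
  window, not the region boundary, is the locus estimate.
- `EffectTable` is consumed, not computed: variant-effect provenance (gene
  models, annotation software) is the caller's responsibility.
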