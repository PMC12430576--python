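# bulkseg

Bulked-segregant analysis by sequencing (BSA-Seq) for QTL mapping in
introgression-line populations, built around the Δ(SNP-index) statistic with
permutation-style confidence envelopes — plus a fully synthetic BC₆F₂
population generator so the entire pipeline runs, and can be validated,
without any external data.

## The problem

Breeders who move chromosome segments from a donor species (e.g. sea-island
cotton, *Gossypium barbadense*) into an elite recurrent background (upland
cotton, *G. hirsutum*) need to know **which donor segment carries the trait**.
BSA-Seq answers this by sequencing two DNA pools built from the phenotypic
extremes of a segregating population — a superior bulk (HC1) and an inferior
bulk (HC2) — together with the two parents.

At every SNP that distinguishes the parents, the **SNP-index** of a pool is
the fraction of its reads carrying the donor allele:

```
SNP-index = donor-allele reads / total reads        ∈ [0, 1]
Δ(SNP-index) = SNP-index(HC1) − SNP-index(HC2)      ∈ [−1, 1]
```

An index of 0 means the pool is identical to the recurrent parent at that
site; 1 means fully donor. Away from any trait locus both pools sample the
same allele frequency and Δ ≈ 0; at a locus that drove the phenotypic sorting
the pools are enriched for opposite alleles and Δ deviates. The pipeline:

1. summarizes the phenotypes (mean, SD, CV%, skewness, kurtosis, range) and
   screens normality by the breeder's |skew| < 1 and |kurt| < 1 rule;
2. assigns families to bulks by strict threshold rules on both traits
   (or by rank for fixed-size bulks);
3. polarizes a multi-sample VCF by the parent genotypes (no assumption that
   REF = recurrent allele) and computes the per-site index track;
4. filters loci with SNP-index < 0.5 in **both** pools, depth < 5× in
   **either** pool, or missing in either pool;
5. averages the surviving sites in 1-Mb sliding windows (100-kb step) and
   compares each window mean against the empirical 95%/99% envelope of a
   simulated no-QTL null (10,000 replicates; finite-bulk allele-frequency
   sampling at the selfed-heterozygote expectation of ½, then binomial read
   noise at the window's depth);
6. merges windows exceeding the 99% envelope into candidate regions and
   intersects them with a variant-effect table to extract nonsynonymous /
   stop-gain / stop-loss sites and their genes, with optional hypergeometric
   term enrichment (Benjamini–Hochberg corrected).

The synthetic mode simulates the whole study design: Haldane-model meiosis
through F₁ → six backcrosses → one selfing, additive phenotypes for two
correlated fiber traits, extreme-bulk construction, and Poisson/binomial
sequencing readout at 20× (parents) / 30× (bulks), with the planted QTL and
true pool frequencies recorded as ground truth.

## Worked example

```sh
bulkseg demo --seed 42 --out demo_out
```

simulates 184 BC₆F₂ families with one major fiber-strength QTL planted on
chromosome A10 at 21.4 Mb, builds 20/12 extreme bulks, and scans. It prints
(abridged):

```
bulk_high: 20
bulk_low: 12
sites_simulated: 4800
filtered_low_index_both: 4565
sites_pass: 235
windows_scored: 116
windows_significant: 96
regions: 1
candidate_genes: 12
```

Of 4800 simulated parent-differential SNPs, 4565 are monomorphic-recurrent
in both pools (SNP-index < 0.5 in both) — exactly what an introgression
population should look like — and the 235 segregating sites cluster around
the planted locus. `demo_out/regions.tsv` contains the single called region:

```
chrom   start     end       span_bp   n_windows  n_sites  peak_delta
A10     18700001  29200000  10499999  96         193      0.794
```

The region covers the true QTL at 21.4 Mb; its ~10 Mb width is honest
linkage drag — six backcrosses of selection for the donor allele retain a
long surrounding segment, and the peak window (largest mean Δ) localizes the
locus much more narrowly. `candidate_sites.tsv` lists the nonsynonymous /
stop sites inside the region and their genes from the (synthetic) effect
table, and `plots/association_panels.png` shows the three per-chromosome
panels: SNP-index(HC1), SNP-index(HC2), and Δ with the 95% (green) and 99%
(orange) envelope lines.

Real data enter through `bulkseg snpindex --vcf calls.vcf --roles roles.yaml`
(a VCF with per-sample AD fields for the two parents and two bulks), followed
by `bulkseg scan`, `regions`, `genes`, `enrich`.

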