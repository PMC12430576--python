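"""Synthetic BC6F2 chromosome-segment-substitution population with sequenced bulks.

The generative model mirrors the breeding scheme behind introgression-line
BSA-Seq studies: an F1 between a recurrent (upland) and a donor (sea-island)
cotton parent is backcrossed to the recurrent parent for ``n_backcross``
generations and then selfed once.  Meiosis follows the Haldane model —
crossover count per chromosome is Poisson with mean equal to the genetic map
length in Morgans, crossover positions uniform along the chromosome, no
interference.  Each resulting family therefore carries none or a few donor
chromosome segments on an otherwise recurrent background, and donor-allele
dosage at the parent-differential SNPs is read directly off the segment
structure.

Phenotypes are additive: trait = baseline + sum over planted QTLs of
(donor dose) x (additive effect)/2 + Gaussian environmental noise, so a
homozygous-donor family deviates from a homozygous-recurrent one by exactly
the stated effect.  Fiber length and fiber strength share the QTL effects
through a genetic-correlation factor.

Sequencing readout: per site and sample, depth ~ Poisson(mean depth) and
donor-allele reads ~ Binomial(depth, f') where f' is the true donor-allele
frequency in the pool perturbed by a symmetric per-read error rate.  Parents
are fixed (frequency 0 for the recurrent parent, 1 for the donor parent).
A Poisson draw of zero depth makes the site missing for that sample.

Because the donor allele at an unselected locus survives six backcrosses with
probability 2^-6, a planted QTL would segregate in almost no family under
neutral transmission.  ``SimConfig.retain_qtl`` (default True) conditions each
backcross gamete on carrying the donor allele at every planted QTL, emulating
the selection a real introgression program applies; the BC6F1 is then
heterozygous at the QTL and the BC6F2 segregates 1:2:1 there.  With no QTLs
the switch is inert and transmission is fully neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotyping import FAMILY_COL, LENGTH_COL, STRENGTH_COL, BulkRule

SAMPLES = ("Prec", "Pdon", "HC1", "HC2")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    map_length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be positive")
        if self.map_length_morgans < 0:
            raise ValueError(f"{self.name}: map length must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, genetic map lengths, and parent-differential SNP positions."""

    chromosomes: tuple[Chromosome, ...]
    snp_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("configuration error: genome needs at least one chromosome")
        n_snps = 0
        for chrom in self.chromosomes:
            pos = np.asarray(self.snp_positions.get(chrom.name, ()), dtype=np.int64)
            self.snp_positions[chrom.name] = pos
            n_snps += pos.size
            if pos.size and not (
                np.all(np.diff(pos) > 0) and pos[0] >= 1 and pos[-1] <= chrom.length_bp
            ):
                raise ValueError(
                    f"{chrom.name}: SNP positions must be strictly increasing in [1, length_bp]"
                )
        if n_snps == 0:
            raise ValueError("configuration error: genome declares no SNPs")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def default(
        cls,
        names: tuple[str, ...] = ("A07", "A08", "A09", "A10"),
        length_bp: int = 60_000_000,
        map_length_morgans: float = 1.0,
        snp_spacing_bp: int = 50_000,
    ) -> "GenomeSpec":
        """Four 60-Mb, 1-Morgan chromosomes with a differential SNP every 50 kb."""
        chroms = tuple(Chromosome(n, length_bp, map_length_morgans) for n in names)
        snps = {
            n: np.arange(snp_spacing_bp, length_bp + 1, snp_spacing_bp, dtype=np.int64)
            for n in names
        }
        return cls(chroms, snps)


@dataclass(frozen=True)
class QTL:
    chrom: str
    position_bp: int
    effect: float  # additive effect on fiber strength, cN/tex (homozygote difference)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults reproduce the study conditions: 184 BC6F2 families from six
    backcrosses, parents sequenced at 20x and pools at 30x, one major fiber-
    strength QTL on chromosome A10 sized to explain about half the trait
    variance, trait baselines and dispersions matching the observed population.
    """

    seed: int
    n_backcross: int = 6
    n_families: int = 184
    qtl_list: tuple[QTL, ...] = (QTL("A10", 21_400_000, 4.9),)
    env_sd_strength: float = 1.74
    env_sd_length: float = 1.07
    # baselines are the all-recurrent genotype values, placed so that the
    # segregating population mean (every family carries the retained QTL at
    # mean dose 1) lands at the observed population means
    baseline_strength: float = 31.25
    baseline_length: float = 28.9
    trait_corr: float = 0.6  # genetic sharing factor between length and strength
    length_per_strength: float = 0.48  # unit conversion mm per cN/tex for shared effects
    seq_error_rate: float = 0.001
    parent_depth_mean: float = 20.0
    bulk_depth_mean: float = 30.0
    bulk_rule: BulkRule = field(default_factory=BulkRule.study_default)
    retain_qtl: bool = True

    def __post_init__(self) -> None:
        if self.n_backcross < 0:
            raise ValueError("n_backcross must be >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.env_sd_strength < 0 or self.env_sd_length < 0:
            raise ValueError("environmental sd must be >= 0")
        if self.parent_depth_mean <= 0 or self.bulk_depth_mean <= 0:
            raise ValueError("depth means must be > 0")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate must be in [0, 0.5)")

    def validate_against(self, genome: GenomeSpec) -> None:
        for q in self.qtl_list:
            try:
                chrom = genome.chromosome(q.chrom)
            except KeyError:
                raise ValueError(f"QTL chromosome {q.chrom!r} not in genome") from None
            if not 1 <= q.position_bp <= chrom.length_bp:
                raise ValueError(f"QTL position {q.position_bp} outside {q.chrom}")


@dataclass
class FamilyGenotype:
    """Donor-origin segments (two homologs per chromosome) and SNP dosages.

    Segments are half-open bp intervals [start, end); ``doses`` holds the
    0/1/2 donor dose at each genome SNP position.
    """

    family_id: str
    homologs: dict[str, tuple[tuple[tuple[float, float], ...], tuple[tuple[float, float], ...]]]
    doses: dict[str, np.ndarray]

    def dose_at(self, chrom: str, position: float) -> int:
        return sum(
            any(s <= position < e for s, e in hom) for hom in self.homologs[chrom]
        )

    def n_segments(self) -> int:
        return sum(len(hom) for pair in self.homologs.values() for hom in pair)

    def donor_fraction(self) -> float:
        """Donor-allele dose fraction over all genome SNP positions."""
        total = sum(int(d.sum()) for d in self.doses.values())
        n = sum(d.size for d in self.doses.values())
        return total / (2 * n)


@dataclass
class TruthRecord:
    """Ground truth for acceptance checks: planted QTLs and true pool frequencies."""

    qtls: tuple[QTL, ...]
    bulk_freq: pd.DataFrame | None = None  # chrom, pos, freq_HC1, freq_HC2 (filled later)


# ---------------------------------------------------------------------------
# meiosis


def _gamete(
    hom_a: tuple[tuple[float, float], ...],
    hom_b: tuple[tuple[float, float], ...],
    chrom: Chromosome,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], ...]:
    """One recombinant gamete under the Haldane model (donor intervals only)."""
    n_xo = rng.poisson(chrom.map_length_morgans)
    cuts = np.sort(rng.uniform(0.0, chrom.length_bp, n_xo)) if n_xo else np.empty(0)
    current = int(rng.integers(2))
    if n_xo == 0:
        return (hom_a, hom_b)[current]
    out: list[tuple[float, float]] = []
    homs = (hom_a, hom_b)
    bounds = np.concatenate(([0.0], cuts, [float(chrom.length_bp)]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        for s, e in homs[current]:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 < e2:
                if out and out[-1][1] == s2:
                    out[-1] = (out[-1][0], e2)  # fuse abutting pieces
                else:
                    out.append((s2, e2))
        current ^= 1
    return tuple(out)


def _carries(intervals, position: float) -> bool:
    return any(s <= position < e for s, e in intervals)


def _doses_from_homologs(homs, positions: np.ndarray) -> np.ndarray:
    """Vectorized donor-dose lookup: position in [s, e) per homolog, summed."""
    dose = np.zeros(positions.size, dtype=np.int8)
    for hom in homs:
        if not hom:
            continue
        edges = np.fromiter((x for iv in hom for x in iv), dtype=float, count=2 * len(hom))
        dose += (np.searchsorted(edges, positions, side="right") % 2).astype(np.int8)
    return dose


def simulate_population(
    genome: GenomeSpec, cfg: SimConfig
) -> tuple[list[FamilyGenotype], TruthRecord]:
    """Simulate BC{n}F2 families: F1 -> n backcrosses to recurrent -> one selfing.

    Returns the family genotypes (segments + SNP dosages) and a TruthRecord
    holding the planted QTLs (pool frequencies are added by
    :func:`simulate_bulk_reads`).  Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate_against(genome)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    qtl_by_chrom: dict[str, list[float]] = {}
    if cfg.retain_qtl:
        for q in cfg.qtl_list:
            qtl_by_chrom.setdefault(q.chrom, []).append(float(q.position_bp))

    full = {c.name: ((0.0, float(c.length_bp)),) for c in genome.chromosomes}
    empty: tuple[tuple[float, float], ...] = ()
    families: list[FamilyGenotype] = []
    width = max(3, len(str(cfg.n_families)))
    for i in range(cfg.n_families):
        homologs = {}
        for chrom in genome.chromosomes:
            # F1: one full-donor homolog, one full-recurrent homolog
            pair = (full[chrom.name], empty)
            targets = qtl_by_chrom.get(chrom.name, [])
            for _ in range(cfg.n_backcross):
                gam = _gamete(pair[0], pair[1], chrom, rng)
                attempts = 0
                while targets and not all(_carries(gam, t) for t in targets):
                    gam = _gamete(pair[0], pair[1], chrom, rng)
                    attempts += 1
                    if attempts > 10_000:
                        raise RuntimeError(
                            f"QTL retention failed on {chrom.name}: donor allele lost"
                        )
                pair = (gam, empty)
            # selfing: two independent gametes from the BC_nF1
            homologs[chrom.name] = (
                _gamete(pair[0], pair[1], chrom, rng),
                _gamete(pair[0], pair[1], chrom, rng),
            )
        doses = {
            name: _doses_from_homologs(homologs[name], genome.snp_positions[name].astype(float))
            for name in genome.names
        }
        families.append(FamilyGenotype(f"F{i + 1:0{width}d}", homologs, doses))
    return families, TruthRecord(qtls=tuple(cfg.qtl_list))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(families: list[FamilyGenotype], cfg: SimConfig) -> pd.DataFrame:
    """Additive phenotypes for fiber strength and (correlated) fiber length.

    strength = baseline + sum(dose_q * effect_q / 2) + N(0, env_sd_strength);
    the genetic value of length is ``trait_corr * length_per_strength`` times
    the strength genetic value, with independent environmental noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    n = len(families)
    g_strength = np.zeros(n)
    for q in cfg.qtl_list:
        doses = np.array([fam.dose_at(q.chrom, q.position_bp) for fam in families])
        g_strength += doses * (q.effect / 2.0)
    g_length = cfg.trait_corr * cfg.length_per_strength * g_strength
    strength = cfg.baseline_strength + g_strength + rng.normal(0, cfg.env_sd_strength, n)
    length = cfg.baseline_length + g_length + rng.normal(0, cfg.env_sd_length, n)
    return pd.DataFrame(
        {
            FAMILY_COL: [f.family_id for f in families],
            LENGTH_COL: length,
            STRENGTH_COL: strength,
        }
    )


# ---------------------------------------------------------------------------
# sequencing readout


_BASES = np.array(list("ACGT"))


def simulate_bulk_reads(
    families: list[FamilyGenotype],
    bulks: tuple[list[str] | tuple[str, ...], list[str] | tuple[str, ...]],
    genome: GenomeSpec,
    cfg: SimConfig,
    truth: TruthRecord | None = None,
) -> pd.DataFrame:
    """Allele-depth table for the two parents and two bulks at every genome SNP.

    ``bulks`` is (HC1 family ids, HC2 family ids); the lists must be disjoint
    and non-empty.  Per sample and site, depth ~ Poisson(mean) and donor reads
    ~ Binomial(depth, f') with f' the error-perturbed true pool frequency;
    zero depth is emitted as missing (NaN counts).  If ``truth`` is given its
    ``bulk_freq`` frame is filled with the true pool frequencies.
    """
    hi, lo = (list(bulks[0]), list(bulks[1]))
    if not hi or not lo:
        raise ValueError("both bulks must be non-empty")
    if set(hi) & set(lo):
        raise ValueError("bulk family lists must be disjoint")
    by_id = {f.family_id: f for f in families}
    missing = [fid for fid in hi + lo if fid not in by_id]
    if missing:
        raise ValueError(f"unknown family ids in bulks: {missing[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    e = cfg.seq_error_rate
    rows = []
    truth_rows = []
    for chrom in genome.chromosomes:
        pos = genome.snp_positions[chrom.name]
        m = pos.size
        f_true = {}
        for label, ids in (("HC1", hi), ("HC2", lo)):
            doses = np.sum([by_id[fid].doses[chrom.name] for fid in ids], axis=0)
            f_true[label] = doses / (2.0 * len(ids))
        f_true["Prec"] = np.zeros(m)
        f_true["Pdon"] = np.ones(m)

        # random parent-differential alleles per site (recurrent != donor)
        rec_idx = rng.integers(0, 4, m)
        don_idx = (rec_idx + rng.integers(1, 4, m)) % 4

        frame = {
            "chrom": np.repeat(chrom.name, m),
            "pos": pos,
            "recurrent_allele": _BASES[rec_idx],
            "donor_allele": _BASES[don_idx],
        }
        for sample in SAMPLES:
            mean = cfg.parent_depth_mean if sample in ("Prec", "Pdon") else cfg.bulk_depth_mean
            depth = rng.poisson(mean, m)
            f_err = f_true[sample] * (1 - e) + (1 - f_true[sample]) * e
            donor = rng.binomial(depth, f_err)
            rec = depth - donor
            rec_f = rec.astype(float)
            don_f = donor.astype(float)
            rec_f[depth == 0] = np.nan
            don_f[depth == 0] = np.nan
            frame[f"{sample}_rec"] = rec_f
            frame[f"{sample}_don"] = don_f
        rows.append(pd.DataFrame(frame))
        truth_rows.append(
            pd.DataFrame(
                {
                    "chrom": np.repeat(chrom.name, m),
                    "pos": pos,
                    "freq_HC1": f_true["HC1"],
                    "freq_HC2": f_true["HC2"],
                }
            )
        )
    adt = pd.concat(rows, ignore_index=True)
    if truth is not None:
        truth.bulk_freq = pd.concat(truth_rows, ignore_index=True)
    return adt


# ---------------------------------------------------------------------------
# synthetic annotation (for end-to-end demo runs)


EFFECT_CLASS_PROBS = {
    "exonic_nonsynonymous": 0.05,
    "exonic_synonymous": 0.05,
    "stopgain": 0.002,
    "stoploss": 0.001,
    "intronic": 0.25,
    "intergenic": 0.597,
    "other": 0.05,
}


def simulate_effect_table(
    genome: GenomeSpec, seed: int, gene_span_bp: int = 100_000
) -> pd.DataFrame:
    """Synthetic variant-effect annotation (synthetic stand-in for an ANNOVAR table).

    Genes tile each chromosome in ``gene_span_bp`` blocks; each SNP draws a
    functional class from a fixed genome-like mixture.  Purely for exercising
    the region -> gene extraction on simulated data.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    classes = np.array(list(EFFECT_CLASS_PROBS))
    probs = np.array(list(EFFECT_CLASS_PROBS.values()))
    probs = probs / probs.sum()
    rows = []
    for chrom in genome.chromosomes:
        pos = genome.snp_positions[chrom.name]
        gene_ids = [f"G_{chrom.name}g{1 + (p - 1) // gene_span_bp:04d}" for p in pos]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": np.repeat(chrom.name, pos.size),
                    "pos": pos,
                    "gene_id": gene_ids,
                    "effect_class": rng.choice(classes, pos.size, p=probs),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_term_map(
    genes: list[str], seed: int, n_terms: int = 12
) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]]]:
    """Synthetic gene->term map over BP/MF/CC namespaces for enrichment demos."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    namespaces = ["BP", "MF", "CC", "pathway"]
    term_meta = {
        f"T{i:03d}": (namespaces[i % len(namespaces)], f"synthetic term {i}")
        for i in range(n_terms)
    }
    terms = list(term_meta)
    gene2term: dict[str, set[str]] = {}
    for g in genes:
        k = 1 + rng.poisson(1.5)
        gene2term[g] = set(rng.choice(terms, size=min(k, n_terms), replace=False))
    return gene2term, term_meta


def neutral_config(seed: int, **overrides) -> SimConfig:
    """A SimConfig with no planted QTLs (neutral transmission), for null runs."""
    return replace(SimConfig(seed=seed, qtl_list=()), **overrides)
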