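"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from bulkseg import bsacore, phenotyping, simdata
from bulkseg.simdata import QTL, Chromosome, GenomeSpec, SimConfig


@pytest.fixture(scope="session")
def default_genome() -> GenomeSpec:
    return GenomeSpec.default()


@pytest.fixture()
def small_genome() -> GenomeSpec:
    """Two short chromosomes for fast unit tests."""
    chroms = (Chromosome("A09", 10_000_000, 0.5), Chromosome("A10", 10_000_000, 0.5))
    snps = {
        c.name: np.arange(100_000, c.length_bp + 1, 100_000, dtype=np.int64)
        for c in chroms
    }
    return GenomeSpec(chroms, snps)


def run_synthetic_scan(
    seed: int,
    qtls: tuple[QTL, ...],
    genome: GenomeSpec | None = None,
    n_high: int = 20,
    n_low: int = 12,
    **cfg_overrides,
):
    """Simulate -> phenotype -> rank bulks -> index -> scan -> regions.

    The workhorse for calibration/power checks; returns (windows, regions,
    track, truth).
    """
    genome = genome or GenomeSpec.default()
    cfg = SimConfig(seed=seed, qtl_list=qtls, **cfg_overrides)
    families, truth = simdata.simulate_population(genome, cfg)
    phen = simdata.simulate_phenotypes(families, cfg)
    bulks = phenotyping.select_extreme_by_rank(phen, n_high, n_low)
    adt = simdata.simulate_bulk_reads(
        families, (bulks.high_ids, bulks.low_ids), genome, cfg, truth
    )
    track = bsacore.filter_sites(bsacore.compute_index_track(adt))
    spec = bsacore.WindowSpec()
    sizes = {c.name: c.length_bp for c in genome.chromosomes}
    windows = bsacore.window_scan(bsacore.pass_sites(track), spec, sizes)
    windows = bsacore.attach_null_thresholds(
        windows, bsacore.NullModel(seed=seed, n_high=n_high, n_low=n_low)
    )
    regions = bsacore.call_regions(windows, spec, 99.0, track=track)
    return windows, regions, track, truth


#: zero-effect donor-segment retention targets: the population segregates at
#: these loci (as a selected introgression program's does) but the phenotype
#: is pure noise, giving a non-vacuous no-QTL null for calibration checks.
NULL_SEGREGATING_QTLS = tuple(
    QTL(c, 30_000_000, 0.0) for c in ("A07", "A08", "A09", "A10")
)


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle for the null Δ(SNP-index) distribution
# (independent of bulkseg.bsacore: direct probability bookkeeping)


def exact_null_delta_distribution(
    depth_high: int, depth_low: int, n_high: int, n_low: int, null_freq: float = 0.5
):
    """Exact atoms and CDF of null Δ: bulk frequency ~ Binom(2n, f0)/2n, reads ~ Binom(d, freq)."""

    def index_distribution(depth: int, n: int):
        freqs = np.arange(2 * n + 1) / (2 * n)
        w = binom.pmf(np.arange(2 * n + 1), 2 * n, null_freq)
        reads = np.arange(depth + 1)
        pr = np.zeros(depth + 1)
        for wf, f in zip(w, freqs):
            pr += wf * binom.pmf(reads, depth, f)
        return reads / depth, pr

    x1, p1 = index_distribution(depth_high, n_high)
    x2, p2 = index_distribution(depth_low, n_low)
    delta = np.round((x1[:, None] - x2[None, :]).ravel(), 12)
    prob = (p1[:, None] * p2[None, :]).ravel()
    atoms: dict[float, float] = {}
    for d, p in zip(delta, prob):
        atoms[d] = atoms.get(d, 0.0) + p
    xs = np.array(sorted(atoms))
    cdf = np.cumsum([atoms[x] for x in xs])
    return xs, cdf


def exact_quantile(xs: np.ndarray, cdf: np.ndarray, p: float) -> float:
    """inf{x : F(x) >= p} on the exact discrete distribution."""
    return float(xs[np.searchsorted(cdf, p - 1e-12)])


def quantile_identifiable(
    xs: np.ndarray, cdf: np.ndarray, p: float, n_reps: int, z: float = 4.0
) -> bool:
    """Whether a nearest-rank quantile of n_reps draws is stable at level p.

    On a lattice distribution the empirical quantile flips a whole atom when
    the CDF at the crossing atom lies within Monte-Carlo noise of p; such
    (depth, level) combinations cannot be compared at a sub-atom tolerance.
    The margin is z standard errors of the ECDF at p.
    """
    se = np.sqrt(p * (1 - p) / n_reps)
    k = int(np.searchsorted(cdf, p - 1e-12))
    margins = [abs(cdf[k] - p)]
    if k > 0:
        margins.append(abs(cdf[k - 1] - p))
    return min(margins) > z * se


# ---------------------------------------------------------------------------
# small builders


def make_track(rows) -> pd.DataFrame:
    """Site track from (chrom, pos, i1, i2, d1, d2) tuples; NaN allowed."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "index_HC1", "index_HC2", "depth_HC1", "depth_HC2"]
    )
    df["delta"] = df["index_HC1"] - df["index_HC2"]
    df["filter_status"] = bsacore.FILTER_PASS
    return df
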