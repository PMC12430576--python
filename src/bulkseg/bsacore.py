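"""SNP-index / Δ(SNP-index) association scan with simulated null envelopes.

The bulked-segregant statistic: at every parent-differential SNP, the
SNP-index of a pool is the fraction of its reads carrying the donor-parent
allele (0 = identical to the recurrent parent, 1 = fully donor), and
Δ(SNP-index) = index(superior pool HC1) − index(inferior pool HC2).  Away
from any trait locus both pools sample the same allele frequency and Δ
fluctuates around 0; near a locus that drove the phenotypic sorting the two
pools are enriched for opposite alleles and Δ deviates.

Site filters (applied after indexing) remove loci whose SNP-index is below
0.5 in *both* pools, loci with read depth below 5 in *either* pool, and loci
missing in either pool.  Window means over the surviving sites are compared
against empirical confidence envelopes of the no-QTL null, obtained from
10,000 replicates in which each pool's allele frequency is drawn from the
finite bulk (2n chromosomes segregating at expected frequency 1/2 — the
selfed-heterozygote expectation at a segregating site) and reads are drawn
binomially at the window's mean depth.  Windows exceeding the 99% envelope
in the positive tail are merged into candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FILTER_PASS = "pass"
FILTER_REASONS = ("low_index_both", "low_depth", "missing_in_pool")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for the genome scan."""

    window_size_bp: int = 1_000_000
    step_bp: int = 100_000
    min_sites_per_window: int = 10

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0 or self.step_bp <= 0 or self.min_sites_per_window <= 0:
            raise ValueError("window parameters must be positive")
        if self.step_bp > self.window_size_bp:
            raise ValueError("step must not exceed window size")


@dataclass(frozen=True)
class NullModel:
    """No-QTL null for the confidence envelopes.

    ``simulation`` (default): per replicate, each pool's donor-allele
    frequency is Binomial(2n, null_freq)/2n — the finite-bulk sampling of a
    site segregating 1:2:1 after selfing a heterozygote — and donor reads are
    Binomial(depth, frequency).  ``label_permutation``: the observed pools'
    read-count pairs are swapped site-wise at random, yielding a single
    genome-wide envelope.
    """

    seed: int
    method: str = "simulation"
    n_reps: int = 10_000
    n_high: int = 20
    n_low: int = 12
    null_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("simulation", "label_permutation"):
            raise ValueError(f"unknown null method {self.method!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("bulk sizes must be >= 1")


@dataclass
class CandidateRegion:
    """A merged run of significant windows; 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    peak_window: int  # index into the window table
    window_indices: list[int]
    peak_delta: float
    confidence: float
    n_sites: int = 0
    member_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def span_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# per-site statistics


def snp_index(donor_reads: float, total_reads: float) -> float:
    """Fraction of pool reads carrying the donor allele; NaN when no reads."""
    if total_reads is None or not total_reads or math.isnan(total_reads):
        return float("nan")
    if donor_reads > total_reads or donor_reads < 0:
        raise ValueError("donor reads must lie in [0, total reads]")
    return donor_reads / total_reads


def delta_snp_index(index_hc1: float, index_hc2: float) -> float:
    """Δ(SNP-index) = index(HC1) − index(HC2), in [−1, 1]."""
    return index_hc1 - index_hc2


def compute_index_track(adt: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP-index track from an allele-depth table (filters not yet applied)."""
    track = adt[["chrom", "pos"]].copy()
    for pool in ("HC1", "HC2"):
        don = adt[f"{pool}_don"].to_numpy(float)
        rec = adt[f"{pool}_rec"].to_numpy(float)
        depth = don + rec
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(depth > 0, don / depth, np.nan)
        track[f"depth_{pool}"] = depth
        track[f"index_{pool}"] = idx
    track["delta"] = track["index_HC1"] - track["index_HC2"]
    track["filter_status"] = FILTER_PASS
    return track


def filter_sites(
    track: pd.DataFrame,
    min_index: float = 0.5,
    min_depth: float = 5,
    index_rule: str = "both",
    depth_rule: str = "either",
) -> pd.DataFrame:
    """Assign filter status to every site; never raises on data.

    Reasons, assessed in order, the first that holds being recorded:

    - ``low_index_both``: SNP-index below ``min_index`` in both pools
      (an index below 0.5 in only one pool is the association signal itself);
    - ``low_depth``: depth below ``min_depth`` in either pool;
    - ``missing_in_pool``: no reads in either pool.

    ``index_rule``/``depth_rule`` switch each clause between "both"/"either"
    semantics for sensitivity analysis; the defaults are the standard reading.
    """
    if index_rule not in ("both", "either") or depth_rule not in ("both", "either"):
        raise ValueError("index_rule/depth_rule must be 'both' or 'either'")
    out = track.copy()
    i1 = out["index_HC1"].to_numpy(float)
    i2 = out["index_HC2"].to_numpy(float)
    d1 = out["depth_HC1"].to_numpy(float)
    d2 = out["depth_HC2"].to_numpy(float)

    with np.errstate(invalid="ignore"):
        li1, li2 = i1 < min_index, i2 < min_index  # NaN compares False
        ld1, ld2 = d1 < min_depth, d2 < min_depth
    low_index = (li1 & li2) if index_rule == "both" else (li1 | li2)
    low_depth = (ld1 | ld2) if depth_rule == "either" else (ld1 & ld2)
    missing = np.isnan(i1) | np.isnan(i2)

    status = np.full(len(out), FILTER_PASS, dtype=object)
    remaining = np.ones(len(out), dtype=bool)
    for reason, mask in (
        ("low_index_both", low_index),
        ("low_depth", low_depth),
        ("missing_in_pool", missing),
    ):
        hit = remaining & mask
        status[hit] = reason
        remaining &= ~hit
    out["filter_status"] = status
    return out


def pass_sites(track: pd.DataFrame) -> pd.DataFrame:
    return track[track["filter_status"] == FILTER_PASS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# windows


def window_scan(
    track: pd.DataFrame,
    spec: WindowSpec,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window means of the pass-filter site track.

    Windows tile each chromosome from position 1 at ``step_bp`` spacing; each
    covers ``window_size_bp`` bases (1-based inclusive, truncated at the
    chromosome end).  Per window the unweighted mean of member-site
    index_HC1, index_HC2, delta and pool depths is reported; windows with
    fewer than ``min_sites_per_window`` sites are flagged missing (NaN means)
    and are excluded from region calling.
    """
    sites = pass_sites(track) if "filter_status" in track.columns else track
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy(np.int64)
        length = int(chrom_sizes[chrom]) if chrom_sizes else int(pos[-1]) if pos.size else 0
        if length <= 0:
            continue
        cols = {
            c: np.concatenate([[0.0], np.cumsum(grp[c].to_numpy(float))])
            for c in ("index_HC1", "index_HC2", "delta", "depth_HC1", "depth_HC2")
        }
        starts = np.arange(1, length + 1, spec.step_bp, dtype=np.int64)
        ends = np.minimum(starts + spec.window_size_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        for s, e, a, b, k in zip(starts, ends, lo, hi, n):
            row = {"chrom": chrom, "start": int(s), "end": int(e), "n_sites": int(k)}
            if k >= spec.min_sites_per_window:
                for c, cs in cols.items():
                    row["mean_" + c] = (cs[b] - cs[a]) / k
            else:
                for c in cols:
                    row["mean_" + c] = np.nan
            rows.append(row)
    windows = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_sites",
            "mean_index_HC1", "mean_index_HC2", "mean_delta",
            "mean_depth_HC1", "mean_depth_HC2",
        ],
    )
    return windows.astype(
        {
            "start": np.int64,
            "end": np.int64,
            "n_sites": np.int64,
            **{c: float for c in windows.columns if c.startswith("mean_")},
        }
    )


# ---------------------------------------------------------------------------
# null envelopes


def _nearest_rank_quantile(sorted_x: np.ndarray, p: float) -> float:
    """Inverse-ECDF (nearest-rank) quantile: inf{x : F(x) >= p}."""
    n = sorted_x.size
    k = max(1, math.ceil(p * n))
    return float(sorted_x[min(k, n) - 1])


def simulate_null_deltas(
    depth_high: int, depth_low: int, null: NullModel, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of Δ(SNP-index) under the no-QTL finite-bulk null."""
    f1 = rng.binomial(2 * null.n_high, null.null_freq, null.n_reps) / (2 * null.n_high)
    f2 = rng.binomial(2 * null.n_low, null.null_freq, null.n_reps) / (2 * null.n_low)
    idx1 = rng.binomial(depth_high, f1) / depth_high
    idx2 = rng.binomial(depth_low, f2) / depth_low
    return idx1 - idx2


def null_thresholds(
    depth_high: float,
    depth_low: float,
    null: NullModel,
    confidence: float,
) -> tuple[float, float]:
    """Two-sided (lower, upper) empirical bounds of null Δ at one depth pair.

    ``confidence`` is a percentage in (0, 100); the bounds are the
    (α/2, 1−α/2) nearest-rank quantiles of ``n_reps`` simulated null deltas.
    """
    if not 0 < confidence < 100:
        raise ValueError("confidence must be in (0, 100)")
    d1, d2 = max(1, int(round(depth_high))), max(1, int(round(depth_low)))
    rng = np.random.default_rng(np.random.SeedSequence(null.seed, spawn_key=(d1, d2)))
    deltas = np.sort(simulate_null_deltas(d1, d2, null, rng))
    alpha = 1 - confidence / 100.0
    return (
        _nearest_rank_quantile(deltas, alpha / 2),
        _nearest_rank_quantile(deltas, 1 - alpha / 2),
    )


def attach_null_thresholds(
    windows: pd.DataFrame,
    null: NullModel,
    confidences: tuple[float, ...] = (95.0, 99.0),
) -> pd.DataFrame:
    """Attach per-window confidence bounds, simulated once per rounded depth pair.

    Window mean depths are rounded to an integer grid so each distinct
    (depth_HC1, depth_HC2) pair costs one simulation of ``null.n_reps``
    replicates; the same seed derivation makes results depth-reproducible.
    """
    out = windows.copy()
    cols: dict[str, np.ndarray] = {}
    for conf in confidences:
        tag = f"{conf:g}".replace(".", "_")
        cols[f"ci{tag}_low"] = np.full(len(out), np.nan)
        cols[f"ci{tag}_high"] = np.full(len(out), np.nan)

    d1 = np.round(out["mean_depth_HC1"].to_numpy(dtype=float))
    d2 = np.round(out["mean_depth_HC2"].to_numpy(dtype=float))
    ok = ~(np.isnan(d1) | np.isnan(d2))
    pairs = {}
    for i in np.flatnonzero(ok):
        pairs.setdefault((int(d1[i]), int(d2[i])), []).append(i)
    for (p1, p2), indices in pairs.items():
        p1, p2 = max(1, p1), max(1, p2)
        rng = np.random.default_rng(np.random.SeedSequence(null.seed, spawn_key=(p1, p2)))
        deltas = np.sort(simulate_null_deltas(p1, p2, null, rng))
        for conf in confidences:
            alpha = 1 - conf / 100.0
            lo = _nearest_rank_quantile(deltas, alpha / 2)
            hi = _nearest_rank_quantile(deltas, 1 - alpha / 2)
            tag = f"{conf:g}".replace(".", "_")
            cols[f"ci{tag}_low"][indices] = lo
            cols[f"ci{tag}_high"][indices] = hi
    for name, arr in cols.items():
        out[name] = arr
    if {"ci99_low", "ci99_high"} <= set(out.columns):
        with np.errstate(invalid="ignore"):
            out["significant_99"] = (
                out["mean_delta"].to_numpy(dtype=float) > out["ci99_high"].to_numpy(dtype=float)
            )
    return out


def permutation_null_envelope(
    track: pd.DataFrame, null: NullModel, confidence: float
) -> tuple[float, float]:
    """Genome-wide null envelope by site-wise swapping of the pools' read counts.

    For each replicate every site's (HC1, HC2) read-count pair keeps or swaps
    its pool labels with probability 1/2; the envelope is taken over the
    resulting per-site deltas pooled across replicates.
    """
    if not 0 < confidence < 100:
        raise ValueError("confidence must be in (0, 100)")
    sites = pass_sites(track)
    if sites.empty:
        return float("nan"), float("nan")
    rng = np.random.default_rng(np.random.SeedSequence(null.seed, spawn_key=(99,)))
    delta = sites["delta"].to_numpy(float)
    reps = max(1, null.n_reps // max(1, len(delta)))
    draws = []
    for _ in range(reps):
        sign = rng.choice([-1.0, 1.0], size=delta.size)
        draws.append(sign * delta)
    pool = np.sort(np.concatenate(draws))
    alpha = 1 - confidence / 100.0
    return (
        _nearest_rank_quantile(pool, alpha / 2),
        _nearest_rank_quantile(pool, 1 - alpha / 2),
    )


# ---------------------------------------------------------------------------
# region calling


def call_regions(
    windows: pd.DataFrame,
    spec: WindowSpec,
    confidence: float = 99.0,
    tail: str = "positive",
    track: pd.DataFrame | None = None,
) -> list[CandidateRegion]:
    """Merge windows exceeding the confidence envelope into candidate regions.

    A window is significant when its mean Δ exceeds the upper bound of the
    ``confidence``% envelope (``tail='positive'``, the default; ``'negative'``
    and ``'both'`` use the lower / either bound).  Significant windows on the
    same chromosome merge when they overlap or are separated by at most one
    step; each region reports its peak window (largest |mean Δ|) and, when the
    site ``track`` is supplied, its member pass-filter sites.
    """
    tag = f"{confidence:g}".replace(".", "_")
    lo_col, hi_col = f"ci{tag}_low", f"ci{tag}_high"
    if hi_col not in windows.columns:
        raise ValueError(f"windows lack {hi_col}; run attach_null_thresholds first")
    delta = windows["mean_delta"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if tail == "positive":
            sig = delta > windows[hi_col].to_numpy(float)
        elif tail == "negative":
            sig = delta < windows[lo_col].to_numpy(float)
        elif tail == "both":
            sig = (delta > windows[hi_col].to_numpy(float)) | (
                delta < windows[lo_col].to_numpy(float)
            )
        else:
            raise ValueError(f"unknown tail {tail!r}")

    regions: list[CandidateRegion] = []
    for chrom in windows["chrom"].unique():
        mask = (windows["chrom"] == chrom).to_numpy() & sig
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        starts = windows["start"].to_numpy()
        ends = windows["end"].to_numpy()
        run = [idx[0]]
        for j in idx[1:]:
            gap = starts[j] - ends[run[-1]] - 1
            if gap <= spec.step_bp:
                run.append(j)
            else:
                regions.append(_make_region(windows, run, confidence, track))
                run = [j]
        regions.append(_make_region(windows, run, confidence, track))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _make_region(
    windows: pd.DataFrame, members: list[int], confidence: float, track: pd.DataFrame | None
) -> CandidateRegion:
    sub = windows.iloc[members]
    peak_local = int(np.nanargmax(np.abs(sub["mean_delta"].to_numpy(float))))
    peak = members[peak_local]
    start = int(sub["start"].min())
    end = int(sub["end"].max())
    chrom = str(sub["chrom"].iloc[0])
    region = CandidateRegion(
        chrom=chrom,
        start=start,
        end=end,
        peak_window=peak,
        window_indices=list(members),
        peak_delta=float(windows["mean_delta"].iloc[peak]),
        confidence=confidence,
    )
    if track is not None:
        sites = pass_sites(track)
        in_region = (
            (sites["chrom"] == chrom)
            & (sites["pos"] >= start)
            & (sites["pos"] <= end)
        )
        region.member_sites = sites.loc[in_region, "pos"].to_numpy(np.int64)
        region.n_sites = int(in_region.sum())
    return region


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Tabulate candidate regions for TSV output."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "span_bp": r.span_bp,
                "n_windows": len(r.window_indices),
                "n_sites": r.n_sites,
                "peak_delta": r.peak_delta,
                "confidence": r.confidence,
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "span_bp",
            "n_windows", "n_sites", "peak_delta", "confidence",
        ],
    )
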