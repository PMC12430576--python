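"""End-to-end orchestration: simulate -> phenotype -> bulks -> index -> scan -> regions -> genes.

A single configured run produces every artifact of the analysis (phenotype
table and summary, bulk membership, VCF, SNP-index track, window track with
confidence envelopes, candidate-region BED/TSV, candidate-gene report,
enrichment table, and the per-chromosome association plots), together with a
manifest of stage-wise record counts so the bookkeeping at each boundary is
auditable (sites read = kept + dropped, and so on).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, bsacore, phenotyping, simdata, variantio
from .bsacore import NullModel, WindowSpec
from .simdata import GenomeSpec, SimConfig

log = logging.getLogger("bulkseg")


@dataclass
class RunConfig:
    """Everything a run needs; ``mode`` is 'synthetic' or 'vcf'."""

    seed: int
    out_dir: str
    mode: str = "synthetic"
    sim: SimConfig | None = None
    genome: GenomeSpec | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    n_reps: int = 10_000
    confidence: float = 99.0
    min_index: float = 0.5
    min_depth: float = 5.0
    tail: str = "positive"
    bulk_by_rank: tuple[int, int] | None = None  # (n_high, n_low); else threshold rule
    vcf_path: str | None = None
    sample_roles: dict[str, str] | None = None
    effects_path: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "vcf"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic":
            if self.sim is None:
                self.sim = SimConfig(seed=self.seed)
            if self.genome is None:
                self.genome = GenomeSpec.default()
        elif self.vcf_path is None or self.sample_roles is None:
            raise ValueError("vcf mode needs vcf_path and sample_roles")

    def semantic_hash(self) -> str:
        """Hash of the semantic configuration (paths and output locations excluded)."""
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "window": dataclasses.asdict(self.window),
            "n_reps": self.n_reps,
            "confidence": self.confidence,
            "min_index": self.min_index,
            "min_depth": self.min_depth,
            "tail": self.tail,
            "bulk_by_rank": self.bulk_by_rank,
        }
        if self.sim is not None:
            sim = dataclasses.asdict(self.sim)
            sim["qtl_list"] = [dataclasses.asdict(q) for q in self.sim.qtl_list]
            sim["bulk_rule"] = dataclasses.asdict(self.sim.bulk_rule)
            payload["sim"] = sim
        if self.genome is not None:
            payload["genome"] = {
                c.name: (c.length_bp, c.map_length_morgans, len(self.genome.snp_positions[c.name]))
                for c in self.genome.chromosomes
            }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Stage-wise tallies for one run."""

    seed: int
    config_hash: str
    version: str
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in order; deterministic given the seed.

    Raises :class:`StageError` naming the failing stage on empty bulks,
    an empty pass-filter track, or zero informative sites.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed, config_hash=cfg.semantic_hash(), version=__version__)
    counts = manifest.counts

    if cfg.mode == "synthetic":
        genome, sim = cfg.genome, cfg.sim
        log.info("simulate: %d families, %d backcrosses", sim.n_families, sim.n_backcross)
        families, truth = simdata.simulate_population(genome, sim)
        counts["families"] = len(families)

        phen = simdata.simulate_phenotypes(families, sim)
        phenotyping.write_phenotypes(phen, out / "phenotypes.tsv")
        summaries = {
            "fiber_length_mm": phenotyping.summarize_trait(phen[phenotyping.LENGTH_COL]),
            "fiber_strength_cN_tex": phenotyping.summarize_trait(phen[phenotyping.STRENGTH_COL]),
        }
        phenotyping.summary_frame(summaries).to_csv(
            out / "phenotype_summary.tsv", sep="\t", index=False
        )
        for trait, s in summaries.items():
            ok, reasons = phenotyping.normality_screen(s)
            log.info("normality %s: %s %s", trait, "pass" if ok else "FAIL", reasons)

        if cfg.bulk_by_rank:
            assignment = phenotyping.select_extreme_by_rank(phen, *cfg.bulk_by_rank)
        else:
            assignment = phenotyping.select_bulks(phen, sim.bulk_rule)
        counts["bulk_high"] = len(assignment.high_ids)
        counts["bulk_low"] = len(assignment.low_ids)
        if not assignment.high_ids or not assignment.low_ids:
            raise StageError("select_bulks", "a bulk is empty; adjust rule or population")
        pd.DataFrame(
            [(fid, "HC1") for fid in assignment.high_ids]
            + [(fid, "HC2") for fid in assignment.low_ids],
            columns=["family_id", "bulk"],
        ).to_csv(out / "bulks.tsv", sep="\t", index=False)

        adt = simdata.simulate_bulk_reads(
            families, (assignment.high_ids, assignment.low_ids), genome, sim, truth
        )
        counts["sites_simulated"] = len(adt)
        truth.bulk_freq.to_csv(out / "truth.tsv", sep="\t", index=False)
        contigs = {c.name: c.length_bp for c in genome.chromosomes}
        variantio.write_vcf(adt, out / "variants.vcf", contigs)
        chrom_sizes = contigs
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {"seed": cfg.seed, "config_hash": manifest.config_hash, "mode": cfg.mode},
                fh,
            )
    else:
        adt, drops = variantio.read_vcf_allele_depths(cfg.vcf_path, cfg.sample_roles)
        counts["sites_kept"] = drops.pop("kept")
        for reason, n in drops.items():
            counts[f"dropped_{reason}"] = n
        counts["sites_read"] = counts["sites_kept"] + sum(drops.values())
        if counts["sites_kept"] == 0:
            raise StageError("read_vcf", "zero informative sites after polarization")
        chrom_sizes = None

    track = bsacore.compute_index_track(adt)
    track = bsacore.filter_sites(track, cfg.min_index, cfg.min_depth)
    counts["sites_total"] = len(track)
    for reason in bsacore.FILTER_REASONS:
        counts[f"filtered_{reason}"] = int((track["filter_status"] == reason).sum())
    counts["sites_pass"] = int((track["filter_status"] == bsacore.FILTER_PASS).sum())
    variantio.write_track_tsv(track, out / "snp_index_track.tsv")
    if counts["sites_pass"] == 0:
        raise StageError("filter_sites", "no sites pass the index/depth filters")

    null = NullModel(seed=cfg.seed, n_reps=cfg.n_reps)
    windows = bsacore.window_scan(bsacore.pass_sites(track), cfg.window, chrom_sizes)
    windows = bsacore.attach_null_thresholds(windows, null)
    counts["windows"] = len(windows)
    counts["windows_scored"] = int(windows["mean_delta"].notna().sum())
    counts["windows_significant"] = int(windows["significant_99"].sum())
    variantio.write_track_tsv(windows, out / "windows.tsv")

    regions = bsacore.call_regions(windows, cfg.window, cfg.confidence, cfg.tail, track)
    counts["regions"] = len(regions)
    bsacore.regions_frame(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    variantio.write_regions_bed(regions, out / "regions.bed")

    if cfg.mode == "synthetic":
        effects = simdata.simulate_effect_table(cfg.genome, cfg.seed)
        effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    elif cfg.effects_path:
        effects = annotate.read_effect_table(cfg.effects_path)
    else:
        effects = None
    if effects is not None and regions:
        report = annotate.genes_in_regions(regions, effects)
        report.sites_frame().to_csv(out / "candidate_sites.tsv", sep="\t", index=False)
        counts["candidate_sites"] = report.n_sites
        counts["candidate_genes"] = len(report.genes)
        if cfg.mode == "synthetic" and report.genes:
            background = sorted(set(effects["gene_id"]))
            gene2term, term_meta = simdata.simulate_term_map(background, cfg.seed)
            annotate.classify_terms(report.genes, gene2term, term_meta).to_csv(
                out / "term_classification.tsv", sep="\t", index=False
            )
            annotate.term_enrichment(report.genes, background, gene2term, term_meta).to_csv(
                out / "term_enrichment.tsv", sep="\t", index=False
            )

    if cfg.make_plots:
        plot_tracks(track, windows, out / "plots")

    manifest.to_json(out / "manifest.json")
    return manifest


def plot_tracks(track: pd.DataFrame, windows: pd.DataFrame, out_dir) -> list[Path]:
    """Per-chromosome association panels: index(HC1), index(HC2), Δ with envelopes.

    Three stacked rows (one per statistic), one column per chromosome; sites
    as points, window means as a red line, 95% envelope green and 99% orange
    on the Δ panel, whose y-limits are the full [−1, 1] domain.  Plotting is
    best-effort: failures are logged, never raised.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        chroms = list(dict.fromkeys(track["chrom"]))
        if not chroms:
            chroms = list(dict.fromkeys(windows["chrom"]))
        ncol = max(1, len(chroms))
        fig, axes = plt.subplots(
            3, ncol, figsize=(3.2 * ncol, 7.5), sharey="row", squeeze=False
        )
        panels = [("index_HC1", "SNP-index HC1"), ("index_HC2", "SNP-index HC2"), ("delta", "Δ(SNP-index)")]
        for j, chrom in enumerate(chroms):
            sites = track[(track["chrom"] == chrom) & (track["filter_status"] == "pass")]
            wins = windows[(windows["chrom"] == chrom) & windows["mean_delta"].notna()]
            mid = (wins["start"] + wins["end"]) / 2e6
            for i, (col, label) in enumerate(panels):
                ax = axes[i][j]
                ax.plot(sites["pos"] / 1e6, sites[col], ".", ms=2, color="0.6", alpha=0.5)
                ax.plot(mid, wins[f"mean_{col}"], color="red", lw=1.2)
                if col == "delta":
                    for bound, color in (("ci95", "green"), ("ci99", "orange")):
                        for side in ("low", "high"):
                            ax.plot(mid, wins[f"{bound}_{side}"], color=color, lw=0.8)
                    ax.set_ylim(-1, 1)
                else:
                    ax.set_ylim(0, 1)
                if i == 0:
                    ax.set_title(chrom)
                if i == 2:
                    ax.set_xlabel("Mb")
                if j == 0:
                    ax.set_ylabel(label)
        fig.tight_layout()
        path = out_dir / "association_panels.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover - plotting is best-effort
        log.exception("plotting failed; continuing")
    return written
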