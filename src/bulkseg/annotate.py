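"""Candidate-gene extraction and database-agnostic term enrichment.

Once candidate regions are called, the variant-effect table (gene and
functional class per SNP, e.g. from an upstream annotator) is intersected
with the regions to pull out the impactful coding sites — by default
nonsynonymous, stop-gain and stop-loss changes — and the genes carrying
them.  The resulting gene set can then be classified or tested for term
enrichment (GO-namespace or pathway style) against a user-supplied
gene-to-term map, without querying any live database.

Coordinates are 1-based inclusive throughout, matching VCF positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

EFFECT_CLASSES = frozenset(
    {
        "exonic_nonsynonymous",
        "exonic_synonymous",
        "stopgain",
        "stoploss",
        "intronic",
        "intergenic",
        "other",
    }
)

#: classes treated as candidate-relevant by default
IMPACT_CLASSES = frozenset({"exonic_nonsynonymous", "stopgain", "stoploss"})


@dataclass
class CandidateGeneReport:
    """Sites and genes inside the candidate regions, by functional class."""

    per_region: list[dict]  # {"chrom","start","end","sites": DataFrame}
    genes: tuple[str, ...]  # deduplicated, sorted
    class_counts: dict[str, int]
    n_sites: int

    def sites_frame(self) -> pd.DataFrame:
        frames = []
        for rec in self.per_region:
            df = rec["sites"].copy()
            df.insert(0, "region", f"{rec['chrom']}:{rec['start']}-{rec['end']}")
            frames.append(df)
        if not frames:
            return pd.DataFrame(
                columns=["region", "chrom", "pos", "gene_id", "effect_class"]
            )
        return pd.concat(frames, ignore_index=True)


def read_effect_table(path) -> pd.DataFrame:
    """Read an effect TSV with columns chrom, pos, gene_id, effect_class."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "pos", "gene_id", "effect_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    bad = set(df["effect_class"]) - EFFECT_CLASSES
    if bad:
        raise ValueError(f"unknown effect classes: {sorted(bad)}")
    return df


def genes_in_regions(
    regions,
    effects: pd.DataFrame,
    classes: frozenset[str] | set[str] = IMPACT_CLASSES,
) -> CandidateGeneReport:
    """Sites within any candidate region whose class is in ``classes``, by gene.

    ``regions`` is a list of objects with ``chrom``, ``start``, ``end``
    (1-based inclusive).  Returns per-region site lists, the deduplicated
    gene set, and per-class tallies over the whole call set.  The result is
    invariant to region order and to splitting a region into abutting halves.
    """
    unknown = set(classes) - EFFECT_CLASSES
    if unknown:
        raise ValueError(f"unknown effect classes requested: {sorted(unknown)}")
    per_region = []
    hit_frames = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        mask = (
            (effects["chrom"] == r.chrom)
            & (effects["pos"] >= r.start)
            & (effects["pos"] <= r.end)
            & effects["effect_class"].isin(classes)
        )
        sites = (
            effects.loc[mask, ["chrom", "pos", "gene_id", "effect_class"]]
            .drop_duplicates()
            .sort_values("pos", kind="stable")
            .reset_index(drop=True)
        )
        per_region.append(
            {"chrom": r.chrom, "start": r.start, "end": r.end, "sites": sites}
        )
        hit_frames.append(sites)
    if hit_frames:
        all_sites = pd.concat(hit_frames, ignore_index=True).drop_duplicates(
            ["chrom", "pos", "gene_id", "effect_class"]
        )
    else:
        all_sites = pd.DataFrame(columns=["chrom", "pos", "gene_id", "effect_class"])
    counts = all_sites["effect_class"].value_counts().to_dict()
    genes = tuple(sorted(set(all_sites["gene_id"])))
    return CandidateGeneReport(
        per_region=per_region,
        genes=genes,
        class_counts={k: int(v) for k, v in counts.items()},
        n_sites=int(len(all_sites)),
    )


def classify_terms(
    genes,
    gene2term: dict[str, set[str]],
    term_meta: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Tally how many of the given genes carry each term, grouped by namespace.

    This is annotation-style classification (bar-chart counts per BP/MF/CC or
    pathway namespace), the appropriate summary for a handful of candidate
    genes; no p-values are computed.
    """
    rows = []
    genes = set(genes)
    for term, (namespace, description) in term_meta.items():
        k = sum(1 for g in genes if term in gene2term.get(g, ()))
        if k:
            rows.append(
                {"term": term, "namespace": namespace, "description": description, "n_genes": k}
            )
    return (
        pd.DataFrame(rows, columns=["term", "namespace", "description", "n_genes"])
        .sort_values(["namespace", "n_genes", "term"], ascending=[True, False, True])
        .reset_index(drop=True)
    )


def term_enrichment(
    selected,
    background,
    gene2term: dict[str, set[str]],
    term_meta: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation test with Benjamini-Hochberg control.

    For each term annotated to at least one selected gene: with M background
    genes, m of them carrying the term, and K selected genes of which k carry
    it, p = P(X >= k) for X ~ Hypergeom(M, m, K).  Terms with k = 0 are not
    reported.  Rows are sorted by p.
    """
    selected = set(selected)
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    offenders = selected - background
    if offenders:
        raise ValueError(f"selected genes not in background: {sorted(offenders)[:10]}")
    term_genes: dict[str, set[str]] = {}
    for g in background:
        for t in gene2term.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    M, K = len(background), len(selected)
    rows = []
    for term, carriers in sorted(term_genes.items()):
        k = len(carriers & selected)
        if k == 0:
            continue
        m = len(carriers)
        p = float(hypergeom.sf(k - 1, M, m, K))
        row = {"term": term, "k": k, "K": K, "m": m, "M": M, "p": min(p, 1.0)}
        if term_meta and term in term_meta:
            row["namespace"], row["description"] = term_meta[term]
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "m", "M", "p", "q"])
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def read_term_map(
    gene2term_path, term_meta_path=None
) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]]]:
    """Read gene->term and term->metadata TSVs (columns gene_id/term, term/namespace/description)."""
    g2t = pd.read_csv(gene2term_path, sep="\t", dtype=str)
    gene2term: dict[str, set[str]] = {}
    for gene, term in zip(g2t["gene_id"], g2t["term"]):
        gene2term.setdefault(gene, set()).add(term)
    term_meta: dict[str, tuple[str, str]] = {}
    if term_meta_path is not None:
        meta = pd.read_csv(term_meta_path, sep="\t", dtype=str)
        for row in meta.itertuples(index=False):
            term_meta[row.term] = (row.namespace, getattr(row, "description", ""))
    referenced = {t for ts in gene2term.values() for t in ts}
    if term_meta:
        dangling = referenced - set(term_meta)
        if dangling:
            raise ValueError(f"terms missing from term table: {sorted(dangling)[:10]}")
    else:
        term_meta = {t: ("pathway", "") for t in sorted(referenced)}
    return gene2term, term_meta
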