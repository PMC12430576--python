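"""VCF / BED / TSV input-output with explicit coordinate and polarity conventions.

The pipeline consumes a multi-sample VCF carrying per-sample allele depths
(the ``AD`` FORMAT field) for the two parents and two bulks, and polarizes
every biallelic SNP so that the "donor allele" is the allele homozygous in
the donor parent and absent (up to a purity tolerance) in the recurrent
parent.  No assumption is made about which parent matches the reference
genome — polarity always comes from the parent genotypes, so REF may be
either allele.

Coordinates: VCF and the internal tables are 1-based inclusive; BED output is
0-based half-open, so a 1-based interval [s, e] becomes (s-1, e).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .simdata import SAMPLES

ROLES = ("recurrent_parent", "donor_parent", "bulk_high", "bulk_low")
_ROLE_TO_SAMPLE = dict(zip(ROLES, SAMPLES))

ADT_COLUMNS = ["chrom", "pos", "recurrent_allele", "donor_allele"] + [
    f"{s}_{a}" for s in SAMPLES for a in ("rec", "don")
]


def read_vcf_allele_depths(
    path,
    sample_roles: dict[str, str],
    parent_purity: float = 0.9,
    min_parent_depth: int = 1,
) -> tuple[pd.DataFrame, Counter]:
    """Read per-sample allele depths from a VCF and polarize by parent genotypes.

    Parameters
    ----------
    path : str
        VCF (plain or bgzipped); records must carry the AD FORMAT field.
    sample_roles : dict
        Maps VCF sample names onto the four roles ``recurrent_parent``,
        ``donor_parent``, ``bulk_high``, ``bulk_low``; all four required.
    parent_purity : float
        A parent is informative when its major allele holds at least this
        fraction of its reads; the two parents must be pure for opposite
        alleles, otherwise the site is dropped.

    Returns
    -------
    (table, drop_counter)
        The allele-depth table (one row per kept site, donor/recurrent read
        counts per sample, NaN where a bulk has no reads) and a counter of
        dropped records by reason, plus a ``kept`` entry.
    """
    from cyvcf2 import VCF

    missing_roles = set(ROLES) - set(sample_roles.values())
    if missing_roles:
        raise ValueError(f"sample_roles must cover all roles; missing {sorted(missing_roles)}")

    vcf = VCF(str(path))
    name_to_idx = {name: i for i, name in enumerate(vcf.samples)}
    unknown = set(sample_roles) - set(name_to_idx)
    if unknown:
        raise ValueError(f"samples not in VCF: {sorted(unknown)}")
    idx = {
        _ROLE_TO_SAMPLE[role]: name_to_idx[name] for name, role in sample_roles.items()
    }

    drops: Counter = Counter()
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            drops["multiallelic_or_indel"] += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"format error: record {var.CHROM}:{var.POS} has no AD field"
            )
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = np.nan  # cyvcf2 encodes missing as negative sentinels

        pr = ad[idx["Prec"], :2]
        pdn = ad[idx["Pdon"], :2]
        dp_rec, dp_don = np.nansum(pr), np.nansum(pdn)
        if dp_rec < min_parent_depth or dp_don < min_parent_depth or np.all(
            np.isnan(pr)
        ) or np.all(np.isnan(pdn)):
            drops["parent_missing"] += 1
            continue
        rec_major = int(np.nanargmax(pr))
        don_major = int(np.nanargmax(pdn))
        pur_rec = np.nan_to_num(pr[rec_major]) / dp_rec
        pur_don = np.nan_to_num(pdn[don_major]) / dp_don
        if pur_rec < parent_purity or pur_don < parent_purity:
            drops["parent_low_purity"] += 1
            continue
        if rec_major == don_major:
            drops["parents_same_allele"] += 1
            continue

        donor_col = don_major  # 0 = REF is the donor allele, 1 = ALT is
        alleles = (var.REF, var.ALT[0])
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "recurrent_allele": alleles[rec_major],
            "donor_allele": alleles[donor_col],
        }
        for sample in SAMPLES:
            pair = ad[idx[sample], :2]
            depth = np.nansum(pair)
            if depth <= 0 or np.all(np.isnan(pair)):
                row[f"{sample}_rec"] = np.nan
                row[f"{sample}_don"] = np.nan
            else:
                row[f"{sample}_don"] = float(np.nan_to_num(pair[donor_col]))
                row[f"{sample}_rec"] = float(np.nan_to_num(pair[1 - donor_col]))
        rows.append(row)
    drops["kept"] = len(rows)
    table = pd.DataFrame(rows, columns=ADT_COLUMNS)
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return table, drops


def write_vcf(table: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """Write an allele-depth table as a minimal VCF 4.2 with per-sample AD and DP.

    REF is written as the recurrent-parent allele and ALT as the donor allele;
    readers must not rely on that (polarization is re-derived from the parent
    samples on input).
    """
    sample_names = {"Prec": "P60", "Pdon": "P36", "HC1": "HC1", "HC2": "HC2"}
    lines = ["##fileformat=VCFv4.2", "##source=bulkseg"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names[s] for s in SAMPLES),
    ]
    for row in table.itertuples(index=False):
        fields = [
            str(row.chrom),
            str(int(row.pos)),
            ".",
            str(row.recurrent_allele),
            str(row.donor_allele),
            ".",
            "PASS",
            ".",
            "GT:AD:DP",
        ]
        for s in SAMPLES:
            rec = getattr(row, f"{s}_rec")
            don = getattr(row, f"{s}_don")
            if pd.isna(rec) or pd.isna(don):
                fields.append("./.:.,.:.")
            else:
                rec, don = int(rec), int(don)
                dp = rec + don
                if don == 0:
                    gt = "0/0"
                elif rec == 0:
                    gt = "1/1"
                else:
                    gt = "0/1"
                fields.append(f"{gt}:{rec},{don}:{dp}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def interval_to_bed(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to BED 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError("invalid 1-based interval")
    return start_1based - 1, end_1based


def write_regions_bed(regions, path) -> None:
    """Write candidate regions as BED6 (name = region id, score = max |delta| x 1000).

    Regions must be sorted by (chromosome, start); raises on unsorted input.
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (chromosome, start)")
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            bed_start, bed_end = interval_to_bed(r.start, r.end)
            score = int(np.clip(round(abs(r.peak_delta) * 1000), 0, 1000))
            fh.write(
                f"{r.chrom}\t{bed_start}\t{bed_end}\tregion_{i:02d}\t{score}\t.\n"
            )


def write_track_tsv(track: pd.DataFrame, path) -> None:
    """Write a site or window track as TSV (lossless float round trip)."""
    track.to_csv(path, sep="\t", index=False)


def read_track_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df
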