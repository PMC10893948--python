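"""Readers and writers for the panel's tabular interchange formats.

All TSVs carry a header line and encode missing values as "NA".  Variant
call sets travel as multi-sample VCF v4.2 with a GT:AD FORMAT (AD =
reference,alternate read depths), written as plain text and read back
through pysam.
"""

from __future__ import annotations

import pandas as pd
import pysam

__all__ = ["write_tsv", "read_tsv", "write_pair_map", "read_pair_map",
           "write_vcf", "read_vcf"]

PAIR_MAP_COLUMNS = ["pair_id", "gene_A", "chrom_A", "idx_A", "len_A_bp",
                    "gene_C", "chrom_C", "idx_C", "len_C_bp"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       **kwargs)


def write_pair_map(pair_map: pd.DataFrame, path) -> None:
    write_tsv(pair_map[PAIR_MAP_COLUMNS], path)


def read_pair_map(path) -> pd.DataFrame:
    pm = read_tsv(path)
    missing = set(PAIR_MAP_COLUMNS) - set(pm.columns)
    if missing:
        raise ValueError(f"pair map missing columns: {sorted(missing)}")
    return pm[PAIR_MAP_COLUMNS]


def write_vcf(calls: pd.DataFrame, sample_ids: list[str], contigs: dict[str, int],
              path: str) -> None:
    """Write per-sample calls as a multi-sample VCF v4.2.

    ``calls`` columns: chrom, pos, ref, alt, qual, sample_id, vad,
    total_depth (optional), gt (optional).  One VCF line per distinct
    (chrom, pos, ref, alt); samples without the call get ``./.``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Read depths for the ref and alt alleles">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    idx = {s: i for i, s in enumerate(sample_ids)}
    order = {name: i for i, name in enumerate(contigs)}
    grouped = calls.groupby(["chrom", "pos", "ref", "alt"], sort=False)
    keys = sorted(grouped.groups, key=lambda k: (order.get(k[0], 1 << 30), k[1]))
    for key in keys:
        chrom, pos, ref, alt = key
        grp = grouped.get_group(key)
        qual = f"{grp.qual.max():g}"
        fields = ["./.:.,."] * len(sample_ids)
        for r in grp.itertuples(index=False):
            total = int(getattr(r, "total_depth", r.vad * 2))
            gt = getattr(r, "gt", "0/1")
            fields[idx[r.sample_id]] = f"{gt}:{max(total - int(r.vad), 0)},{int(r.vad)}"
        lines.append("\t".join([chrom, str(int(pos)), ".", ref, alt, qual, ".",
                                ".", "GT:AD"] + fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> pd.DataFrame:
    """Read a VCF into per-sample call rows (multi-allelic sites split).

    Returns columns chrom, pos, ref, alt, qual, sample_id, vad,
    total_depth, gt for every sample genotype that carries the alternate
    allele.
    """
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                for sample_id, sd in rec.samples.items():
                    gt = sd.get("GT")
                    if gt is None or all(g in (None, 0) for g in gt):
                        continue
                    if ai not in gt:
                        continue
                    ad = sd.get("AD")
                    vad = int(ad[ai]) if ad is not None and ad[ai] is not None else 0
                    total = sum(int(x) for x in ad if x is not None) if ad else vad
                    gt_str = "/".join("." if g is None else str(g) for g in gt)
                    rows.append((rec.chrom, rec.pos, rec.ref, alt,
                                 float(rec.qual) if rec.qual is not None else 0.0,
                                 sample_id, vad, total, gt_str))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual",
                                       "sample_id", "vad", "total_depth", "gt"])
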