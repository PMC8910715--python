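"""Readers and writers for the pipeline's file formats.

Native tables are plain TSV with documented headers; intervals are also
emitted as BED (0-based half-open, per the standard — internal coordinates
stay 1-based inclusive).  Allele depths can come from the native TSV or from
a VCF with per-sample AD fields (read via pysam); which parent matches REF
is declared by the caller, since M/P orientation depends on the parental
genotypes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bsa import CandidateInterval

DEPTH_COLUMNS = ["chrom", "pos", "ref", "alt", "M_tall", "P_tall", "M_dwarf", "P_dwarf", "missing"]


# ---------------------------------------------------------------------------
# allele depths
# ---------------------------------------------------------------------------


def write_allele_depths(records: pd.DataFrame, path) -> None:
    records.loc[:, DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_depths(path, fmt: str | None = None, **kw) -> pd.DataFrame:
    """Read allele depths from native TSV or VCF (by extension unless given)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return read_vcf_depths(path, **kw)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"allele-depth table missing columns: {missing_cols}")
    df["missing"] = df["missing"].astype(bool)
    if not df.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing).all():
        import warnings

        warnings.warn("input not position-sorted; sorting", stacklevel=2)
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


def write_vcf_depths(
    records: pd.DataFrame, path, tall_sample: str = "tall_bulk", dwarf_sample: str = "dwarf_bulk"
) -> None:
    """Minimal uncompressed VCF with per-bulk AD (REF = maternal allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in records["chrom"].unique():
            length = int(records.loc[records["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tall_sample}\t{dwarf_sample}\n"
        )
        for r in records.itertuples(index=False):
            ad_t = f"{r.M_tall},{r.P_tall}"
            ad_d = f"{r.M_dwarf},{r.P_dwarf}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{ad_t}\t./.:{ad_d}\n"
            )


def read_vcf_depths(
    path,
    tall_sample: str = "tall_bulk",
    dwarf_sample: str = "dwarf_bulk",
    maternal_is_ref: bool = True,
) -> pd.DataFrame:
    """Per-bulk M/P depths from a VCF's AD fields.

    ``maternal_is_ref`` states which parent the reference allele belongs to;
    with False, REF and ALT depths swap roles.  Sites with absent AD are
    flagged missing.
    """
    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (tall_sample, dwarf_sample):
            if s not in samples:
                raise ValueError(f"sample {s!r} not in VCF ({samples})")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # biallelic only
            ad_t = rec.samples[tall_sample].get("AD")
            ad_d = rec.samples[dwarf_sample].get("AD")
            miss = (
                ad_t is None
                or ad_d is None
                or any(a is None for a in ad_t)
                or any(a is None for a in ad_d)
            )
            if miss:
                mt = pt = md = pd_ = 0
            else:
                rt, at = int(ad_t[0]), int(ad_t[1])
                rd, ad = int(ad_d[0]), int(ad_d[1])
                if maternal_is_ref:
                    mt, pt, md, pd_ = rt, at, rd, ad
                else:
                    mt, pt, md, pd_ = at, rt, ad, rd
            rows.append(
                (rec.chrom, rec.pos, rec.ref, rec.alts[0], mt, pt, md, pd_, bool(miss))
            )
    df = pd.DataFrame(rows, columns=DEPTH_COLUMNS)
    df["missing"] = df["missing"] | (
        (df["M_tall"] + df["P_tall"] == 0) | (df["M_dwarf"] + df["P_dwarf"] == 0)
    )
    return df


# ---------------------------------------------------------------------------
# tracks, intervals, gene models
# ---------------------------------------------------------------------------


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values="NA")


def write_intervals(intervals: list[CandidateInterval], path) -> None:
    """Native interval TSV (1-based inclusive)."""
    pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.n_snps, iv.peak_delta) for iv in intervals],
        columns=["chrom", "start", "end", "n_snps", "peak_delta"],
    ).to_csv(path, sep="\t", index=False)


def read_intervals(path) -> list[CandidateInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CandidateInterval(r.chrom, int(r.start), int(r.end), int(r.n_snps), float(r.peak_delta))
        for r in df.itertuples(index=False)
    ]


def write_intervals_bed(intervals: list[CandidateInterval], path) -> None:
    """BED export: 0-based half-open, so start-1 .. end."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tdelta_peak={iv.peak_delta:.4f}\n")


def read_intervals_bed(path) -> list[tuple[str, int, int]]:
    """BED input converted to 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_gene_models(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene_id", "chrom", "start", "end", "length"}
    if not need <= set(df.columns):
        raise ValueError(f"gene model table must have columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# counts, hormones, qPCR
# ---------------------------------------------------------------------------


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).to_numpy())
    out.to_csv(path, sep="\t")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("count table needs a 'length' column")
    lengths = df.pop("length")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return df.astype(np.int64), lengths


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_hormone_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"compound", "class", "group", "replicate", "concentration"}
    if not need <= set(df.columns):
        raise ValueError(f"hormone panel must have columns {sorted(need)}")
    return df


def read_qpcr(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"gene_id", "group", "replicate", "ct_target", "ct_reference"}
    if not need <= set(df.columns):
        raise ValueError(f"qPCR table must have columns {sorted(need)}")
    return df
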