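"""Readers and writers for the pipeline's on-disk formats.

Fixture bundles are plain text: FASTA reference, VCF v4.2 sites file,
and TSV tables (long-format counts, read metrics, sample metadata,
simulation truth).  Reading goes through pysam (VCF) and pyfaidx (FASTA).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

from .containers import VariantCounts, validate_metadata


def write_fasta(reference: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_sites_vcf(info: pd.DataFrame, path, contigs: dict[str, int] | None = None) -> None:
    """Write a sites-only VCF v4.2 with variant_id and class in INFO."""
    info = info.sort_values(["chrom", "pos", "variant_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VID,Number=1,Type=String,Description="Variant identifier">\n')
        fh.write('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SBS or ID)">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in info["chrom"].unique():
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in info.itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\tVID={row.variant_id};VC={row.variant_class}\n"
            )


def read_sites_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                dict(
                    variant_id=rec.info["VID"],
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    variant_class=rec.info["VC"],
                )
            )
    return pd.DataFrame(rows)


def write_counts_tsv(counts: VariantCounts, path) -> None:
    """Long-format counts: variant_id, sample_id, alt, depth."""
    alt = counts.alt.stack()
    depth = counts.depth.stack()
    long = pd.DataFrame({"alt": alt, "depth": depth}).reset_index()
    long.columns = ["variant_id", "sample_id", "alt", "depth"]
    long.to_csv(path, sep="\t", index=False)


def read_counts_tsv(counts_path, sites_path) -> VariantCounts:
    """Rebuild a VariantCounts from a long-format TSV plus a sites VCF."""
    info = read_sites_vcf(sites_path)
    long = pd.read_csv(counts_path, sep="\t")
    alt = long.pivot(index="variant_id", columns="sample_id", values="alt")
    depth = long.pivot(index="variant_id", columns="sample_id", values="depth")
    info = info.set_index("variant_id").loc[alt.index].reset_index()
    alt.columns.name = depth.columns.name = None
    return VariantCounts(info, alt, depth)


def write_fixture(bundle, out_dir) -> dict[str, Path]:
    """Write a complete cohort bundle; returns the paths written."""
    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    validate_metadata(bundle.metadata)
    paths = {
        "reference": out / "reference.fa",
        "sites": out / "variants.vcf",
        "counts": out / "counts.tsv",
        "metrics": out / "metrics.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(bundle.reference, paths["reference"])
    contigs = {name: len(seq) for name, seq in bundle.reference.items()}
    write_sites_vcf(bundle.counts.info, paths["sites"], contigs)
    write_counts_tsv(bundle.counts, paths["counts"])
    bundle.metrics.to_csv(paths["metrics"], sep="\t", index=False)
    bundle.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    bundle.truth.mutations.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_fixture(out_dir):
    """Round-trip reader for :func:`write_fixture` outputs."""
    out = Path(out_dir)
    counts = read_counts_tsv(out / "counts.tsv", out / "variants.vcf")
    metrics = pd.read_csv(out / "metrics.tsv", sep="\t")
    metadata = pd.read_csv(out / "metadata.tsv", sep="\t")
    truth = pd.read_csv(out / "truth.tsv", sep="\t", keep_default_na=False)
    reference = read_fasta(out / "reference.fa")
    return counts, metrics, metadata, truth, reference
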