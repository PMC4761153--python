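"""Readers and writers: GeneTable TSV pair, VCF + class BED, run manifests.

Coordinates are 0-based half-open internally; 1-based only at the VCF
boundary. TSVs are tab-delimited with a header row and '.' for undefined
statistics. Every randomized output can be accompanied by a JSON manifest
(config hash, seed, input checksums) so deterministic stages reproduce
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .sweep import GENE_COLUMNS, GeneTable

logger = logging.getLogger("sfsweep")

__all__ = [
    "SchemaError",
    "read_gene_table",
    "write_gene_table",
    "read_vcf_biallelic",
    "write_vcf_bed",
    "read_class_bed",
    "write_tsv",
    "write_manifest",
    "DNDS_FILTER_MAX",
]

DNDS_FILTER_MAX = 0.8  # genes with dN > 0.8 or dS > 0.8 are excluded at load
SNV_KEY_COLUMNS = ["gene_id", "pos", "site_class"]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_gene_table(table: GeneTable, genes_path: str | Path, snv_path: str | Path) -> None:
    """Write the TSV pair: gene summaries and SNVs (wide dosage columns)."""
    write_tsv(table.genes, genes_path)
    snv = table.snv.copy()
    dos = pd.DataFrame(table.dosages, columns=table.samples, index=snv.index)
    write_tsv(pd.concat([snv, dos], axis=1), snv_path)


def read_gene_table(
    genes_path: str | Path, snv_path: str | Path, apply_filter: bool = True
) -> GeneTable:
    """Load the TSV pair; by default applies the dN/dS > 0.8 exclusion
    (maximum-likelihood divergence above 0.8 is unreliable)."""
    genes = pd.read_csv(genes_path, sep="\t")
    if genes.empty:
        raise SchemaError(f"{genes_path}: no gene rows")
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise SchemaError(f"{genes_path}: missing columns {missing}")
    snv = pd.read_csv(snv_path, sep="\t")
    missing = [c for c in SNV_KEY_COLUMNS if c not in snv.columns]
    if missing:
        raise SchemaError(f"{snv_path}: missing columns {missing}")
    samples = [c for c in snv.columns if c not in SNV_KEY_COLUMNS]
    if apply_filter:
        keep = (genes["dN"] <= DNDS_FILTER_MAX) & (genes["dS"] <= DNDS_FILTER_MAX)
        n_drop = int((~keep).sum())
        genes = genes[keep].reset_index(drop=True)
        if genes.empty:
            raise SchemaError("no genes retained after the dN/dS filter")
        snv_keep = snv["gene_id"].isin(set(genes["gene_id"])).to_numpy()
        snv = snv[snv_keep].reset_index(drop=True)
        logger.info(
            "gene table: retained %d genes (%d excluded by dN/dS > %.1f)",
            len(genes), n_drop, DNDS_FILTER_MAX,
        )
    dosages = snv[samples].to_numpy(dtype=np.int8) if samples else np.zeros(
        (len(snv), 0), dtype=np.int8
    )
    return GeneTable(
        genes=genes,
        snv=snv[SNV_KEY_COLUMNS].reset_index(drop=True),
        dosages=dosages,
        samples=samples,
    )


def write_vcf_bed(table: GeneTable, vcf_path: str | Path, bed_path: str | Path) -> None:
    """Minimal VCF 4.2 (GT only, one contig per gene) plus a BED of site
    classes (0-based half-open)."""
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for gid in table.genes["gene_id"]:
            vcf.write(f"##contig=<ID={gid}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(table.samples))
        vcf.write(cols + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for row_i, rec in enumerate(table.snv.itertuples(index=False)):
            gts = "\t".join(gt_codes[int(d)] for d in table.dosages[row_i])
            vcf.write(f"{rec.gene_id}\t{rec.pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    with open(bed_path, "w") as bed:
        for rec in table.snv.itertuples(index=False):
            bed.write(f"{rec.gene_id}\t{rec.pos}\t{rec.pos + 1}\t{rec.site_class}\n")


def read_vcf_biallelic(
    path: str | Path, sample_subset: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read bi-allelic SNVs from a VCF.

    Returns (dosages, sites, samples): dosages is sites x samples with
    alternate-allele counts 0/1/2 and NaN for missing calls; multi-allelic
    and non-SNV records are dropped (counted in the log). Positions are
    converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=sample_subset)
    samples = list(vcf.samples)
    rows, recs, dropped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            dropped += 1
            continue
        gts = var.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        rows.append(gts.sum(axis=1))
        recs.append({"chrom": var.CHROM, "pos": var.POS - 1, "ref": var.REF, "alt": var.ALT[0]})
    if dropped:
        logger.info("%s: dropped %d non-bi-allelic/non-SNV records", path, dropped)
    dosages = np.vstack(rows) if rows else np.zeros((0, len(samples)))
    return dosages, pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"]), samples


def read_class_bed(path: str | Path) -> pd.DataFrame:
    """BED of per-site functional classes: chrom, start, end, site_class."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "site_class"]
    )
    if bed.empty:
        raise SchemaError(f"{path}: empty BED")
    return bed


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int | None = None,
    inputs: list[str | Path] = (),
) -> dict:
    """JSON sidecar: config hash, seed, package versions, input checksums."""
    import scipy

    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "seed": seed,
        "versions": {
            "sfsweep": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "inputs": {str(p): _checksum(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
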