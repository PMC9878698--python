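"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as biallelic GT-only VCF v4.2 (parsed with pysam) or as a
plain dosage TSV (SNP metadata columns followed by one 0/1/2 column per
accession).  Gene annotations come as BED6 (0-based half-open, converted to
1-based inclusive on read) or GFF3-lite ``gene`` features (taken as-is).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .association import GeneAnnotation, GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_annotations",
    "write_annotations_bed",
]

logger = logging.getLogger("phenotray")

_DOSAGE_META = ["chrom", "pos", "ref", "alt"]


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a biallelic genotype matrix from VCF or dosage TSV.

    Multiallelic VCF records are skipped (count logged); non-diploid GT
    calls are an error.  Accession (sample) order is preserved.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError("VCF has no sample columns")
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        dos = np.empty(len(samples))
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                dos[i] = np.nan
                continue
            if len(gt) != 2:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos} sample {s}: ploidy {len(gt)} != 2"
                )
            if any(a is None for a in gt):
                dos[i] = np.nan
            else:
                dos[i] = sum(gt)
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(alts[0])
        rows.append(dos)
    vf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    G = GenotypeMatrix(
        samples=samples,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosage=np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0)),
    )
    G.n_multiallelic_skipped = n_multi
    return G


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ValueError(f"malformed dosage TSV: missing columns {missing}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    dosage = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(
        samples=samples,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        dosage=dosage,
    )


def write_genotypes(G: GenotypeMatrix, path, format: str = "tsv") -> None:
    """Write a genotype matrix as dosage TSV or minimal GT-only VCF v4.2.

    The TSV layout round-trips losslessly through :func:`read_genotypes`.
    """
    if format == "tsv":
        df = pd.DataFrame(
            {
                "chrom": G.chrom,
                "pos": G.pos,
                "ref": G.ref,
                "alt": G.alt,
            }
        )
        dos = pd.DataFrame(G.dosage.T, columns=G.samples)
        # integers where calls are present, empty where missing
        dos = dos.map(lambda v: "" if np.isnan(v) else str(int(v)))
        pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(G, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(G: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in pd.unique(np.asarray(G.chrom)):
            fh.write(f"##contig=<ID={ch}>\n")
        cols = "\t".join(
            ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        )
        fh.write(cols + "\t" + "\t".join(G.samples) + "\n")
        for j in range(G.n_snps):
            calls = [
                "./." if np.isnan(v) else _GT_CODE[int(v)] for v in G.dosage[:, j]
            ]
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t.\t{G.ref[j]}\t{G.alt[j]}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_annotations(path, format: str = "bed") -> list:
    """Load gene annotations from BED6 or GFF3-lite as 1-based intervals."""
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_bed(path) -> list:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 4 fields")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}:{ln}: invalid BED interval {start0}-{end0}")
            genes.append(
                GeneAnnotation(
                    gene_id=name, chrom=chrom, start=start0 + 1, end=end0, strand=strand
                )
            )
    return genes


def _read_gff3(path) -> list:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line has fewer than 9 fields")
            chrom, _src, feature, start, end, _score, strand, _phase, attrs = parts[:9]
            if feature != "gene":
                continue
            start, end = int(start), int(end)
            if end < start or start < 1:
                raise ValueError(f"{path}:{ln}: invalid GFF3 interval {start}-{end}")
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                elif kv.startswith("Name=") and gene_id is None:
                    gene_id = kv[5:]
            if gene_id is None:
                gene_id = f"gene_{ln}"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                )
            )
    return genes


def write_annotations_bed(genes, path) -> None:
    """Write gene annotations as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n"
            )
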