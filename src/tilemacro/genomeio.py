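"""Readers and writers for the plain-text formats the pipeline exchanges.

BED3/BED6 (tab-delimited, no header, 0-based half-open), GFF3 gene models
(1-based closed on disk, converted to 0-based half-open on read), two-column
chromosome-sizes TSV, and the probe-table TSV produced by the synthetic-data
generator.
"""

from __future__ import annotations

import os
import tempfile
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    empty_intervals,
    intervals,
    validate_intervals,
)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3/BED6. Returns an interval frame (extra columns kept if present)."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return empty_intervals()
    ncol = min(raw.shape[1], 6)
    raw = raw.iloc[:, :ncol]
    raw.columns = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    raw["chrom"] = raw["chrom"].astype(str)
    raw = raw.astype({"start": np.int64, "end": np.int64})
    return validate_intervals(raw, os.path.basename(path))


def write_bed(df: pd.DataFrame, path: str) -> None:
    """Write BED3 or BED6 depending on the columns present (no header)."""
    cols = ["chrom", "start", "end"]
    if {"name", "score", "strand"}.issubset(df.columns):
        cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(r.chrom): int(r.size) for r in df.itertuples(index=False)}


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


PROBE_META_COLS = ["probe_id", "chrom", "start", "length", "gc"]


def read_probe_table(path: str) -> pd.DataFrame:
    """Probe TSV: probe_id, chrom, start, length, gc, one column per condition."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_probe_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def condition_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c not in PROBE_META_COLS]


def read_gff3_genes(path: str, name: str = "gff3") -> AnnotationSet:
    """Read gene models (gene/transcript/exon/CDS) from GFF3 into an AnnotationSet.

    A gene is considered protein coding when any of its descendants is a CDS
    feature; its exons become ``coding_exon``, other genes' exons become
    ``noncoding_exon``.  TSS and terminus are strand-aware single-nucleotide
    intervals of coding genes.  Coordinates are converted to 0-based half-open.
    """
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbfn = tmp.name
    try:
        db = gffutils.create_db(
            path, dbfn=dbfn, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes, coding_exons, noncoding_exons, tss, term = [], [], [], [], []
        for gene in db.features_of_type("gene"):
            g = (str(gene.seqid), gene.start - 1, gene.end, gene.id, 0,
                 gene.strand or ".")
            genes.append(g)
            has_cds = any(True for _ in db.children(gene, featuretype="CDS"))
            exon_rows = [
                (str(ex.seqid), ex.start - 1, ex.end, gene.id, 0, ex.strand or ".")
                for ex in db.children(gene, featuretype="exon")
            ]
            (coding_exons if has_cds else noncoding_exons).extend(exon_rows)
            if has_cds:
                chrom, s, e, strand = str(gene.seqid), gene.start - 1, gene.end, gene.strand
                five = s if strand != "-" else e - 1
                three = e - 1 if strand != "-" else s
                tss.append((chrom, five, five + 1, gene.id, 0, strand or "."))
                term.append((chrom, three, three + 1, gene.id, 0, strand or "."))
    finally:
        if os.path.exists(dbfn):
            os.unlink(dbfn)

    return AnnotationSet(
        name=name,
        features={
            "gene_body": intervals(genes),
            "coding_exon": intervals(coding_exons) if coding_exons else empty_intervals(),
            "noncoding_exon": intervals(noncoding_exons) if noncoding_exons else empty_intervals(),
            "tss": intervals(tss) if tss else empty_intervals(),
            "terminus": intervals(term) if term else empty_intervals(),
        },
    )


def write_gff3_genes(genes: pd.DataFrame, exons: pd.DataFrame, path: str) -> None:
    """Write a minimal GFF3 gene model (gene + one transcript + exons [+ CDS]).

    ``genes`` needs chrom/start/end/gene_id/strand and a boolean ``coding``
    column; ``exons`` needs chrom/start/end/gene_id.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\ttilemacro\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gid}\n"
            )
            fh.write(
                f"{g.chrom}\ttilemacro\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            gene_exons = exons[exons["gene_id"] == gid]
            for i, ex in enumerate(gene_exons.itertuples(index=False)):
                fh.write(
                    f"{ex.chrom}\ttilemacro\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f"ID={gid}.e{i + 1};Parent={gid}.t1\n"
                )
                if getattr(g, "coding", True):
                    fh.write(
                        f"{ex.chrom}\ttilemacro\tCDS\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t0\t"
                        f"ID={gid}.c{i + 1};Parent={gid}.t1\n"
                    )
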