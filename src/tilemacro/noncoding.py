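"""Reduce segments to bona fide non-coding intervals and classify them.

The filter removes, in order: (i) nucleotides overlapping coding or
pseudogene exons; (ii) nucleotides overlapping significant coding-potential
segments (RNAcode P < 0.05, supplied precomputed); (iii) among nucleotides
RNAcode could not evaluate, those with protein similarity (tblastn e < 0.05,
supplied precomputed); then (iv) discards surviving intervals shorter than a
minimum length — 17 nt by default, the size of the smallest described human
ncRNA species.  Survivors are classified as intergenic (no gene-body
overlap) or intronic (inside a gene body, no coding-exon overlap).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    CoverageIndex,
    empty_intervals,
    merge_intervals,
    subtract_intervals,
)

EVIDENCE_LAYERS = (
    "coding_exons",
    "pseudogene_exons",
    "rnacode_hits",
    "rnacode_covered",
    "tblastn_hits",
)


@dataclasses.dataclass
class CodingEvidence:
    """Precomputed coding-evidence interval layers.

    Empty frames are legal "no evidence" inputs; a missing (None) layer is an
    error so silently dropped evidence cannot go unnoticed.
    ``rnacode_hits`` must lie within ``rnacode_covered`` (the regions RNAcode
    could evaluate at all).
    """

    coding_exons: pd.DataFrame
    pseudogene_exons: pd.DataFrame
    rnacode_hits: pd.DataFrame
    rnacode_covered: pd.DataFrame
    tblastn_hits: pd.DataFrame

    def __post_init__(self) -> None:
        for layer in EVIDENCE_LAYERS:
            if getattr(self, layer) is None:
                raise ValueError(f"missing coding-evidence layer {layer!r}")
        hits = merge_intervals(self.rnacode_hits)
        if len(hits):
            outside = subtract_intervals(hits, self.rnacode_covered)
            if len(outside):
                raise ValueError(
                    "rnacode_hits extend outside rnacode_covered "
                    f"(e.g. {outside.iloc[0].to_dict()})"
                )

    @classmethod
    def empty(cls) -> "CodingEvidence":
        return cls(*(empty_intervals() for _ in EVIDENCE_LAYERS))


def classify_relative_to_genes(
    interval_df: pd.DataFrame, annotation: AnnotationSet
) -> np.ndarray:
    """Class per interval: intergenic / intronic / exon_overlapping.

    intergenic: zero gene-body overlap.  exon_overlapping: any coding-exon
    overlap.  intronic: inside a gene body with no coding-exon overlap.
    Gene-boundary straddlers without exon overlap are assigned the class
    covering the majority of their nucleotides; ties go to intronic.
    """
    genes = CoverageIndex(annotation.get("gene_body"))
    exons = CoverageIndex(annotation.get("coding_exon"))
    chroms = interval_df["chrom"].to_numpy()
    starts = interval_df["start"].to_numpy()
    ends = interval_df["end"].to_numpy()
    lengths = ends - starts
    gene_cov = genes.overlap_many(chroms, starts, ends)
    exon_cov = exons.overlap_many(chroms, starts, ends)
    out = np.where(
        exon_cov > 0,
        "exon_overlapping",
        np.where(
            gene_cov == 0,
            "intergenic",
            # straddlers resolved by majority nucleotide, ties -> intronic
            np.where(gene_cov * 2 >= lengths, "intronic", "intergenic"),
        ),
    )
    return out


def bona_fide_filter(
    segments: pd.DataFrame,
    evidence: CodingEvidence,
    annotation: AnnotationSet,
    min_len: int = 17,
) -> pd.DataFrame:
    """Apply the four-step bona fide non-coding filter.

    Returns surviving intervals with a ``klass`` column in
    {intergenic, intronic}; exon-overlapping nucleotides cannot survive step
    (i), so straddler resolution only ever yields those two classes.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    x = merge_intervals(segments, "segments")
    # (i) coding + pseudogene exon nucleotides
    exonic = pd.concat(
        [evidence.coding_exons, evidence.pseudogene_exons], ignore_index=True
    )
    x = subtract_intervals(x, exonic)
    # (ii) predicted coding segments
    x = subtract_intervals(x, evidence.rnacode_hits)
    # (iii) protein similarity, but only where RNAcode could not evaluate
    tblastn_uncovered = subtract_intervals(
        evidence.tblastn_hits, evidence.rnacode_covered
    )
    x = subtract_intervals(x, tblastn_uncovered)
    # (iv) minimum length
    if len(x):
        x = x[(x["end"] - x["start"]) >= min_len].reset_index(drop=True)
    if len(x) == 0:
        out = empty_intervals()
        out["klass"] = pd.Series(dtype=str)
        return out
    x = x.copy()
    x["klass"] = classify_relative_to_genes(x, annotation)
    # exon-overlapping survivors are impossible when the evidence includes the
    # annotation's coding exons; classify defensively anyway
    x.loc[x["klass"] == "exon_overlapping", "klass"] = "intronic"
    return x
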