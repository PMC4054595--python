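"""Reduce DE-TARs to bona fide non-coding intervals.

Subtracts coding-exon nucleotides (and, when provided, RNAcode hits and
tblastn similarity outside RNAcode coverage), discards remnants below 17 nt
and classifies survivors as intergenic or intronic.  Reads
results/01_simulate/genes.gff3 and results/02_segment/detars.bed; writes
results/03_filter/bona_fide_noncoding.bed with the class in the name field.
"""

import argparse
import os

from tilemacro.genomeio import read_bed, read_gff3_genes, write_bed
from tilemacro.intervals import empty_intervals
from tilemacro.noncoding import CodingEvidence, bona_fide_filter

OUT = os.path.join("results", "03_filter")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--min-len", type=int, default=17)
    ap.add_argument("--rnacode-hits", default=None)
    ap.add_argument("--rnacode-covered", default=None)
    ap.add_argument("--tblastn", default=None)
    args = ap.parse_args()
    os.makedirs(OUT, exist_ok=True)

    ann = read_gff3_genes("results/01_simulate/genes.gff3")
    detars = read_bed("results/02_segment/detars.bed")
    load = lambda p: read_bed(p) if p else empty_intervals()
    evidence = CodingEvidence(
        coding_exons=ann.get("coding_exon"),
        pseudogene_exons=empty_intervals(),
        rnacode_hits=load(args.rnacode_hits),
        rnacode_covered=load(args.rnacode_covered),
        tblastn_hits=load(args.tblastn),
    )
    bona = bona_fide_filter(detars[["chrom", "start", "end"]]
                            if len(detars) else empty_intervals(),
                            evidence, ann, args.min_len)
    path = f"{OUT}/bona_fide_noncoding.bed"
    if len(bona):
        write_bed(bona.assign(name=bona["klass"], score=0, strand=".")[
            ["chrom", "start", "end", "name", "score", "strand"]], path)
    else:
        open(path, "w").close()

    nt = int((bona["end"] - bona["start"]).sum()) if len(bona) else 0
    by_class = bona["klass"].value_counts().to_dict() if len(bona) else {}
    print(f"bona fide non-coding: {len(bona)} intervals, {nt:,} nt "
          f"({by_class})")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
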