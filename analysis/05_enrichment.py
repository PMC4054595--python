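"""Annotation-overlap enrichment of the bona fide non-coding intervals.

Samples randomized background interval lists with the query's length
distribution (excluding repeats and gaps), computes observed-vs-background
odds ratios per annotation and tests them with Fisher's exact test.  Writes
results/05_enrichment/enrichment.tsv.
"""

import argparse
import os

import pandas as pd

from tilemacro.enrichment import enrichment_report
from tilemacro.genomeio import read_bed, read_chrom_sizes, read_gff3_genes
from tilemacro.intervals import empty_intervals, merge_intervals

OUT = os.path.join("results", "05_enrichment")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-backgrounds", type=int, default=100)
    args = ap.parse_args()
    os.makedirs(OUT, exist_ok=True)

    query = read_bed("results/03_filter/bona_fide_noncoding.bed")
    if len(query) == 0:
        print("no bona fide non-coding intervals; nothing to test")
        return
    ann = read_gff3_genes("results/01_simulate/genes.gff3")
    sizes = read_chrom_sizes("results/01_simulate/chrom.sizes")
    repeats = read_bed("results/01_simulate/repeats.bed")
    gaps = read_bed("results/01_simulate/gaps.bed")
    space = pd.DataFrame({"chrom": list(sizes), "start": 0,
                          "end": list(sizes.values())})
    exclusions = merge_intervals(pd.concat([repeats, gaps], ignore_index=True)) \
        if len(repeats) + len(gaps) else empty_intervals()
    annotations = {
        "gene_body": ann.get("gene_body")[["chrom", "start", "end"]],
        "coding_exon": ann.get("coding_exon"),
        "noncoding_exon": ann.get("noncoding_exon"),
    }
    annotations = {k: v for k, v in annotations.items() if len(v)}
    report = enrichment_report(query[["chrom", "start", "end"]], annotations,
                               space, exclusions,
                               n_backgrounds=args.n_backgrounds,
                               seed=args.seed)
    report.to_csv(f"{OUT}/enrichment.tsv", sep="\t", index=False)
    cols = ["annotation", "ov_obs", "n_obs", "ov_bg_mean", "odds_ratio",
            "log2_odds_ratio", "p", "stars"]
    print(report[cols].to_string(index=False))
    print(f"wrote {OUT}/enrichment.tsv")


if __name__ == "__main__":
    main()
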