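"""Generate the study's synthetic dataset: genome, planted truth, probe table.

Writes results/01_simulate/: the genome annotation (GFF3 + BED), the tiled
probe table with per-condition log2 intensities, the planted truth (expressed,
differential, macroRNA), and the synthetic reference-platform calls.
"""

import argparse
import dataclasses
import os

import pandas as pd

from tilemacro import synth
from tilemacro.genomeio import (
    write_bed,
    write_chrom_sizes,
    write_gff3_genes,
    write_probe_table,
)

OUT = os.path.join("results", "01_simulate")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    os.makedirs(OUT, exist_ok=True)

    genome = synth.generate_genome(synth.GenomeConfig(), args.seed)
    truth = synth.make_truth(genome, synth.TruthConfig(), args.seed + 1)
    probes = synth.generate_probes(genome, seed=args.seed + 2)
    probes = synth.simulate_intensities(probes, truth, seed=args.seed + 3)
    contrast = tuple(truth.conditions()[:2])
    positions = probes.assign(end=probes["start"] + probes["length"])
    reference = synth.generate_reference_platform(
        truth, contrast, positions, flip_rate=0.0, seed=args.seed + 4
    )

    write_chrom_sizes(genome.chrom_sizes, f"{OUT}/chrom.sizes")
    write_gff3_genes(genome.genes, genome.exons, f"{OUT}/genes.gff3")
    write_bed(genome.repeats, f"{OUT}/repeats.bed")
    write_bed(genome.gaps, f"{OUT}/gaps.bed")
    write_probe_table(probes, f"{OUT}/probes.tsv")
    reference.to_csv(f"{OUT}/reference.tsv", sep="\t", index=False)
    for cond, df in truth.expressed.items():
        write_bed(df[["chrom", "start", "end"]],
                  f"{OUT}/truth_expressed_{cond}.bed")
    diff = truth.differential.get(contrast)
    if diff is not None:
        write_bed(diff[["chrom", "start", "end"]],
                  f"{OUT}/truth_differential.bed")
    pd.DataFrame([dataclasses.asdict(m) for m in truth.macrornas]).to_csv(
        f"{OUT}/truth_macrornas.tsv", sep="\t", index=False
    )

    masked = genome.mask
    print(f"genome: {sum(genome.chrom_sizes.values()):,} nt, "
          f"{len(genome.genes)} genes, "
          f"{int((masked['end'] - masked['start']).sum()):,} nt masked")
    print(f"probes: {len(probes):,} across conditions {list(contrast)}")
    for m in truth.macrornas:
        print(f"macroRNA: {m.chrom}:{m.start:,}-{m.end:,} "
              f"({m.length / 1000:.0f} kb, {m.speed_kb_per_h:.0f} kb/h, "
              f"decay {m.decay_per_kb}/kb)")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
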