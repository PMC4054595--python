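"""Synthetic tiling-array data with known ground truth.

The generator emulates the signal structure of an unstranded genome tiling
experiment: probes of ~25 nt tiled every ~35 nt across the non-repeat part of
a genome, a GC-dependent affinity term, planted multi-exon expressed genes,
planted differential segments, and planted macroRNAs that share a start site,
elongate at a polymerase-like speed (roughly 80-275 kb/h) and decay towards
their 3' ends.  Every output is a pure function of (config, seed), so each
downstream stage can be tested against the planted truth without any external
download.

Intensities are Gaussian on the log2 scale around a flat baseline; this
distributional stand-in is isolated in :func:`_noise` for replacement.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    CoverageIndex,
    empty_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)


class InfeasibleConfigError(ValueError):
    """The requested genome layout does not fit on the chromosomes."""


@dataclasses.dataclass(frozen=True)
class GenomeConfig:
    """Layout of the synthetic genome.

    Defaults give a 4-Mb single-chromosome genome with ~25% repeat-masked
    sequence and a handful of multi-exon coding genes, i.e. a desk-scale
    stand-in for the non-repetitive fraction of a mammalian chromosome.
    """

    chrom_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 4_000_000}
    )
    n_genes: int = 12
    gene_span: tuple[int, int] = (20_000, 60_000)
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (150, 400)
    repeat_fraction: float = 0.25
    repeat_length: tuple[int, int] = (300, 3_000)
    n_gaps: int = 1
    gap_length: tuple[int, int] = (5_000, 15_000)
    n_lncrnas: int = 2
    lncrna_length: tuple[int, int] = (500, 3_000)

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0, 1)")


@dataclasses.dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # chrom,start,end,gene_id,strand,coding
    exons: pd.DataFrame  # chrom,start,end,gene_id
    repeats: pd.DataFrame
    gaps: pd.DataFrame
    lncrnas: pd.DataFrame

    @property
    def mask(self) -> pd.DataFrame:
        """Unprobed space: repeats plus assembly gaps."""
        return merge_intervals(
            pd.concat([self.repeats, self.gaps], ignore_index=True)
        ) if len(self.repeats) + len(self.gaps) else empty_intervals()

    def annotation(self, name: str = "synthetic") -> AnnotationSet:
        genes = self.genes
        coding = genes[genes["coding"]]
        strand_plus = coding["strand"] == "+"
        tss_pos = np.where(strand_plus, coding["start"], coding["end"] - 1)
        term_pos = np.where(strand_plus, coding["end"] - 1, coding["start"])
        point = lambda pos: pd.DataFrame(
            {"chrom": coding["chrom"].to_numpy(), "start": pos, "end": pos + 1,
             "name": coding["gene_id"].to_numpy(), "score": 0,
             "strand": coding["strand"].to_numpy()}
        )
        coding_exons = self.exons.merge(
            coding[["gene_id"]], on="gene_id"
        )[["chrom", "start", "end"]]
        introns = subtract_intervals(
            coding[["chrom", "start", "end"]], self.exons
        )
        features = {
            "gene_body": coding[["chrom", "start", "end", "gene_id", "strand"]]
            .rename(columns={"gene_id": "name"}).assign(score=0),
            "coding_exon": coding_exons,
            "intron": introns,
            "repeat": self.repeats,
            "gap": self.gaps,
            "lncrna_exon": self.lncrnas[["chrom", "start", "end"]]
            if len(self.lncrnas) else empty_intervals(),
            "tss": point(tss_pos) if len(coding) else empty_intervals(),
            "terminus": point(term_pos) if len(coding) else empty_intervals(),
        }
        return AnnotationSet(name=name, features=features)


@dataclasses.dataclass(frozen=True)
class MacroRNA:
    """A planted macroRNA: common start site, polymerase-limited elongation,
    linear 3' signal decay."""

    chrom: str
    start: int
    length: int
    amplitude: float = 2.5
    speed_kb_per_h: float = 120.0
    decay_per_kb: float = 0.002

    def __post_init__(self) -> None:
        if self.length < 10_000:
            raise ValueError("macroRNA length must be >= 10^4 nt")

    @property
    def end(self) -> int:
        return self.start + self.length

    def covered_length(self, elapsed_h: float) -> int:
        """Nucleotides reached by the polymerase after ``elapsed_h`` hours."""
        if np.isinf(elapsed_h):
            return self.length
        return int(min(self.length, elapsed_h * self.speed_kb_per_h * 1000.0))


@dataclasses.dataclass
class TruthSet:
    """Planted ground truth: expressed segments per condition (log2 amplitude),
    signed differential segments per contrast, and macroRNAs."""

    expressed: dict[str, pd.DataFrame]
    differential: dict[tuple[str, str], pd.DataFrame]
    macrornas: list[MacroRNA]
    condition_times: dict[str, float]

    def validate(self) -> None:
        for contrast, df in self.differential.items():
            a, b = contrast
            union = pd.concat(
                [self.expressed.get(a, empty_intervals()),
                 self.expressed.get(b, empty_intervals())],
                ignore_index=True,
            )
            if len(df) and not len(union):
                raise ValueError(
                    f"differential segments of {contrast} expressed in no condition"
                )
            if len(df):
                idx = CoverageIndex(union)
                cov = idx.overlap_many(df["chrom"].to_numpy(),
                                       df["start"].to_numpy(), df["end"].to_numpy())
                if (cov == 0).any():
                    raise ValueError(
                        f"differential segment of {contrast} not expressed anywhere"
                    )

    def conditions(self) -> list[str]:
        return list(self.condition_times)

    def macro_extent(self, condition: str) -> pd.DataFrame:
        """Region of each macroRNA carrying signal under ``condition``."""
        t = self.condition_times[condition]
        rows = []
        for m in self.macrornas:
            covered = m.covered_length(t)
            # signal also requires positive decay term
            if m.decay_per_kb > 0:
                covered = min(covered, int(np.ceil(1000.0 / m.decay_per_kb)))
            if covered > 0:
                rows.append((m.chrom, m.start, m.start + covered))
        return (
            pd.DataFrame(rows, columns=["chrom", "start", "end"])
            if rows else empty_intervals()
        )

    def differential_truth(self, contrast: tuple[str, str]) -> pd.DataFrame:
        """Nucleotides with a genuinely different mean signal in the contrast:
        planted differential segments plus macro regions reached in one
        condition but not the other."""
        parts = [self.differential.get(contrast, empty_intervals())[
            ["chrom", "start", "end"]
        ]]
        a, b = contrast
        ea, eb = self.macro_extent(a), self.macro_extent(b)
        parts.append(subtract_intervals(ea, eb))
        parts.append(subtract_intervals(eb, ea))
        return merge_intervals(pd.concat(parts, ignore_index=True)) \
            if sum(map(len, parts)) else empty_intervals()


# ----------------------------------------------------------------------------
# genome generation


def _sample_clear_intervals(
    rng: np.random.Generator,
    allowed: pd.DataFrame,
    lengths: Sequence[int],
) -> pd.DataFrame:
    """Place intervals of the given lengths uniformly inside ``allowed``
    (merged), without mutual overlap, by removing each placement from the
    remaining space."""
    space = merge_intervals(allowed)
    rows = []
    for L in lengths:
        cand = space[(space["end"] - space["start"]) >= L]
        if len(cand) == 0:
            raise InfeasibleConfigError(f"no room for an interval of length {L}")
        weights = (cand["end"] - cand["start"] - L + 1).to_numpy(dtype=float)
        k = rng.choice(len(cand), p=weights / weights.sum())
        row = cand.iloc[int(k)]
        off = int(rng.integers(0, row["end"] - row["start"] - L + 1))
        start = int(row["start"]) + off
        rows.append((row["chrom"], start, start + L))
        space = subtract_intervals(
            space, pd.DataFrame([rows[-1]], columns=["chrom", "start", "end"])
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows \
        else empty_intervals()


def generate_genome(config: GenomeConfig, seed: int) -> SyntheticGenome:
    """Deterministically build a synthetic genome for a (config, seed) pair."""
    rng = np.random.default_rng(seed)
    sizes = dict(config.chrom_sizes)
    total = sum(sizes.values())
    mean_span = sum(config.gene_span) / 2.0
    if config.n_genes * mean_span > total:
        raise InfeasibleConfigError(
            f"{config.n_genes} genes with mean span {mean_span:.0f} nt do not fit "
            f"on {total} nt of sequence"
        )

    # allocate genes to chromosomes proportionally to size, largest first
    chroms = sorted(sizes, key=sizes.get, reverse=True)
    alloc = {c: int(round(config.n_genes * sizes[c] / total)) for c in chroms}
    while sum(alloc.values()) < config.n_genes:
        alloc[chroms[0]] += 1
    while sum(alloc.values()) > config.n_genes:
        for c in reversed(chroms):
            if alloc[c] > 0:
                alloc[c] -= 1
                break

    gene_rows, exon_rows = [], []
    gid = 0
    for chrom in chroms:
        n_c = alloc[chrom]
        if n_c == 0:
            continue
        slot = sizes[chrom] // n_c
        if config.gene_span[1] > slot:
            raise InfeasibleConfigError(
                f"gene span up to {config.gene_span[1]} nt exceeds the "
                f"{slot}-nt slot available per gene on {chrom}"
            )
        for i in range(n_c):
            span = int(rng.integers(config.gene_span[0], config.gene_span[1] + 1))
            start = i * slot + int(rng.integers(0, slot - span + 1))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_id = f"gene{gid}"
            gene_rows.append((chrom, start, end, gene_id, strand, True))
            k = int(rng.integers(config.exons_per_gene[0],
                                 config.exons_per_gene[1] + 1))
            lens = rng.integers(config.exon_length[0],
                                config.exon_length[1] + 1, size=k)
            intron_total = span - int(lens.sum())
            cuts = np.sort(rng.integers(0, intron_total + 1, size=k - 1))
            intron_lens = np.diff(np.concatenate([[0], cuts, [intron_total]]))
            pos = start
            for j in range(k):
                if j > 0:
                    pos += int(intron_lens[j])
                exon_rows.append((chrom, pos, pos + int(lens[j]), gene_id))
                pos += int(lens[j])

    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "gene_id", "strand", "coding"]
    ) if gene_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "gene_id", "strand", "coding"]
    )
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])

    # repeats: random intervals until the target coverage fraction is reached
    repeat_rows = []
    if config.repeat_fraction > 0:
        for chrom, size in sizes.items():
            target = config.repeat_fraction * size
            covered = 0.0
            guard = 0
            while covered < target and guard < 100_000:
                guard += 1
                L = int(rng.integers(config.repeat_length[0],
                                     config.repeat_length[1] + 1))
                s = int(rng.integers(0, max(1, size - L)))
                repeat_rows.append((chrom, s, s + L))
                if guard % 50 == 0 or covered == 0:
                    covered = total_length(merge_intervals(pd.DataFrame(
                        repeat_rows, columns=["chrom", "start", "end"]
                    ).query("chrom == @chrom")))
    repeats = merge_intervals(
        pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"])
    ) if repeat_rows else empty_intervals()

    gap_rows = []
    for _ in range(config.n_gaps):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(config.gap_length[0], config.gap_length[1] + 1))
        s = int(rng.integers(0, max(1, sizes[chrom] - L)))
        gap_rows.append((chrom, s, s + L))
    gaps = merge_intervals(
        pd.DataFrame(gap_rows, columns=["chrom", "start", "end"])
    ) if gap_rows else empty_intervals()

    # lncRNAs live in intergenic, non-gap space (they may span repeats, which
    # merely lack probes)
    whole = pd.DataFrame(
        {"chrom": list(sizes), "start": 0, "end": list(sizes.values())}
    )
    free = subtract_intervals(
        whole,
        pd.concat([genes[["chrom", "start", "end"]], gaps], ignore_index=True),
    )
    lnc_lengths = [
        int(rng.integers(config.lncrna_length[0], config.lncrna_length[1] + 1))
        for _ in range(config.n_lncrnas)
    ]
    lncrnas = _sample_clear_intervals(rng, free, lnc_lengths) \
        if lnc_lengths else empty_intervals()

    return SyntheticGenome(
        chrom_sizes=sizes, genes=genes, exons=exons,
        repeats=repeats, gaps=gaps, lncrnas=lncrnas,
    )


# ----------------------------------------------------------------------------
# probes and intensities


def generate_probes(
    genome: SyntheticGenome,
    probe_length: int = 25,
    spacing: int = 35,
    gc_beta: tuple[float, float] = (10.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Tile the non-masked genome with probes at fixed spacing.

    Probes start at 0, spacing, 2*spacing, ... and must fit on the chromosome
    (``start + probe_length <= size``); any probe intersecting the repeat/gap
    mask by >= 1 nt is dropped, mirroring an array design that omits
    repeat-masked sequence.  GC fractions are Beta-distributed.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    rng = np.random.default_rng(seed)
    mask_idx = CoverageIndex(genome.mask)
    frames = []
    for chrom, size in genome.chrom_sizes.items():
        if size < probe_length:
            continue
        starts = np.arange(0, size - probe_length + 1, spacing, dtype=np.int64)
        ov = mask_idx.overlap_many(
            np.repeat(chrom, len(starts)), starts, starts + probe_length
        )
        starts = starts[ov == 0]
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "length": probe_length}
        ))
    probes = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "length"]
    )
    probes = probes.sort_values(["chrom", "start"]).reset_index(drop=True)
    probes.insert(0, "probe_id", [f"p{i}" for i in range(len(probes))])
    probes["gc"] = rng.beta(gc_beta[0], gc_beta[1], size=len(probes))
    return probes


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """Measurement noise on the log2 scale; swap here to change the model."""
    return rng.normal(0.0, sd, size=n)


def simulate_intensities(
    probes: pd.DataFrame,
    truth: TruthSet,
    noise_sd: float = 0.5,
    gc_effect: float = 1.0,
    baseline: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition log2 intensities for every probe.

    intensity = baseline + gc_effect * (gc - mean gc)
              + amplitude   (probe center inside an expressed segment)
              + macro term  (amplitude * max(0, 1 - decay * d_kb), only where
                             the polymerase has arrived: time*speed >= d)
              + Gaussian noise.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    truth.validate()
    rng = np.random.default_rng(seed)
    out = probes.copy()
    centers = probes["start"].to_numpy() + probes["length"].to_numpy() // 2
    chrom_arr = probes["chrom"].to_numpy()
    gc = probes["gc"].to_numpy()
    gc_term = gc_effect * (gc - gc.mean()) if len(gc) else gc

    for cond in truth.conditions():
        signal = baseline + gc_term + _noise(rng, noise_sd, len(probes))
        expr = truth.expressed.get(cond, empty_intervals())
        for seg in expr.itertuples(index=False):
            inside = (
                (chrom_arr == seg.chrom)
                & (centers >= seg.start)
                & (centers < seg.end)
            )
            amp = getattr(seg, "amplitude", 1.0)
            signal[inside] += amp
        t = truth.condition_times[cond]
        for m in truth.macrornas:
            covered = m.covered_length(t)
            if covered <= 0:
                continue
            d = centers - m.start
            inside = (chrom_arr == m.chrom) & (d >= 0) & (d < covered)
            term = m.amplitude * np.maximum(
                0.0, 1.0 - m.decay_per_kb * d[inside] / 1000.0
            )
            signal[inside] += term
        out[cond] = signal
    return out


def generate_reference_platform(
    truth: TruthSet,
    contrast: tuple[str, str],
    positions: pd.DataFrame,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate an independent reference platform's differential calls.

    ``positions`` supplies the reference probes (chrom/start/end).  A probe
    overlapping the contrast's true differential nucleotides is flagged DE
    with probability 1 - flip_rate, any other probe with probability
    flip_rate.  Returns chrom/start/end plus ``de_flag`` and the underlying
    ``true_flag``.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    de_truth = truth.differential_truth(contrast)
    idx = CoverageIndex(de_truth) if len(de_truth) else None
    out = positions[["chrom", "start", "end"]].copy().reset_index(drop=True)
    if idx is None:
        true_flag = np.zeros(len(out), dtype=bool)
    else:
        cov = idx.overlap_many(out["chrom"].to_numpy(),
                               out["start"].to_numpy(), out["end"].to_numpy())
        true_flag = cov > 0
    flips = rng.random(len(out)) < flip_rate
    out["true_flag"] = true_flag
    out["de_flag"] = true_flag ^ flips
    return out


# ----------------------------------------------------------------------------
# default truth builder


@dataclasses.dataclass(frozen=True)
class TruthConfig:
    """Planted-signal design: a resting condition and a stimulated condition
    sampled 1 h after induction (macroRNA elongation is time-limited), plus
    optional extra time points."""

    conditions: tuple[str, ...] = ("rest", "stim")
    condition_times: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"rest": 0.0, "stim": 1.0}
    )
    expressed_gene_fraction: float = 0.6
    expressed_amplitude: tuple[float, float] = (2.0, 4.0)
    n_differential_segments: int = 3
    differential_length: tuple[int, int] = (3_000, 8_000)
    differential_effect: tuple[float, float] = (2.0, 3.0)
    n_macrornas: int = 1
    macro_length: tuple[int, int] = (30_000, 50_000)
    macro_amplitude: float = 2.5
    macro_speed_kb_per_h: tuple[float, float] = (80.0, 275.0)
    macro_decay_per_kb: float = 0.002


def make_truth(
    genome: SyntheticGenome, config: TruthConfig = TruthConfig(), seed: int = 0
) -> TruthSet:
    """Plant expressed genes, differential intergenic segments and macroRNAs."""
    rng = np.random.default_rng(seed)
    conds = list(config.conditions)
    if set(conds) != set(config.condition_times):
        raise ValueError("conditions and condition_times disagree")

    # constitutively expressed genes: exons expressed in every condition
    genes = genome.genes
    n_expr = int(round(config.expressed_gene_fraction * len(genes)))
    chosen = rng.choice(len(genes), size=n_expr, replace=False) if n_expr else []
    expr_exons = genome.exons.merge(
        genes.iloc[sorted(chosen)][["gene_id"]], on="gene_id"
    )[["chrom", "start", "end"]].copy() if n_expr else empty_intervals()
    amps = rng.uniform(*config.expressed_amplitude, size=len(expr_exons))
    expr_exons["amplitude"] = amps

    expressed = {c: expr_exons.copy() for c in conds}

    # differential segments and macroRNAs live in intergenic, non-gap space;
    # they may span repeats (probes are simply missing there).  Each
    # differential segment is also expressed in the condition it is up in,
    # satisfying the expression invariant.
    whole = pd.DataFrame(
        {"chrom": list(genome.chrom_sizes), "start": 0,
         "end": list(genome.chrom_sizes.values())}
    )
    free = subtract_intervals(
        whole,
        pd.concat(
            [genes[["chrom", "start", "end"]],
             genome.gaps, genome.lncrnas[["chrom", "start", "end"]]
             if len(genome.lncrnas) else empty_intervals()],
            ignore_index=True,
        ),
    )
    # macroRNAs are placed first (they need the longest contiguous gaps)
    macros: list[MacroRNA] = []
    mac_lens = [
        int(rng.integers(config.macro_length[0], config.macro_length[1] + 1))
        for _ in range(config.n_macrornas)
    ]
    if mac_lens:
        placed = _sample_clear_intervals(rng, free, mac_lens)
        for row in placed.itertuples(index=False):
            macros.append(MacroRNA(
                chrom=row.chrom, start=int(row.start),
                length=int(row.end - row.start),
                amplitude=config.macro_amplitude,
                speed_kb_per_h=float(rng.uniform(*config.macro_speed_kb_per_h)),
                decay_per_kb=config.macro_decay_per_kb,
            ))
        free = subtract_intervals(free, placed)

    lens = [
        int(rng.integers(config.differential_length[0],
                         config.differential_length[1] + 1))
        for _ in range(config.n_differential_segments)
    ]
    diff_iv = _sample_clear_intervals(rng, free, lens) if lens else empty_intervals()
    effects = rng.uniform(*config.differential_effect, size=len(diff_iv))
    signs = np.where(rng.random(len(diff_iv)) < 0.5, 1.0, -1.0)
    diff_iv = diff_iv.copy()
    diff_iv["effect"] = effects * signs

    contrast = (conds[0], conds[1]) if len(conds) >= 2 else None
    differential: dict[tuple[str, str], pd.DataFrame] = {}
    if contrast is not None and len(diff_iv):
        differential[contrast] = diff_iv
        # effect > 0: up in the second (stimulated) condition
        for row in diff_iv.itertuples(index=False):
            cond_up = contrast[1] if row.effect > 0 else contrast[0]
            expressed[cond_up] = pd.concat(
                [expressed[cond_up],
                 pd.DataFrame([(row.chrom, row.start, row.end, abs(row.effect))],
                              columns=["chrom", "start", "end", "amplitude"])],
                ignore_index=True,
            )

    truth = TruthSet(
        expressed=expressed,
        differential=differential,
        macrornas=macros,
        condition_times=dict(config.condition_times),
    )
    truth.validate()
    return truth
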