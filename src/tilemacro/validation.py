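"""Cross-platform validation: FDR/sensitivity/specificity against a
reference platform, non-specific probe filtering, 3' signal-decay profiling
and proximal ncRNA-mRNA pairing.

The reference platform (an independent custom expression array run on the
same samples) supplies per-probe differential calls; tiling-side calls at a
sweep of q thresholds are compared nucleotide-wise against the reference
probe footprint:

    sensitivity = TP / P      specificity = 1 - FP / N
    FDR = FP / (FP + TP)

where TP (FP) are tiling-significant nucleotides covered by reference
DE (non-DE) probes, P and N are the total reference DE and non-DE probe
nucleotides, and nucleotides under no reference probe are ignored.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .intervals import (
    CoverageIndex,
    empty_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)


# ----------------------------------------------------------------------------
# non-specific probe filtering


def probe_nonspecific_filter(
    intensities: pd.DataFrame,
    negative_controls: pd.DataFrame,
    min_samples: int = 4,
    iqr_min: float = 0.5,
) -> np.ndarray:
    """Boolean retention mask over probes (rows are probes, columns samples).

    A probe is retained iff its intensity exceeds the background — mean plus
    three standard deviations of the negative-control spots — in at least
    ``min_samples`` samples, and its interquartile range across all samples
    exceeds ``iqr_min``.
    """
    neg = np.asarray(negative_controls, dtype=float)
    if neg.size == 0:
        raise ValueError("at least one negative control probe is required")
    background = neg.mean() + 3.0 * neg.std(ddof=0)
    x = np.asarray(intensities, dtype=float)
    expressed = (x > background).sum(axis=1) >= min_samples
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    return expressed & ((q75 - q25) > iqr_min)


# ----------------------------------------------------------------------------
# cross-platform FDR estimation


@dataclasses.dataclass
class ValidationCounts:
    q_threshold: float
    TP: int
    FP: int
    P: int
    N: int

    @property
    def sensitivity(self) -> float:
        return self.TP / self.P if self.P else float("nan")

    @property
    def specificity(self) -> float:
        return 1.0 - self.FP / self.N if self.N else float("nan")

    @property
    def fdr(self) -> float:
        return self.FP / (self.FP + self.TP) if (self.FP + self.TP) else 0.0


def default_q_grid(n: int = 20) -> np.ndarray:
    """Log-spaced q thresholds over [1e-4, 1]."""
    return np.logspace(-4, 0, n)


def fdr_curve(
    windows: pd.DataFrame,
    reference: pd.DataFrame,
    q_grid=None,
) -> pd.DataFrame:
    """Sensitivity/specificity/FDR of tiling differential calls per q.

    ``windows`` is a differential window table (chrom/start/end/q);
    ``reference`` holds reference probes (chrom/start/end/de_flag).
    Nucleotides under overlapping reference probes with conflicting flags
    count once, as DE.
    """
    if len(reference) == 0:
        raise ValueError("reference probe set is empty")
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    de_cover = merge_intervals(reference[reference["de_flag"]])
    non_cover = subtract_intervals(reference[~reference["de_flag"]], de_cover)
    P = total_length(de_cover)
    N = total_length(non_cover)
    de_idx = CoverageIndex(de_cover) if P else None
    non_idx = CoverageIndex(non_cover) if N else None
    evaluated = windows[~windows["q"].isna()]
    rows = []
    for q in q_grid:
        sig = merge_intervals(evaluated[evaluated["q"] <= q]) \
            if len(evaluated) else empty_intervals()
        if len(sig):
            c, s, e = (sig["chrom"].to_numpy(), sig["start"].to_numpy(),
                       sig["end"].to_numpy())
            tp = int(de_idx.overlap_many(c, s, e).sum()) if de_idx else 0
            fp = int(non_idx.overlap_many(c, s, e).sum()) if non_idx else 0
        else:
            tp = fp = 0
        vc = ValidationCounts(q_threshold=float(q), TP=tp, FP=fp, P=P, N=N)
        rows.append((vc.q_threshold, vc.TP, vc.FP, vc.P, vc.N,
                     vc.sensitivity, vc.specificity, vc.fdr))
    return pd.DataFrame(
        rows, columns=["q", "TP", "FP", "P", "N",
                       "sensitivity", "specificity", "fdr"],
    )


# ----------------------------------------------------------------------------
# 3' decay profiling


def decay_profile(
    segments: pd.DataFrame,
    probes: pd.DataFrame,
    value_col: str,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean probe value per normalized 5'->3' position bin across segments.

    Each probe center inside a segment maps to (pos - start) / length; a
    segment ``strand`` of "-" flips the coordinate.  Segments without probes
    are skipped.  Returns bin midpoints, means and per-bin probe counts.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    centers = probes["start"].to_numpy() + probes.get(
        "length", pd.Series(np.zeros(len(probes)))
    ).to_numpy() // 2
    chroms = probes["chrom"].to_numpy()
    vals = probes[value_col].to_numpy(dtype=float)
    rel_all, val_all = [], []
    n_used = 0
    for seg in segments.itertuples(index=False):
        inside = (chroms == seg.chrom) & (centers >= seg.start) & (centers < seg.end)
        if not inside.any():
            continue
        n_used += 1
        rel = (centers[inside] - seg.start) / (seg.end - seg.start)
        if getattr(seg, "strand", "+") == "-":
            rel = 1.0 - rel
        rel_all.append(rel)
        val_all.append(vals[inside])
    if not rel_all:
        return pd.DataFrame(columns=["bin_mid", "mean", "n_probes"])
    rel = np.concatenate(rel_all)
    val = np.concatenate(val_all)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append(((edges[b] + edges[b + 1]) / 2.0,
                         float(val[sel].mean()), int(sel.sum())))
    out = pd.DataFrame(rows, columns=["bin_mid", "mean", "n_probes"])
    out.attrs["n_segments"] = n_used
    return out


# ----------------------------------------------------------------------------
# proximal ncRNA-mRNA pairs


@dataclasses.dataclass
class PairCall:
    probe_id: str
    probe_chrom: str
    probe_pos: int
    probe_strand: str
    probe_direction: str  # up / down
    gene_id: str
    gene_strand: str
    gene_direction: str  # up / down / ns (not significant) / inconsistent
    distance: int
    verdict: str  # retained / excluded / unpaired
    reason: str


def proximal_pairs(
    nc_probes: pd.DataFrame,
    genes: pd.DataFrame,
) -> list[PairCall]:
    """Pair each differentially expressed non-coding probe with its nearest
    protein-coding gene and apply the retention rules.

    ``nc_probes``: probe_id, chrom, pos, strand, direction (up/down).
    ``genes``: gene_id, chrom, start, end, strand, de (bool),
    direction (up/down), consistent (bool: exon-probe fold-change signs agree).

    The nearest gene is chosen strand-blind (distance 0 when overlapping;
    equidistant ties break toward the 5' side of the probe, i.e. the lower
    coordinate).  A pair is retained only when the gene is differentially
    expressed with internally consistent sign AND probe and gene share the
    strand with opposite directions of change.  All different-strand pairs
    with significant changes on both sides are excluded, and a non-DE or
    inconsistent gene never forms a pair.
    """
    calls: list[PairCall] = []
    for p in nc_probes.itertuples(index=False):
        cands = genes[genes["chrom"] == p.chrom]
        if len(cands) == 0:
            calls.append(PairCall(
                probe_id=str(p.probe_id), probe_chrom=p.chrom,
                probe_pos=int(p.pos), probe_strand=p.strand,
                probe_direction=p.direction, gene_id="", gene_strand="",
                gene_direction="", distance=-1,
                verdict="unpaired", reason="no-genes-on-chromosome",
            ))
            continue
        starts = cands["start"].to_numpy()
        ends = cands["end"].to_numpy()
        dist = np.where(
            (p.pos >= starts) & (p.pos < ends), 0,
            np.minimum(np.abs(starts - p.pos), np.abs(ends - 1 - p.pos)),
        )
        best = dist == dist.min()
        idx = np.flatnonzero(best)
        if len(idx) > 1:  # tie: toward the 5' side (lower coordinate)
            idx = [idx[int(np.argmin(starts[idx]))]]
        g = cands.iloc[int(idx[0])]
        if not g["de"]:
            verdict, reason = "excluded", "gene-not-differential"
            gdir = "ns"
        elif not g["consistent"]:
            verdict, reason = "excluded", "gene-sign-inconsistent"
            gdir = "inconsistent"
        elif p.strand != g["strand"]:
            verdict, reason = "excluded", "different-strand"
            gdir = g["direction"]
        elif p.direction == g["direction"]:
            verdict, reason = "excluded", "same-direction-same-strand"
            gdir = g["direction"]
        else:
            verdict, reason = "retained", "opposite-direction-same-strand"
            gdir = g["direction"]
        calls.append(PairCall(
            probe_id=str(p.probe_id), probe_chrom=p.chrom, probe_pos=int(p.pos),
            probe_strand=p.strand, probe_direction=p.direction,
            gene_id=str(g["gene_id"]), gene_strand=str(g["strand"]),
            gene_direction=gdir, distance=int(dist.min()),
            verdict=verdict, reason=reason,
        ))
    return calls


def pairs_frame(calls: list[PairCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])
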