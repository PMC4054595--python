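"""Permutation-based segmentation of tiling signal into TARs and DE-TARs.

Expressed windows are scored with a min/max-trimmed mean of probe
intensities and compared against a pooled null built from GC-binned
permutations of the probe signals: probes are shuffled uniformly only within
GC-content classes, which controls sequence-affinity bias.  Differential
windows are scored on per-probe intensity differences (log-fold-changes,
where affinity effects cancel and a single GC class suffices), discarding
probes whose difference opposes the window's net direction.  Window p-values
are empirical with a +1 pseudocount and adjusted by Benjamini-Hochberg;
significant windows are merged (>= 1 nt overlap) into segments.

Windows are anchored at each probe start (one fixed-width window per probe);
a window's members are the probes whose start lies inside it.  Windows with
fewer than ``min_probes`` members are not evaluated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import CoverageIndex, empty_intervals, merge_intervals


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    window: int = 200
    min_probes: int = 3
    n_permutations: int = 10_000
    gc_classes: int = 4
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_probes < 3:
            raise ValueError("window >= 1 and min_probes >= 3 required")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")


def differential_config(**kw) -> SegmentationConfig:
    """Defaults for the differential stage: difference shuffles need no GC
    binning and use the stricter q < 0.005 threshold."""
    base = dict(n_permutations=100_000, gc_classes=1, q_threshold=0.005)
    base.update(kw)
    return SegmentationConfig(**base)


def assign_gc_bins(gc: np.ndarray, n_classes: int) -> np.ndarray:
    """GC-quantile classes of near-equal size; ties broken by stable rank."""
    gc = np.asarray(gc)
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_classes > len(gc):
        raise ValueError(f"n_classes={n_classes} exceeds {len(gc)} probes")
    order = np.argsort(gc, kind="stable")
    ranks = np.empty(len(gc), dtype=np.int64)
    ranks[order] = np.arange(len(gc))
    return (ranks * n_classes) // len(gc)


def trimmed_mean_score(values) -> float:
    """Arithmetic mean after removing exactly one maximal and one minimal value."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("trimmed mean needs >= 3 values")
    return float((v.sum() - v.max() - v.min()) / (len(v) - 2))


def differential_score(log_diffs) -> tuple[int, float]:
    """Window direction and mean retained log-fold-change.

    Direction is the sign of the summed differences (zero-sum ties -> up);
    probes opposing that sign are discarded; the score is the signed mean of
    the retained differences.
    """
    d = np.asarray(log_diffs, dtype=float)
    direction = 1 if d.sum() >= 0 else -1
    retained = d[d * direction > 0]
    score = float(retained.mean()) if len(retained) else 0.0
    return direction, score


class WindowIndex:
    """Probe-anchored fixed-width windows over a sorted probe table.

    Precomputes member index ranges and the gather matrices used to score all
    windows of each member-count in one vectorized pass per permutation.
    """

    def __init__(self, probes: pd.DataFrame, window: int = 200,
                 min_probes: int = 3):
        self.window = window
        self.min_probes = min_probes
        self.probes = probes.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)

        chrom_arr = self.probes["chrom"].to_numpy()
        start_arr = self.probes["start"].to_numpy()
        lo_parts, hi_parts = [], []
        offset = 0
        for chrom in pd.unique(chrom_arr):
            sel = chrom_arr == chrom
            starts = start_arr[sel]
            n_c = len(starts)
            lo_parts.append(offset + np.arange(n_c))
            hi_parts.append(
                offset + np.searchsorted(starts, starts + window, side="left")
            )
            offset += n_c
        self.lo = np.concatenate(lo_parts) if lo_parts else np.empty(0, int)
        self.hi = np.concatenate(hi_parts) if hi_parts else np.empty(0, int)
        self.chrom = chrom_arr
        self.win_start = start_arr
        self.win_end = start_arr + window
        self.n_members = self.hi - self.lo
        self.valid = self.n_members >= min_probes
        self._groups = []
        for k in np.unique(self.n_members[self.valid]):
            rows = np.flatnonzero(self.valid & (self.n_members == k))
            idx = self.lo[rows][:, None] + np.arange(int(k))[None, :]
            self._groups.append((rows, idx, int(k)))

    def __len__(self) -> int:
        return len(self.lo)

    def trimmed_scores(self, values: np.ndarray) -> np.ndarray:
        """Trimmed-mean score per window; NaN where the window is invalid."""
        scores = np.full(len(self.lo), np.nan)
        for rows, idx, k in self._groups:
            vals = values[idx]
            scores[rows] = (vals.sum(axis=1) - vals.max(axis=1)
                            - vals.min(axis=1)) / (k - 2)
        return scores

    def diff_scores(self, diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed differential score and direction per window (NaN/0 invalid)."""
        pos = np.where(diffs > 0, diffs, 0.0)
        neg = np.where(diffs < 0, diffs, 0.0)
        cp = np.concatenate([[0.0], np.cumsum(pos)])
        cn = np.concatenate([[0.0], np.cumsum(neg)])
        cpc = np.concatenate([[0], np.cumsum(diffs > 0)])
        cnc = np.concatenate([[0], np.cumsum(diffs < 0)])
        pos_sum = cp[self.hi] - cp[self.lo]
        neg_sum = cn[self.hi] - cn[self.lo]
        pos_cnt = cpc[self.hi] - cpc[self.lo]
        neg_cnt = cnc[self.hi] - cnc[self.lo]
        total = pos_sum + neg_sum
        direction = np.where(total >= 0, 1, -1)
        ret_sum = np.where(direction > 0, pos_sum, neg_sum)
        ret_cnt = np.where(direction > 0, pos_cnt, neg_cnt)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(ret_cnt > 0, ret_sum / np.maximum(ret_cnt, 1), 0.0)
        score = np.where(self.valid, score, np.nan)
        return score, direction


def shuffle_within_bins(
    values: np.ndarray, bin_members: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    out = values.copy()
    for idx in bin_members:
        out[idx] = values[idx[rng.permutation(len(idx))]]
    return out


def _bin_members(bins: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(bins == b) for b in np.unique(bins)]


def permutation_pvalues(
    windex: WindowIndex,
    values: np.ndarray,
    gc_bins: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    kind: str = "expression",
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Empirical upper-tail p per window against a pooled permutation null.

    Per permutation, probe values are shuffled uniformly within GC bins
    across the whole probe set and every evaluated window is rescored; the
    null is the pooled multiset of all permuted window scores.  For
    ``kind="differential"`` the tail is two-sided on the score magnitude.
    p = (1 + #{null >= observed}) / (1 + null size).
    """
    evaluated = windex.valid if eligible is None else (windex.valid & eligible)
    if kind == "expression":
        obs = windex.trimmed_scores(values)
    elif kind == "differential":
        obs = np.abs(windex.diff_scores(values)[0])
    else:
        raise ValueError(f"unknown kind {kind!r}")
    obs_eval = obs[evaluated]
    n_eval = len(obs_eval)
    p = np.full(len(windex), np.nan)
    if n_eval == 0:
        return p
    order = np.argsort(obs_eval)
    obs_sorted = obs_eval[order]
    counts = np.zeros(n_eval, dtype=np.int64)
    members = _bin_members(gc_bins)
    for _ in range(n_permutations):
        v = shuffle_within_bins(values, members, rng)
        if kind == "expression":
            s = windex.trimmed_scores(v)[evaluated]
        else:
            s = np.abs(windex.diff_scores(v)[0][evaluated])
        s.sort()
        counts += n_eval - np.searchsorted(s, obs_sorted, side="left")
    null_size = n_permutations * n_eval
    p_sorted = (1.0 + counts) / (1.0 + null_size)
    p_eval = np.empty(n_eval)
    p_eval[order] = p_sorted
    p[evaluated] = p_eval
    return p


def empirical_q(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment over the evaluated (non-NaN) windows."""
    q = np.full(len(p), np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _windows_frame(windex: WindowIndex, score, p, q, direction=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {"chrom": windex.chrom, "start": windex.win_start, "end": windex.win_end,
         "n_probes": windex.n_members, "score": score, "p_emp": p, "q": q}
    )
    if direction is not None:
        df["direction"] = np.where(direction > 0, "up", "down")
    return df


def _merge_significant(windows: pd.DataFrame, label: str, kind: str) -> pd.DataFrame:
    """Merge overlapping windows into segments; summary score = max member score."""
    if len(windows) == 0:
        out = empty_intervals()
        out["name"] = pd.Series(dtype=str)
        out["score"] = pd.Series(dtype=float)
        out["kind"] = pd.Series(dtype=str)
        return out
    segs = merge_intervals(windows)
    seg_scores = np.zeros(len(segs))
    for i, seg in enumerate(segs.itertuples(index=False)):
        member = (
            (windows["chrom"] == seg.chrom)
            & (windows["start"] < seg.end)
            & (windows["end"] > seg.start)
        )
        seg_scores[i] = windows.loc[member, "score"].abs().max()
    segs["name"] = label
    segs["score"] = seg_scores
    segs["kind"] = kind
    return segs


def call_tars(windows: pd.DataFrame, q_threshold: float,
              condition: str = "cond") -> pd.DataFrame:
    """Merge windows with q < threshold into TARs for one condition."""
    sig = windows[windows["q"] < q_threshold]
    return _merge_significant(sig, condition, "TAR")


def call_de_tars(
    windows: pd.DataFrame, q_threshold: float, contrast: str = "contrast"
) -> pd.DataFrame:
    """Merge significant differential windows into DE-TARs, stratified by
    direction: abutting up- and down-windows yield separate segments."""
    out = []
    for direction in ("up", "down"):
        sig = windows[(windows["q"] < q_threshold)
                      & (windows["direction"] == direction)]
        segs = _merge_significant(sig, contrast, "DE-TAR")
        segs["direction"] = direction
        out.append(segs)
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["chrom", "start"]).reset_index(drop=True) \
        if len(res) else res


def segment_expressed(
    probes: pd.DataFrame, condition: str,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score, test and merge expressed windows for one condition.

    Returns (window table, TAR segments)."""
    windex = WindowIndex(probes, config.window, config.min_probes)
    values = windex.probes[condition].to_numpy(dtype=float)
    gc_bins = assign_gc_bins(windex.probes["gc"].to_numpy(), config.gc_classes)
    rng = np.random.default_rng(config.seed)
    score = windex.trimmed_scores(values)
    p = permutation_pvalues(windex, values, gc_bins,
                            config.n_permutations, rng, "expression")
    q = empirical_q(p)
    windows = _windows_frame(windex, score, p, q)
    return windows, call_tars(windows, config.q_threshold, condition)


def segment_differential(
    probes: pd.DataFrame,
    contrast: tuple[str, str],
    h_intervals: dict[str, pd.DataFrame],
    config: SegmentationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score, test and merge differential windows for one contrast.

    Only windows overlapping the union of the contrast's significantly
    expressed (H) intervals are evaluated, so signal variation at the
    detection limit is never called differential.  Differences are
    ``probes[b] - probes[a]`` for contrast ``(a, b)``; direction "up" means
    higher in ``b``.
    """
    config = config or differential_config()
    a, b = contrast
    for cond in contrast:
        if cond not in h_intervals:
            raise ValueError(f"missing H intervals for condition {cond!r}")
    windex = WindowIndex(probes, config.window, config.min_probes)
    diffs = (windex.probes[b] - windex.probes[a]).to_numpy(dtype=float)
    h_union = pd.concat(
        [h_intervals[a][["chrom", "start", "end"]],
         h_intervals[b][["chrom", "start", "end"]]],
        ignore_index=True,
    )
    if len(h_union):
        cov = CoverageIndex(h_union)
        eligible = cov.overlap_many(windex.chrom, windex.win_start,
                                    windex.win_end) > 0
    else:
        eligible = np.zeros(len(windex), dtype=bool)
    gc_bins = assign_gc_bins(windex.probes["gc"].to_numpy(), config.gc_classes)
    rng = np.random.default_rng(config.seed)
    score, direction = windex.diff_scores(diffs)
    p = permutation_pvalues(windex, diffs, gc_bins, config.n_permutations,
                            rng, "differential", eligible=eligible)
    q = empirical_q(p)
    windows = _windows_frame(windex, score, p, q, direction)
    windows["eligible"] = eligible
    return windows, call_de_tars(windows, config.q_threshold,
                                 f"{a}_vs_{b}")
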