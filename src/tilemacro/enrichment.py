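"""Annotation-overlap enrichment against randomized genomic backgrounds.

The observed quantity is the number of nucleotides of a query interval set
(typically DE-TARs) overlapping an annotation.  Significance is assessed
against N randomized background lists, each containing intervals with
exactly the query's multiset of lengths, placed uniformly in a sampling
space that excludes assembly gaps and repeat regions (and, for
intergenic/intronic queries, is restricted to the corresponding space).

    odds_obs   = ov_obs / (n_obs - ov_obs)
    odds_bg    = (sum_i ov_bg_i / N) / (sum_i (n_bg_i - ov_bg_i) / N)
    odds ratio = odds_obs / odds_bg

The odds ratio is tested with Fisher's exact test on the 2x2 table of
observed versus (rounded mean) background nucleotide counts, with a 95%
confidence interval on the log odds ratio.  A Haldane-Anscombe +0.5
correction is applied to all four cells when any cell is zero.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    CoverageIndex,
    empty_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)


class BackgroundSamplingError(ValueError):
    """A query length cannot be placed anywhere in the sampling space."""


def sample_background(
    query: pd.DataFrame,
    space: pd.DataFrame,
    exclusions: pd.DataFrame,
    n_lists: int = 100,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Draw N randomized interval lists matching the query's lengths.

    Every sampled interval lies inside ``space`` minus ``exclusions``; each
    list carries exactly the query's multiset of lengths.  Placement is
    uniform over all feasible positions: an allowed sub-interval is chosen
    with probability proportional to its number of feasible start positions,
    then a start is drawn uniformly inside it, so a length with a single
    feasible placement is placed there deterministically.
    """
    rng = np.random.default_rng(seed)
    allowed = subtract_intervals(merge_intervals(space, "space"), exclusions)
    if len(allowed) == 0:
        raise BackgroundSamplingError("sampling space is empty after exclusions")
    a_len = (allowed["end"] - allowed["start"]).to_numpy()
    lengths = np.sort((query["end"] - query["start"]).to_numpy())[::-1]
    for L in np.unique(lengths):
        if not (a_len >= L).any():
            raise BackgroundSamplingError(
                f"no interval of the sampling space can hold length {int(L)}"
            )
    lists = []
    for _ in range(n_lists):
        rows = []
        for L in lengths:
            feasible = np.flatnonzero(a_len >= L)
            weights = (a_len[feasible] - L + 1).astype(float)
            k = int(feasible[rng.choice(len(feasible), p=weights / weights.sum())])
            row = allowed.iloc[k]
            start = int(row["start"]) + int(rng.integers(0, a_len[k] - L + 1))
            rows.append((row["chrom"], start, start + int(L)))
        lists.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return lists


@dataclasses.dataclass
class OverlapStats:
    annotation: str
    ov_obs: int
    n_obs: int
    ov_bg_mean: float
    n_bg_mean: float
    n_lists: int
    odds_obs: float
    odds_bg: float
    odds_ratio: float
    log2_odds_ratio: float
    ci95: tuple[float, float]
    p: float
    ci_method: str = "normal-log-odds"
    zero_cell: bool = False
    stars: str = ""


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, tuple[float, float], str]:
    """Two-sided Fisher p and a 95% CI for the table's odds ratio.

    Degenerate margins (a zero row or column) give p = 1 and a NaN CI.  The
    CI is a normal approximation on the log odds ratio of the (Haldane-
    corrected, if needed) table.
    """
    t = np.asarray(table, dtype=float)
    if t.min() < 0 or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, (float("nan"), float("nan")), "degenerate"
    p = float(stats.fisher_exact(t.astype(np.int64), alternative="two-sided")[1])
    tc = t + 0.5 if (t == 0).any() else t
    log_or = math.log((tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0]))
    se = math.sqrt((1.0 / tc).sum())
    z = stats.norm.ppf(0.975)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    return p, ci, "normal-log-odds"


def odds_ratio(
    ov_obs: int,
    n_obs: int,
    backgrounds: list[tuple[int, int]],
    annotation: str = "",
) -> OverlapStats:
    """Observed-vs-background odds ratio with Fisher test and CI.

    ``backgrounds`` holds (ov_bg_i, n_bg_i) per list.  The Fisher test
    consumes the rounded mean background cells.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be > 0")
    N = len(backgrounds)
    if N < 1:
        raise ValueError("at least one background list is required")
    ov_bg = float(np.mean([b[0] for b in backgrounds]))
    n_bg = float(np.mean([b[1] for b in backgrounds]))
    cells = np.array(
        [[ov_obs, n_obs - ov_obs],
         [round(ov_bg), round(n_bg - ov_bg)]], dtype=float
    )
    zero_cell = bool((cells == 0).any())
    c = cells + 0.5 if zero_cell else cells
    odds_obs = c[0, 0] / c[0, 1]
    odds_bg = c[1, 0] / c[1, 1]
    ratio = odds_obs / odds_bg
    p, ci, method = fisher_exact_2x2(np.round(cells))
    return OverlapStats(
        annotation=annotation,
        ov_obs=int(ov_obs), n_obs=int(n_obs),
        ov_bg_mean=ov_bg, n_bg_mean=n_bg, n_lists=N,
        odds_obs=float(odds_obs), odds_bg=float(odds_bg),
        odds_ratio=float(ratio),
        log2_odds_ratio=float(np.log2(ratio)),
        ci95=ci, p=p, ci_method=method,
        zero_cell=zero_cell, stars=_stars(p),
    )


def overlap_counts(query: pd.DataFrame, annotation: pd.DataFrame) -> tuple[int, int]:
    """(overlapping nt, total unique nt) of the query against an annotation."""
    q = merge_intervals(query, "query")
    n = total_length(q)
    if n == 0 or len(annotation) == 0:
        return 0, n
    ann = CoverageIndex(annotation)
    ov = int(ann.overlap_many(q["chrom"].to_numpy(), q["start"].to_numpy(),
                              q["end"].to_numpy()).sum())
    return ov, n


def enrichment_report(
    query: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    space: pd.DataFrame,
    exclusions: pd.DataFrame | None = None,
    n_backgrounds: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """One OverlapStats row per named annotation set.

    Backgrounds are sampled once and reused across annotations, as with a
    single set of randomized query lists.
    """
    exclusions = exclusions if exclusions is not None else empty_intervals()
    backgrounds = sample_background(query, space, exclusions,
                                    n_lists=n_backgrounds, seed=seed)
    rows = []
    for name, ann in annotations.items():
        ov_obs, n_obs = overlap_counts(query, ann)
        bg_counts = [overlap_counts(bg, ann) for bg in backgrounds]
        st = odds_ratio(ov_obs, n_obs, bg_counts, annotation=name)
        rows.append(dataclasses.asdict(st))
    df = pd.DataFrame(rows)
    df[["ci95_lo", "ci95_hi"]] = pd.DataFrame(df["ci95"].tolist(), index=df.index)
    return df.drop(columns=["ci95"])
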