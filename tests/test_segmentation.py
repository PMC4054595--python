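"""Window scoring, GC-binned permutation nulls, BH adjustment, segment calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tilemacro import segmentation as seg
from tilemacro.intervals import intervals


def make_probes(starts, values=None, gc=None, chrom="chr1"):
    n = len(starts)
    df = pd.DataFrame(
        {"probe_id": [f"p{i}" for i in range(n)], "chrom": chrom,
         "start": np.asarray(starts, dtype=np.int64), "length": 25,
         "gc": gc if gc is not None else np.full(n, 0.5)}
    )
    if values is not None:
        df["x"] = np.asarray(values, dtype=float)
    return df


class TestGcBins:
    def test_quartiles_of_sorted_values(self):
        gc = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        assert seg.assign_gc_bins(gc, 4).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_single_class(self):
        assert seg.assign_gc_bins(np.array([0.3, 0.9, 0.1]), 1).tolist() == [0, 0, 0]

    def test_ties_assigned_by_stable_rank(self):
        out = seg.assign_gc_bins(np.full(8, 0.5), 4)
        assert out.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_more_classes_than_probes_raises(self):
        with pytest.raises(ValueError):
            seg.assign_gc_bins(np.array([0.5, 0.6]), 3)


class TestScores:
    def test_trimmed_mean_drops_one_extreme_each_side(self):
        assert seg.trimmed_mean_score([1, 2, 3, 4, 10]) == pytest.approx(3.0)

    def test_trimmed_mean_of_constants(self):
        assert seg.trimmed_mean_score([5, 5, 5]) == pytest.approx(5.0)

    def test_trimmed_mean_needs_three_values(self):
        with pytest.raises(ValueError):
            seg.trimmed_mean_score([7])

    @pytest.mark.parametrize(
        "diffs,direction,score",
        [
            ([+1.0, +0.8, -0.2], 1, 0.9),
            ([-1.0, -1.0, +0.1], -1, -1.0),
            ([+0.5, -0.5], 1, 0.5),  # zero-sum tie breaks up
        ],
    )
    def test_differential_score(self, diffs, direction, score):
        d, s = seg.differential_score(diffs)
        assert d == direction
        assert s == pytest.approx(score)

    def test_window_too_sparse_is_invalid_not_error(self):
        probes = make_probes([0, 500, 1000], values=[1.0, 2.0, 3.0])
        windex = seg.WindowIndex(probes, window=200, min_probes=3)
        scores = windex.trimmed_scores(probes["x"].to_numpy())
        assert np.isnan(scores).all()

    def test_vectorized_scores_match_scalar_functions(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(5_000, size=80, replace=False))
        values = rng.normal(size=80)
        probes = make_probes(starts, values)
        windex = seg.WindowIndex(probes, window=200, min_probes=3)
        v = windex.probes["x"].to_numpy()
        trimmed = windex.trimmed_scores(v)
        dscore, ddir = windex.diff_scores(v)
        for w in range(len(windex)):
            members = v[windex.lo[w]: windex.hi[w]]
            if len(members) < 3:
                assert np.isnan(trimmed[w])
                continue
            assert trimmed[w] == pytest.approx(seg.trimmed_mean_score(members))
            d_ref, s_ref = seg.differential_score(members)
            assert ddir[w] == d_ref
            assert dscore[w] == pytest.approx(s_ref)


class TestPermutationNull:
    def test_full_array_window_gives_point_mass_null(self):
        """A window containing every probe has a permutation-invariant score,
        so the pooled null is a point mass at the observed score and p = 1."""
        probes = make_probes([0, 10, 20], values=[1.0, 2.0, 4.0])
        windex = seg.WindowIndex(probes, window=200, min_probes=3)
        assert windex.valid.sum() == 1
        rng = np.random.default_rng(0)
        p = seg.permutation_pvalues(
            windex, probes["x"].to_numpy(), np.zeros(3, dtype=np.int64),
            n_permutations=50, rng=rng,
        )
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_intensities_give_p_one(self):
        probes = make_probes([0, 35, 70, 105], values=[5.0] * 4)
        windex = seg.WindowIndex(probes, window=200, min_probes=3)
        rng = np.random.default_rng(0)
        p = seg.permutation_pvalues(
            windex, probes["x"].to_numpy(), np.zeros(4, dtype=np.int64),
            n_permutations=20, rng=rng,
        )
        valid = ~np.isnan(p)
        assert np.allclose(p[valid], 1.0)

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """Two 3-probe windows, six probes: exhaustive 720-permutation oracle.

        Values are binary fractions so trimmed-mean ties are exact in both
        the oracle and the implementation."""
        values = np.array([1.25, -0.5, 0.75, 3.0, 0.25, -1.0])
        starts = [0, 30, 60, 300, 330, 360]
        probes = make_probes(starts, values)
        windex = seg.WindowIndex(probes, window=100, min_probes=3)
        valid_w = np.flatnonzero(windex.valid)
        assert len(valid_w) == 2

        def oracle_trimmed(vals):
            v = sorted(vals)
            return sum(v[1:-1]) / (len(v) - 2)

        obs = [oracle_trimmed(values[windex.lo[w]: windex.hi[w]])
               for w in valid_w]
        null = []
        for perm in itertools.permutations(values):
            arr = np.asarray(perm)
            for w in valid_w:
                null.append(oracle_trimmed(arr[windex.lo[w]: windex.hi[w]]))
        null = np.asarray(null)
        p_exact = [(1 + (null >= o).sum()) / (1 + len(null)) for o in obs]

        n_perm = 4000
        rng = np.random.default_rng(1)
        p_sampled = seg.permutation_pvalues(
            windex, values, np.zeros(6, dtype=np.int64), n_perm, rng
        )[valid_w]
        for ps, pe in zip(p_sampled, p_exact):
            mc_sd = np.sqrt(pe * (1 - pe) / n_perm)
            assert abs(ps - pe) <= 3 * mc_sd + 1e-9


class TestEmpiricalQ:
    def test_pseudocount_formula(self):
        """Observed above the whole null of size 999 -> p = 1/1000."""
        null = np.arange(999, dtype=float)
        obs = np.array([2000.0])
        p = (1 + (null >= obs[0]).sum()) / (1 + len(null))
        assert p == pytest.approx(1 / 1000)

    def test_bh_adjustment_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(seg.empirical_q(p), [0.04, 0.04, 0.04, 0.04])

    def test_bh_keeps_nan_for_unevaluated(self):
        q = seg.empirical_q(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


def _window_table(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "q", "direction"]
    )
    return df


class TestSegmentCalls:
    def test_overlapping_significant_windows_merge(self):
        w = _window_table([("chr1", 0, 200, 5.0, 0.01, "up"),
                           ("chr1", 100, 300, 6.0, 0.01, "up")])
        tars = seg.call_tars(w, 0.05, "c1")
        assert tars[["start", "end"]].values.tolist() == [[0, 300]]
        assert tars.iloc[0]["score"] == 6.0
        assert tars.iloc[0]["kind"] == "TAR"

    def test_no_significant_windows(self):
        w = _window_table([("chr1", 0, 200, 5.0, 0.5, "up")])
        assert len(seg.call_tars(w, 0.05)) == 0

    def test_chromosomes_stay_separate(self):
        w = _window_table([("chr1", 0, 200, 5.0, 0.01, "up"),
                           ("chr2", 0, 200, 5.0, 0.01, "up")])
        assert len(seg.call_tars(w, 0.05)) == 2

    def test_opposite_directions_give_abutting_de_tars(self):
        w = _window_table([("chr1", 0, 200, 1.0, 0.001, "up"),
                           ("chr1", 100, 300, -1.0, 0.001, "down")])
        detars = seg.call_de_tars(w, 0.005)
        assert len(detars) == 2
        assert sorted(detars["direction"]) == ["down", "up"]

    def test_missing_h_intervals_raise(self, small_probes):
        with pytest.raises(ValueError, match="missing H intervals"):
            seg.segment_differential(
                small_probes, ("rest", "stim"), {"rest": intervals([])},
                seg.SegmentationConfig(n_permutations=1, gc_classes=1),
            )


class TestEndToEnd:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        """120 probes, one strongly expressed block, modest null elsewhere."""
        rng = np.random.default_rng(9)
        starts = np.arange(0, 120 * 35, 35)
        values = rng.normal(6.0, 0.5, size=120)
        inside = (starts >= 1400) & (starts < 2800)
        values[inside] += 3.0
        probes = make_probes(starts, gc=rng.beta(10, 10, 120))
        probes["cond"] = values
        return probes, inside

    def test_planted_block_called_significant(self, planted):
        probes, inside = planted
        cfg = seg.SegmentationConfig(n_permutations=300, gc_classes=1,
                                     q_threshold=0.05, seed=4)
        windows, tars = seg.segment_expressed(probes, "cond", cfg)
        assert len(tars) >= 1
        top = tars.sort_values("score").iloc[-1]
        assert top["start"] < 1600 and top["end"] > 2600

    def test_lower_q_never_enlarges_tars(self, planted):
        probes, _ = planted
        cfg = seg.SegmentationConfig(n_permutations=300, gc_classes=1, seed=4)
        windows, _ = seg.segment_expressed(probes, "cond", cfg)
        nts = []
        for q in (0.05, 0.01, 0.001):
            tars = seg.call_tars(windows, q)
            nts.append(int((tars["end"] - tars["start"]).sum())
                       if len(tars) else 0)
        assert nts[0] >= nts[1] >= nts[2]

    def test_h_restriction_masks_outside_windows(self, planted):
        """A significant DE window outside every H interval is not reported;
        inside an H interval of one condition it is."""
        probes, inside = planted
        rng = np.random.default_rng(5)
        probes = probes.copy()
        probes["other"] = rng.normal(6.0, 0.5, size=len(probes))
        # strong differential signal in a region expressed in neither condition
        out_block = (probes["start"] >= 95 * 35) & (probes["start"] < 115 * 35)
        probes.loc[out_block, "other"] += 4.0

        h_in = {"cond": intervals([("chr1", 1400, 2800)]),
                "other": intervals([])}
        cfg = seg.differential_config(n_permutations=300, seed=6)
        windows, detars = seg.segment_differential(
            probes, ("cond", "other"), h_in, cfg
        )
        eligible_block = windows[windows["start"].between(95 * 35, 115 * 35 - 200)]
        assert not eligible_block["eligible"].any()
        assert eligible_block["q"].isna().all()
        # the planted expressed block is eligible via cond's H interval
        in_block = windows[windows["start"].between(1400, 2600)]
        assert in_block["eligible"].all()


class TestGcConfounding:
    def test_gc_binning_reduces_false_positives(self):
        """With a GC-driven intensity gradient and no planted signal, 4-bin
        nulls call fewer windows significant than a 1-bin null."""
        rng = np.random.default_rng(21)
        n = 2_000
        starts = np.arange(0, n * 35, 35)
        # regionally coherent GC (isochore-like), so whole windows share a
        # GC-driven intensity offset that a global shuffle would destroy
        gc = np.clip(
            0.5 + 0.2 * np.sin(2 * np.pi * starts / 14_000)
            + rng.normal(0, 0.02, n), 0.05, 0.95,
        )
        values = 6.0 + 4.0 * (gc - gc.mean()) + rng.normal(0, 0.5, n)
        probes = make_probes(starts, gc=gc)
        probes["cond"] = values
        sig = {}
        for classes in (1, 4):
            cfg = seg.SegmentationConfig(n_permutations=150, gc_classes=classes,
                                         q_threshold=0.05, seed=8)
            windows, _ = seg.segment_expressed(probes, "cond", cfg)
            sig[classes] = int((windows["q"] < 0.05).sum())
        assert sig[4] < sig[1]
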