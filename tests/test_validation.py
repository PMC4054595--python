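"""Probe filtering, cross-platform FDR, decay profiling, proximal pairs."""

import numpy as np
import pandas as pd
import pytest

from tilemacro.intervals import intervals
from tilemacro.validation import (
    decay_profile,
    default_q_grid,
    fdr_curve,
    pairs_frame,
    probe_nonspecific_filter,
    proximal_pairs,
)


class TestNonspecificFilter:
    # negative controls with mean 4, sd 0.2 -> background 4.6
    neg = np.array([3.8, 4.2, 4.0, 4.0])

    def test_expression_criterion_counts_samples_above_background(self):
        probes = np.array([[5, 5, 5, 5, 3]], dtype=float)
        # passes expression (4 of 5 above 4.6) but IQR = 0 -> filtered
        out = probe_nonspecific_filter(probes, self.neg, min_samples=4,
                                       iqr_min=0.5)
        assert out.tolist() == [False]

    def test_three_of_five_fails_expression(self):
        probes = np.array([[5, 5, 5, 3, 3]], dtype=float)
        out = probe_nonspecific_filter(probes, self.neg, min_samples=4,
                                       iqr_min=0.0)
        assert out.tolist() == [False]

    def test_constant_probe_fails_iqr(self):
        probes = np.array([[10, 10, 10, 10, 10]], dtype=float)
        out = probe_nonspecific_filter(probes, self.neg, min_samples=4,
                                       iqr_min=0.5)
        assert out.tolist() == [False]

    def test_variable_expressed_probe_passes(self):
        probes = np.array([[5.0, 6.5, 5.2, 7.0, 6.0]])
        out = probe_nonspecific_filter(probes, self.neg, min_samples=4,
                                       iqr_min=0.5)
        assert out.tolist() == [True]

    def test_no_negative_controls_is_an_error(self):
        with pytest.raises(ValueError):
            probe_nonspecific_filter(np.ones((1, 4)), np.empty(0))


def window_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "q"])


def reference_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "de_flag"])
    df["de_flag"] = df["de_flag"].astype(bool)
    return df


class TestFdrCurve:
    def test_forced_arithmetic(self):
        """TP = 80 nt, FP = 20 nt -> FDR 0.2, sensitivity TP/P."""
        windows = window_table([("chr1", 0, 100, 0.001)])
        ref = reference_table([
            ("chr1", 0, 80, True),    # 80 covered DE nt
            ("chr1", 80, 100, False),  # 20 covered non-DE nt
            ("chr1", 200, 220, True),  # uncovered DE probe -> P = 100
        ])
        out = fdr_curve(windows, ref, q_grid=[0.01])
        row = out.iloc[0]
        assert (row["TP"], row["FP"], row["P"], row["N"]) == (80, 20, 100, 20)
        assert row["fdr"] == pytest.approx(0.2)
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["specificity"] == pytest.approx(0.0)

    def test_zero_fp_gives_zero_fdr(self):
        windows = window_table([("chr1", 0, 80, 0.001)])
        ref = reference_table([("chr1", 0, 80, True),
                               ("chr1", 500, 600, False)])
        row = fdr_curve(windows, ref, q_grid=[0.01]).iloc[0]
        assert row["FP"] == 0 and row["fdr"] == 0.0
        assert row["specificity"] == 1.0

    def test_conflicting_probe_flags_count_once_as_de(self):
        windows = window_table([("chr1", 0, 100, 0.001)])
        ref = reference_table([("chr1", 0, 60, True), ("chr1", 40, 100, False)])
        row = fdr_curve(windows, ref, q_grid=[0.01]).iloc[0]
        assert row["P"] == 60 and row["N"] == 40
        assert row["TP"] + row["FP"] == 100

    def test_monotone_in_q(self):
        rng = np.random.default_rng(8)
        rows = [("chr1", s, s + 200, float(rng.uniform(1e-5, 1)))
                for s in range(0, 40_000, 200)]
        windows = window_table(rows)
        ref = reference_table([
            ("chr1", s, s + 60, bool(rng.random() < 0.4))
            for s in range(0, 40_000, 120)
        ])
        out = fdr_curve(windows, ref, q_grid=default_q_grid(15))
        assert (np.diff(out["sensitivity"]) >= -1e-12).all()
        assert (np.diff(out["specificity"]) <= 1e-12).all()

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            fdr_curve(window_table([("chr1", 0, 100, 0.5)]),
                      reference_table([]))


class TestDecayProfile:
    def probes(self, values):
        starts = np.arange(0, len(values) * 100, 100)
        return pd.DataFrame(
            {"chrom": "chr1", "start": starts, "length": 25, "z": values}
        )

    def test_constant_values_give_flat_profile(self):
        probes = self.probes(np.full(100, 2.0))
        segs = intervals([("chr1", 0, 10_000)])
        out = decay_profile(segs, probes, "z", n_bins=5)
        assert np.allclose(out["mean"], 2.0)

    def test_planted_linear_decay_is_monotone(self):
        vals = np.linspace(3.0, 0.5, 100)
        probes = self.probes(vals)
        segs = intervals([("chr1", 0, 10_000)])
        out = decay_profile(segs, probes, "z", n_bins=10)
        assert (np.diff(out["mean"]) < 0).all()

    def test_single_bin_equals_overall_mean(self):
        vals = np.arange(100, dtype=float)
        probes = self.probes(vals)
        segs = intervals([("chr1", 0, 10_000)])
        out = decay_profile(segs, probes, "z", n_bins=1)
        assert len(out) == 1
        assert out.iloc[0]["mean"] == pytest.approx(vals.mean())

    def test_minus_strand_flips_orientation(self):
        vals = np.linspace(3.0, 0.5, 100)
        probes = self.probes(vals)
        segs = intervals([("chr1", 0, 10_000)])
        segs["strand"] = "-"
        out = decay_profile(segs, probes, "z", n_bins=10)
        assert (np.diff(out["mean"]) > 0).all()

    def test_probe_free_segment_skipped(self):
        probes = self.probes(np.full(10, 1.0))
        segs = intervals([("chr1", 0, 1_000), ("chr2", 0, 1_000)])
        out = decay_profile(segs, probes, "z", n_bins=2)
        assert out.attrs["n_segments"] == 1


def gene_row(gene_id, start, end, strand, de=True, direction="down",
             consistent=True, chrom="chr1"):
    return {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "de": de, "direction": direction,
            "consistent": consistent}


def probe_row(pid, pos, strand, direction, chrom="chr1"):
    return {"probe_id": pid, "chrom": chrom, "pos": pos, "strand": strand,
            "direction": direction}


class TestProximalPairs:
    @pytest.mark.parametrize(
        "p_strand,p_dir,g_strand,g_dir,verdict,reason",
        [
            ("+", "up", "+", "down", "retained", "opposite-direction-same-strand"),
            ("+", "down", "+", "up", "retained", "opposite-direction-same-strand"),
            ("+", "up", "+", "up", "excluded", "same-direction-same-strand"),
            ("+", "down", "+", "down", "excluded", "same-direction-same-strand"),
            ("+", "up", "-", "down", "excluded", "different-strand"),
            ("+", "up", "-", "up", "excluded", "different-strand"),
        ],
    )
    def test_strand_direction_rules(self, p_strand, p_dir, g_strand, g_dir,
                                    verdict, reason):
        genes = pd.DataFrame([gene_row("g1", 10_000, 20_000, g_strand,
                                       direction=g_dir)])
        probes = pd.DataFrame([probe_row("p1", 5_000, p_strand, p_dir)])
        calls = proximal_pairs(probes, genes)
        assert calls[0].verdict == verdict
        assert calls[0].reason == reason

    def test_non_de_gene_never_pairs(self):
        genes = pd.DataFrame([gene_row("g1", 10_000, 20_000, "+", de=False)])
        probes = pd.DataFrame([probe_row("p1", 5_000, "+", "up")])
        assert proximal_pairs(probes, genes)[0].reason == "gene-not-differential"

    def test_inconsistent_gene_sign_excluded(self):
        genes = pd.DataFrame([gene_row("g1", 10_000, 20_000, "+",
                                       consistent=False)])
        probes = pd.DataFrame([probe_row("p1", 5_000, "+", "up")])
        assert proximal_pairs(probes, genes)[0].reason == "gene-sign-inconsistent"

    def test_nearest_gene_chosen_strand_blind(self):
        genes = pd.DataFrame([
            gene_row("near", 6_000, 7_000, "-"),
            gene_row("far", 20_000, 30_000, "+"),
        ])
        probes = pd.DataFrame([probe_row("p1", 5_500, "+", "up")])
        call = proximal_pairs(probes, genes)[0]
        assert call.gene_id == "near"
        assert call.distance == 500

    def test_overlapping_gene_distance_zero(self):
        genes = pd.DataFrame([gene_row("g1", 1_000, 9_000, "+")])
        probes = pd.DataFrame([probe_row("p1", 5_000, "+", "up")])
        assert proximal_pairs(probes, genes)[0].distance == 0

    def test_equidistant_tie_breaks_to_lower_coordinate(self):
        genes = pd.DataFrame([
            gene_row("downstream", 6_000, 7_000, "+"),
            gene_row("upstream", 3_000, 4_000, "+"),
        ])
        probes = pd.DataFrame([probe_row("p1", 5_000, "+", "up")])
        # distances: to upstream end-1 (3999) = 1001; to downstream start = 1000
        probes2 = pd.DataFrame([probe_row("p1", 4_999, "+", "up")])
        call = proximal_pairs(probes2, genes)[0]
        assert call.gene_id == "upstream"  # tie at 1000 nt -> lower coordinate

    def test_no_genes_on_chromosome_reports_unpaired(self):
        genes = pd.DataFrame([gene_row("g1", 0, 100, "+", chrom="chr9")])
        probes = pd.DataFrame([probe_row("p1", 5_000, "+", "up")])
        assert proximal_pairs(probes, genes)[0].verdict == "unpaired"

    def test_verdicts_invariant_under_input_order(self):
        rng = np.random.default_rng(12)
        genes = pd.DataFrame([
            gene_row(f"g{i}", int(s), int(s) + 2_000,
                     "+" if rng.random() < 0.5 else "-",
                     de=bool(rng.random() < 0.8),
                     direction="up" if rng.random() < 0.5 else "down",
                     consistent=bool(rng.random() < 0.9))
            for i, s in enumerate(rng.choice(200_000, 10, replace=False))
        ])
        probes = pd.DataFrame([
            probe_row(f"p{i}", int(p), "+" if rng.random() < 0.5 else "-",
                      "up" if rng.random() < 0.5 else "down")
            for i, p in enumerate(rng.choice(200_000, 15, replace=False))
        ])
        base = pairs_frame(proximal_pairs(probes, genes)).sort_values(
            "probe_id").reset_index(drop=True)
        shuffled = pairs_frame(proximal_pairs(
            probes.sample(frac=1, random_state=3),
            genes.sample(frac=1, random_state=4),
        )).sort_values("probe_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(base, shuffled)
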