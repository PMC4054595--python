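"""Shared fixtures: a small synthetic genome with planted truth."""

import pandas as pd
import pytest

from tilemacro import synth


@pytest.fixture(scope="session")
def small_genome():
    cfg = synth.GenomeConfig(
        chrom_sizes={"chr1": 600_000}, n_genes=4,
        gene_span=(20_000, 40_000), repeat_fraction=0.15,
        n_gaps=1, n_lncrnas=1,
    )
    return synth.generate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    cfg = synth.TruthConfig(
        n_differential_segments=2, differential_length=(3_000, 6_000),
        n_macrornas=1, macro_length=(30_000, 40_000),
    )
    return synth.make_truth(small_genome, cfg, seed=12)


@pytest.fixture(scope="session")
def small_probes(small_genome, small_truth):
    probes = synth.generate_probes(small_genome, seed=13)
    return synth.simulate_intensities(probes, small_truth, seed=14)


@pytest.fixture()
def iv():
    """Shorthand interval-frame builder."""
    from tilemacro.intervals import intervals

    return intervals


def null_truth(conditions=("a", "b")) -> synth.TruthSet:
    """A truth set with nothing planted (global null)."""
    return synth.TruthSet(
        expressed={}, differential={}, macrornas=[],
        condition_times={c: 0.0 for c in conditions},
    )
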