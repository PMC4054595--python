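"""End-to-end orchestration: simulate -> segment -> filter -> stairfinder ->
enrich -> validate, reproducibly from one config.

A run writes each stage's outputs into its own subdirectory of a write-once
run directory, plus a JSON manifest recording parameters, per-stage seeds
(derived as ``seed + stage index`` so stages can be rerun independently),
stage-level counts and sha256 checksums of every output file.  Rerunning
with the same config reproduces the manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import noncoding, segmentation, synth, validation
from .enrichment import enrichment_report
from .genomeio import write_bed, write_chrom_sizes, write_gff3_genes, write_probe_table
from .intervals import empty_intervals, merge_intervals
from .stairfinder import stairfinder

STAGES = ("simulate", "segment", "filter", "stairfinder", "enrich", "validate")


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters.

    Segmentation, detector and enrichment defaults are the production
    settings of the analysis (200-nt windows, q < 0.05 with 10,000
    GC-binned permutations in 4 classes for expression; q < 0.005 with
    100,000 difference shuffles in 1 class for differential calls; 100-kb
    bandwidth with 50% flooding; 100 background lists; 17-nt minimum
    non-coding interval).  ``genome`` and ``truth`` override the synthetic
    generator's layout.
    """

    seed: int = 1
    window: int = 200
    min_probes: int = 3
    q_expressed: float = 0.05
    q_differential: float = 0.005
    permutations_expressed: int = 10_000
    permutations_differential: int = 100_000
    gc_classes_expressed: int = 4
    gc_classes_differential: int = 1
    bandwidth: float = 100_000.0
    level: float = 0.5
    min_macro_length: int = 10_000
    min_noncoding_length: int = 17
    n_backgrounds: int = 100
    probe_length: int = 25
    probe_spacing: int = 35
    noise_sd: float = 0.5
    gc_effect: float = 1.0
    baseline: float = 6.0
    flip_rate: float = 0.0
    fdr_q_grid_points: int = 20
    decay_bins: int = 20
    genome: dict = dataclasses.field(default_factory=dict)
    truth: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0 < self.q_expressed <= 1, "q_expressed must be in (0, 1]"),
            (0 < self.q_differential <= 1, "q_differential must be in (0, 1]"),
            (self.permutations_expressed >= 1, "permutations_expressed >= 1"),
            (self.permutations_differential >= 1, "permutations_differential >= 1"),
            (self.gc_classes_expressed >= 1, "gc_classes_expressed >= 1"),
            (self.gc_classes_differential >= 1, "gc_classes_differential >= 1"),
            (self.bandwidth > 0, "bandwidth must be > 0"),
            (0 <= self.level <= 1, "level must be in [0, 1]"),
            (self.min_macro_length >= 1, "min_macro_length >= 1"),
            (self.min_noncoding_length >= 1, "min_noncoding_length >= 1"),
            (self.n_backgrounds >= 1, "n_backgrounds >= 1"),
            (self.probe_spacing >= 1, "probe_spacing >= 1"),
            (self.noise_sd > 0, "noise_sd must be > 0"),
            (0 <= self.flip_rate < 0.5, "flip_rate must be in [0, 0.5)"),
            (self.window >= 1 and self.min_probes >= 3,
             "window >= 1 and min_probes >= 3"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def genome_config(self) -> synth.GenomeConfig:
        return synth.GenomeConfig(**_coerce(self.genome, synth.GenomeConfig))

    def truth_config(self) -> synth.TruthConfig:
        return synth.TruthConfig(**_coerce(self.truth, synth.TruthConfig))


def _coerce(overrides: dict, dc_type) -> dict:
    """Coerce YAML lists back to the tuples the dataclasses expect."""
    out = {}
    defaults = {f.name: f.default_factory() if f.default_factory
                is not dataclasses.MISSING else f.default
                for f in dataclasses.fields(dc_type)}
    for key, val in (overrides or {}).items():
        if key not in defaults:
            raise ValueError(f"unknown {dc_type.__name__} key {key!r}")
        if isinstance(defaults[key], tuple) and isinstance(val, list):
            val = tuple(val)
        out[key] = val
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir: str) -> dict[str, Any]:
    """Run all six stages, returning (and writing) the manifest."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "parameters": dataclasses.asdict(config),
        "stages": [],
    }
    state: dict[str, Any] = {}
    for i, stage in enumerate(STAGES):
        stage_seed = config.seed + i
        stage_dir = os.path.join(out_dir, f"{i + 1:02d}_{stage}")
        os.makedirs(stage_dir, exist_ok=True)
        try:
            counts = _STAGE_FUNCS[stage](config, stage_seed, stage_dir, state)
        except Exception as err:  # noqa: BLE001 - abort names the stage
            raise StageFailure(stage, err) from err
        outputs = {
            name: _sha256(os.path.join(stage_dir, name))
            for name in sorted(os.listdir(stage_dir))
        }
        manifest["stages"].append(
            {"name": stage, "seed": stage_seed, "counts": counts,
             "outputs": outputs}
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    genome = synth.generate_genome(config.genome_config(), seed)
    truth = synth.make_truth(genome, config.truth_config(), seed + 1000)
    probes = synth.generate_probes(
        genome, config.probe_length, config.probe_spacing, seed=seed + 2000
    )
    probes = synth.simulate_intensities(
        probes, truth, config.noise_sd, config.gc_effect, config.baseline,
        seed=seed + 3000,
    )
    contrast = tuple(truth.conditions()[:2])
    ref_positions = probes.assign(end=probes["start"] + probes["length"])
    reference = synth.generate_reference_platform(
        truth, contrast, ref_positions, config.flip_rate, seed + 4000
    )
    state.update(genome=genome, truth=truth, probes=probes,
                 reference=reference, contrast=contrast)

    write_chrom_sizes(genome.chrom_sizes, os.path.join(out, "chrom.sizes"))
    write_gff3_genes(genome.genes, genome.exons, os.path.join(out, "genes.gff3"))
    for name, df in [("repeats", genome.repeats), ("gaps", genome.gaps),
                     ("lncrnas", genome.lncrnas)]:
        write_bed(df, os.path.join(out, f"{name}.bed"))
    write_probe_table(probes, os.path.join(out, "probes.tsv"))
    for cond, df in truth.expressed.items():
        write_bed(df.assign(name=cond,
                            score=(df["amplitude"] * 1000).round().astype(int),
                            strand=".")[
            ["chrom", "start", "end", "name", "score", "strand"]],
            os.path.join(out, f"truth_expressed_{cond}.bed"))
    diff = truth.differential.get(contrast, empty_intervals())
    if len(diff):
        write_bed(diff.assign(name="diff",
                              score=(diff["effect"] * 1000).round().astype(int),
                              strand=".")[
            ["chrom", "start", "end", "name", "score", "strand"]],
            os.path.join(out, "truth_differential.bed"))
    pd.DataFrame([dataclasses.asdict(m) for m in truth.macrornas]).to_csv(
        os.path.join(out, "truth_macrornas.tsv"), sep="\t", index=False
    )
    reference.to_csv(os.path.join(out, "reference.tsv"), sep="\t", index=False)
    return {"probes": len(probes), "conditions": len(truth.conditions()),
            "macrornas": len(truth.macrornas)}


def _stage_segment(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    probes, truth = state["probes"], state["truth"]
    contrast = state["contrast"]
    h_intervals: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    for j, cond in enumerate(truth.conditions()):
        cfg = segmentation.SegmentationConfig(
            window=config.window, min_probes=config.min_probes,
            n_permutations=config.permutations_expressed,
            gc_classes=config.gc_classes_expressed,
            q_threshold=config.q_expressed, seed=seed + j,
        )
        windows, tars = segmentation.segment_expressed(probes, cond, cfg)
        windows.to_csv(os.path.join(out, f"windows_{cond}.tsv"),
                       sep="\t", index=False)
        _write_segments(tars, os.path.join(out, f"tars_{cond}.bed"))
        h_intervals[cond] = tars
        counts[f"windows_{cond}"] = int((~windows["q"].isna()).sum())
        counts[f"significant_windows_{cond}"] = int(
            (windows["q"] < config.q_expressed).sum())
        counts[f"tars_{cond}"] = len(tars)
    dcfg = segmentation.SegmentationConfig(
        window=config.window, min_probes=config.min_probes,
        n_permutations=config.permutations_differential,
        gc_classes=config.gc_classes_differential,
        q_threshold=config.q_differential, seed=seed + 100,
    )
    dwindows, detars = segmentation.segment_differential(
        probes, contrast, h_intervals, dcfg
    )
    dwindows.to_csv(os.path.join(out, "windows_differential.tsv"),
                    sep="\t", index=False)
    _write_segments(detars, os.path.join(out, "detars.bed"))
    counts["de_tars"] = len(detars)
    counts["de_tar_nt"] = int((detars["end"] - detars["start"]).sum()) \
        if len(detars) else 0
    state.update(h_intervals=h_intervals, diff_windows=dwindows, detars=detars)
    return counts


def _write_segments(segs: pd.DataFrame, path: str) -> None:
    if len(segs) == 0:
        open(path, "w").close()
        return
    bed = segs.copy()
    bed["score"] = (bed["score"] * 1000).round().astype(int)
    bed["strand"] = "."
    write_bed(bed, path)


def _stage_filter(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    genome, detars = state["genome"], state["detars"]
    ann = genome.annotation()
    evidence = noncoding.CodingEvidence(
        coding_exons=ann.get("coding_exon"),
        pseudogene_exons=empty_intervals(),
        rnacode_hits=empty_intervals(),
        rnacode_covered=empty_intervals(),
        tblastn_hits=empty_intervals(),
    )
    segs = detars[["chrom", "start", "end"]] if len(detars) else empty_intervals()
    bona = noncoding.bona_fide_filter(segs, evidence, ann,
                                      config.min_noncoding_length)
    if len(bona):
        write_bed(bona.assign(name=bona["klass"], score=0, strand=".")[
            ["chrom", "start", "end", "name", "score", "strand"]],
            os.path.join(out, "bona_fide_noncoding.bed"))
    else:
        open(os.path.join(out, "bona_fide_noncoding.bed"), "w").close()
    state["bona_fide"] = bona
    return {
        "bona_fide_intervals": len(bona),
        "bona_fide_nt": int((bona["end"] - bona["start"]).sum()) if len(bona) else 0,
        "intergenic": int((bona["klass"] == "intergenic").sum()) if len(bona) else 0,
        "intronic": int((bona["klass"] == "intronic").sum()) if len(bona) else 0,
    }


def _stage_stairfinder(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    genome, detars = state["genome"], state["detars"]
    # macro accumulations are detected on the density of TARs and DE-TARs
    parts = [t[["chrom", "start", "end"]] for t in state["h_intervals"].values()
             if len(t)]
    if len(detars):
        parts.append(detars[["chrom", "start", "end"]])
    segs = pd.concat(parts, ignore_index=True) if parts else empty_intervals()
    regions = stairfinder(
        segs, genome.annotation(), bandwidth=config.bandwidth,
        level=config.level, min_length=config.min_macro_length,
        chrom_sizes=genome.chrom_sizes,
    )
    regions.to_csv(os.path.join(out, "macro_regions.tsv"), sep="\t", index=False)
    state["macro_regions"] = regions
    return {"regions": len(regions),
            "macro_regions": int(regions["is_macro"].sum()) if len(regions) else 0}


def _stage_enrich(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    genome = state["genome"]
    bona = state["bona_fide"]
    ann = genome.annotation()
    query = bona[["chrom", "start", "end"]] if len(bona) else empty_intervals()
    path = os.path.join(out, "enrichment.tsv")
    if len(query) == 0:
        pd.DataFrame().to_csv(path, sep="\t", index=False)
        return {"annotations": 0}
    space = pd.DataFrame(
        {"chrom": list(genome.chrom_sizes), "start": 0,
         "end": list(genome.chrom_sizes.values())}
    )
    exclusions = merge_intervals(
        pd.concat([genome.repeats, genome.gaps], ignore_index=True)
    ) if len(genome.repeats) + len(genome.gaps) else empty_intervals()
    annotations = {
        "coding_exon": ann.get("coding_exon"),
        "intron": ann.get("intron"),
        "lncrna_exon": ann.get("lncrna_exon"),
        "gene_body": ann.get("gene_body")[["chrom", "start", "end"]],
    }
    report = enrichment_report(query, annotations, space, exclusions,
                               n_backgrounds=config.n_backgrounds, seed=seed)
    report.to_csv(path, sep="\t", index=False)
    return {"annotations": len(report)}


def _stage_validate(config: RunConfig, seed: int, out: str, state: dict) -> dict:
    truth, probes = state["truth"], state["probes"]
    reference, contrast = state["reference"], state["contrast"]
    dwindows = state["diff_windows"]
    curve = validation.fdr_curve(
        dwindows, reference, validation.default_q_grid(config.fdr_q_grid_points)
    )
    curve.to_csv(os.path.join(out, "fdr_curve.tsv"), sep="\t", index=False)

    macro_ext = truth.macro_extent(contrast[1])
    zprobes = probes.copy()
    zprobes["z"] = (
        probes[contrast[1]] - probes[contrast[1]].mean()
    ) / probes[contrast[1]].std(ddof=0)
    profile = validation.decay_profile(macro_ext, zprobes, "z",
                                       n_bins=config.decay_bins)
    profile.to_csv(os.path.join(out, "decay_profile.tsv"), sep="\t", index=False)
    at_005 = curve.iloc[(curve["q"] - config.q_differential).abs().argmin()]
    return {"fdr_grid_points": len(curve),
            "fdr_at_q_nearest": float(at_005["fdr"]),
            "decay_bins": len(profile)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "filter": _stage_filter,
    "stairfinder": _stage_stairfinder,
    "enrich": _stage_enrich,
    "validate": _stage_validate,
}
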