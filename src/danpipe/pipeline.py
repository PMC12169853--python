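"""Simulate-then-analyze pipeline tying the three stages together.

:func:`run_pipeline` executes the requested stages in order — connectome
hub analysis, reciprocal-conditioning statistics, calcium-response
quantification — on either user-supplied tables or freshly simulated
ones, writes every output with a provenance header, and returns a
manifest listing all files together with the configuration and seed
used.  Identical configuration and seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .behavior import compare_groups, performance_index, significance_code
from .connectome import (
    AnalysisConfig,
    aggregate_pairs,
    cluster_specificity,
    find_sensory_to_dan_interneurons,
    hub_table,
    hub_table_frame,
    input_decomposition,
    load_connectome,
    sensory_composition,
)
from .imaging import compute_dff, group_response_test, peak_response
from .simulate import (
    BehaviorSimConfig,
    ConnectomeSimConfig,
    TraceSimConfig,
    simulate_behavior,
    simulate_connectome,
    simulate_traces,
)

logger = logging.getLogger(__name__)

STAGES = ("connectome", "behavior", "imaging")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineConfig:
    outdir: Path = Path("danpipe-out")
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # input tables; None means simulate with the matching sim config
    edges_path: Path | None = None
    annotations_path: Path | None = None
    counts_path: Path | None = None
    traces_path: Path | None = None
    connectome_sim: ConnectomeSimConfig = field(default_factory=ConnectomeSimConfig)
    behavior_sim: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    trace_sim: TraceSimConfig = field(default_factory=TraceSimConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for p in (self.edges_path, self.annotations_path,
                  self.counts_path, self.traces_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")


def _reseeded(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def run_connectome_stage(config: PipelineConfig, outdir: Path) -> list[Path]:
    seed = config.seed
    if config.edges_path is not None and config.annotations_path is not None:
        edges = io.read_edges(config.edges_path)
        ann = io.read_annotations(config.annotations_path)
        truth = None
    else:
        sim = _reseeded(config.connectome_sim, seed)
        edges, ann, truth = simulate_connectome(sim)
    files = [
        io.write_edges(edges, outdir / "edges.csv", seed, config.analysis),
        io.write_annotations(ann, outdir / "annotations.tsv", seed, config.analysis),
    ]
    if truth is not None:
        files.append(io.write_json(truth.to_dict(), outdir / "connectome_truth.json",
                                   seed, config.analysis))

    cg = load_connectome(edges, ann)
    if config.analysis.pair_mode == "per_pair":
        cg = aggregate_pairs(cg)
    dan_ids = cg.dan_ids()
    records = hub_table(cg, dan_ids, config.analysis)
    files.append(io.write_table(hub_table_frame(records), outdir / "hubs.csv",
                                seed, config.analysis))

    paths = find_sensory_to_dan_interneurons(cg, dan_ids, config.analysis)
    decomp_rows = [
        dataclasses.asdict(
            input_decomposition(cg, d, paths.interneurons_by_dan[d], config.analysis)
        )
        for d in dan_ids
    ]
    files.append(io.write_table(pd.DataFrame(decomp_rows),
                                outdir / "decomposition.csv",
                                seed, config.analysis))

    dl1, ppam = cg.dan_ids("DL1"), cg.dan_ids("pPAM")
    if dl1 and ppam:
        report = cluster_specificity(cg, dl1, ppam, config.analysis)
        files.append(io.write_json(dataclasses.asdict(report),
                                   outdir / "specificity.json",
                                   seed, config.analysis))
    if paths.interneuron_union:
        comp = sensory_composition(cg, paths.interneuron_union, config.analysis)
        files.append(io.write_json({"composition_pct": comp},
                                   outdir / "sensory_composition.json",
                                   seed, config.analysis))
    return files


def run_behavior_stage(config: PipelineConfig, outdir: Path) -> list[Path]:
    seed = config.seed
    files = []
    if config.counts_path is not None:
        counts = io.read_counts(config.counts_path)
    else:
        sim = _reseeded(config.behavior_sim, seed)
        counts, truth = simulate_behavior(sim)
        files.append(io.write_json({"theta_by_group": truth},
                                   outdir / "behavior_truth.json", seed, sim))
    files.append(io.write_counts(counts, outdir / "counts.csv", seed))

    pairs_by_group = io.reciprocal_pairs_from_counts(counts)
    pi_rows = []
    for group, pairs in sorted(pairs_by_group.items()):
        for i, pair in enumerate(pairs, start=1):
            pi_rows.append((group, i, performance_index(pair)))
    pi_df = pd.DataFrame(pi_rows, columns=["group", "replicate", "pi"])
    files.append(io.write_table(pi_df, outdir / "pi.csv", seed))

    if len(pairs_by_group) >= 2:
        groups = {g: pi_df.loc[pi_df.group == g, "pi"].to_numpy()
                  for g in sorted(pairs_by_group)}
        cmp_ = compare_groups(groups)
        report = dataclasses.asdict(cmp_)
        report["pairwise"] = [
            {**dataclasses.asdict(p),
             "significance": significance_code(p.p_value, cmp_.alpha)}
            for p in cmp_.pairwise
        ]
        files.append(io.write_json(report, outdir / "comparison.json", seed))
    return files


def run_imaging_stage(config: PipelineConfig, outdir: Path) -> list[Path]:
    seed = config.seed
    files = []
    if config.traces_path is not None:
        table = io.read_traces(config.traces_path)
    else:
        sim = _reseeded(config.trace_sim, seed)
        table, truth = simulate_traces(sim)
        files.append(io.write_json(truth, outdir / "traces_truth.json", seed, sim))
    files.append(io.write_traces(table, outdir / "traces.csv", seed))

    summaries = [
        peak_response(compute_dff(tr)) for tr in io.traces_from_table(table)
    ]
    sum_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    files.append(io.write_table(sum_df, outdir / "summaries.csv", seed))
    group = group_response_test(summaries)
    files.append(io.write_json(dataclasses.asdict(group),
                               outdir / "group_response.json", seed))
    return files


_STAGE_RUNNERS = {
    "connectome": run_connectome_stage,
    "behavior": run_behavior_stage,
    "imaging": run_imaging_stage,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and write a manifest; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            files = _STAGE_RUNNERS[stage](config, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        outputs.extend(sorted(str(f.relative_to(outdir)) for f in files))
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config_hash": io.config_hash(config),
        "outputs": outputs,
    }
    io.write_json(manifest, outdir / "manifest.json", config.seed, config)
    return manifest
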