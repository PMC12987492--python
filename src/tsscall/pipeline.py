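"""End-to-end prediction pipeline and the run configuration.

Order of operations: normalize -> detect (per replicate/strand) -> window
reduction -> cross-replicate reconciliation -> enrichment filter -> cross-
condition clustering -> gene-relative classification.  Everything is
deterministic given a configuration; the only randomness in the package
lives in the synthetic generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .classify import classify
from .consolidate import (DetectedTss, cluster_across_conditions,
                          enrichment_filter, reconcile_replicates)
from .detect import detect_candidates, reduce_close_candidates
from .errors import ConfigurationError
from .formats import (load_layout_pairs, read_fasta, read_gff,
                      write_gff_output, write_master_table,
                      write_normalized_tracks)
from .model import (CONTROL, ENRICHED, FORWARD, REVERSE, ConsolidatedTss,
                    ExperimentLayout, GeneRecord, LibraryPair)
from .normalize import NormalizationStats, normalize_experiment
from .params import ParameterSet
from .stats import differential_test, write_differential_tsv

logger = logging.getLogger(__name__)

_STRAND_NAMES = {"forward": FORWARD, "reverse": REVERSE}
_STRAND_KEYS = {FORWARD: "forward", REVERSE: "reverse"}


@dataclass
class RunConfig:
    """A complete, file-serializable description of one prediction run."""

    layout: ExperimentLayout
    params: ParameterSet = field(default_factory=ParameterSet)
    annotation: Path | None = None
    genome: Path | None = None
    output_dir: Path = Path("tsscall_out")
    export_normalized: bool = False
    write_gff: bool = True
    percentile_normalization: bool = True
    enrichment_normalization: bool = True
    differential_pairs: list[tuple[str, str]] = field(default_factory=list)
    half_window: int = 50

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        files: dict = {}
        for (cond, rep, strand, lib), path in self.layout.files.items():
            files.setdefault(cond, {}).setdefault(rep, {}).setdefault(
                _STRAND_KEYS[strand], {})[lib] = str(path)
        params = dataclasses.asdict(self.params)
        if params.get("preset_name") is None:
            params.pop("preset_name", None)
        return {
            "conditions": list(self.layout.conditions),
            "replicates": {c: list(r) for c, r in
                           self.layout.replicates.items()},
            "files": files,
            "annotation": str(self.annotation) if self.annotation else None,
            "genome": str(self.genome) if self.genome else None,
            "output_dir": str(self.output_dir),
            "parameters": params,
            "flags": {
                "export_normalized": self.export_normalized,
                "write_gff": self.write_gff,
                "percentile_normalization": self.percentile_normalization,
                "enrichment_normalization": self.enrichment_normalization,
            },
            "differential_pairs": [list(p) for p in self.differential_pairs],
            "half_window": self.half_window,
        }

    @classmethod
    def from_dict(cls, data: dict, base: Path | None = None) -> "RunConfig":
        def resolve(value):
            if value is None:
                return None
            path = Path(value)
            if base is not None and not path.is_absolute():
                path = base / path
            return path

        layout = ExperimentLayout(list(data["conditions"]),
                                  {c: list(r) for c, r in
                                   data["replicates"].items()})
        for cond, reps in data.get("files", {}).items():
            for rep, strands in reps.items():
                for strand_name, libs in strands.items():
                    strand = _STRAND_NAMES.get(strand_name, strand_name)
                    for lib, path in libs.items():
                        layout.assign(cond, rep, strand, lib, resolve(path))

        pdata = dict(data.get("parameters", {}))
        preset = pdata.pop("preset", None) or pdata.pop("preset_name", None)
        if preset:
            params = ParameterSet.from_preset(preset, **pdata)
        else:
            params = ParameterSet(**pdata)

        flags = data.get("flags", {})
        return cls(
            layout=layout, params=params,
            annotation=resolve(data.get("annotation")),
            genome=resolve(data.get("genome")),
            output_dir=resolve(data.get("output_dir", "tsscall_out")),
            export_normalized=flags.get("export_normalized", False),
            write_gff=flags.get("write_gff", True),
            percentile_normalization=flags.get("percentile_normalization",
                                               True),
            enrichment_normalization=flags.get("enrichment_normalization",
                                               True),
            differential_pairs=[tuple(p) for p in
                                data.get("differential_pairs", [])],
            half_window=int(data.get("half_window", 50)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data, base=path.parent)


@dataclass
class PredictionResult:
    tss: list[ConsolidatedTss]
    stats: NormalizationStats
    pairs: list[LibraryPair]           # normalized
    effective_params: ParameterSet
    stage_counts: dict[str, int]


def predict(pairs: Sequence[LibraryPair], conditions: Sequence[str],
            genes: Sequence[GeneRecord], params: ParameterSet,
            percentile: bool = True, enrichment: bool = True,
            ) -> PredictionResult:
    """Run the full in-memory pipeline on loaded library pairs."""
    norm_pairs, stats = normalize_experiment(
        pairs, percentile=percentile, enrichment=enrichment,
        percentile_rank=params.percentile_rank)
    effective = params.scaled_by(stats.q_min)

    groups: dict[tuple[str, str, str], dict[str, LibraryPair]] = {}
    for pair in norm_pairs:
        groups.setdefault((pair.condition, pair.replicon_id, pair.strand),
                          {})[pair.replicate] = pair

    counts = {"candidates": 0, "detected": 0, "enriched": 0}
    by_condition: dict[str, list[DetectedTss]] = {c: [] for c in conditions}
    for (cond, _replicon, _strand), reps in sorted(groups.items()):
        cands_by_rep = {}
        for rep, pair in reps.items():
            cands = reduce_close_candidates(
                detect_candidates(pair, effective),
                effective.window, effective.reduction_mode)
            counts["candidates"] += len(cands)
            cands_by_rep[rep] = cands
        detected = reconcile_replicates(cands_by_rep, reps, effective)
        counts["detected"] += len(detected)
        enriched_tss = enrichment_filter(detected, reps, effective)
        counts["enriched"] += len(enriched_tss)
        by_condition[cond].extend(enriched_tss)

    tss = cluster_across_conditions(by_condition, effective, conditions)
    counts["consolidated"] = len(tss)
    classify(tss, genes, effective)
    return PredictionResult(tss, stats, norm_pairs, effective, counts)


def run_predict(config: RunConfig) -> PredictionResult:
    """Load inputs, run the pipeline and write all outputs to disk."""
    config.layout.validate()
    n_reps = min(len(r) for r in config.layout.replicates.values())
    if config.params.min_replicates > n_reps:
        raise ConfigurationError(
            f"min_replicates={config.params.min_replicates} exceeds the "
            f"{n_reps} replicates of the smallest condition")

    pairs = load_layout_pairs(config.layout)
    genes = read_gff(config.annotation) if config.annotation else []
    genome = read_fasta(config.genome) if config.genome else None

    result = predict(pairs, config.layout.conditions, genes, config.params,
                     percentile=config.percentile_normalization,
                     enrichment=config.enrichment_normalization)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_master_table(result.tss, config.layout, out / "MasterTable.tsv",
                       genome=genome)
    if config.write_gff:
        for cond in config.layout.conditions:
            write_gff_output(result.tss, cond, out / f"TSS_{cond}.gff")
    if config.export_normalized:
        write_normalized_tracks(result.pairs, out / "normalized")

    log = {
        "normalization": {
            "percentile_rank": result.stats.percentile_rank,
            "q_min": result.stats.q_min,
            "q_pl": {"/".join(k): v for k, v in result.stats.q_pl.items()},
            "ef_max": result.stats.ef_max,
            "median_ef": {"/".join(k): v
                          for k, v in result.stats.median_ef.items()},
        },
        "effective_parameters": dataclasses.asdict(result.effective_params),
        "stage_counts": result.stage_counts,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    logger.info("prediction finished: %s", result.stage_counts)
    return result


def run_differential(config: RunConfig, condition_a: str, condition_b: str,
                     out_path: str | Path | None = None):
    """Run prediction, then test every TSS between two conditions."""
    for cond in (condition_a, condition_b):
        if cond not in config.layout.conditions:
            raise ConfigurationError(
                f"unknown condition {cond!r}; valid: "
                f"{', '.join(config.layout.conditions)}")
    result = run_predict(config)
    diffs = differential_test(result.tss, result.pairs, condition_a,
                              condition_b, half_window=config.half_window)
    if out_path is None:
        out_path = Path(config.output_dir) / \
            f"differential_{condition_a}_vs_{condition_b}.tsv"
    write_differential_tsv(diffs, out_path)
    return diffs
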