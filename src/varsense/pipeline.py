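"""End-to-end benchmark orchestration.

``run_benchmark`` wires the stages together: generate (or accept) a
synthetic cohort, thin it to each target library size and replicate seed,
emulate each caller profile, apply both filtering strategies, match against
the truth set and tabulate sensitivity. The output is a tidy frame with one
row per (caller, strategy, library size, replicate, truth subset), plus the
depth-stratified and cumulative-in-depth tables and the VAF x expression
detection grid. A run manifest records the configuration, seeds and output
hashes so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .design import (DEFAULT_LIBRARY_SIZES, DownsampleSpec,
                     run_downsampling_experiment)
from .filters import (apply_annotation_filters, apply_default_filters,
                      kept_calls, reason_histogram)
from .matching import EXACT, PARTIAL, evaluate_truth_set
from .pon import build_pon
from .sensitivity import (cumulative_sensitivity, reports_to_frame,
                          sensitivity, sensitivity_by_depth_interval)
from .synthetic import (DEFAULT_PROFILES, CallerProfile, CohortConfig,
                        SyntheticCohort, emulate_caller, generate_cohort)
from .variants import SNV

DEFAULT_FILTERS = "default"
ANNOTATION_FILTERS = "annotation"


@dataclass
class BenchmarkConfig:
    seed: int = 100
    cohort: CohortConfig | None = None
    library_sizes: tuple[float, ...] = DEFAULT_LIBRARY_SIZES
    profiles: tuple[CallerProfile, ...] = DEFAULT_PROFILES
    strategies: tuple[str, ...] = (DEFAULT_FILTERS, ANNOTATION_FILTERS)
    indel_mode: str = EXACT
    cumulative_thresholds: tuple[float, ...] = tuple(range(0, 101, 10))
    include_initial: bool = True


@dataclass
class BenchmarkResult:
    sensitivity: pd.DataFrame       # per run x truth subset
    by_depth: pd.DataFrame          # depth-interval strata
    cumulative: pd.DataFrame        # Eq.-3-style d sweep
    reason_counts: pd.DataFrame     # removal-reason counters per run
    manifest: dict
    cohort: SyntheticCohort


def _truth_subsets(truth):
    return {
        "all": list(truth),
        "SNV": [t for t in truth if t.vtype == SNV],
        "indel": [t for t in truth if t.vtype != SNV],
    }


def run_benchmark(config: BenchmarkConfig | None = None,
                  cohort: SyntheticCohort | None = None) -> BenchmarkResult:
    cfg = config or BenchmarkConfig()
    if cohort is None:
        cohort_cfg = cfg.cohort or CohortConfig(seed=cfg.seed)
        cohort = generate_cohort(cohort_cfg)
    truth_subsets = _truth_subsets(cohort.truth)
    initial = cohort.config.initial_fragments

    runs: dict[tuple[float, int], pd.DataFrame] = {}
    if cfg.include_initial:
        base = cohort.sites.copy()
        base["library_size_fragments"] = initial
        base["replicate_seed"] = cohort.config.seed
        runs[(initial, cohort.config.seed)] = base
    runs.update(run_downsampling_experiment(
        cohort.sites, initial, sizes=cfg.library_sizes, spec=DownsampleSpec()))

    pons = {p.caller_id: build_pon(cohort.normal_callsets, caller_id=p.caller_id)
            for p in cfg.profiles}

    sens_rows, depth_rows, cum_rows, reason_rows = [], [], [], []
    for (size, rep_seed), sites in sorted(runs.items()):
        depths = cohort.depth_track(sites)
        for i_profile, profile in enumerate(cfg.profiles):
            child = np.random.SeedSequence(
                entropy=cfg.seed,
                spawn_key=(int(size), int(rep_seed), i_profile),
            )
            rng = np.random.Generator(np.random.PCG64(child))
            calls = emulate_caller(sites, profile, rng)
            for strategy in cfg.strategies:
                if strategy == DEFAULT_FILTERS:
                    decisions = apply_default_filters(calls, pons[profile.caller_id])
                elif strategy == ANNOTATION_FILTERS:
                    decisions = apply_annotation_filters(
                        calls, pons[profile.caller_id], cohort.resources)
                else:
                    raise ValueError(f"unknown filtering strategy {strategy!r}")
                for reason, count in reason_histogram(decisions).items():
                    reason_rows.append({
                        "caller_id": profile.caller_id, "strategy": strategy,
                        "library_size": size, "replicate_seed": rep_seed,
                        "reason": reason, "count": count,
                    })
                matches_all = evaluate_truth_set(
                    cohort.truth, decisions, indel_mode=cfg.indel_mode)
                by_truth = {(m.truth.chrom, m.truth.pos, m.truth.ref): m
                            for m in matches_all}
                for subset_name, subset in truth_subsets.items():
                    matches = [by_truth[(t.chrom, t.pos, t.ref)] for t in subset]
                    labels = dict(caller_id=profile.caller_id, library_size=size,
                                  truth_set_id=subset_name,
                                  replicate_id=str(rep_seed))
                    rep = sensitivity(matches, **labels)
                    sens_rows.append(_row(rep, strategy))
                    if subset_name == "all":
                        for r in sensitivity_by_depth_interval(matches, depths,
                                                               **labels):
                            depth_rows.append(_row(r, strategy))
                        for d in cfg.cumulative_thresholds:
                            r = cumulative_sensitivity(matches, depths, d, **labels)
                            cum_rows.append(_row(r, strategy))

    sens = pd.DataFrame(sens_rows)
    by_depth = pd.DataFrame(depth_rows)
    cumulative = pd.DataFrame(cum_rows)
    reasons = pd.DataFrame(reason_rows)
    manifest = build_manifest(cfg, cohort, {
        "sensitivity": sens, "by_depth": by_depth, "cumulative": cumulative,
        "reason_counts": reasons,
    })
    return BenchmarkResult(sens, by_depth, cumulative, reasons, manifest, cohort)


def _row(report, strategy) -> dict:
    return {
        "caller_id": report.caller_id, "strategy": strategy,
        "library_size": report.library_size,
        "truth_set_id": report.truth_set_id,
        "replicate_id": report.replicate_id, "stratum": report.stratum,
        "tp": report.tp, "fn": report.fn,
        "sensitivity": round(report.sensitivity, 4)
        if report.tp + report.fn else float("nan"),
    }


def _frame_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()


def build_manifest(cfg: BenchmarkConfig, cohort: SyntheticCohort,
                   tables: Mapping[str, pd.DataFrame]) -> dict:
    return {
        "tool_version": __version__,
        "seed": cfg.seed,
        "library_sizes": list(cfg.library_sizes),
        "strategies": list(cfg.strategies),
        "profiles": [p.caller_id for p in cfg.profiles],
        "cohort_config": _jsonable(dataclasses.asdict(cohort.config)),
        "table_hashes": {name: _frame_hash(df) for name, df in tables.items()},
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


SUPPORTED_FORMATS = ("tsv", "json")


def report(result: BenchmarkResult, out_dir, fmt: str = "tsv") -> list[Path]:
    """Write the benchmark tables; percent formatting happens only here."""
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {SUPPORTED_FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "sensitivity": result.sensitivity,
        "sensitivity_by_depth": result.by_depth,
        "cumulative_sensitivity": result.cumulative,
        "filter_reason_counts": result.reason_counts,
    }
    written = []
    if fmt == "tsv":
        for name, df in tables.items():
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    else:
        path = out_dir / "benchmark.json"
        payload = {name: json.loads(df.to_json(orient="records"))
                   for name, df in tables.items()}
        path.write_text(json.dumps(payload, indent=1))
        written.append(path)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=1))
    written.append(manifest_path)
    return written
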