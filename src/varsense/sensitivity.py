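"""Recall computation: overall, depth-stratified, cumulative-in-depth and the
VAF x expression detection grid.

Sensitivity is TP/(TP+FN) over a truth set for one caller, library size and
replicate. The depth stratification bins truth-site total depth in steps of
10X up to 100X, then [100, 130) and a final closed bin from 130X to the
maximum observed depth. Cumulative sensitivity at threshold ``d`` restricts
both the numerator and the denominator to truth sites with total depth >= d
and counts a variant as called only then; at d=0 it coincides exactly with
plain sensitivity. Replicate summaries report the median with the min and
max across downsampling runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import MatchResult
from .variants import TruthVariant

DEPTH_EDGES = list(range(0, 101, 10)) + [130]  # then a final closed bin to max


@dataclass(frozen=True)
class SensitivityReport:
    caller_id: str = ""
    library_size: float = float("nan")
    truth_set_id: str = ""
    replicate_id: str = ""
    tp: int = 0
    fn: int = 0
    stratum: str = ""

    @property
    def sensitivity(self) -> float:
        """TP/(TP+FN); NaN (explicit NA) when the truth set is empty."""
        n = self.tp + self.fn
        return self.tp / n if n else float("nan")


def _site_key(t: TruthVariant) -> tuple[str, int]:
    return (t.chrom, t.pos)


def _labels(matches: Sequence[MatchResult], **overrides) -> dict:
    lab = {"caller_id": "", "library_size": float("nan"),
           "truth_set_id": "", "replicate_id": ""}
    sets = {m.truth.set_id for m in matches}
    if len(sets) == 1:
        lab["truth_set_id"] = sets.pop()
    callers = {m.matched_call.caller_id for m in matches if m.matched_call}
    if len(callers) == 1:
        lab["caller_id"] = callers.pop()
    lab.update({k: v for k, v in overrides.items() if v is not None})
    return lab


def sensitivity(matches: Sequence[MatchResult], **labels) -> SensitivityReport:
    """Plain recall over a set of match results."""
    tp = sum(1 for m in matches if m.called)
    return SensitivityReport(tp=tp, fn=len(matches) - tp, **_labels(matches, **labels))


def depth_bin_label(depth: float, max_depth: float) -> str:
    """Assign a total depth to its stratum label.

    Bins are left-closed right-open except the final [130, max] bin, which is
    closed.
    """
    if depth < 0:
        raise ValueError("negative depth")
    for lo, hi in zip(DEPTH_EDGES[:-1], DEPTH_EDGES[1:]):
        if lo <= depth < hi:
            return f"[{lo},{hi})"
    return f"[130,{int(max(max_depth, 130))}]"


def sensitivity_by_depth_interval(
    matches: Sequence[MatchResult],
    depths: Mapping[tuple[str, int], float],
    **labels,
) -> list[SensitivityReport]:
    """Recall stratified by total depth at the truth site.

    ``depths`` must cover every truth site (including misses); it is the
    per-site depth track of the evaluated library.
    """
    for m in matches:
        if _site_key(m.truth) not in depths:
            raise ValueError(f"no depth for truth site {_site_key(m.truth)}")
    max_depth = max((depths[_site_key(m.truth)] for m in matches), default=130)
    by_bin: dict[str, list[MatchResult]] = {}
    for m in matches:
        by_bin.setdefault(
            depth_bin_label(depths[_site_key(m.truth)], max_depth), []
        ).append(m)
    out = []
    for lo, hi in zip(DEPTH_EDGES[:-1], DEPTH_EDGES[1:]):
        label = f"[{lo},{hi})"
        if label in by_bin:
            out.append(_stratum_report(by_bin[label], label, matches, labels))
    last = f"[130,{int(max(max_depth, 130))}]"
    if last in by_bin:
        out.append(_stratum_report(by_bin[last], last, matches, labels))
    return out


def _stratum_report(group, label, all_matches, labels) -> SensitivityReport:
    tp = sum(1 for m in group if m.called)
    return SensitivityReport(tp=tp, fn=len(group) - tp, stratum=label,
                             **_labels(all_matches, **labels))


def cumulative_sensitivity(
    matches: Sequence[MatchResult],
    depths: Mapping[tuple[str, int], float],
    d: float,
    **labels,
) -> SensitivityReport:
    """Recall restricted to truth sites with total depth >= d."""
    if d < 0:
        raise ValueError("d must be >= 0")
    eligible = [m for m in matches if depths[_site_key(m.truth)] >= d]
    if matches and not eligible:
        import warnings
        warnings.warn(f"depth threshold d={d} exceeds every truth-site depth")
    tp = sum(1 for m in eligible if m.called)
    return SensitivityReport(tp=tp, fn=len(eligible) - tp, stratum=f"d>={d:g}",
                             **_labels(matches, **labels))


def reports_to_frame(reports: Iterable[SensitivityReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "caller_id": r.caller_id, "library_size": r.library_size,
            "truth_set_id": r.truth_set_id, "replicate_id": r.replicate_id,
            "stratum": r.stratum, "tp": r.tp, "fn": r.fn,
            "sensitivity": r.sensitivity,
        })
    return pd.DataFrame(rows, columns=["caller_id", "library_size",
                                       "truth_set_id", "replicate_id",
                                       "stratum", "tp", "fn", "sensitivity"])


def aggregate_replicates(reports) -> pd.DataFrame:
    """Median / min / max sensitivity across replicates per group.

    ``reports`` may be a list of SensitivityReport or a tidy frame from
    :func:`reports_to_frame`; any extra grouping columns (e.g. a filtering
    strategy label) are preserved in the group keys.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    if df.empty:
        raise ValueError("no reports to aggregate")
    group_cols = [c for c in df.columns
                  if c not in ("replicate_id", "tp", "fn", "sensitivity")]
    agg = (
        df.groupby(group_cols, dropna=False)["sensitivity"]
        .agg(median="median", min="min", max="max", n_replicates="count")
        .reset_index()
    )
    return agg


def detection_grid(
    records: pd.DataFrame,
    vaf_bins: Sequence[float],
    expr_bins: Sequence[float],
) -> pd.DataFrame:
    """Mean detection rate per (VAF bin x log2-expression bin).

    ``records`` needs one row per truth variant per caller with columns
    ``vaf``, ``log2_expr`` and ``called`` (0/1). The mean is taken over the
    per-variant-per-caller called indicator within each cell; empty cells
    are NA.
    """
    df = records.copy()
    df["vaf_bin"] = pd.cut(df["vaf"], bins=list(vaf_bins), include_lowest=True)
    df["expr_bin"] = pd.cut(df["log2_expr"], bins=list(expr_bins), include_lowest=True)
    grid = df.pivot_table(index="vaf_bin", columns="expr_bin", values="called",
                          aggfunc="mean", observed=False)
    return grid
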