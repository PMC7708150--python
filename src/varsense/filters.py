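"""The two variant-filtering strategies and their genomic-context detectors.

*default-filters* keep only calls the caller itself flagged PASS and that are
absent from the panel of normals. *annotation-filters* ignore caller FILTER
flags and instead combine database knowledge (COSMIC rescue of PON hits,
dbSNP+ExAC germline removal), genomic-context exclusion (exon-boundary
windows, homopolymer runs, repeat regions, optionally RNA-editing sites) and
hard quality thresholds (mean base quality > 18, alt depth >= 5, total depth
>= 15, VAF >= 0.03).

Every failing reason is recorded for each removed call — evaluation does not
short-circuit — so removal-reason histograms are complete.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pon import PanelOfNormals, in_pon
from .variants import StandardVariant, VariantKey

# reason labels, in evaluation order
NOT_PASS = "not_PASS"
PON = "PON"
PON_NOT_COSMIC = "PON_not_COSMIC"
DBSNP_EXAC = "dbSNP_ExAC"
EXON_BOUNDARY = "exon_boundary"
HOMOPOLYMER = "homopolymer"
REPEAT = "repeat"
RNA_EDITING = "rna_editing"
LOW_BASE_QUALITY = "low_base_quality"
LOW_ALT_DEPTH = "low_alt_depth"
LOW_TOTAL_DEPTH = "low_total_depth"
LOW_VAF = "low_vaf"


@dataclass(frozen=True)
class FilterDecision:
    kept: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be equivalent to an empty reason list")


class IntervalTrack:
    """Per-chromosome, merged, non-overlapping intervals.

    Stored 0-based half-open internally; every public surface speaks 1-based
    closed coordinates and converts here, at a single boundary.
    """

    def __init__(self, intervals0: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in (intervals0 or {}).items():
            merged = self._merge(ivs)
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @staticmethod
    def _merge(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if s < 0 or e < s:
                raise ValueError(f"invalid interval ({s}, {e})")
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    @classmethod
    def from_closed(cls, intervals1: Mapping[str, Sequence[tuple[int, int]]]) -> "IntervalTrack":
        """Build from 1-based fully-closed intervals."""
        return cls({c: [(s - 1, e) for s, e in ivs] for c, ivs in intervals1.items()})

    def to_closed(self) -> dict[str, list[tuple[int, int]]]:
        return {
            c: [(int(s) + 1, int(e)) for s, e in zip(self._starts[c], self._ends[c])]
            for c in self._starts
        }

    def overlaps(self, chrom: str, start: int, end: int | None = None) -> bool:
        """Any overlap with the 1-based closed query [start, end]?"""
        if end is None:
            end = start
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        q_s, q_e = start - 1, end  # half-open query
        i = bisect_right(starts, q_e - 1)
        return bool(i > 0 and self._ends[chrom][i - 1] > q_s)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())


def detect_homopolymers(sequences, min_run: int = 6) -> dict[str, list[tuple[int, int]]]:
    """Find maximal single-nucleotide runs of length >= ``min_run``.

    The default of 6 implements "runs strictly longer than 5 bp". Accepts a
    mapping of chromosome name to sequence string or a pyfaidx.Fasta.
    Returned intervals are 1-based closed.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in sequences.keys():
        seq = str(sequences[chrom]).upper()
        runs: list[tuple[int, int]] = []
        i, n = 0, len(seq)
        while i < n:
            j = i + 1
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= min_run and seq[i] != "N":
                runs.append((i + 1, j))
            i = j
        out[chrom] = runs
    return out


@dataclass
class AnnotationResources:
    """Membership sets and genomic-context tracks for annotation-filters."""

    cosmic: frozenset[VariantKey] = frozenset()
    dbsnp: frozenset[VariantKey] = frozenset()
    exac: frozenset[VariantKey] = frozenset()
    rna_editing_sites: frozenset[tuple[str, int]] = frozenset()
    repeat_regions: IntervalTrack = field(default_factory=IntervalTrack)
    homopolymers: IntervalTrack = field(default_factory=IntervalTrack)
    exon_boundaries: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def near_exon_boundary(
    v: StandardVariant,
    exon_boundaries: Mapping[str, Sequence[tuple[int, int]]],
    window: int = 4,
    symmetric: bool = False,
) -> bool:
    """Does the variant's reference span fall in an exon-boundary window?

    The literal (intronic-flank) reading: within ``window`` bp upstream of an
    exon start ([start-window, start-1]) or downstream of an exon end
    ([end+1, end+window]). With ``symmetric=True`` the windows extend
    ``window`` bp on both sides of each boundary, the common splice-junction
    filter interpretation.
    """
    exons = exon_boundaries.get(v.chrom, ())
    span_s, span_e = v.ref_span()
    for start, end in exons:
        if symmetric:
            windows = ((start - window, start + window), (end - window, end + window))
        else:
            windows = ((start - window, start - 1), (end + 1, end + window))
        for w_s, w_e in windows:
            if span_s <= w_e and span_e >= w_s:
                return True
    return False


def apply_default_filters(
    calls: Iterable[StandardVariant],
    pon: PanelOfNormals,
) -> list[tuple[StandardVariant, FilterDecision]]:
    """Caller PASS flag plus PON removal."""
    out = []
    for call in calls:
        reasons: list[str] = []
        if "PASS" not in call.filter_flags:
            reasons.append(NOT_PASS)
        if in_pon(call.key, pon):
            reasons.append(PON)
        out.append((call, FilterDecision(kept=not reasons, reasons=tuple(reasons))))
    return out


@dataclass(frozen=True)
class QualityThresholds:
    min_base_quality: float = 18.0  # strict >
    min_alt_depth: int = 5          # >=
    min_total_depth: int = 15       # >=
    min_vaf: float = 0.03           # >=


def apply_annotation_filters(
    calls: Iterable[StandardVariant],
    pon: PanelOfNormals,
    resources: AnnotationResources,
    thresholds: QualityThresholds | None = None,
    remove_rna_editing: bool = False,
    boundary_window: int = 4,
    boundary_symmetric: bool = False,
) -> list[tuple[StandardVariant, FilterDecision]]:
    """Database + genomic-context + hard-threshold filtering.

    Caller FILTER flags are ignored: the strategy is applied to every
    reported call. COSMIC membership rescues PON hits but not context
    failures. All failing reasons are recorded per call.
    """
    th = thresholds or QualityThresholds()
    for name in ("cosmic", "dbsnp", "exac"):
        if getattr(resources, name) is None:
            raise ValueError(f"annotation resource set {name!r} is missing; "
                             f"supply it or pass an empty set to disable")
    out = []
    for call in calls:
        key = call.key
        reasons: list[str] = []
        in_cosmic = key in resources.cosmic
        if in_pon(key, pon) and not in_cosmic:
            reasons.append(PON_NOT_COSMIC)
        if not in_cosmic and key in resources.dbsnp and key in resources.exac:
            reasons.append(DBSNP_EXAC)
        if near_exon_boundary(call, resources.exon_boundaries,
                              window=boundary_window, symmetric=boundary_symmetric):
            reasons.append(EXON_BOUNDARY)
        span_s, span_e = call.ref_span()
        if resources.homopolymers.overlaps(call.chrom, span_s, span_e):
            reasons.append(HOMOPOLYMER)
        if resources.repeat_regions.overlaps(call.chrom, span_s, span_e):
            reasons.append(REPEAT)
        if remove_rna_editing and (call.chrom, call.pos) in resources.rna_editing_sites:
            reasons.append(RNA_EDITING)
        if not (call.mean_base_quality > th.min_base_quality):
            reasons.append(LOW_BASE_QUALITY)
        if call.alt_depth < th.min_alt_depth:
            reasons.append(LOW_ALT_DEPTH)
        if call.total_depth < th.min_total_depth:
            reasons.append(LOW_TOTAL_DEPTH)
        if not (call.vaf >= th.min_vaf):
            reasons.append(LOW_VAF)
        out.append((call, FilterDecision(kept=not reasons, reasons=tuple(reasons))))
    return out


def min_depth_for_vaf_below(min_alt: int = 5, vaf_threshold: float = 0.03) -> int:
    """Smallest total depth D such that min_alt/D falls below the VAF cut.

    With the default thresholds a variant whose true VAF is below 0.03 can
    only survive the joint alt-depth/VAF rule when covered by at least 167
    reads.
    """
    if min_alt < 1:
        raise ValueError("min_alt must be >= 1")
    if not (0 < vaf_threshold < 1):
        raise ValueError("vaf_threshold must lie in (0, 1)")
    d = max(min_alt, math.floor(min_alt / vaf_threshold))
    while min_alt / d >= vaf_threshold:
        d += 1
    return d


def reason_histogram(
    decisions: Iterable[tuple[StandardVariant, FilterDecision]]
) -> dict[str, int]:
    """Count removal reasons across calls (one count per failing reason)."""
    hist: dict[str, int] = {}
    for _, dec in decisions:
        for r in dec.reasons:
            hist[r] = hist.get(r, 0) + 1
    return hist


def kept_calls(
    decisions: Iterable[tuple[StandardVariant, FilterDecision]]
) -> list[StandardVariant]:
    return [c for c, d in decisions if d.kept]
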