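"""Truth-set matching: was each validated mutation recovered by a call set?

SNVs match only on exact (chrom, pos, ref, alt) equality after
normalisation. Indels tolerate representation differences: any indel call
within +/-50 bp of the truth position is a candidate, matched either on
normalised allele equality (``exact`` mode) or on a shared contiguous
allele subsequence of at least 3 bp (``partial`` mode) — the latter joins
composite events that some callers emit as split SNV + indel pieces.
Ties among window candidates are broken deterministically (smallest
positional distance, then lexicographic alt), replacing the manual curation
a human analyst would otherwise perform, and candidate lists can be audited.
Misses are classified as ``filtered`` (reported pre-filter, then removed,
with the removal reasons) or ``not_reported``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .filters import FilterDecision
from .variants import SNV, StandardVariant, TruthVariant, VariantKey

CALLED = "called"
FILTERED = "filtered"
NOT_REPORTED = "not_reported"
ALLELE_MISMATCH = "allele_mismatch"

EXACT = "exact"
WINDOW = "window"
PARTIAL = "partial"

DEFAULT_WINDOW = 50
MIN_PARTIAL_OVERLAP = 3


@dataclass
class MatchResult:
    truth: TruthVariant
    status: str
    matched_call: StandardVariant | None = None
    match_mode: str = ""
    reasons: tuple[str, ...] = ()

    @property
    def called(self) -> bool:
        return self.status == CALLED


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring shared by a and b."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _candidate_sort_key(truth: TruthVariant):
    def key(call: StandardVariant):
        return (abs(call.pos - truth.pos), call.alt)
    return key


def match_snv(
    truth: TruthVariant,
    calls: Sequence[StandardVariant],
    used: set[int] | None = None,
) -> MatchResult:
    """Exact-key matching for SNV truth records.

    ``truth.alt`` must be resolved (see :func:`resolve_truth_alleles` for
    truth sets published without alternative alleles).
    """
    same_site = [
        c for i, c in enumerate(calls)
        if c.chrom == truth.chrom and c.pos == truth.pos and c.ref == truth.ref
        and (used is None or i not in used)
    ]
    if truth.alt is not None:
        for i, c in enumerate(calls):
            if used is not None and i in used:
                continue
            if (c.chrom, c.pos, c.ref, c.alt) == truth.key:
                if used is not None:
                    used.add(i)
                return MatchResult(truth, CALLED, matched_call=c, match_mode=EXACT)
    if same_site:
        return MatchResult(truth, ALLELE_MISMATCH)
    return MatchResult(truth, NOT_REPORTED)


def match_indel(
    truth: TruthVariant,
    calls: Sequence[StandardVariant],
    window: int = DEFAULT_WINDOW,
    mode: str = EXACT,
    min_overlap: int = MIN_PARTIAL_OVERLAP,
    used: set[int] | None = None,
) -> MatchResult:
    """Windowed matching for insertion/deletion/composite truth records."""
    if truth.alt is None:
        return MatchResult(truth, NOT_REPORTED)
    candidates = [
        (i, c) for i, c in enumerate(calls)
        if c.chrom == truth.chrom and c.vtype != SNV
        and abs(c.pos - truth.pos) <= window
        and (used is None or i not in used)
    ]
    candidates.sort(key=lambda ic: _candidate_sort_key(truth)(ic[1]))
    for i, c in candidates:
        if _indel_match(truth, c, mode, min_overlap):
            if used is not None:
                used.add(i)
            match_mode = EXACT if (c.pos == truth.pos and c.ref == truth.ref
                                   and c.alt == truth.alt) else (
                WINDOW if mode == EXACT else PARTIAL)
            return MatchResult(truth, CALLED, matched_call=c, match_mode=match_mode)
    return MatchResult(truth, NOT_REPORTED)


def _indel_match(truth: TruthVariant, call: StandardVariant, mode: str,
                 min_overlap: int) -> bool:
    if call.ref == truth.ref and call.alt == truth.alt:
        return True
    if mode == EXACT:
        return False
    if mode != PARTIAL:
        raise ValueError(f"unknown indel match mode {mode!r}")
    alt_ok = longest_common_substring(call.alt, truth.alt) >= min_overlap
    if truth.vtype == "deletion":
        return alt_ok and longest_common_substring(call.ref, truth.ref) >= min_overlap
    return alt_ok


def resolve_truth_alleles(
    truth_set: Sequence[TruthVariant],
    initial_calls: Sequence[StandardVariant],
) -> list[TruthVariant]:
    """Fill missing truth alt alleles from calls on the initial library.

    For truth sets published without alternative alleles, the allele called
    on the largest (initial) library stands in as the truth allele.
    """
    by_site: dict[tuple[str, int, str], str] = {}
    for c in initial_calls:
        by_site.setdefault((c.chrom, c.pos, c.ref), c.alt)
    out = []
    for t in truth_set:
        if t.alt is None:
            alt = by_site.get((t.chrom, t.pos, t.ref))
            if alt is not None:
                t = TruthVariant(t.chrom, t.pos, t.ref, alt, t.vtype,
                                 t.vaf_expected, t.gene_id, t.set_id)
        out.append(t)
    return out


def match_truth(
    truth: TruthVariant,
    calls: Sequence[StandardVariant],
    window: int = DEFAULT_WINDOW,
    indel_mode: str = EXACT,
    used: set[int] | None = None,
) -> MatchResult:
    if truth.vtype == SNV:
        return match_snv(truth, calls, used=used)
    return match_indel(truth, calls, window=window, mode=indel_mode, used=used)


def classify_missed(
    truth: TruthVariant,
    decisions: Sequence[tuple[StandardVariant, FilterDecision]],
    window: int = DEFAULT_WINDOW,
    indel_mode: str = EXACT,
) -> MatchResult:
    """Classify a miss: present pre-filter but removed, or never reported."""
    removed = [c for c, d in decisions if not d.kept]
    reasons_by_id = {id(c): d.reasons for c, d in decisions if not d.kept}
    res = match_truth(truth, removed, window=window, indel_mode=indel_mode)
    if res.status == CALLED:
        return MatchResult(truth, FILTERED, matched_call=res.matched_call,
                           match_mode=res.match_mode,
                           reasons=reasons_by_id[id(res.matched_call)])
    if res.status == ALLELE_MISMATCH:
        return MatchResult(truth, NOT_REPORTED)
    return res


def evaluate_truth_set(
    truth_set: Sequence[TruthVariant],
    decisions: Sequence[tuple[StandardVariant, FilterDecision]],
    window: int = DEFAULT_WINDOW,
    indel_mode: str = EXACT,
) -> list[MatchResult]:
    """Match every truth variant against a filtered call set.

    Greedy one-to-one assignment: each kept call may satisfy at most one
    truth variant; truth variants are processed in genomic order.
    """
    kept = [c for c, d in decisions if d.kept]
    used: set[int] = set()
    results = []
    for t in sorted(truth_set, key=lambda t: (t.chrom, t.pos)):
        res = match_truth(t, kept, window=window, indel_mode=indel_mode, used=used)
        if res.status in (NOT_REPORTED, ALLELE_MISMATCH):
            missed = classify_missed(t, decisions, window=window, indel_mode=indel_mode)
            if missed.status == FILTERED:
                res = missed
            elif res.status == NOT_REPORTED:
                res = missed
        results.append(res)
    return results


def audit_frame(results: Iterable[MatchResult]) -> pd.DataFrame:
    """Tidy match audit: truth key, status, mode, matched call key, reasons."""
    rows = []
    for r in results:
        c = r.matched_call
        rows.append({
            "chrom": r.truth.chrom, "pos": r.truth.pos, "ref": r.truth.ref,
            "alt": r.truth.alt if r.truth.alt is not None else "",
            "vtype": r.truth.vtype, "set_id": r.truth.set_id,
            "status": r.status, "match_mode": r.match_mode,
            "call_pos": c.pos if c else "",
            "call_ref": c.ref if c else "", "call_alt": c.alt if c else "",
            "reasons": ";".join(r.reasons),
        })
    return pd.DataFrame(rows)
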