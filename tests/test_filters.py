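"""Filtering strategies, context detectors and threshold arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varsense import filters as flt
from varsense.filters import (AnnotationResources, IntervalTrack,
                              QualityThresholds, apply_annotation_filters,
                              apply_default_filters, detect_homopolymers,
                              min_depth_for_vaf_below, near_exon_boundary,
                              reason_histogram)
from varsense.pon import PanelOfNormals
from varsense.synthetic import generate_reference
from varsense.variants import StandardVariant

EMPTY_PON = PanelOfNormals(entries={}, n_samples_total=17)


def _pon(key, n=3, max_vaf=0.01):
    return PanelOfNormals(entries={key: (n, max_vaf)}, n_samples_total=17)


def _resources(**kwargs):
    return AnnotationResources(**kwargs)


def _call(pos=500, ref="A", alt="G", total=200, alt_depth=40, bq=30.0,
          flags=("PASS",), chrom="chr1"):
    return StandardVariant(chrom, pos, ref, alt, total_depth=total,
                           alt_depth=alt_depth, mean_base_quality=bq,
                           filter_flags=frozenset(flags))


# ---------------------------------------------------------------------------
# homopolymer detection


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CCAAAAAATT", [(3, 8)]),   # one 6-A run
        ("AAAAA", []),              # run of 5: not longer than 5 bp
        ("ACGTACGT", []),
        ("AAAAAAA", [(1, 7)]),
        ("GGGGGGTTTTTT", [(1, 6), (7, 12)]),
    ],
)
def test_detect_homopolymers_examples(seq, expected):
    assert detect_homopolymers({"c": seq})["c"] == expected


def test_detect_homopolymers_empty_sequence():
    assert detect_homopolymers({"c": ""})["c"] == []


def _brute_force_runs(seq, min_run):
    out = set()
    for s in range(len(seq)):
        for e in range(s, len(seq)):
            sub = seq[s:e + 1]
            if len(sub) >= min_run and len(set(sub)) == 1 and sub[0] != "N":
                maximal = ((s == 0 or seq[s - 1] != sub[0])
                           and (e == len(seq) - 1 or seq[e + 1] != sub[0]))
                if maximal:
                    out.add((s + 1, e + 1))
    return sorted(out)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACGT", min_size=0, max_size=40),
       min_run=st.integers(min_value=2, max_value=7))
def test_detect_homopolymers_matches_exhaustive_scan(seq, min_run):
    got = detect_homopolymers({"c": seq}, min_run=min_run)["c"]
    assert got == _brute_force_runs(seq, min_run)


def test_planted_runs_recovered_exactly():
    ref, truth = generate_reference(5000, [(1000, "A", 8), (2000, "G", 7)],
                                    seed=3)
    assert detect_homopolymers(ref)["chr1"] == truth["chr1"]
    assert truth["chr1"] == [(1000, 1007), (2000, 2006)]


def test_generate_reference_rejects_overlapping_plants():
    with pytest.raises(ValueError, match="overlap"):
        generate_reference(1000, [(100, "A", 8), (105, "T", 8)], seed=0)


# ---------------------------------------------------------------------------
# exon boundary windows


EXONS = {"chr1": [(100, 200)]}


@pytest.mark.parametrize(
    "pos,expected",
    [
        (97, True),    # within 4 bp upstream of the exon start
        (96, True),
        (95, False),   # 5 bp upstream: outside the window
        (99, True),
        (100, False),  # inside the exon
        (204, True),   # within 4 bp downstream of the exon end
        (205, False),
        (150, False),
    ],
)
def test_near_exon_boundary_window_arithmetic(pos, expected):
    assert near_exon_boundary(_call(pos=pos), EXONS) is expected


def test_near_exon_boundary_symmetric_option():
    assert not near_exon_boundary(_call(pos=102), EXONS)
    assert near_exon_boundary(_call(pos=102), EXONS, symmetric=True)


def test_near_exon_boundary_uses_ref_span_for_indels():
    # deletion starting at 93 spanning 93-97 reaches into [96, 99]
    v = _call(pos=93, ref="AAAAA", alt="A")
    assert near_exon_boundary(v, EXONS)


def test_interval_track_closed_round_trip_and_overlap():
    track = IntervalTrack.from_closed({"chr1": [(10, 20), (30, 40)]})
    assert track.to_closed()["chr1"] == [(10, 20), (30, 40)]
    assert track.overlaps("chr1", 20, 20)
    assert track.overlaps("chr1", 21, 29) is False
    assert track.overlaps("chr1", 25, 30)
    assert not track.overlaps("chr2", 10, 20)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ivs=st.lists(st.tuples(st.integers(1, 80), st.integers(0, 10)),
                    min_size=0, max_size=6),
       q=st.integers(1, 100))
def test_interval_track_overlap_matches_point_scan(ivs, q):
    closed = [(s, s + l) for s, l in ivs]
    track = IntervalTrack.from_closed({"c": closed})
    brute = any(s <= q <= e for s, e in closed)
    assert track.overlaps("c", q) == brute


# ---------------------------------------------------------------------------
# default filters


def test_default_filters_pass_and_pon():
    key_call = _call()
    kept = apply_default_filters([key_call], EMPTY_PON)
    assert kept[0][1].kept

    in_pon_call = _call()
    dec = apply_default_filters([in_pon_call], _pon(in_pon_call.key, n=3))
    assert not dec[0][1].kept and dec[0][1].reasons == (flt.PON,)

    flagged = _call(flags=("clustered_events",))
    dec = apply_default_filters([flagged], EMPTY_PON)
    assert dec[0][1].reasons == (flt.NOT_PASS,)


def test_default_filters_record_all_reasons():
    c = _call(flags=("clustered_events",))
    dec = apply_default_filters([c], _pon(c.key, n=5))
    assert dec[0][1].reasons == (flt.NOT_PASS, flt.PON)


# ---------------------------------------------------------------------------
# annotation filters


def test_cosmic_rescues_pon_variant():
    c = _call()
    res = _resources(cosmic=frozenset({c.key}))
    dec = apply_annotation_filters([c], _pon(c.key, n=3), res)
    assert dec[0][1].kept


def test_pon_without_cosmic_removed():
    c = _call()
    dec = apply_annotation_filters([c], _pon(c.key, n=3), _resources())
    assert dec[0][1].reasons == (flt.PON_NOT_COSMIC,)


def test_dbsnp_exac_removes_non_cosmic():
    c = _call()
    res = _resources(dbsnp=frozenset({c.key}), exac=frozenset({c.key}))
    dec = apply_annotation_filters([c], EMPTY_PON, res)
    assert dec[0][1].reasons == (flt.DBSNP_EXAC,)
    # membership in dbSNP alone is not enough
    res2 = _resources(dbsnp=frozenset({c.key}))
    assert apply_annotation_filters([c], EMPTY_PON, res2)[0][1].kept


def test_homopolymer_overrides_cosmic():
    c = _call(pos=505)
    res = _resources(
        cosmic=frozenset({c.key}),
        homopolymers=IntervalTrack.from_closed({"chr1": [(500, 510)]}),
    )
    dec = apply_annotation_filters([c], EMPTY_PON, res)
    assert dec[0][1].reasons == (flt.HOMOPOLYMER,)


def test_hard_thresholds():
    dec = apply_annotation_filters([_call(total=100, alt_depth=4)],
                                   EMPTY_PON, _resources())
    assert dec[0][1].reasons == (flt.LOW_ALT_DEPTH,)
    dec = apply_annotation_filters([_call(bq=18.0)], EMPTY_PON, _resources())
    assert dec[0][1].reasons == (flt.LOW_BASE_QUALITY,)  # strict >
    dec = apply_annotation_filters([_call(total=300, alt_depth=6)],
                                   EMPTY_PON, _resources())
    assert dec[0][1].reasons == (flt.LOW_VAF,)


def test_caller_flags_ignored_by_annotation_filters():
    c = _call(flags=("clustered_events",))
    assert apply_annotation_filters([c], EMPTY_PON, _resources())[0][1].kept


def test_rna_editing_optional():
    c = _call()
    res = _resources(rna_editing_sites=frozenset({(c.chrom, c.pos)}))
    assert apply_annotation_filters([c], EMPTY_PON, res)[0][1].kept
    dec = apply_annotation_filters([c], EMPTY_PON, res, remove_rna_editing=True)
    assert dec[0][1].reasons == (flt.RNA_EDITING,)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(total=st.integers(0, 14), alt_frac=st.floats(0, 1))
def test_low_total_depth_always_removed(total, alt_frac):
    c = _call(total=total, alt_depth=int(alt_frac * total))
    dec = apply_annotation_filters([c], EMPTY_PON, _resources())
    assert not dec[0][1].kept
    assert flt.LOW_TOTAL_DEPTH in dec[0][1].reasons


@settings(max_examples=50, deadline=None, derandomize=True)
@given(data=st.data())
def test_keep_set_anti_monotone_in_thresholds(data):
    """Raising any threshold never adds kept variants."""
    rng = np.random.Generator(np.random.PCG64(data.draw(st.integers(0, 2**20))))
    calls = [
        _call(pos=100 + 10 * i, total=int(t), alt_depth=min(int(a), int(t)),
              bq=b)
        for i, (t, a, b) in enumerate(zip(
            rng.integers(1, 400, 30), rng.integers(0, 120, 30),
            rng.uniform(5, 40, 30)))
    ]
    base = QualityThresholds()
    bump = data.draw(st.sampled_from(
        ["min_base_quality", "min_alt_depth", "min_total_depth", "min_vaf"]))
    raised = {
        "min_base_quality": QualityThresholds(min_base_quality=25),
        "min_alt_depth": QualityThresholds(min_alt_depth=8),
        "min_total_depth": QualityThresholds(min_total_depth=30),
        "min_vaf": QualityThresholds(min_vaf=0.1),
    }[bump]
    kept_base = {c.key for c, d in
                 apply_annotation_filters(calls, EMPTY_PON, _resources(), base)
                 if d.kept}
    kept_raised = {c.key for c, d in
                   apply_annotation_filters(calls, EMPTY_PON, _resources(), raised)
                   if d.kept}
    assert kept_raised <= kept_base


def test_reason_histogram_counts_every_failing_reason():
    calls = [_call(total=10, alt_depth=2, bq=10.0),  # fails bq, alt, dp
             _call(pos=600)]
    dec = apply_annotation_filters(calls, EMPTY_PON, _resources())
    hist = reason_histogram(dec)
    assert hist[flt.LOW_BASE_QUALITY] == 1
    assert hist[flt.LOW_ALT_DEPTH] == 1
    assert hist[flt.LOW_TOTAL_DEPTH] == 1


# ---------------------------------------------------------------------------
# threshold arithmetic


@pytest.mark.parametrize(
    "min_alt,vaf,expected",
    [(5, 0.03, 167), (5, 0.05, 101), (1, 0.5, 3)],
)
def test_min_depth_for_vaf_below(min_alt, vaf, expected):
    assert min_depth_for_vaf_below(min_alt, vaf) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(min_alt=st.integers(1, 50),
       vaf=st.floats(min_value=0.005, max_value=0.9))
def test_min_depth_is_the_smallest_qualifying_depth(min_alt, vaf):
    d = min_depth_for_vaf_below(min_alt, vaf)
    assert min_alt / d < vaf
    assert min_alt / (d - 1) >= vaf


def test_min_depth_rejects_bad_threshold():
    with pytest.raises(ValueError):
        min_depth_for_vaf_below(5, 0.0)
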