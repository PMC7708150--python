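"""The synthetic cohort generator: determinism, calibration and planted
ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from varsense.design import expected_site_depth
from varsense.filters import (apply_annotation_filters, apply_default_filters,
                              kept_calls, reason_histogram)
from varsense.matching import EXACT, PARTIAL, match_indel
from varsense.pon import build_pon, in_pon
from varsense.synthetic import (DEFAULT_PROFILES, CallerProfile, CohortConfig,
                                emulate_caller, generate_cohort,
                                generate_reference)
from varsense.variants import SNV, TruthVariant


def test_same_seed_reproduces_everything():
    a = generate_cohort(CohortConfig(seed=7))
    b = generate_cohort(CohortConfig(seed=7))
    assert a.reference == b.reference
    pd.testing.assert_frame_equal(a.sites, b.sites)
    assert [t.key for t in a.truth] == [t.key for t in b.truth]
    assert a.labels["hotspot_key"] == b.labels["hotspot_key"]


def test_different_seed_changes_the_cohort():
    a = generate_cohort(CohortConfig(seed=7))
    b = generate_cohort(CohortConfig(seed=8))
    assert a.reference != b.reference


def test_truth_set_composition(cohort):
    """88 variants in the published type proportions."""
    assert len(cohort.truth) == 88
    cats = cohort.sites.category.value_counts()
    assert cats["SNV"] == 58
    assert cats["short_insertion"] == 15
    assert cats["composite_indel"] == 9
    assert cats["long_insertion"] == 3
    assert cats["short_deletion"] == 2
    assert cats["indel_not_reported"] == 1
    unreported = [t for t in cohort.truth if t.alt is None]
    assert len(unreported) == 1


def test_truth_vafs_respect_published_ranges(cohort):
    truth_sites = cohort.sites[cohort.sites.category == "SNV"]
    assert truth_sites.vaf_true.between(0.05, 0.97).all()
    li = cohort.sites[cohort.sites.category == "long_insertion"]
    assert li.vaf_true.between(0.41, 0.64).all()


def test_truth_sites_are_deep_in_the_initial_library(cohort):
    """Validated variants are well covered before any downsampling."""
    truth = cohort.sites[~cohort.sites.category.str.startswith("decoy")]
    assert (truth.total_depth >= 60).all()
    assert (truth.alt_depth >= 6).all() or (truth.alt == "").any()


def test_depth_calibration_follows_the_planning_formula():
    """With a flat 4-RPKM transcriptome and 37.5M fragments the mean realised
    depth over 500 sites is 30X within 3 SE (Poisson)."""
    cfg = CohortConfig(
        seed=11, n_genes=530,
        truth_counts={"SNV": 500, "short_insertion": 0, "composite_indel": 0,
                      "long_insertion": 0, "short_deletion": 0,
                      "indel_not_reported": 0},
        log2_rpkm_mean=2.0, log2_rpkm_sd=0.0, log2_rpkm_floor=2.0,
        initial_fragments=37.5e6,
    )
    cohort = generate_cohort(cfg)
    sites = cohort.sites[cohort.sites.category == "SNV"]
    assert len(sites) == 500
    expected = expected_site_depth(4.0, 100, 37.5e6)
    assert expected == pytest.approx(30.0)
    se = math.sqrt(expected / len(sites))
    assert abs(sites.total_depth.mean() - expected) <= 3 * se


def test_reference_plants_are_deterministic_and_detected():
    ref_a, truth_a = generate_reference(3000, [(1500, "A", 8)], seed=5)
    ref_b, _ = generate_reference(3000, [(1500, "A", 8)], seed=5)
    assert ref_a == ref_b
    assert truth_a["chr1"] == [(1500, 1507)]


def test_pon_labels_match_the_rule(cohort):
    pon = build_pon(cohort.normal_callsets)
    for key, expected in cohort.labels["pon_truth"].items():
        assert in_pon(key, pon) is expected, key


def test_hotspot_removed_by_default_rescued_by_annotation(cohort, rng):
    """A COSMIC hotspot lurking at low VAF in a few normals is lost to the
    PON under default-filters but rescued by database knowledge."""
    hk = cohort.labels["hotspot_key"]
    pon = build_pon(cohort.normal_callsets)
    calls = emulate_caller(cohort.sites, DEFAULT_PROFILES[0], rng)
    assert hk in {c.key for c in calls}
    kept_default = {c.key for c in kept_calls(apply_default_filters(calls, pon))}
    kept_annot = {c.key for c in kept_calls(
        apply_annotation_filters(calls, pon, cohort.resources))}
    assert hk not in kept_default
    assert hk in kept_annot


def test_clustered_truth_lost_by_default_recovered_by_annotation(cohort, rng):
    """Three co-located truth SNVs get the clustered-events flag from the
    flagging caller profile: default-filters lose them, annotation-filters
    (which ignore caller flags) keep them."""
    mutect_like = next(p for p in DEFAULT_PROFILES if p.clustered_events)
    pon = build_pon(cohort.normal_callsets)
    calls = emulate_caller(cohort.sites, mutect_like, rng)
    clustered = set(cohort.labels["clustered_keys"])
    flagged = {c.key for c in calls if "clustered_events" in c.filter_flags}
    assert flagged == clustered
    kept_default = {c.key for c in kept_calls(apply_default_filters(calls, pon))}
    kept_annot = {c.key for c in kept_calls(
        apply_annotation_filters(calls, pon, cohort.resources))}
    assert not (clustered & kept_default)
    assert clustered <= kept_annot


def test_reason_histograms_equal_planted_counts(cohort, rng):
    """Each planted decoy fails exactly its intended filter, so the
    removal-reason histograms equal the planted counts exactly."""
    pon = build_pon(cohort.normal_callsets)
    for profile in DEFAULT_PROFILES:
        calls = emulate_caller(cohort.sites, profile, rng)
        annot = reason_histogram(
            apply_annotation_filters(calls, pon, cohort.resources))
        assert annot == cohort.labels["expected_annotation_reasons"]
        default = reason_histogram(apply_default_filters(calls, pon))
        expected = dict(cohort.labels["expected_default_reasons"])
        if profile.clustered_events:
            expected["not_PASS"] = \
                cohort.labels["expected_default_not_pass_clustered"]
        assert default == expected


def test_zero_alt_sites_are_never_reported(rng):
    sites = pd.DataFrame([{
        "chrom": "chr1", "pos": 100, "ref": "A", "alt": "G", "vtype": SNV,
        "total_depth": 50, "alt_depth": 0, "mean_bq": 30.0,
    }])
    assert emulate_caller(sites, DEFAULT_PROFILES[0], rng) == []


def test_block_vs_split_composite_representation(cohort, rng):
    """The same composite truth variant matches exactly under a block-mode
    profile but needs partial matching under a split-mode profile."""
    block = CallerProfile("block", indel_mode="block",
                          report_prob={SNV: 1.0, "insertion": 1.0,
                                       "deletion": 1.0, "composite": 1.0})
    split = CallerProfile("split", indel_mode="split",
                          report_prob=block.report_prob)
    composite_truth = next(t for t in cohort.truth if t.vtype == "composite")
    block_calls = emulate_caller(cohort.sites, block, rng)
    split_calls = emulate_caller(cohort.sites, split, rng)
    assert match_indel(composite_truth, block_calls, mode=EXACT).called
    assert not match_indel(composite_truth, split_calls, mode=EXACT).called
    assert match_indel(composite_truth, split_calls, mode=PARTIAL).called
    assert match_indel(composite_truth, block_calls, mode=PARTIAL).called


def test_split_pieces_reassemble_to_the_block_allele(cohort, rng):
    split = CallerProfile("split", indel_mode="split",
                          report_prob={SNV: 1.0, "insertion": 1.0,
                                       "deletion": 1.0, "composite": 1.0})
    calls = emulate_caller(cohort.sites, split, rng)
    composites = cohort.sites[cohort.sites.category == "composite_indel"]
    for row in composites.itertuples(index=False):
        pieces = sorted((c for c in calls
                         if c.chrom == row.chrom and row.pos <= c.pos <= row.pos + 1),
                        key=lambda c: c.pos)
        assert len(pieces) == 2
        assert pieces[0].alt + pieces[1].alt == row.alt
        assert pieces[0].ref + pieces[1].ref == row.ref
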