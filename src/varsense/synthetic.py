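"""Synthetic AML-like cohort generation with fully known ground truth.

Everything the benchmarking pipeline consumes can be generated here:

* a reference sequence with planted homopolymer runs (and none arising by
  chance), organised into single-exon gene blocks;
* a truth set shaped like a validated AML RNA-Seq mutation catalogue:
  58 SNVs, 15 short insertions, 9 composite indels, 3 long insertions,
  2 short deletions and one indel with no reported allele (88 variants),
  with per-type VAFs drawn from triangular distributions over the
  published min/mean/max ranges;
* expression-driven site depths: each variant's gene receives a log2 RPKM
  draw, the expected initial depth follows the library-size formula, and
  realised depths are Poisson (optionally negative-binomial) around it;
* a panel of 17 normal call sets with planted recurrent artifacts, a
  low-VAF COSMIC hotspot present in a few normals (the NRAS scenario) and
  singleton noise straddling the 0.03 VAF rule;
* annotation resources (COSMIC/dbSNP/ExAC membership, repeat and
  RNA-editing tracks, exon boundaries) with planted decoy calls that each
  fail exactly one annotation filter, so removal-reason histograms have
  exact expected counts;
* emulated caller outputs parameterised by :class:`CallerProfile` —
  block vs split indel representation, per-type reporting probabilities and
  a clustered-events flag model.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import filters as flt
from .design import expected_site_depth
from .filters import AnnotationResources, IntervalTrack, detect_homopolymers
from .variants import (COMPOSITE, DELETION, INSERTION, SNV, StandardVariant,
                       TruthVariant, VariantKey, classify_vtype)

_BASES = "ACGT"

# truth-set composition: per-category counts and (min, mode, max) VAF ranges
DEFAULT_TRUTH_COUNTS: dict[str, int] = {
    "SNV": 58,
    "short_insertion": 15,
    "composite_indel": 9,
    "long_insertion": 3,
    "short_deletion": 2,
    "indel_not_reported": 1,
}
DEFAULT_VAF_RANGES: dict[str, tuple[float, float, float]] = {
    "SNV": (0.05, 0.37, 0.97),
    "short_insertion": (0.07, 0.33, 0.84),
    "composite_indel": (0.06, 0.25, 0.56),
    "long_insertion": (0.41, 0.50, 0.64),
    "short_deletion": (0.09, 0.24, 0.38),
    "indel_not_reported": (0.84, 0.84, 0.84),
}
_CATEGORY_VTYPE = {
    "SNV": SNV,
    "short_insertion": INSERTION,
    "long_insertion": INSERTION,
    "short_deletion": DELETION,
    "composite_indel": COMPOSITE,
    "indel_not_reported": INSERTION,
}

DEFAULT_DECOY_COUNTS: dict[str, int] = {
    "germline": 5,        # in dbSNP and ExAC, not COSMIC
    "pon_artifact": 4,    # recurrent in the PON, not COSMIC
    "homopolymer": 2,     # inside a planted homopolymer run (in COSMIC)
    "repeat": 2,          # inside a planted repeat interval (in COSMIC)
    "exon_boundary": 2,   # 3 bp upstream of an exon start (in COSMIC)
    "low_base_quality": 2,
    "low_alt_depth": 2,
    "low_total_depth": 2,
    "low_vaf": 2,
}


@dataclass
class CohortConfig:
    seed: int = 100
    chrom: str = "chr1"
    n_genes: int = 120
    gene_span: int = 1000
    truth_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_COUNTS))
    vaf_ranges: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VAF_RANGES))
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DECOY_COUNTS))
    # expression model (log2 RPKM of variant-hosting genes); the floor keeps
    # every truth site above ~90X total depth in the initial deep library
    log2_rpkm_mean: float = 3.5
    log2_rpkm_sd: float = 1.2
    log2_rpkm_floor: float = 2.0
    initial_fragments: float = 113e6
    read_length: int = 100
    n_normals: int = 17
    # truth-site support in the initial deep library: validated variants are
    # detectable there, so alt support is conditioned on a floor and a VAF
    # margin above the 0.03 filter threshold
    alt_floor: int = 6
    vaf_margin: float = 0.035
    mean_bq: float = 30.0
    bq_sd: float = 3.0
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    # PON planting
    artifact_recurrence: int = 10
    hotspot_normals: int = 3
    pon_singletons_low: int = 3   # VAF < 0.03, one normal -> absent from PON
    pon_singletons_high: int = 2  # VAF > 0.03, one normal -> present in PON
    # database decoys (keys never called in the tumour)
    cosmic_extra: int = 20
    dbsnp_only: int = 2
    rna_editing_sites: int = 3

    @property
    def n_truth(self) -> int:
        return sum(self.truth_counts.values())


@dataclass(frozen=True)
class CallerProfile:
    """Parameterised emulation of one caller's reporting behaviour."""

    caller_id: str
    indel_mode: str = "block"  # "block" or "split" composite representation
    report_prob: Mapping[str, float] = field(
        default_factory=lambda: {SNV: 1.0, INSERTION: 0.62, DELETION: 0.62,
                                 COMPOSITE: 0.62})
    min_alt_reads: int = 3
    clustered_events: bool = False
    cluster_k: int = 3
    cluster_window: int = 100


DEFAULT_PROFILES: tuple[CallerProfile, ...] = (
    CallerProfile("vardict_like", indel_mode="block",
                  report_prob={SNV: 1.0, INSERTION: 0.62, DELETION: 0.62,
                               COMPOSITE: 0.62}),
    CallerProfile("mutect_like", indel_mode="split", clustered_events=True,
                  report_prob={SNV: 1.0, INSERTION: 0.45, DELETION: 0.50,
                               COMPOSITE: 0.90}),
    CallerProfile("varscan_like", indel_mode="split",
                  report_prob={SNV: 1.0, INSERTION: 0.40, DELETION: 0.45,
                               COMPOSITE: 0.80}),
)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    reference: dict[str, str]
    genes: pd.DataFrame            # gene_id, exon_start, exon_end, log2_rpkm, rpkm
    truth: list[TruthVariant]
    sites: pd.DataFrame            # one row per callable site (truth + decoys)
    resources: AnnotationResources
    normal_callsets: list[list[StandardVariant]]
    labels: dict

    def depth_track(self, sites: pd.DataFrame | None = None) -> dict[tuple[str, int], int]:
        df = self.sites if sites is None else sites
        return {(str(r.chrom), int(r.pos)): int(r.total_depth)
                for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    length: int,
    planted_homopolymers: Sequence[tuple[int, str, int]] = (),
    seed: int = 0,
    chrom: str = "chr1",
    max_natural_run: int = 5,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Random sequence with homopolymer runs only where planted.

    ``planted_homopolymers`` are (1-based start, base, run_length) with
    run_length > max_natural_run; overlapping plants raise. Returns the
    sequence dict and the ground-truth run intervals (1-based closed).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    seq = []
    run = 0
    for _ in range(length):
        if run >= max_natural_run:
            choices = [b for b in _BASES if b != seq[-1]]
        else:
            choices = list(_BASES)
        b = choices[int(rng.integers(len(choices)))]
        run = run + 1 if seq and b == seq[-1] else 1
        seq.append(b)
    occupied: list[tuple[int, int]] = []
    intervals: list[tuple[int, int]] = []
    for start1, base, run_len in sorted(planted_homopolymers):
        if run_len <= max_natural_run:
            raise ValueError(f"planted run of {run_len} is not a homopolymer "
                             f"under the > {max_natural_run} bp rule")
        s0, e0 = start1 - 1, start1 - 1 + run_len
        if s0 < 1 or e0 > length - 1:
            raise ValueError("planted run must leave one flanking base")
        for os_, oe in occupied:
            if s0 - 1 < oe and os_ < e0 + 1:
                raise ValueError("overlapping planted homopolymers")
        occupied.append((s0 - 1, e0 + 1))
        seq[s0:e0] = base * run_len
        # force flanking bases to singleton runs so the planted run is
        # maximal and no natural run is accidentally extended
        for flank in (s0 - 1, e0):
            forbidden = {base}
            if flank - 1 >= 0:
                forbidden.add(seq[flank - 1])
            if flank + 1 < length:
                forbidden.add(seq[flank + 1])
            seq[flank] = next(b for b in _BASES if b not in forbidden)
        intervals.append((start1, start1 + run_len - 1))
    return {chrom: "".join(seq)}, {chrom: sorted(intervals)}


# ---------------------------------------------------------------------------
# cohort generation


def _triangular(rng, lo, mode, hi):
    if lo == hi:
        return lo
    return float(rng.triangular(lo, min(max(mode, lo), hi), hi))


def _draw_depth(rng, expected: float, overdispersion: float | None) -> int:
    if overdispersion is None:
        return int(rng.poisson(expected))
    size = overdispersion
    p = size / (size + expected)
    return int(rng.negative_binomial(size, p))


def _conditioned_alt(rng, total: int, vaf: float, alt_floor: int,
                     vaf_margin: float) -> int:
    """Binomial alt support conditioned on detectability in the deep library."""
    lo = max(alt_floor, math.ceil(vaf_margin * total))
    if total <= lo:
        return max(1, total)
    for _ in range(1000):
        alt = int(rng.binomial(total, vaf))
        if alt >= lo:
            return min(alt, total)
    return lo


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=n))


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic study: reference, truth, depths, PON,
    resources and planted-ground-truth labels."""
    cfg = config or CohortConfig()
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    chrom = cfg.chrom
    span = cfg.gene_span
    n_decoys = sum(cfg.decoy_counts.values())
    # gene 0 hosts the clustered triplet; SNV counts include triplet + hotspot
    n_truth_genes = 1 + (cfg.n_truth - 3)
    if cfg.truth_counts.get("SNV", 0) < 4:
        raise ValueError("need at least 4 SNVs (hotspot + clustered triplet)")
    if n_truth_genes + n_decoys + 2 > cfg.n_genes:
        raise ValueError("n_genes too small for the planted layout")

    # --- gene layout: single-exon genes on a fixed grid -------------------
    exon_starts = [i * span + 101 for i in range(cfg.n_genes)]
    exon_ends = [i * span + 700 for i in range(cfg.n_genes)]

    # --- reference with planted homopolymer runs --------------------------
    hp_gene0 = n_truth_genes + _decoy_offset(cfg, "homopolymer")
    planted_runs = []
    hp_positions = []
    for j in range(cfg.decoy_counts.get("homopolymer", 0)):
        g = hp_gene0 + j
        start1 = exon_starts[g] + 200
        planted_runs.append((start1, "A", 8))
        hp_positions.append(start1 + 3)
    # extra intergenic runs exercise the detector away from any call
    extra_run_start = exon_ends[cfg.n_genes - 1] + 60
    planted_runs.append((extra_run_start, "T", 7))
    reference, hp_intervals = generate_reference(
        cfg.n_genes * span + 2000, planted_runs, seed=int(rng.integers(2**31)),
        chrom=chrom)
    seq = reference[chrom]

    # --- expression -------------------------------------------------------
    log2 = rng.normal(cfg.log2_rpkm_mean, cfg.log2_rpkm_sd, size=cfg.n_genes)
    n_variant_genes = n_truth_genes + n_decoys
    for i in range(n_variant_genes):
        while log2[i] < cfg.log2_rpkm_floor:
            log2[i] = rng.normal(cfg.log2_rpkm_mean, cfg.log2_rpkm_sd)
    genes = pd.DataFrame({
        "gene_id": [f"gene_{i:04d}" for i in range(cfg.n_genes)],
        "exon_start": exon_starts,
        "exon_end": exon_ends,
        "log2_rpkm": log2,
        "rpkm": np.exp2(log2),
    })

    # --- truth variants ---------------------------------------------------
    def slot_pos(gene_idx: int) -> int:
        return exon_starts[gene_idx] + 60 + 10 * int(rng.integers(0, 31))

    truth_rows: list[dict] = []
    categories = [c for c, n in cfg.truth_counts.items() for _ in range(n)]
    # clustered triplet: first three SNVs share gene 0
    triplet_pos = [exon_starts[0] + 100, exon_starts[0] + 130, exon_starts[0] + 160]
    snv_seen = 0
    gene_cursor = 1
    for cat in categories:
        vmin, vmode, vmax = cfg.vaf_ranges[cat]
        vaf = _triangular(rng, vmin, vmode, vmax)
        if cat == "SNV" and snv_seen < 3:
            g, pos = 0, triplet_pos[snv_seen]
            snv_seen += 1
        else:
            g, pos = gene_cursor, slot_pos(gene_cursor)
            gene_cursor += 1
            if cat == "SNV":
                snv_seen += 1
        ref, alt = _alleles_for(cat, seq, pos, rng)
        truth_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "vtype": _CATEGORY_VTYPE[cat], "category": cat,
            "gene_id": genes.gene_id[g], "gene_idx": g, "vaf_true": vaf,
        })
    # hotspot: the fourth SNV (first non-triplet) is the COSMIC/PON case
    hotspot_row = next(r for r in truth_rows
                       if r["category"] == "SNV" and r["gene_idx"] != 0)
    hotspot_key = (chrom, hotspot_row["pos"], hotspot_row["ref"], hotspot_row["alt"])
    clustered_keys = [(chrom, p, r["ref"], r["alt"])
                      for p, r in zip(triplet_pos,
                                      [t for t in truth_rows if t["gene_idx"] == 0])]

    # --- decoys -----------------------------------------------------------
    decoy_rows: list[dict] = []
    decoy_keys: dict[str, list[VariantKey]] = {k: [] for k in cfg.decoy_counts}
    g = n_truth_genes
    for kind, count in cfg.decoy_counts.items():
        for j in range(count):
            if kind == "homopolymer":
                pos = hp_positions[j]
            elif kind == "exon_boundary":
                pos = exon_starts[g] - 3
            else:
                pos = slot_pos(g)
            ref = seq[pos - 1]
            alt = _other_base(ref, rng)
            row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                   "vtype": SNV, "category": f"decoy_{kind}",
                   "gene_id": genes.gene_id[g], "gene_idx": g,
                   "vaf_true": float(rng.uniform(0.2, 0.5))}
            if kind == "germline":
                row["vaf_true"] = float(rng.uniform(0.4, 0.6))
            decoy_rows.append(row)
            decoy_keys[kind].append((chrom, pos, ref, alt))
            g += 1

    # --- depths -----------------------------------------------------------
    all_rows = truth_rows + decoy_rows
    for row in all_rows:
        rpkm = float(genes.rpkm[row["gene_idx"]])
        row["log2_rpkm"] = float(genes.log2_rpkm[row["gene_idx"]])
        expected = expected_site_depth(rpkm, cfg.read_length, cfg.initial_fragments)
        row["expected_depth"] = expected
        total = max(1, _draw_depth(rng, expected, cfg.overdispersion))
        row["total_depth"] = total
        row["alt_depth"] = _conditioned_alt(rng, total, row["vaf_true"],
                                            cfg.alt_floor, cfg.vaf_margin)
        bq = float(rng.normal(cfg.mean_bq, cfg.bq_sd))
        row["mean_bq"] = max(bq, 20.5)
    # quality decoys override the drawn depths so exactly one filter fails
    for row in all_rows:
        cat = row["category"]
        if cat == "decoy_low_base_quality":
            row["mean_bq"] = 15.0
        elif cat == "decoy_low_alt_depth":
            row["total_depth"], row["alt_depth"] = 100, 4
        elif cat == "decoy_low_total_depth":
            row["total_depth"], row["alt_depth"] = 14, 6
        elif cat == "decoy_low_vaf":
            row["total_depth"], row["alt_depth"] = 300, 6
        if cat.startswith("decoy_low_"):
            row["vaf_true"] = row["alt_depth"] / row["total_depth"]

    sites = pd.DataFrame(all_rows)
    # the unreported-allele truth record is kept in the site table (its depth
    # feeds the depth track) but carries no callable allele
    sites.loc[sites["category"] == "indel_not_reported", "alt"] = ""

    truth = [
        TruthVariant(
            chrom=chrom, pos=int(r["pos"]), ref=str(r["ref"]),
            alt=None if r["category"] == "indel_not_reported" else str(r["alt"]),
            vtype=r["vtype"], vaf_expected=float(r["vaf_true"]),
            gene_id=str(r["gene_id"]), set_id="truth",
        )
        for r in truth_rows
    ]

    # --- panel of normals -------------------------------------------------
    normal_callsets, pon_truth = _generate_pon(cfg, rng, chrom, seq,
                                               decoy_keys["pon_artifact"],
                                               hotspot_key, exon_ends)

    # --- annotation resources --------------------------------------------
    resources, db_extra = _generate_resources(cfg, rng, chrom, seq, reference,
                                              truth, decoy_keys, genes,
                                              hotspot_key, exon_ends)

    expected_annotation = {
        flt.PON_NOT_COSMIC: cfg.decoy_counts["pon_artifact"],
        flt.DBSNP_EXAC: cfg.decoy_counts["germline"],
        flt.EXON_BOUNDARY: cfg.decoy_counts["exon_boundary"],
        flt.HOMOPOLYMER: cfg.decoy_counts["homopolymer"],
        flt.REPEAT: cfg.decoy_counts["repeat"],
        flt.LOW_BASE_QUALITY: cfg.decoy_counts["low_base_quality"],
        flt.LOW_ALT_DEPTH: cfg.decoy_counts["low_alt_depth"],
        flt.LOW_TOTAL_DEPTH: cfg.decoy_counts["low_total_depth"],
        flt.LOW_VAF: cfg.decoy_counts["low_vaf"],
    }
    expected_default = {flt.PON: cfg.decoy_counts["pon_artifact"] + 1}  # + hotspot

    labels = {
        "hotspot_key": hotspot_key,
        "clustered_keys": clustered_keys,
        "decoy_keys": decoy_keys,
        "pon_truth": pon_truth,
        "homopolymer_intervals": hp_intervals,
        "expected_annotation_reasons": expected_annotation,
        "expected_default_reasons": expected_default,
        "expected_default_not_pass_clustered": 3,
        "db_extra": db_extra,
    }
    return SyntheticCohort(cfg, reference, genes, truth, sites, resources,
                           normal_callsets, labels)


def _decoy_offset(cfg: CohortConfig, kind: str) -> int:
    off = 0
    for k, n in cfg.decoy_counts.items():
        if k == kind:
            return off
        off += n
    raise KeyError(kind)


def _other_base(base: str, rng) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(3))]


def _alleles_for(cat: str, seq: str, pos: int, rng) -> tuple[str, str]:
    anchor = seq[pos - 1]
    if cat == "SNV":
        return anchor, _other_base(anchor, rng)
    if cat == "short_insertion":
        return anchor, anchor + _random_seq(rng, int(rng.integers(1, 9)))
    if cat == "long_insertion":
        return anchor, anchor + _random_seq(rng, int(rng.integers(10, 16)))
    if cat == "short_deletion":
        n = int(rng.integers(1, 9))
        return seq[pos - 1: pos - 1 + n + 1], anchor
    if cat == "composite_indel":
        n_del = int(rng.integers(2, 5))
        ref = seq[pos - 1: pos - 1 + n_del + 1]
        while True:
            alt = _random_seq(rng, int(rng.integers(5, 10)))
            if classify_vtype(ref, alt) == COMPOSITE and alt[0] != ref[0]:
                return ref, alt
    if cat == "indel_not_reported":
        return anchor, anchor + _random_seq(rng, 4)
    raise KeyError(cat)


def _generate_pon(cfg, rng, chrom, seq, artifact_keys, hotspot_key, exon_ends):
    """Normal-sample call sets with planted recurrence structure."""
    n = cfg.n_normals
    callsets: list[list[StandardVariant]] = [[] for _ in range(n)]
    pon_truth: dict[VariantKey, bool] = {}

    def add(key, sample_idx, vaf):
        chrom_, pos, ref, alt = key
        total = 100
        alt_depth = max(1, int(round(vaf * total)))
        callsets[sample_idx].append(StandardVariant(
            chrom=chrom_, pos=pos, ref=ref, alt=alt,
            total_depth=total, alt_depth=alt_depth,
            mean_base_quality=30.0, filter_flags=frozenset({"PASS"}),
            sample_id=f"normal_{sample_idx:02d}", caller_id="pon",
        ))

    for key in artifact_keys:
        samples = rng.choice(n, size=cfg.artifact_recurrence, replace=False)
        for s in samples:
            add(key, int(s), float(rng.uniform(0.01, 0.05)))
        pon_truth[key] = True  # recurrent in > 2 normals
    samples = rng.choice(n, size=cfg.hotspot_normals, replace=False)
    for s in samples:
        add(hotspot_key, int(s), float(rng.uniform(0.005, 0.02)))
    pon_truth[hotspot_key] = cfg.hotspot_normals > 2

    # singleton noise at positions never called in the tumour
    noise_pos = exon_ends[-1] + 300
    for i in range(cfg.pon_singletons_low + cfg.pon_singletons_high):
        pos = noise_pos + 20 * i
        ref = seq[pos - 1]
        key = (chrom, pos, ref, _other_base(ref, rng))
        high = i >= cfg.pon_singletons_low
        vaf = float(rng.uniform(0.035, 0.1)) if high else float(rng.uniform(0.005, 0.025))
        add(key, int(rng.integers(n)), vaf)
        pon_truth[key] = high  # single normal: present only when VAF > 0.03
    return callsets, pon_truth


def _generate_resources(cfg, rng, chrom, seq, reference, truth, decoy_keys,
                        genes, hotspot_key, exon_ends):
    """Membership sets and context tracks, with planted ground truth."""
    truth_keys = {t.key for t in truth if t.key is not None}
    cosmic = set(truth_keys)
    cosmic.update(decoy_keys["homopolymer"])
    cosmic.update(decoy_keys["repeat"])
    cosmic.update(decoy_keys["exon_boundary"])
    # extra COSMIC keys at positions never called
    extra_base = exon_ends[-1] + 500
    cosmic_extra = []
    for i in range(cfg.cosmic_extra):
        pos = extra_base + 10 * i
        ref = seq[pos - 1]
        cosmic_extra.append((chrom, pos, ref, _other_base(ref, rng)))
    cosmic.update(cosmic_extra)

    dbsnp = set(decoy_keys["germline"])
    exac = set(decoy_keys["germline"])
    dbsnp_only = []
    for i in range(cfg.dbsnp_only):
        pos = extra_base + 10 * (cfg.cosmic_extra + i)
        ref = seq[pos - 1]
        dbsnp_only.append((chrom, pos, ref, _other_base(ref, rng)))
    dbsnp.update(dbsnp_only)

    editing = frozenset((chrom, extra_base + 700 + 15 * i)
                        for i in range(cfg.rna_editing_sites))

    repeat_ivs = [(k[1] - 10, k[1] + 10) for k in decoy_keys["repeat"]]
    repeats = IntervalTrack.from_closed({chrom: repeat_ivs})
    homopolymers = IntervalTrack.from_closed(detect_homopolymers(reference))
    exons = {chrom: list(zip(genes.exon_start, genes.exon_end))}
    resources = AnnotationResources(
        cosmic=frozenset(cosmic), dbsnp=frozenset(dbsnp), exac=frozenset(exac),
        rna_editing_sites=editing, repeat_regions=repeats,
        homopolymers=homopolymers, exon_boundaries=exons,
    )
    return resources, {"cosmic_extra": cosmic_extra, "dbsnp_only": dbsnp_only}


def generate_pon_cohort(config: CohortConfig | None = None):
    """Convenience: the normal call sets and PON ground-truth labels of a
    generated cohort."""
    cohort = generate_cohort(config)
    return cohort.normal_callsets, cohort.labels["pon_truth"]


# ---------------------------------------------------------------------------
# caller emulation


def emulate_caller(
    sites: pd.DataFrame,
    profile: CallerProfile,
    rng: np.random.Generator,
) -> list[StandardVariant]:
    """Emit a pre-filter call set from a (possibly thinned) site table.

    A site is reported iff its alt support meets the profile's minimum and a
    per-type Bernoulli succeeds; sites with zero alt reads are never
    reported. Split-mode profiles decompose composite alleles into a
    co-located SNV piece plus an indel piece that reassemble to the block
    allele. The clustered-events flag model replaces PASS on any call with
    >= cluster_k calls (itself included) within the cluster window.
    """
    calls: list[StandardVariant] = []
    lib = sites["library_size_fragments"] if "library_size_fragments" in sites else None
    rep = sites["replicate_seed"] if "replicate_seed" in sites else None
    for idx, row in enumerate(sites.itertuples(index=False)):
        alt = str(row.alt)
        if not alt or alt == "nan":
            continue
        alt_depth = int(row.alt_depth)
        total = int(row.total_depth)
        if alt_depth <= 0 or alt_depth < profile.min_alt_reads or total <= 0:
            continue
        vtype = str(row.vtype)
        prob = profile.report_prob.get(vtype, 1.0)
        if rng.random() >= prob:
            continue
        common = dict(
            total_depth=total,
            alt_depth=alt_depth,
            mean_base_quality=float(row.mean_bq),
            filter_flags=frozenset({"PASS"}),
            sample_id=str(getattr(row, "sample_id", "tumour")),
            caller_id=profile.caller_id,
            library_size_fragments=float(lib.iloc[idx]) if lib is not None else float("nan"),
            replicate_id=str(rep.iloc[idx]) if rep is not None else "",
        )
        ref = str(row.ref)
        pos = int(row.pos)
        if vtype == COMPOSITE and profile.indel_mode == "split":
            calls.append(StandardVariant(chrom=str(row.chrom), pos=pos,
                                         ref=ref[0], alt=alt[0], **common))
            calls.append(StandardVariant(chrom=str(row.chrom), pos=pos + 1,
                                         ref=ref[1:], alt=alt[1:], **common))
        else:
            calls.append(StandardVariant(chrom=str(row.chrom), pos=pos,
                                         ref=ref, alt=alt, **common))
    if profile.clustered_events:
        calls = _apply_clustered_flags(calls, profile.cluster_k,
                                       profile.cluster_window)
    return calls


def _apply_clustered_flags(calls, k: int, window: int):
    out = []
    for c in calls:
        n_near = sum(1 for o in calls
                     if o.chrom == c.chrom and abs(o.pos - c.pos) <= window)
        if n_near >= k:
            c = replace(c, filter_flags=frozenset({"clustered_events"}))
        out.append(c)
    return out
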