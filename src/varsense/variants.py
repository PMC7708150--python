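"""Harmonised variant records shared by every pipeline stage.

Calls from different somatic callers (MuTect2-, VarScan2-, VarDict-style
output) are reduced to a single :class:`StandardVariant` schema carrying the
site, alleles, depths, VAF, base quality, FILTER flags and provenance labels.
Alongside the schema live the allele-level utilities every other stage relies
on: type classification, vt-style indel normalisation (left-align + parsimony
trim) and the ``(chrom, pos, ref, alt)`` key used for panel-of-normals lookup
and truth matching.

Coordinates are 1-based fully closed, as in VCF.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
COMPOSITE = "composite"

_VALID_BASES = frozenset("ACGTN")

VariantKey = tuple[str, int, str, str]


@dataclass
class StandardVariant:
    """One harmonised variant call (one record per ALT allele)."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    vtype: str = ""
    total_depth: int = 0
    alt_depth: int = 0
    mean_base_quality: float = float("nan")
    filter_flags: frozenset[str] = frozenset()
    sample_id: str = ""
    caller_id: str = ""
    library_size_fragments: float = float("nan")
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_depth <= self.total_depth):
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth="
                f"{self.total_depth}] at {self.chrom}:{self.pos}"
            )
        if not self.vtype:
            self.vtype = classify_vtype(self.ref, self.alt)
        if not isinstance(self.filter_flags, frozenset):
            self.filter_flags = frozenset(self.filter_flags)

    @property
    def vaf(self) -> float:
        """alt_depth / total_depth; NaN when the site has no coverage."""
        if self.total_depth > 0:
            return self.alt_depth / self.total_depth
        return float("nan")

    @property
    def key(self) -> VariantKey:
        return variant_key(self)

    @property
    def is_indel(self) -> bool:
        return self.vtype != SNV

    def ref_span(self) -> tuple[int, int]:
        """1-based closed interval of reference bases the allele replaces."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class TruthVariant:
    """A validated mutation scored against call sets.

    ``alt`` may be ``None`` for truth records whose alternative allele was
    never published; such records are excluded from allele-aware matching but
    still count in sensitivity denominators.
    """

    chrom: str
    pos: int
    ref: str
    alt: str | None
    vtype: str
    vaf_expected: float = float("nan")
    gene_id: str = ""
    set_id: str = "truth"

    @property
    def key(self) -> VariantKey | None:
        if self.alt is None:
            return None
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneExpression:
    """Expression of one gene, the driver of expected RNA coverage."""

    gene_id: str
    rpkm: float
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"negative RPKM for {self.gene_id}")

    @property
    def log2_rpkm(self) -> float:
        return math.log2(self.rpkm + self.pseudocount)


def classify_vtype(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as SNV, insertion, deletion or composite.

    Composite covers block substitutions and any indel whose alleles do not
    nest (both inserted and deleted nucleotides).
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    for allele in (ref, alt):
        if not _VALID_BASES.issuperset(allele.upper()):
            raise ValueError(f"non-ACGTN characters in allele {allele!r}")
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return DELETION
    return COMPOSITE


def variant_key(v: StandardVariant) -> VariantKey:
    """(chrom, pos, ref, alt) — stable across callers after normalisation."""
    return (v.chrom, v.pos, v.ref, v.alt)


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Reference slice [start0, end0) 0-based, from a dict of sequences or a
    pyfaidx.Fasta."""
    if start0 < 0:
        raise ValueError(f"position before start of {chrom}")
    seq = reference[chrom]
    out = str(seq[start0:end0]).upper()
    if len(out) != end0 - start0:
        raise ValueError(f"position beyond end of {chrom}")
    return out


def normalize_indel(v: StandardVariant, reference) -> StandardVariant:
    """Left-align and parsimony-trim an indel against the reference.

    Follows the vt-normalize procedure: repeatedly truncate a shared
    rightmost base, extending both alleles one reference base to the left
    whenever one allele would empty; finally trim shared leftmost bases down
    to a single anchor. SNVs are returned unchanged. Idempotent; the edited
    haplotype is preserved.
    """
    observed = _fetch(reference, v.chrom, v.pos - 1, v.pos - 1 + len(v.ref))
    if observed != v.ref.upper():
        raise ValueError(
            f"REF disagreement at {v.chrom}:{v.pos}: record has {v.ref!r}, "
            f"reference has {observed!r}"
        )
    if v.vtype == SNV:
        return v

    pos0 = v.pos - 1
    ref, alt = v.ref.upper(), v.alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
            if (len(ref) == 1 or len(alt) == 1) and pos0 == 0:
                break  # cannot left-extend past the chromosome start
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos0 -= 1
                base = _fetch(reference, v.chrom, pos0, pos0 + 1)
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1

    return replace(v, pos=pos0 + 1, ref=ref, alt=alt, vtype=classify_vtype(ref, alt))


def apply_to_reference(seq: str, pos: int, ref: str, alt: str, offset: int = 0) -> str:
    """Reconstruct the alternate haplotype over a reference window.

    ``seq`` starts at 1-based coordinate ``offset + 1``. Used as the oracle
    that normalisation preserves the set of edited bases.
    """
    i = pos - 1 - offset
    if seq[i : i + len(ref)].upper() != ref.upper():
        raise ValueError("ref allele does not match window")
    return seq[:i] + alt + seq[i + len(ref) :]


# ---------------------------------------------------------------------------
# VCF I/O


@dataclass(frozen=True)
class VcfFieldMap:
    """Where to find depths and base quality in a caller's VCF output."""

    depth: str = "DP"
    allele_depth: str = "AD"
    alt_depth: str = "AO"  # fallback when AD is absent (VarDict/freebayes style)
    base_quality: str = "MBQ"


def read_calls(
    vcf_path,
    provenance: Mapping[str, object] | None = None,
    field_map: VcfFieldMap | None = None,
) -> list[StandardVariant]:
    """Parse a VCF 4.x file into standardised calls.

    Multi-allelic rows are split into one record per ALT allele. Records
    missing the mapped depth fields are skipped with a logged warning;
    structurally malformed files raise with the offending record number.
    """
    fm = field_map or VcfFieldMap()
    prov = dict(provenance or {})
    calls: list[StandardVariant] = []
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for n_rec, rec in enumerate(vf, start=1):
            try:
                flags = frozenset(rec.filter.keys())
                sample = rec.samples[0] if rec.samples else None
                for i, alt in enumerate(rec.alts or ()):
                    fields = _extract_depths(rec, sample, i, fm)
                    if fields is None:
                        skipped += 1
                        logger.warning(
                            "skipping %s:%s alt=%s (record %d): missing depth fields",
                            rec.chrom, rec.pos, alt, n_rec,
                        )
                        continue
                    dp, ad, bq = fields
                    calls.append(
                        StandardVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            total_depth=dp,
                            alt_depth=ad,
                            mean_base_quality=bq,
                            filter_flags=flags,
                            sample_id=str(prov.get("sample_id", "")),
                            caller_id=str(prov.get("caller_id", "")),
                            library_size_fragments=float(
                                prov.get("library_size_fragments", float("nan"))
                            ),
                            replicate_id=str(prov.get("replicate_id", "")),
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed VCF record {n_rec} in {vcf_path}: {exc}")
    if skipped:
        logger.warning("%s: skipped %d ALT records with missing fields", vcf_path, skipped)
    return calls


def _get_field(rec, sample, name):
    if sample is not None and name in sample:
        return sample[name]
    if name in rec.info:
        return rec.info[name]
    return None


def _extract_depths(rec, sample, alt_index, fm: VcfFieldMap):
    dp = _get_field(rec, sample, fm.depth)
    ad = _get_field(rec, sample, fm.allele_depth)
    if ad is not None and not isinstance(ad, (int, float)):
        ad = ad[alt_index + 1]  # AD lists ref first
    if ad is None:
        ao = _get_field(rec, sample, fm.alt_depth)
        if ao is not None and not isinstance(ao, (int, float)):
            ao = ao[alt_index]
        ad = ao
    if dp is None or ad is None:
        return None
    bq = _get_field(rec, sample, fm.base_quality)
    if bq is not None and not isinstance(bq, (int, float)):
        bq = bq[alt_index] if len(bq) > alt_index else bq[0]
    return int(dp), int(ad), float(bq) if bq is not None else float("nan")


def write_calls(
    calls: Sequence[StandardVariant],
    path,
    contigs: Mapping[str, int] | None = None,
    sample_name: str | None = None,
) -> None:
    """Write standardised calls back out as single-sample VCF 4.2."""
    if contigs is None:
        contigs = {}
        for c in calls:
            end = c.pos + len(c.ref) + 1000
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), end)
    if sample_name is None:
        sample_name = next((c.sample_id for c in calls if c.sample_id), "SAMPLE")

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    flags = sorted({f for c in calls for f in c.filter_flags} - {"PASS"})
    for f in flags:
        header.filters.add(f, None, None, "caller flag")
    header.formats.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("MBQ", 1, "Float", "Mean base quality of alt-supporting reads")
    header.add_sample(sample_name)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            if c.filter_flags:
                for f in sorted(c.filter_flags):
                    rec.filter.add(f)
            rec.samples[sample_name]["DP"] = c.total_depth
            rec.samples[sample_name]["AD"] = (c.total_depth - c.alt_depth, c.alt_depth)
            if not math.isnan(c.mean_base_quality):
                rec.samples[sample_name]["MBQ"] = c.mean_base_quality
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV serialisation of the standardised schema

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vtype", "total_depth", "alt_depth",
    "vaf", "mean_base_quality", "filter_flags", "sample_id", "caller_id",
    "library_size_fragments", "replicate_id",
]


def calls_to_frame(calls: Iterable[StandardVariant]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = dataclasses.asdict(c)
        d["vaf"] = c.vaf
        d["filter_flags"] = ";".join(sorted(c.filter_flags))
        rows.append(d)
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> list[StandardVariant]:
    calls = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "filter_flags", "") or ""
        calls.append(
            StandardVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                total_depth=int(row.total_depth),
                alt_depth=int(row.alt_depth),
                mean_base_quality=float(getattr(row, "mean_base_quality", float("nan"))),
                filter_flags=frozenset(f for f in str(flags).split(";") if f and f != "nan"),
                sample_id=str(getattr(row, "sample_id", "") or ""),
                caller_id=str(getattr(row, "caller_id", "") or ""),
                library_size_fragments=float(
                    getattr(row, "library_size_fragments", float("nan"))
                ),
                replicate_id=str(getattr(row, "replicate_id", "") or ""),
            )
        )
    return calls


def write_calls_tsv(calls: Iterable[StandardVariant], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[StandardVariant]:
    return frame_to_calls(pd.read_csv(path, sep="\t", keep_default_na=False,
                                      na_values=[""]))


def truth_to_frame(truth: Iterable[TruthVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(t) for t in truth],
        columns=["chrom", "pos", "ref", "alt", "vtype", "vaf_expected",
                 "gene_id", "set_id"],
    )


def frame_to_truth(df: pd.DataFrame) -> list[TruthVariant]:
    out = []
    for row in df.itertuples(index=False):
        alt = row.alt
        if alt is None or (isinstance(alt, float) and math.isnan(alt)) or alt == "":
            alt = None
        out.append(
            TruthVariant(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alt=alt, vtype=str(row.vtype),
                vaf_expected=float(row.vaf_expected),
                gene_id=str(row.gene_id), set_id=str(row.set_id),
            )
        )
    return out
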