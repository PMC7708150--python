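"""Library-size planning and downsampling simulation.

The planning formula connects library size to the expected read depth at a
variant site through the expression level of the host gene::

    library_size = (depth_at_site * 1e3 * 1e6) / (RPKM * read_length * 2)

for paired-end data (the trailing 2 is the two reads per fragment). A 30X
target in a 4-RPKM gene with 100 bp PE reads therefore needs 37.5M
fragments; 20X needs 25M. Inverting the formula gives the depth expected at
a site for a given library size.

Smaller libraries are simulated by thinning: each fragment is kept
independently with probability p = target/initial, so per-site alt and
reference read counts are thinned binomially and the VAF is preserved in
expectation. A mapping-rate adjustment factor scales the sampling
proportion when the cohort's mapping rate differs from the reference
cohort's. Paired FASTQ subsampling (seqtk-style) is also provided for
read-level fixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: replicate seeds used for the downsampling runs
DEFAULT_REPLICATE_SEEDS: tuple[int, ...] = (100, 26880, 56745, 7234, 9999)

#: fixed downsampled library sizes (fragments)
DEFAULT_LIBRARY_SIZES: tuple[float, ...] = (80e6, 50e6, 40e6, 30e6, 20e6)


@dataclass(frozen=True)
class LibraryPlan:
    target_depth: float
    rpkm: float
    read_length: int
    paired_factor: int = 2

    @property
    def required_fragments(self) -> float:
        return (self.target_depth * 1e3 * 1e6) / (
            self.rpkm * self.read_length * self.paired_factor
        )

    @property
    def required_fragments_millions(self) -> float:
        return self.required_fragments / 1e6


def required_library_size(
    target_depth: float, rpkm: float, read_length: int, paired_factor: int = 2
) -> LibraryPlan:
    """Fragments needed for a target mean depth at a variant site."""
    for name, val in (("target_depth", target_depth), ("rpkm", rpkm),
                      ("read_length", read_length), ("paired_factor", paired_factor)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    return LibraryPlan(target_depth, rpkm, read_length, paired_factor)


def expected_site_depth(
    rpkm: float, read_length: int, fragments: float, paired_factor: int = 2
) -> float:
    """Expected total depth at a site of a gene, given a library size.

    Exact inverse of :func:`required_library_size`.
    """
    if rpkm < 0 or read_length < 0 or fragments < 0:
        raise ValueError("inputs must be non-negative")
    return rpkm * read_length * paired_factor * fragments / (1e3 * 1e6)


def mapping_rate_adjustment(rate_reference_pct: float, rate_observed_pct: float) -> float:
    """Factor scaling sampling proportions for a lower-mapping-rate cohort.

    Returned at full precision; round to 2 decimals for reporting (93.4 vs
    75.6 gives 1.24).
    """
    if not (0 < rate_reference_pct <= 100):
        raise ValueError("reference mapping rate must be in (0, 100]")
    if not (0 < rate_observed_pct <= 100):
        raise ValueError("observed mapping rate must be in (0, 100]")
    return rate_reference_pct / rate_observed_pct


@dataclass
class DownsampleSpec:
    target_fragments: float = float("nan")
    replicate_seeds: tuple[int, ...] = DEFAULT_REPLICATE_SEEDS
    n_replicates: int | None = None  # None: 3 when p > high_p_cutoff else 5
    high_p_cutoff: float = 0.7
    mapping_rate_adjustment: float = 1.0

    def replicates_for(self, p: float) -> tuple[int, ...]:
        n = self.n_replicates
        if n is None:
            n = 3 if p > self.high_p_cutoff else 5
        return self.replicate_seeds[:n]


def thin_site(
    total_depth: int, alt_depth: int, p: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomially thin one site's read counts to sampling proportion p.

    Alt-supporting and reference reads are thinned independently, so the VAF
    is preserved in expectation while total depth scales by p.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"sampling proportion must be in [0, 1], got {p}")
    if alt_depth > total_depth:
        raise ValueError("alt_depth exceeds total_depth")
    alt = int(rng.binomial(alt_depth, p))
    ref = int(rng.binomial(total_depth - alt_depth, p))
    return alt + ref, alt


def thin_sites(
    sites: pd.DataFrame, p: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorised :func:`thin_site` over a site table with ``total_depth``
    and ``alt_depth`` columns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"sampling proportion must be in [0, 1], got {p}")
    out = sites.copy()
    alt = rng.binomial(sites["alt_depth"].to_numpy(), p)
    ref = rng.binomial((sites["total_depth"] - sites["alt_depth"]).to_numpy(), p)
    out["alt_depth"] = alt
    out["total_depth"] = alt + ref
    return out


def run_downsampling_experiment(
    sites: pd.DataFrame,
    initial_fragments: float,
    sizes: Sequence[float] = DEFAULT_LIBRARY_SIZES,
    spec: DownsampleSpec | None = None,
) -> dict[tuple[float, int], pd.DataFrame]:
    """Thin a site table to each target library size, once per replicate seed.

    Returns ``{(target_size, seed): thinned site table}``; each table keeps
    all truth and artifact sites (it doubles as the per-site depth track) and
    gains ``library_size_fragments`` / ``replicate_seed`` columns. Targets at
    or above the initial size fall back to p=1 with a warning.
    """
    spec = spec or DownsampleSpec()
    out: dict[tuple[float, int], pd.DataFrame] = {}
    for size in sizes:
        p = size / initial_fragments * spec.mapping_rate_adjustment
        if p > 1.0:
            warnings.warn(
                f"target {size:g} exceeds initial {initial_fragments:g} after "
                "adjustment; using all reads (p=1)"
            )
            p = 1.0
        for seed in spec.replicates_for(p):
            rng = np.random.Generator(np.random.PCG64(seed))
            thinned = thin_sites(sites, p, rng)
            thinned["library_size_fragments"] = size
            thinned["replicate_seed"] = seed
            out[(size, seed)] = thinned
    return out


# ---------------------------------------------------------------------------
# Paired FASTQ subsampling

def _read_fastq_records(path) -> list[list[str]]:
    records = []
    with open(path) as fh:
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                break
            if not lines[3]:
                raise ValueError(f"{path}: truncated FASTQ record {len(records)}")
            records.append(lines)
    return records


def downsample_fastq(
    r1_path,
    r2_path,
    out_r1,
    out_r2,
    n: int | None = None,
    proportion: float | None = None,
    seed: int = 100,
) -> int:
    """Sample fragments without replacement from a paired FASTQ.

    The same fragment index set is applied to both mates, preserving pair
    synchrony; records pass through byte-identically. With ``n`` a one-pass
    reservoir selects exactly n fragments; with ``proportion`` each fragment
    is kept by an independent seeded Bernoulli draw (seqtk-style). Returns
    the number of fragments written.
    """
    if (n is None) == (proportion is None):
        raise ValueError("give exactly one of n or proportion")
    rec1 = _read_fastq_records(r1_path)
    rec2 = _read_fastq_records(r2_path)
    if len(rec1) != len(rec2):
        raise ValueError(
            f"desynchronised mates: {len(rec1)} vs {len(rec2)} records "
            f"(first offending record index {min(len(rec1), len(rec2))})"
        )
    for i, (a, b) in enumerate(zip(rec1, rec2)):
        if a[0].split("/")[0].split()[0] != b[0].split("/")[0].split()[0]:
            raise ValueError(f"desynchronised mates at record index {i}")
    rng = np.random.Generator(np.random.PCG64(seed))
    total = len(rec1)
    if n is not None:
        if n > total:
            raise ValueError(f"requested {n} fragments from {total}")
        # one-pass reservoir over fragment indices
        reservoir = list(range(n))
        for i in range(n, total):
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = i
        keep = sorted(reservoir)
    else:
        if not (0.0 <= proportion <= 1.0):
            raise ValueError("proportion must be in [0, 1]")
        draws = rng.random(total)
        keep = [i for i in range(total) if draws[i] < proportion or proportion == 1.0]
    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for i in keep:
            f1.writelines(rec1[i])
            f2.writelines(rec2[i])
    return len(keep)
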