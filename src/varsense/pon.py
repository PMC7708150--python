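"""Panel-of-normals (PON) construction and membership.

Recurrent artifacts and germline leakage are flagged by aggregating call sets
from normal samples: for every normalised variant key we track how many
distinct normal samples carried it and the largest VAF observed. A variant
counts as "present in normals" when it recurs in more than ``min_samples``
normals, or appears in fewer than ``min_samples`` normals but at a VAF above
``vaf_threshold`` (defaults 2 and 0.03). The rule is applied literally, which
leaves the n == min_samples case classified as absent; both thresholds are
configurable for users who prefer inclusive semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .variants import StandardVariant, VariantKey

DEFAULT_MIN_SAMPLES = 2
DEFAULT_VAF_THRESHOLD = 0.03


@dataclass
class PanelOfNormals:
    entries: dict[VariantKey, tuple[int, float]] = field(default_factory=dict)
    n_samples_total: int = 0
    caller_id: str = ""
    min_samples: int = DEFAULT_MIN_SAMPLES
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD

    def __contains__(self, key: VariantKey) -> bool:
        return in_pon(key, self)

    def __len__(self) -> int:
        return len(self.entries)


def build_pon(
    normal_callsets: Sequence[Iterable[StandardVariant]],
    caller_id: str = "",
    min_samples: int = DEFAULT_MIN_SAMPLES,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> PanelOfNormals:
    """Aggregate normal-sample call sets into a PON.

    Each element of ``normal_callsets`` is the call set of one distinct
    normal sample; a key present several times within one sample counts once.
    Calls are used regardless of their FILTER flags.
    """
    if not normal_callsets:
        raise ValueError("build_pon requires at least one normal call set")
    entries: dict[VariantKey, tuple[int, float]] = {}
    for callset in normal_callsets:
        per_sample: dict[VariantKey, float] = {}
        for call in callset:
            vaf = call.vaf
            if math.isnan(vaf):
                vaf = 0.0
            key = call.key
            per_sample[key] = max(per_sample.get(key, 0.0), vaf)
        for key, vaf in per_sample.items():
            n, max_vaf = entries.get(key, (0, 0.0))
            entries[key] = (n + 1, max(max_vaf, vaf))
    return PanelOfNormals(
        entries=entries,
        n_samples_total=len(normal_callsets),
        caller_id=caller_id,
        min_samples=min_samples,
        vaf_threshold=vaf_threshold,
    )


def in_pon(
    key: VariantKey,
    pon: PanelOfNormals,
    min_samples: int | None = None,
    vaf_threshold: float | None = None,
) -> bool:
    """True when the key is classified as present in normals.

    Present iff seen in more than ``min_samples`` normals, or in fewer than
    ``min_samples`` normals with max VAF above ``vaf_threshold``. A key with
    exactly ``min_samples`` occurrences is absent under the literal rule.
    """
    entry = pon.entries.get(key)
    if entry is None:
        return False
    n, max_vaf = entry
    ms = pon.min_samples if min_samples is None else min_samples
    vt = pon.vaf_threshold if vaf_threshold is None else vaf_threshold
    return n > ms or (n < ms and max_vaf > vt)


def write_pon(pon: PanelOfNormals, path) -> None:
    """Persist as TSV with a JSON metadata header line."""
    meta = {
        "n_samples_total": pon.n_samples_total,
        "caller_id": pon.caller_id,
        "min_samples": pon.min_samples,
        "vaf_threshold": pon.vaf_threshold,
    }
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
         "n_normal_samples": n, "max_vaf": v}
        for k, (n, v) in sorted(pon.entries.items())
    ]
    with open(path, "w") as fh:
        fh.write("##pon=" + json.dumps(meta) + "\n")
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "n_normal_samples", "max_vaf"]
        ).to_csv(fh, sep="\t", index=False)


def read_pon(path) -> PanelOfNormals:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##pon="):
            raise ValueError(f"{path}: missing PON metadata header")
        meta = json.loads(first[len("##pon="):])
        df = pd.read_csv(fh, sep="\t")
    entries = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)):
            (int(r.n_normal_samples), float(r.max_vaf))
        for r in df.itertuples(index=False)
    }
    return PanelOfNormals(entries=entries, **meta)
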