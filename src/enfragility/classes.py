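"""Fragile / regular / stable enhancer classes from deMP density.

Enhancers holding at least one deMP are ranked by deMP density (deMP
count over total interval length); the top, middle and bottom 20% are the
fragile, regular and stable classes.  Ties are broken by enhancer id so
the partition is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd

from .core import GenomicInterval

FRAGILE = "fragile"
REGULAR = "regular"
STABLE = "stable"
UNCLASSIFIED = "unclassified"


@dataclass
class EnhancerRecord:
    interval: GenomicInterval
    demp_count: int
    class_label: str = UNCLASSIFIED

    @property
    def density(self) -> float:
        return self.demp_count / len(self.interval)

    @property
    def id(self) -> str:
        return self.interval.id or f"{self.interval.chrom}:{self.interval.start}"


def demp_density(enhancer: GenomicInterval, demps: Sequence[int]) -> float:
    """deMP positions per enhancer base (denominator = full length)."""
    if len(enhancer) == 0:
        raise ValueError("zero-length enhancer")
    inside = [p for p in demps if enhancer.start <= p < enhancer.end]
    if len(inside) != len(demps):
        raise ValueError("deMP positions outside enhancer bounds")
    return len(set(inside)) / len(enhancer)


def partition_quintiles(records: Sequence[EnhancerRecord]
                        ) -> List[EnhancerRecord]:
    """Label the top/middle/bottom 20% by density as fragile/regular/stable.

    All inputs must hold at least one deMP.  Sorting is by density
    descending, enhancer id ascending; each class has floor(0.2 n)
    members, with the middle window anchored at offset floor(0.4 n);
    everything else stays unclassified.
    """
    n = len(records)
    if n < 5:
        raise ValueError(f"need at least 5 deMP-holding enhancers, got {n}")
    if any(r.demp_count < 1 for r in records):
        raise ValueError("classification requires demp_count >= 1 for all")
    order = sorted(records, key=lambda r: (-r.density, r.id))
    size = n // 5
    for r in order:
        r.class_label = UNCLASSIFIED
    for r in order[:size]:
        r.class_label = FRAGILE
    mid0 = int(0.4 * n)
    for r in order[mid0 : mid0 + size]:
        r.class_label = REGULAR
    for r in order[n - size :]:
        r.class_label = STABLE
    return order


def class_summary(records: Sequence[EnhancerRecord]) -> pd.DataFrame:
    """Per-class n, mean/median density and length statistics."""
    rows = []
    for label in (FRAGILE, REGULAR, STABLE):
        sel = [r for r in records if r.class_label == label]
        if not sel:
            continue
        dens = [r.density for r in sel]
        lens = [len(r.interval) for r in sel]
        rows.append({
            "class": label,
            "n": len(sel),
            "mean_density": sum(dens) / len(sel),
            "median_density": sorted(dens)[len(sel) // 2],
            "mean_length": sum(lens) / len(sel),
        })
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[EnhancerRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "id": r.id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "demp_count": r.demp_count,
            "density": r.density,
            "class": r.class_label,
        }
        for r in records
    ])
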