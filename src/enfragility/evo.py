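"""Evolutionary constraint statistics and GWAS disease-type enrichment.

Divergence is measured as the fraction of alignable, non-repetitive
positions that differ from the outgroup; SNP density is positions
carrying a polymorphism over total positions; conserved-element overlap
is the per-enhancer fraction of non-repetitive bases covered by
conserved elements.  GWAS tag SNPs are expanded by linkage
disequilibrium (r^2 > 0.8 within 500 kb by default) and disease-type
enrichment of one enhancer class's SNPs against another's is the upper
tail of the hypergeometric distribution, reported as -log10 p in both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu

from .core import Genome, GenomicInterval, UndefinedStatisticError


@dataclass
class EvoMasks:
    """Per-base alignability and divergence indicators plus SNP positions.

    ``diverged`` is forced to be a subset of ``alignable``.
    """

    alignable: Dict[str, np.ndarray]
    diverged: Dict[str, np.ndarray]
    snp_positions: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.diverged:
            self.diverged[chrom] = self.diverged[chrom] & self.alignable[chrom]


def _repeat_mask(genome: Optional[Genome], chrom: str, n: int) -> np.ndarray:
    if genome is None:
        return np.zeros(n, dtype=bool)
    arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
    return arr >= 97


def divergence_fraction(
    intervals: Sequence[GenomicInterval],
    masks: EvoMasks,
    genome: Optional[Genome] = None,
) -> float:
    """Diverged / alignable positions over the intervals, excluding
    repeat-masked positions from both counts."""
    div = 0
    alin = 0
    for iv in intervals:
        a = masks.alignable[iv.chrom][iv.start:iv.end]
        d = masks.diverged[iv.chrom][iv.start:iv.end]
        rep = _repeat_mask(genome, iv.chrom, len(masks.alignable[iv.chrom]))[
            iv.start:iv.end]
        a = a & ~rep
        alin += int(a.sum())
        div += int((d & a).sum())
    if alin == 0:
        raise UndefinedStatisticError("no alignable positions in intervals")
    return div / alin


def snp_fraction(
    intervals: Sequence[GenomicInterval],
    snp_positions: Dict[str, np.ndarray],
) -> float:
    """Fraction of interval positions carrying a SNP."""
    total = 0
    hit = 0
    for iv in intervals:
        total += len(iv)
        snps = snp_positions.get(iv.chrom)
        if snps is None or len(snps) == 0:
            continue
        snps = np.asarray(snps)
        hit += int(((snps >= iv.start) & (snps < iv.end)).sum())
    if total == 0:
        raise UndefinedStatisticError("empty interval set")
    return hit / total


def conserved_fraction(
    enhancer: GenomicInterval,
    conserved: Sequence[GenomicInterval],
    genome: Optional[Genome] = None,
) -> float:
    """Fraction of an enhancer's non-repetitive positions covered by
    conserved elements."""
    n = len(enhancer)
    covered = np.zeros(n, dtype=bool)
    for el in conserved:
        if el.chrom != enhancer.chrom:
            continue
        s = max(el.start, enhancer.start) - enhancer.start
        e = min(el.end, enhancer.end) - enhancer.start
        if s < e:
            covered[s:e] = True
    if genome is not None:
        rep = _repeat_mask(genome, enhancer.chrom,
                           genome.length(enhancer.chrom))[
            enhancer.start:enhancer.end]
    else:
        rep = np.zeros(n, dtype=bool)
    keep = ~rep
    if keep.sum() == 0:
        raise UndefinedStatisticError("enhancer entirely repeat-masked")
    return float(covered[keep].sum() / keep.sum())


def conserved_fraction_comparison(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float, float]:
    """(median_a, median_b, rank-sum p) for two groups of per-enhancer
    conserved fractions (two-sided Mann-Whitney-Wilcoxon)."""
    stat = mannwhitneyu(group_a, group_b, alternative="two-sided")
    return (float(np.median(group_a)), float(np.median(group_b)),
            float(stat.pvalue))


def ortholog_activity_test(table: pd.DataFrame,
                           class_a: str = "stable",
                           class_b: str = "fragile") -> Dict[str, float]:
    """Active-ortholog fraction per class and the Fisher exact p-value for
    class_a vs class_b among enhancers that have an ortholog.

    ``table`` columns: id, class, has_ortholog (bool), ortholog_active
    (bool).
    """
    with_orth = table[table["has_ortholog"].astype(bool)]
    out: Dict[str, float] = {}
    counts = {}
    for cls in (class_a, class_b):
        sub = with_orth[with_orth["class"] == cls]
        if len(sub) == 0:
            raise ValueError(f"class {cls!r} has zero enhancers with orthologs")
        act = int(sub["ortholog_active"].astype(bool).sum())
        counts[cls] = (act, len(sub) - act)
        out[f"active_fraction_{cls}"] = act / len(sub)
    _, p = fisher_exact([list(counts[class_a]), list(counts[class_b])],
                        alternative="two-sided")
    out["fisher_p"] = float(p)
    return out


# ---------------------------------------------------------------------------
# LD expansion and disease-type enrichment


class LDTable:
    """Symmetric lookup of pairwise r^2 and distance between SNP ids."""

    def __init__(self, df: pd.DataFrame):
        required = {"snpA", "snpB", "r2", "dist"}
        if not required.issubset(df.columns):
            raise ValueError(f"LD table needs columns {sorted(required)}")
        if ((df["r2"] < 0) | (df["r2"] > 1)).any():
            raise ValueError("r2 outside [0, 1]")
        self.df = df
        self._partners: Dict[str, List[Tuple[str, float, float]]] = {}
        for r in df.itertuples():
            self._partners.setdefault(r.snpA, []).append(
                (r.snpB, r.r2, r.dist))
            self._partners.setdefault(r.snpB, []).append(
                (r.snpA, r.r2, r.dist))

    def partners(self, snp: str) -> List[Tuple[str, float, float]]:
        return self._partners.get(snp, [])


def ld_expand(
    tag_snps: Iterable[str],
    ld_table: LDTable,
    r2_min: float = 0.8,
    max_dist: float = 500_000,
) -> Set[str]:
    """Tags plus partners with r^2 strictly above ``r2_min`` within
    ``max_dist`` (one round, no transitive chaining)."""
    out = set(tag_snps)
    for tag in list(out):
        for partner, r2, dist in ld_table.partners(tag):
            if r2 > r2_min and dist <= max_dist:
                out.add(partner)
    return out


def hypergeom_upper_tail(universe: int, draws: int, successes: int,
                         observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeom(universe, successes, draws)."""
    return float(np.clip(hypergeom.sf(observed - 1, universe, successes,
                                      draws), 0.0, 1.0))


def disease_type_enrichment(
    snps_a: Set[str],
    snps_b: Set[str],
    disease_sets: Dict[str, Set[str]],
) -> pd.DataFrame:
    """-log10 upper-tail hypergeometric enrichment per disease type, both
    directions, over the universe snps_a | snps_b."""
    universe = snps_a | snps_b
    if not universe:
        raise ValueError("empty SNP universe")
    rows = []
    for disease, dset in sorted(disease_sets.items()):
        in_universe = dset & universe
        for name, draws in (("a_vs_b", snps_a), ("b_vs_a", snps_b)):
            obs = len(dset & draws)
            p = hypergeom_upper_tail(len(universe), len(draws),
                                     len(in_universe), obs)
            rows.append({
                "disease_type": disease,
                "direction": name,
                "universe": len(universe),
                "draws": len(draws),
                "disease_in_universe": len(in_universe),
                "observed": obs,
                "p": p,
                "neg_log10_p": float(-np.log10(p)) if 0 < p < 1 else
                (0.0 if p >= 1 else np.inf),
            })
    return pd.DataFrame(rows)
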