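"""Synthetic regulatory "world" generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
is meant to recover, on a single synthetic chromosome:

* **enhancers of two architectures** — *homotypic* enhancers carry 3-5
  copies of one pioneer-like motif (binding-site redundancy), while
  *heterotypic* enhancers carry one copy each of 3-5 distinct
  tissue-specific-like motifs (every site is a single point of failure);
* **chromatin signal tracks** elevated over planted sites, with
  overdispersed (gamma-Poisson, i.e. negative-binomial) count noise;
* **labeled training variants** — *deactivating* variants disrupt a
  planted site that has no redundant backup copy (heterotypic sites);
  *neutral* variants either disrupt a redundant (homotypic) site, whose
  loss is buffered by the remaining copies, or fall on enhancer sequence
  outside any site.  Positives and negatives share the same simulated
  minor-allele-frequency distribution and distance-to-enhancer profile;
* **an LD panel** with block structure (constant within-block r^2, zero
  across blocks) and trait-tagged SNPs grouped into disease types, with
  configurable architecture bias;
* **per-base divergence/alignability masks**, SNP positions, conserved
  elements and an ortholog activity table implementing a two-rate
  substitution model (constrained over planted sites and conserved
  elements, neutral elsewhere).

All randomness derives from one master seed through a fixed
``numpy.random.SeedSequence.spawn`` order (genome, tracks, variants, LD,
evolution), so adding one artifact never perturbs the others and
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval, SignalTrack, VariantRecord, revcomp
from .evo import EvoMasks, LDTable
from .tfbs import PSSM

_BASES = "ACGT"

HOMOTYPIC = "homotypic"
HETEROTYPIC = "heterotypic"


@dataclass(frozen=True)
class Motif:
    """A planted motif: consensus plus one controlled degenerate position."""

    name: str
    consensus: str
    group: str                      # "pioneer" or "ts"
    degenerate_pos: int = 5
    second_base: str = "C"

    def __post_init__(self) -> None:
        if set(self.consensus) - set(_BASES):
            raise ValueError("motif consensus must be uppercase ACGT")
        if not (0 <= self.degenerate_pos < len(self.consensus)):
            raise ValueError("degenerate position outside motif")
        if self.second_base == self.consensus[self.degenerate_pos]:
            raise ValueError("second-best base equals the consensus base")

    @property
    def width(self) -> int:
        return len(self.consensus)

    def to_pssm(self) -> PSSM:
        """Probability model implied by the planting rule, as a log-odds
        PSSM.  Information content varies across positions (as in real
        motifs) so the score distribution is fine-grained enough for
        false-positive-rate calibration; the degenerate position gets a
        0.60/0.30 consensus/second-best split."""
        w = self.width
        probs = np.zeros((w, 4))
        split = np.array([0.5, 0.3, 0.2])
        for i, b in enumerate(self.consensus):
            cons = 0.95 - 0.04 * (i % 4)
            bi = _BASES.index(b)
            others = [j for j in range(4) if j != bi]
            probs[i, bi] = cons
            for k in range(3):
                probs[i, others[(i + k) % 3]] = (1 - cons) * split[k]
        i = self.degenerate_pos
        probs[i] = 0.05
        probs[i, _BASES.index(self.consensus[i])] = 0.60
        probs[i, _BASES.index(self.second_base)] = 0.30
        return PSSM.from_probabilities(self.name, probs)


DEFAULT_MOTIFS: Tuple[Motif, ...] = (
    # pioneer-like motifs planted in homotypic clusters
    Motif("FOXP", "TGTTTACTCA", "pioneer", 5, "G"),
    Motif("PION2", "CATCGATTGG", "pioneer", 4, "A"),
    # tissue-specific-like motifs planted one copy each in heterotypic mixes
    Motif("NRA", "CAAAGGTCAT", "ts", 5, "T"),
    Motif("NRB", "TTGCCCTAGA", "ts", 4, "A"),
    Motif("NRC", "AGGATATCCG", "ts", 6, "C"),
    Motif("NRD", "GCTGAGTCAC", "ts", 3, "C"),
    Motif("NRE", "ACCGGAAGTG", "ts", 5, "C"),
)


@dataclass(frozen=True)
class TrackConfig:
    name: str
    effect: float = 5.0             # fold elevation of mean over sites
    background_mean: float = 5.0    # counts per bin off-site
    dispersion: float = 0.3         # NB dispersion; var = mu + disp*mu^2
    bin_size: int = 20


@dataclass(frozen=True)
class DiseaseConfig:
    name: str
    n_tags: int = 40
    biased_architecture: Optional[str] = None   # None = uniform tagging
    bias: float = 0.7


@dataclass
class WorldConfig:
    """Every knob of the synthetic world; the master seed is mandatory."""

    seed: int
    genome_length: int = 2_000_000
    chrom: str = "chr1"
    gc: float = 0.41
    repeat_fraction: float = 0.15
    repeat_mean_length: int = 300
    n_enhancers: Tuple[int, int] = (100, 100)     # (homotypic, heterotypic)
    enhancer_length: Tuple[int, int] = (250, 400)
    min_gap: int = 500
    edge_margin: int = 2_000
    motifs: Tuple[Motif, ...] = DEFAULT_MOTIFS
    homotypic_copies: Tuple[int, int] = (3, 5)
    heterotypic_distinct: Tuple[int, int] = (3, 5)
    degeneracy: float = 0.2
    tracks: Tuple[TrackConfig, ...] = (
        TrackConfig("H3K27ac", 5.0), TrackConfig("DNase", 5.0),
    )
    n_pos: int = 500
    n_neg: int = 500
    neg_site_fraction: float = 0.5     # negatives placed at redundant sites
    maf_beta: Tuple[float, float] = (0.5, 2.0)
    # LD panel; block length is scaled to the miniature genome so a block
    # holds at most one enhancer (constant within-block r^2, 0 across)
    ld_block_length: int = 5_000
    ld_r2_within: float = 0.9
    snps_per_block: int = 2
    snps_per_enhancer: int = 3
    diseases: Tuple[DiseaseConfig, ...] = (
        DiseaseConfig("cancer", 40, HOMOTYPIC, 0.7),
        DiseaseConfig("metabolic", 40, HETEROTYPIC, 0.7),
        DiseaseConfig("other", 40, None, 0.0),
    )
    # evolution
    neutral_div_rate: float = 0.01
    constrained_div_rate: float = 0.002
    alignable_fraction: float = 0.9
    conserved_prob: Dict[str, float] = field(
        default_factory=lambda: {HOMOTYPIC: 0.6, HETEROTYPIC: 0.2})
    snp_neutral_rate: float = 0.005
    snp_constrained_rate: float = 0.001
    ortholog_prob: float = 0.5
    ortholog_active_prob: Dict[str, float] = field(
        default_factory=lambda: {HOMOTYPIC: 0.7, HETEROTYPIC: 0.3})

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        max_motif = max(m.width for m in self.motifs)
        max_sites = max(self.homotypic_copies[1], self.heterotypic_distinct[1])
        if self.enhancer_length[0] < max_motif * max_sites:
            raise ValueError(
                "enhancers too short to hold the maximum planted site load"
            )
        n_total = sum(self.n_enhancers)
        need = (n_total * (self.enhancer_length[1] + self.min_gap)
                + 2 * self.edge_margin)
        if need > self.genome_length:
            raise ValueError(
                f"infeasible geometry: {n_total} enhancers need ~{need} bp "
                f"but the genome is {self.genome_length} bp"
            )

    def pioneer_motifs(self) -> List[Motif]:
        return [m for m in self.motifs if m.group == "pioneer"]

    def ts_motifs(self) -> List[Motif]:
        return [m for m in self.motifs if m.group == "ts"]


@dataclass
class PlantedSite:
    site_id: str
    enhancer_id: str
    tf: str
    interval: GenomicInterval       # strand records planting orientation
    planted_seq: str                # as written on the + strand of the genome


@dataclass
class TruthTable:
    """Ground truth: architectures, planted sites, and variant labels."""

    architecture: Dict[str, str]                 # enhancer id -> label
    sites: List[PlantedSite]
    variant_labels: Optional[pd.DataFrame] = None

    def sites_of(self, enhancer_id: str) -> List[PlantedSite]:
        return [s for s in self.sites if s.enhancer_id == enhancer_id]

    def site_intervals(self) -> List[GenomicInterval]:
        return [s.interval for s in self.sites]


@dataclass
class World:
    config: WorldConfig
    genome: Genome
    enhancers: List[GenomicInterval]
    truth: TruthTable
    tracks: List[SignalTrack]
    variants: pd.DataFrame                       # labeled training variants
    ld_table: LDTable
    snp_positions_df: pd.DataFrame               # panel SNPs (id, pos, block)
    traits: pd.DataFrame
    evo_masks: EvoMasks
    conserved: List[GenomicInterval]
    orthologs: pd.DataFrame

    def enhancers_by_architecture(self, label: str) -> List[GenomicInterval]:
        return [e for e in self.enhancers
                if self.truth.architecture[e.id] == label]


# ---------------------------------------------------------------------------
# genome + enhancers + planted sites


def _place_enhancers(cfg: WorldConfig, rng: np.random.Generator
                     ) -> List[GenomicInterval]:
    n_total = sum(cfg.n_enhancers)
    placed: List[Tuple[int, int]] = []
    lo = cfg.edge_margin
    hi = cfg.genome_length - cfg.edge_margin
    tries = 0
    while len(placed) < n_total:
        tries += 1
        if tries > 200 * n_total:
            raise ValueError("could not place all enhancers: genome too dense")
        length = int(rng.integers(cfg.enhancer_length[0],
                                  cfg.enhancer_length[1] + 1))
        start = int(rng.integers(lo, hi - length))
        end = start + length
        ok = all(end + cfg.min_gap <= s or e + cfg.min_gap <= start
                 for s, e in placed)
        if ok:
            placed.append((start, end))
    placed.sort()
    return [GenomicInterval(cfg.chrom, s, e, id=f"enh{i:04d}")
            for i, (s, e) in enumerate(placed)]


def _plant_sites(
    cfg: WorldConfig,
    seq: np.ndarray,
    enhancers: Sequence[GenomicInterval],
    arch: Dict[str, str],
    rng: np.random.Generator,
) -> List[PlantedSite]:
    sites: List[PlantedSite] = []
    motif_by_name = {m.name: m for m in cfg.motifs}
    for enh in enhancers:
        label = arch[enh.id]
        if label == HOMOTYPIC:
            motif = cfg.pioneer_motifs()[
                int(rng.integers(0, len(cfg.pioneer_motifs())))]
            n_sites = int(rng.integers(cfg.homotypic_copies[0],
                                       cfg.homotypic_copies[1] + 1))
            chosen = [motif] * n_sites
        else:
            ts = cfg.ts_motifs()
            n_sites = int(rng.integers(cfg.heterotypic_distinct[0],
                                       cfg.heterotypic_distinct[1] + 1))
            idx = rng.choice(len(ts), size=n_sites, replace=False)
            chosen = [ts[i] for i in idx]
        # non-overlapping offsets inside the enhancer
        offsets: List[Tuple[int, int]] = []
        for motif in chosen:
            w = motif.width
            for _ in range(1000):
                off = int(rng.integers(0, len(enh) - w + 1))
                if all(off + w + 1 <= o or oe + 1 <= off
                       for o, oe in offsets):
                    offsets.append((off, off + w))
                    break
            else:
                raise ValueError("could not place sites inside an enhancer")
        for motif, (off, off_end) in zip(chosen, offsets):
            planted = list(motif.consensus)
            if rng.random() < cfg.degeneracy:
                planted[motif.degenerate_pos] = motif.second_base
            strand = "+" if rng.random() < 0.5 else "-"
            planted_str = "".join(planted)
            genome_str = planted_str if strand == "+" else revcomp(planted_str)
            start = enh.start + off
            seq[start:start + motif.width] = np.frombuffer(
                genome_str.encode("ascii"), dtype=np.uint8)
            sites.append(PlantedSite(
                site_id=f"{enh.id}_s{len(sites)}",
                enhancer_id=enh.id,
                tf=motif.name,
                interval=GenomicInterval(cfg.chrom, start,
                                         start + motif.width, strand),
                planted_seq=genome_str,
            ))
    return sites


def _mask_repeats(
    cfg: WorldConfig,
    seq: np.ndarray,
    enhancers: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> None:
    """Lowercase random runs outside enhancers until the target repeat
    fraction is reached (planted sites are inside enhancers, so repeats
    never touch them)."""
    target = int(cfg.repeat_fraction * cfg.genome_length)
    blocked = np.zeros(cfg.genome_length, dtype=bool)
    for enh in enhancers:
        blocked[max(0, enh.start - 50):enh.end + 50] = True
    masked = 0
    tries = 0
    while masked < target and tries < 100_000:
        tries += 1
        run = int(rng.geometric(1.0 / cfg.repeat_mean_length))
        run = max(20, min(run, 5 * cfg.repeat_mean_length))
        start = int(rng.integers(0, cfg.genome_length - run))
        window = slice(start, start + run)
        if blocked[window].any():
            continue
        seq[window] = seq[window] + 32          # ASCII uppercase -> lowercase
        blocked[window] = True
        masked += run


def generate_genome(cfg: WorldConfig, seed_seq: np.random.SeedSequence
                    ) -> Tuple[Genome, List[GenomicInterval],
                               Dict[str, str], List[PlantedSite]]:
    rng = np.random.default_rng(seed_seq)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                       size=cfg.genome_length, p=p)
    enhancers = _place_enhancers(cfg, rng)
    labels = ([HOMOTYPIC] * cfg.n_enhancers[0]
              + [HETEROTYPIC] * cfg.n_enhancers[1])
    perm = rng.permutation(len(labels))
    arch = {enh.id: labels[perm[i]] for i, enh in enumerate(enhancers)}
    sites = _plant_sites(cfg, codes, enhancers, arch, rng)
    _mask_repeats(cfg, codes, enhancers, rng)
    genome = Genome([(cfg.chrom, codes.tobytes().decode("ascii"))])
    return genome, enhancers, arch, sites


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(
    cfg: WorldConfig,
    truth: TruthTable,
    seed_seq: np.random.SeedSequence,
) -> List[SignalTrack]:
    """Negative-binomial (gamma-Poisson) coverage per bin, elevated by each
    track's fold effect over bins overlapping planted sites."""
    rng = np.random.default_rng(seed_seq)
    tracks = []
    for tc in cfg.tracks:
        n_bins = cfg.genome_length // tc.bin_size
        mu = np.full(n_bins, tc.background_mean)
        for s in truth.sites:
            b0 = s.interval.start // tc.bin_size
            b1 = (s.interval.end - 1) // tc.bin_size
            mu[b0:b1 + 1] = tc.background_mean * tc.effect
        if tc.dispersion > 0:
            lam = rng.gamma(shape=1.0 / tc.dispersion,
                            scale=mu * tc.dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(float)
        starts = np.arange(n_bins) * tc.bin_size
        df = pd.DataFrame({
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + tc.bin_size,
            "value": counts,
        })
        tracks.append(SignalTrack(tc.name, df))
    return tracks


# ---------------------------------------------------------------------------
# training variants


def _disrupting_base(motif: Motif, offset: int, ref: str,
                     rng: np.random.Generator) -> str:
    """A base that breaks the consensus (never the tolerated second base)."""
    avoid = {ref, motif.consensus[offset]}
    if offset == motif.degenerate_pos:
        avoid.add(motif.second_base)
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def simulate_training_variants(
    cfg: WorldConfig,
    genome: Genome,
    truth: TruthTable,
    enhancers: Sequence[GenomicInterval],
    seed_seq: np.random.SeedSequence,
    n_pos: Optional[int] = None,
    n_neg: Optional[int] = None,
) -> pd.DataFrame:
    """Labeled training variants.

    Positives disrupt a heterotypic (non-redundant) planted site; negatives
    are split between disruptions of homotypic (redundant) sites and
    enhancer positions outside any site.  Both classes draw MAF from the
    same Beta distribution and lie inside enhancers (distance 0), so the
    matched covariates have identical distributions by construction.
    """
    rng = np.random.default_rng(seed_seq)
    n_pos = cfg.n_pos if n_pos is None else n_pos
    n_neg = cfg.n_neg if n_neg is None else n_neg
    motif_by_name = {m.name: m for m in cfg.motifs}

    het_sites = [s for s in truth.sites
                 if truth.architecture[s.enhancer_id] == HETEROTYPIC]
    homo_sites = [s for s in truth.sites
                  if truth.architecture[s.enhancer_id] == HOMOTYPIC]
    het_positions = [(s, off) for s in het_sites
                     for off in range(len(s.interval))]
    if n_pos > len(het_positions):
        raise ValueError(
            f"n_pos={n_pos} exceeds the {len(het_positions)} mutable "
            "non-redundant site bases"
        )

    site_arrays = {}
    for enh in enhancers:
        mask = np.zeros(len(enh), dtype=bool)
        for s in truth.sites_of(enh.id):
            mask[s.interval.start - enh.start:s.interval.end - enh.start] = True
        site_arrays[enh.id] = mask

    def _site_variant(site: PlantedSite, genome_off: int) -> Tuple[str, str]:
        motif = motif_by_name[site.tf]
        pos = site.interval.start + genome_off
        ref = genome[cfg.chrom][pos].upper()
        # offset in motif coordinates depends on planting strand
        if site.interval.strand == "-":
            m_off = site.interval.end - 1 - pos
            comp = dict(zip("ACGT", "TGCA"))
            alt_m = _disrupting_base(motif, m_off, comp[ref], rng)
            alt = comp[alt_m]
        else:
            m_off = pos - site.interval.start
            alt = _disrupting_base(motif, m_off, ref, rng)
        return ref, alt

    rows = []
    chosen = rng.choice(len(het_positions), size=n_pos, replace=False)
    for i in chosen:
        site, off = het_positions[int(i)]
        pos = site.interval.start + off
        ref, alt = _site_variant(site, off)
        rows.append((cfg.chrom, pos, ref, alt, "deactivating", site.site_id))

    n_neg_site = int(round(cfg.neg_site_fraction * n_neg))
    homo_positions = [(s, off) for s in homo_sites
                      for off in range(len(s.interval))]
    for _ in range(n_neg_site):
        site, off = homo_positions[int(rng.integers(0, len(homo_positions)))]
        pos = site.interval.start + off
        ref, alt = _site_variant(site, off)
        rows.append((cfg.chrom, pos, ref, alt, "neutral", site.site_id))
    for _ in range(n_neg - n_neg_site):
        enh = enhancers[int(rng.integers(0, len(enhancers)))]
        mask = site_arrays[enh.id]
        free = np.flatnonzero(~mask)
        off = int(free[rng.integers(0, len(free))])
        pos = enh.start + off
        ref = genome[cfg.chrom][pos].upper()
        choices = [b for b in _BASES if b != ref]
        alt = choices[int(rng.integers(0, len(choices)))]
        rows.append((cfg.chrom, pos, ref, alt, "neutral", ""))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "label", "site_id"])
    a, b = cfg.maf_beta
    df["maf"] = rng.beta(a, b, size=len(df)) * 0.5
    starts = np.array([e.start for e in enhancers])
    ends = np.array([e.end for e in enhancers])
    dist = []
    for pos in df["pos"]:
        inside = (starts <= pos) & (pos < ends)
        d = 0 if inside.any() else int(
            np.minimum(np.abs(starts - pos), np.abs(pos - ends + 1)).min())
        dist.append(d)
    df["dist_to_enhancer"] = dist
    return df


# ---------------------------------------------------------------------------
# LD panel


def simulate_ld_panel(
    cfg: WorldConfig,
    enhancers: Sequence[GenomicInterval],
    arch: Dict[str, str],
    seed_seq: np.random.SeedSequence,
) -> Tuple[LDTable, pd.DataFrame, pd.DataFrame]:
    """Block-structured LD panel plus trait-tagged SNPs.

    Within a block every pair has the configured r^2; across blocks no
    pair is recorded (r^2 = 0).  Returns (ld_table, snps, traits).
    """
    rng = np.random.default_rng(seed_seq)
    positions = []
    n_blocks = cfg.genome_length // cfg.ld_block_length
    for b in range(n_blocks):
        lo = b * cfg.ld_block_length
        hi = min(lo + cfg.ld_block_length, cfg.genome_length)
        positions.extend(
            int(x) for x in rng.integers(lo, hi, size=cfg.snps_per_block))
    for enh in enhancers:
        positions.extend(
            int(x) for x in
            rng.integers(enh.start, enh.end, size=cfg.snps_per_enhancer))
    positions = sorted(set(positions))
    snps = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(len(positions))],
        "chrom": cfg.chrom,
        "pos": positions,
    })
    snps["block"] = snps["pos"] // cfg.ld_block_length

    pairs = []
    for _, grp in snps.groupby("block"):
        ids = grp["snp"].tolist()
        pos = grp["pos"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j], cfg.ld_r2_within,
                              abs(pos[j] - pos[i])))
    ld = LDTable(pd.DataFrame(pairs, columns=["snpA", "snpB", "r2", "dist"]))

    # trait tagging with optional architecture bias
    pos_arr = snps["pos"].to_numpy()
    in_arch: Dict[str, np.ndarray] = {}
    for label in (HOMOTYPIC, HETEROTYPIC):
        mask = np.zeros(len(snps), dtype=bool)
        for enh in enhancers:
            if arch[enh.id] == label:
                mask |= (pos_arr >= enh.start) & (pos_arr < enh.end)
        in_arch[label] = mask
    trait_rows = []
    for dc in cfg.diseases:
        for t in range(dc.n_tags):
            if (dc.biased_architecture is not None
                    and rng.random() < dc.bias
                    and in_arch[dc.biased_architecture].any()):
                pool = np.flatnonzero(in_arch[dc.biased_architecture])
            else:
                pool = np.arange(len(snps))
            i = int(pool[rng.integers(0, len(pool))])
            trait_rows.append((snps["snp"].iat[i],
                               f"{dc.name}_trait{t}", dc.name))
    traits = pd.DataFrame(trait_rows, columns=["snp", "trait", "disease_type"])
    return ld, snps, traits


# ---------------------------------------------------------------------------
# evolution


def simulate_evolution(
    cfg: WorldConfig,
    genome: Genome,
    truth: TruthTable,
    enhancers: Sequence[GenomicInterval],
    seed_seq: np.random.SeedSequence,
) -> Tuple[EvoMasks, List[GenomicInterval], pd.DataFrame]:
    """Two-rate substitution model: low rate over planted sites and
    conserved elements, neutral rate elsewhere; iid alignability; SNPs
    with the same two-rate structure; ortholog activity biased toward
    homotypic-architecture enhancers."""
    rng = np.random.default_rng(seed_seq)
    L = cfg.genome_length
    constrained = np.zeros(L, dtype=bool)
    for s in truth.sites:
        constrained[s.interval.start:s.interval.end] = True
    conserved: List[GenomicInterval] = []
    for enh in enhancers:
        label = truth.architecture[enh.id]
        if rng.random() < cfg.conserved_prob[label]:
            conserved.append(GenomicInterval(cfg.chrom, enh.start, enh.end,
                                             id=f"ce_{enh.id}"))
            constrained[enh.start:enh.end] = True
    rate = np.where(constrained, cfg.constrained_div_rate,
                    cfg.neutral_div_rate)
    diverged = rng.random(L) < rate
    alignable = rng.random(L) < cfg.alignable_fraction
    snp_rate = np.where(constrained, cfg.snp_constrained_rate,
                        cfg.snp_neutral_rate)
    snp_pos = np.flatnonzero(rng.random(L) < snp_rate)
    masks = EvoMasks(
        alignable={cfg.chrom: alignable},
        diverged={cfg.chrom: diverged},
        snp_positions={cfg.chrom: snp_pos},
    )
    rows = []
    for enh in enhancers:
        label = truth.architecture[enh.id]
        has = rng.random() < cfg.ortholog_prob
        active = bool(has and rng.random() < cfg.ortholog_active_prob[label])
        rows.append((enh.id, label, has, active))
    orthologs = pd.DataFrame(
        rows, columns=["id", "architecture", "has_ortholog",
                       "ortholog_active"])
    return masks, conserved, orthologs


# ---------------------------------------------------------------------------
# the full world


def generate_world(cfg: WorldConfig) -> World:
    """Generate every artifact of the synthetic world deterministically.

    Sub-seeds are spawned from the master seed in a fixed order (genome,
    tracks, variants, LD, evolution), so regenerating with the same config
    reproduces every artifact byte-identically.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_genome, s_tracks, s_vars, s_ld, s_evo = ss.spawn(5)
    genome, enhancers, arch, sites = generate_genome(cfg, s_genome)
    truth = TruthTable(architecture=arch, sites=sites)
    tracks = simulate_tracks(cfg, truth, s_tracks)
    variants = simulate_training_variants(
        cfg, genome, truth, enhancers, s_vars)
    truth.variant_labels = variants
    ld, snps, traits = simulate_ld_panel(cfg, enhancers, arch, s_ld)
    masks, conserved, orthologs = simulate_evolution(
        cfg, genome, truth, enhancers, s_evo)
    return World(
        config=cfg, genome=genome, enhancers=enhancers, truth=truth,
        tracks=tracks, variants=variants, ld_table=ld,
        snp_positions_df=snps, traits=traits, evo_masks=masks,
        conserved=conserved, orthologs=orthologs,
    )


def write_world(world: World, outdir) -> None:
    """Emit the world's plain-text artifacts (masks written sparsely:
    only diverged / non-alignable positions are listed)."""
    from . import io as eio
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(world.genome, outdir / "genome.fa")
    with open(outdir / "enhancers.bed", "w") as fh:
        for enh in world.enhancers:
            fh.write(f"{enh.chrom}\t{enh.start}\t{enh.end}\t{enh.id}\t"
                     f"{world.truth.architecture[enh.id]}\n")
    (outdir / "tracks").mkdir(exist_ok=True)
    for tr in world.tracks:
        eio.write_bedgraph(tr, outdir / "tracks" / f"{tr.name}.bedgraph")
    variants = [VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
                for r in world.variants.itertuples()]
    eio.write_vcf_lite(variants, outdir / "variants.vcf")
    world.variants.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    world.ld_table.df.to_csv(outdir / "ld.tsv", sep="\t", index=False)
    world.traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
    chrom = world.config.chrom
    div = np.flatnonzero(world.evo_masks.diverged[chrom])
    pd.DataFrame({"chrom": chrom, "pos": div, "flag": 1}).to_csv(
        outdir / "divergence.tsv", sep="\t", index=False)
    unaln = np.flatnonzero(~world.evo_masks.alignable[chrom])
    pd.DataFrame({"chrom": chrom, "pos": unaln, "flag": 0}).to_csv(
        outdir / "align.tsv", sep="\t", index=False)
    eio.write_bed(world.conserved, outdir / "conserved.bed")
    world.orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    manifest = {
        "seed": world.config.seed,
        "genome_length": world.config.genome_length,
        "n_enhancers": list(world.config.n_enhancers),
        "n_sites": len(world.truth.sites),
        "n_variants": len(world.variants),
    }
    with open(outdir / "world.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
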