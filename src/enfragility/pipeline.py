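"""End-to-end orchestration: simulate -> controls -> vocab -> score ->
classify -> tfbs -> evo -> gwas, with one config and full determinism.

Every stage runs from one :class:`RunConfig`; the numeric defaults are
the method's design constants (Fisher alpha 1e-3 with Bonferroni
correction, deM FPR 0.01, control tolerances GC 0.005 / repeat 0.01,
PSSM false-positive rate 5 per 10 kb, cluster rule >= 3 sites within
1 kb, LD expansion r^2 > 0.8 within 500 kb).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from . import io as eio
from .classes import (EnhancerRecord, FRAGILE, STABLE, class_summary,
                      partition_quintiles, records_to_frame)
from .controls import ControlSet, sample_control_set
from .core import Genome, GenomicInterval, VariantRecord
from .evo import (conserved_fraction, disease_type_enrichment,
                  divergence_fraction, ld_expand, ortholog_activity_test,
                  snp_fraction)
from .kmers import build_vocabularies
from .scoring import (DeMCall, EnhancerScorer, FeatureSchema, WeightSet,
                      calibrate_fpr_threshold, call_demps, fit_weights,
                      score_and_decompose)
from .synth import (HETEROTYPIC, HOMOTYPIC, World, WorldConfig,
                    generate_world, simulate_training_variants, write_world)
from .tfbs import (PSSM, TFBSHit, calibrate_pssm_threshold, cluster_flags,
                   find_clusters, fraction_sites_with_demp,
                   nonrepetitive_length, scan_pssm, tfbs_enrichment)

ALL_STAGES = ("simulate", "controls", "vocab", "score", "classify",
              "tfbs", "evo", "gwas")


@dataclass
class RunConfig:
    """One config for the whole pipeline; defaults are the design values."""

    world: WorldConfig
    seed: int = 0                      # pipeline seed (controls, CV, calib.)
    stages: Tuple[str, ...] = ALL_STAGES
    n_controls: int = 5
    max_dgc: float = 0.005
    max_drepeat: float = 0.01
    alpha: float = 1e-3
    k_sizes: Tuple[int, ...] = (4, 6, 8, 10, 12)
    peak_quantile: float = 0.8
    flank_window: int = 100
    fpr: float = 0.01
    n_calibration_negatives: int = 2_000
    pssm_target_rate: float = 5.0      # hits per 10 kb
    pssm_background_length: int = 100_000
    min_sites: int = 3
    max_span: int = 1_000
    r2_min: float = 0.8
    max_dist: int = 500_000
    write_world_files: bool = False


@dataclass
class PipelineResult:
    config: RunConfig
    world: World
    controls: Optional[ControlSet] = None
    vocabularies: Optional[dict] = None
    schema: Optional[FeatureSchema] = None
    weights: Optional[WeightSet] = None
    cv_report: Optional[dict] = None
    threshold: Optional[float] = None
    demps: Dict[str, List[int]] = field(default_factory=dict)
    calls: Dict[str, List[DeMCall]] = field(default_factory=dict)
    enhancer_records: List[EnhancerRecord] = field(default_factory=list)
    classes_df: Optional[pd.DataFrame] = None
    hits: Dict[str, List[TFBSHit]] = field(default_factory=dict)
    control_hits: Dict[str, int] = field(default_factory=dict)
    cluster_df: Optional[pd.DataFrame] = None
    enrichment_df: Optional[pd.DataFrame] = None
    evo_report: Optional[pd.DataFrame] = None
    gwas_df: Optional[pd.DataFrame] = None
    summary: Dict[str, float] = field(default_factory=dict)

    def class_of(self, enhancer_id: str) -> str:
        for r in self.enhancer_records:
            if r.id == enhancer_id:
                return r.class_label
        return "unclassified"

    def density_by_architecture(self) -> Dict[str, List[float]]:
        out: Dict[str, List[float]] = {HOMOTYPIC: [], HETEROTYPIC: []}
        for enh in self.world.enhancers:
            dens = len(self.demps.get(enh.id, [])) / len(enh)
            out[self.world.truth.architecture[enh.id]].append(dens)
        return out


def _find_enhancer(enhancers: Sequence[GenomicInterval], pos: int
                   ) -> Optional[GenomicInterval]:
    for enh in enhancers:
        if enh.start <= pos < enh.end:
            return enh
    return None


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Run the enabled stages in dependency order; optionally write the
    stage outputs and a manifest under ``outdir``."""
    ss = np.random.SeedSequence(config.seed)
    (s_controls, s_fit, s_calib, s_bg) = ss.spawn(4)
    stages = set(config.stages)

    world = generate_world(config.world)
    result = PipelineResult(config=config, world=world)
    genome = world.genome
    enhancers = world.enhancers
    chrom = config.world.chrom

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if config.write_world_files:
            write_world(world, outdir / "world")

    # ---- controls ----------------------------------------------------
    if "controls" in stages:
        result.controls = sample_control_set(
            genome, enhancers, n=config.n_controls,
            max_dgc=config.max_dgc, max_drepeat=config.max_drepeat,
            seed=int(s_controls.generate_state(1)[0] % (2**31)),
        )
        if outdir is not None:
            _write_controls(result.controls, outdir)

    # ---- vocabularies ------------------------------------------------
    if "vocab" in stages:
        result.vocabularies = build_vocabularies(
            genome, enhancers, result.controls.sequences, world.tracks,
            k_sizes=config.k_sizes, alpha=config.alpha,
            peak_quantile=config.peak_quantile,
        )
        if outdir is not None:
            rows = [
                {"k": k, "track": tr, "n_top": v.n_top,
                 "enh_windows": v.enh_total, "ctrl_windows": v.ctrl_total}
                for (k, tr), v in sorted(result.vocabularies.items())
            ]
            pd.DataFrame(rows).to_csv(outdir / "vocab_summary.tsv",
                                      sep="\t", index=False)

    # ---- scoring -----------------------------------------------------
    if "score" in stages:
        track_names = tuple(t.name for t in world.tracks)
        schema = FeatureSchema(tracks=track_names,
                               k_sizes=config.k_sizes,
                               flank_window=config.flank_window)
        result.schema = schema
        scorers = {
            enh.id: EnhancerScorer(
                genome.fetch(GenomicInterval(chrom, enh.start, enh.end)),
                result.vocabularies, schema, chrom=chrom, offset=enh.start)
            for enh in enhancers
        }
        # training features
        X, y = _training_matrix(world.variants, enhancers, scorers, schema)
        weights, report = fit_weights(
            X, y, schema, seed=int(s_fit.generate_state(1)[0] % (2**31)))
        result.weights, result.cv_report = weights, report
        # FPR calibration on fresh negatives from the same generator
        calib = simulate_training_variants(
            config.world, genome, world.truth, enhancers, s_calib,
            n_pos=0, n_neg=config.n_calibration_negatives)
        Xc, _ = _training_matrix(calib, enhancers, scorers, schema)
        neg_scores = [score_and_decompose(fv, weights).score for fv in Xc]
        result.threshold = calibrate_fpr_threshold(neg_scores, config.fpr)
        # call deMs / deMPs
        vocab_k8 = result.vocabularies[(8, "pooled")]
        for enh in enhancers:
            demps, calls = call_demps(
                scorers[enh.id], vocab_k8, weights, result.threshold)
            result.demps[enh.id] = demps
            result.calls[enh.id] = calls
        if outdir is not None:
            weights.save_tsv(outdir / "weights.tsv")
            _write_calls(result, outdir)

    # ---- classification ----------------------------------------------
    if "classify" in stages:
        records = [EnhancerRecord(enh, len(result.demps.get(enh.id, [])))
                   for enh in enhancers]
        with_demp = [r for r in records if r.demp_count >= 1]
        partition_quintiles(with_demp)
        result.enhancer_records = records
        result.classes_df = records_to_frame(records)
        if outdir is not None:
            result.classes_df.to_csv(outdir / "classes.tsv", sep="\t",
                                     index=False)

    # ---- TFBS analysis -----------------------------------------------
    if "tfbs" in stages:
        _tfbs_stage(config, result, s_bg)
        if outdir is not None:
            result.enrichment_df.to_csv(outdir / "enrichment.tsv", sep="\t",
                                        index=False)
            result.cluster_df.to_csv(outdir / "clusters.tsv", sep="\t",
                                     index=False)

    # ---- evolutionary constraint --------------------------------------
    if "evo" in stages:
        result.evo_report = _evo_stage(result)
        if outdir is not None:
            result.evo_report.to_csv(outdir / "evo_report.tsv", sep="\t",
                                     index=False)

    # ---- GWAS disease-type enrichment ---------------------------------
    if "gwas" in stages:
        result.gwas_df = _gwas_stage(config, result)
        if outdir is not None:
            result.gwas_df.to_csv(outdir / "gwas_enrichment.tsv", sep="\t",
                                  index=False)

    result.summary = _summarize(result)
    if outdir is not None:
        write_report(result, outdir)
    return result


def _training_matrix(variants: pd.DataFrame,
                     enhancers: Sequence[GenomicInterval],
                     scorers: Dict[str, EnhancerScorer],
                     schema: FeatureSchema) -> Tuple[np.ndarray, np.ndarray]:
    X = np.zeros((len(variants), schema.n_features))
    y = np.zeros(len(variants), dtype=int)
    for i, row in enumerate(variants.itertuples()):
        enh = _find_enhancer(enhancers, int(row.pos))
        if enh is None:
            continue
        v = VariantRecord(row.chrom, int(row.pos), row.ref, row.alt)
        X[i] = scorers[enh.id].features(v)
        y[i] = 1 if row.label == "deactivating" else 0
    return X, y


def _tfbs_stage(config: RunConfig, result: PipelineResult,
                seed_seq: np.random.SeedSequence) -> None:
    world = result.world
    cfg = config.world
    rng = np.random.default_rng(seed_seq)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    bg = "".join(rng.choice(list("ACGT"),
                            size=config.pssm_background_length, p=p))
    pssms = []
    for motif in cfg.motifs:
        pssm = motif.to_pssm()
        pssm.threshold = calibrate_pssm_threshold(
            pssm, bg, target_rate=config.pssm_target_rate)
        pssms.append(pssm)

    chrom = cfg.chrom
    all_demps = sorted({p for ps in result.demps.values() for p in ps})
    enh_hits: Dict[str, List[TFBSHit]] = {}
    for enh in world.enhancers:
        seq = world.genome[chrom][enh.start:enh.end]
        hits: List[TFBSHit] = []
        for pssm in pssms:
            hits.extend(scan_pssm(seq, pssm, chrom=chrom, offset=enh.start))
        enh_hits[enh.id] = hits
    result.hits = enh_hits

    ctrl_hit_counts: Dict[str, int] = {m.name: 0 for m in cfg.motifs}
    ctrl_nonrep = 0
    if result.controls is not None:
        for rec in result.controls.records:
            ctrl_nonrep += sum(1 for c in rec.seq if not c.islower())
            for pssm in pssms:
                ctrl_hit_counts[pssm.tf] += len(scan_pssm(rec.seq, pssm))
    result.control_hits = ctrl_hit_counts

    # per-class enrichment, deMP fragility of sites, cluster typing
    classes = {r.id: r.class_label for r in result.enhancer_records}
    rows = []
    for label in (FRAGILE, "regular", STABLE):
        sel = [e for e in world.enhancers if classes.get(e.id) == label]
        if not sel:
            continue
        nonrep = nonrepetitive_length(world.genome, sel)
        # class-specific control length: share the pooled control set
        for pssm in pssms:
            n_enh = sum(
                1 for e in sel for h in enh_hits[e.id] if h.tf == pssm.tf)
            enr = tfbs_enrichment(n_enh, ctrl_hit_counts[pssm.tf],
                                  nonrep, max(ctrl_nonrep, 1))
            class_hits = [h for e in sel for h in enh_hits[e.id]
                          if h.tf == pssm.tf]
            frac = fraction_sites_with_demp(class_hits, all_demps)
            rows.append({"class": label, "tf": pssm.tf, "n_hits": n_enh,
                         "enrichment": enr, "fraction_sites_with_demp": frac})
    result.enrichment_df = pd.DataFrame(rows)

    crows = []
    for enh in world.enhancers:
        clusters = find_clusters(enh_hits[enh.id],
                                 min_sites=config.min_sites,
                                 max_span=config.max_span)
        has_homo, has_het = cluster_flags(clusters)
        crows.append({
            "id": enh.id,
            "architecture": world.truth.architecture[enh.id],
            "class": classes.get(enh.id, "unclassified"),
            "n_hits": len(enh_hits[enh.id]),
            "n_clusters": len(clusters),
            "has_homotypic": has_homo,
            "has_heterotypic": has_het,
        })
    result.cluster_df = pd.DataFrame(crows)


def _evo_stage(result: PipelineResult) -> pd.DataFrame:
    world = result.world
    genome = world.genome
    masks = world.evo_masks
    classes = {r.id: r.class_label for r in result.enhancer_records}
    rows = []
    for enh in world.enhancers:
        try:
            div = divergence_fraction([enh], masks, genome)
        except Exception:
            div = np.nan
        snp = snp_fraction([enh], masks.snp_positions)
        cons = conserved_fraction(enh, world.conserved, genome)
        rows.append({
            "id": enh.id,
            "architecture": world.truth.architecture[enh.id],
            "class": classes.get(enh.id, "unclassified"),
            "divergence": div,
            "snp_fraction": snp,
            "conserved_fraction": cons,
        })
    return pd.DataFrame(rows)


def _gwas_stage(config: RunConfig, result: PipelineResult) -> pd.DataFrame:
    world = result.world
    snps = world.snp_positions_df
    classes = {r.id: r.class_label for r in result.enhancer_records}

    def class_snps(label: str) -> set:
        out = set()
        pos = snps["pos"].to_numpy()
        for enh in world.enhancers:
            if classes.get(enh.id) != label:
                continue
            sel = (pos >= enh.start) & (pos < enh.end)
            out.update(snps["snp"][sel])
        return out

    tagged = set(world.traits["snp"])
    stable_tags = class_snps(STABLE) & tagged
    fragile_tags = class_snps(FRAGILE) & tagged
    stable_exp = ld_expand(stable_tags, world.ld_table,
                           config.r2_min, config.max_dist)
    fragile_exp = ld_expand(fragile_tags, world.ld_table,
                            config.r2_min, config.max_dist)
    disease_sets = {}
    for disease, grp in world.traits.groupby("disease_type"):
        disease_sets[disease] = ld_expand(set(grp["snp"]), world.ld_table,
                                          config.r2_min, config.max_dist)
    if not stable_exp | fragile_exp:
        return pd.DataFrame()
    df = disease_type_enrichment(stable_exp, fragile_exp, disease_sets)
    df["direction"] = df["direction"].map(
        {"a_vs_b": "stable_vs_fragile", "b_vs_a": "fragile_vs_stable"})
    return df


def _summarize(result: PipelineResult) -> Dict[str, float]:
    s: Dict[str, float] = {}
    world = result.world
    if result.enhancer_records:
        df = records_to_frame(result.enhancer_records)
        for label, grp in df.groupby("class"):
            s[f"mean_demp_density_{label}"] = float(grp["density"].mean())
        s["n_enhancers_with_demp"] = int((df["demp_count"] >= 1).sum())
        s["n_enhancers"] = len(df)
    dens = result.density_by_architecture()
    if result.demps:
        for label, vals in dens.items():
            if vals:
                s[f"median_demp_density_{label}"] = float(np.median(vals))
        if dens[HOMOTYPIC] and dens[HETEROTYPIC]:
            stat = mannwhitneyu(dens[HETEROTYPIC], dens[HOMOTYPIC],
                                alternative="greater")
            s["density_het_gt_homo_p"] = float(stat.pvalue)
    if result.cv_report:
        s["cv_auc"] = float(result.cv_report["oof_auc"])
    if result.threshold is not None:
        s["dem_threshold"] = float(result.threshold)
    if result.cluster_df is not None and len(result.cluster_df):
        for label in (HOMOTYPIC, HETEROTYPIC):
            sub = result.cluster_df[result.cluster_df["architecture"] == label]
            if len(sub):
                s[f"has_homotypic_rate_{label}"] = float(
                    sub["has_homotypic"].mean())
                s[f"has_heterotypic_rate_{label}"] = float(
                    sub["has_heterotypic"].mean())
    if result.evo_report is not None and len(result.evo_report):
        er = result.evo_report
        for label in (HOMOTYPIC, HETEROTYPIC):
            sub = er[er["architecture"] == label]
            s[f"median_divergence_{label}"] = float(
                sub["divergence"].median())
        homo = er[er["architecture"] == HOMOTYPIC]["divergence"].dropna()
        het = er[er["architecture"] == HETEROTYPIC]["divergence"].dropna()
        if len(homo) and len(het):
            stat = mannwhitneyu(homo, het, alternative="less")
            s["divergence_homo_lt_het_p"] = float(stat.pvalue)
        try:
            orth = world.orthologs.copy()
            cls = {r.id: r.class_label for r in result.enhancer_records}
            orth["class"] = orth["id"].map(cls)
            test = ortholog_activity_test(orth)
            s["ortholog_active_fraction_stable"] = test[
                "active_fraction_stable"]
            s["ortholog_active_fraction_fragile"] = test[
                "active_fraction_fragile"]
            s["ortholog_fisher_p"] = test["fisher_p"]
        except (ValueError, KeyError):
            pass
    if result.gwas_df is not None and len(result.gwas_df):
        for r in result.gwas_df.itertuples():
            s[f"gwas_{r.disease_type}_{r.direction}_neglog10p"] = float(
                r.neg_log10_p)
    return s


def _write_controls(controls: ControlSet, outdir: Path) -> None:
    sampled = [r.interval for r in controls.records if r.interval is not None]
    eio.write_bed(sampled, outdir / "controls.bed")
    with open(outdir / "controls.fa", "w") as fh:
        for i, rec in enumerate(controls.records):
            if rec.origin == "shuffled":
                fh.write(f">{rec.enhancer_id}_shuf{i} origin=shuffled\n")
                fh.write(rec.seq + "\n")


def _write_calls(result: PipelineResult, outdir: Path) -> None:
    rows = []
    for enh_id, calls in result.calls.items():
        for c in calls:
            rows.append((c.variant.chrom, c.variant.pos, c.variant.ref,
                         c.variant.alt, c.decomposition.ws_delta,
                         c.decomposition.ws_s, c.decomposition.margin,
                         c.decomposition.score, c.is_dem))
    pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "ws_delta", "ws_s", "margin",
        "score", "is_dem"]).to_csv(outdir / "dem_calls.tsv", sep="\t",
                                   index=False)
    with open(outdir / "demps.bed", "w") as fh:
        for enh_id in sorted(result.demps):
            for p in result.demps[enh_id]:
                fh.write(f"{result.world.config.chrom}\t{p}\t{p + 1}\t"
                         f"{enh_id}\n")


def write_report(result: PipelineResult, outdir) -> None:
    """Consolidated one-row-per-metric summary (TSV + JSON) and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = sorted(result.summary.items())
    pd.DataFrame(items, columns=["metric", "value"]).to_csv(
        outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(dict(items), fh, indent=2, sort_keys=True)
    digests = {}
    for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed")):
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "seed": result.config.seed,
        "world_seed": result.config.world.seed,
        "stages": list(result.config.stages),
        "thresholds": {
            "alpha": result.config.alpha,
            "fpr": result.config.fpr,
            "max_dgc": result.config.max_dgc,
            "max_drepeat": result.config.max_drepeat,
            "pssm_target_rate_per_10kb": result.config.pssm_target_rate,
            "min_sites": result.config.min_sites,
            "max_span": result.config.max_span,
            "r2_min": result.config.r2_min,
            "max_dist": result.config.max_dist,
        },
        "digests": digests,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
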