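"""Workspace orchestration: each stage reads its inputs from, and writes its
versioned outputs to, a single workspace directory, so stages can be rerun
independently and `run_all` chains them end to end.

Every stochastic stage derives its randomness from the master seed via
named substreams; reruns with the same config are byte-identical.
"""
from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd
import yaml

from . import dge as dge_mod
from . import integrate as integ
from . import io as io_mod
from . import motifs as motif_mod
from . import peaks as peak_mod
from . import simulate as sim
from .models import GenomeAnnotation, RegulonSpec

DEFAULT_CONFIG: dict = {
    "simulate": {},  # SimulationConfig field overrides
    "dge": {"alpha": 0.01, "fold_tiers": [2.0, 3.0, 10.0],
            "prior_df": 20.0, "pseudocount": 0.5},
    "promoter": {"upstream": 500, "downstream": 50},
    "peaks": {"q_threshold": 0.05, "min_overlap_frac": 0.5},
    "motifs": {"width": 14, "n_restarts": 5, "n_discovery_seqs": 100,
               "summit_flank": 100, "threshold_frac": 0.6},
    "profiles": {"min_peak_rpkm": 1.0, "min_correlation": 0.8,
                 "min_rise_fold": 4.0},
    "integration": {"expression_floor": 1.0},
    "seed": 0,
}

STAGES = ("simulate", "dge", "peaks", "motifs", "integrate", "report")


class PipelineError(RuntimeError):
    pass


def load_config(path: Optional[str] = None, seed: Optional[int] = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _require(workspace: Path, filename: str, producer: str) -> Path:
    p = workspace / filename
    if not p.exists():
        raise PipelineError(
            f"missing {filename} in {workspace}; run the '{producer}' stage first")
    return p


def _sim_config(cfg: dict) -> sim.SimulationConfig:
    kwargs = dict(cfg.get("simulate", {}))
    kwargs.setdefault("seed", cfg.get("seed", 0))
    up_down = cfg.get("promoter", {})
    if "promoter_window" not in kwargs and up_down:
        kwargs["promoter_window"] = (up_down.get("upstream", 500),
                                     up_down.get("downstream", 50))
    if "chrom_lengths" in kwargs and kwargs["chrom_lengths"] is not None:
        kwargs["chrom_lengths"] = {str(k): int(v)
                                   for k, v in kwargs["chrom_lengths"].items()}
    if "timepoints" in kwargs:
        kwargs["timepoints"] = tuple(kwargs["timepoints"])
    if "promoter_window" in kwargs:
        kwargs["promoter_window"] = tuple(kwargs["promoter_window"])
    return sim.SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(workspace: Path, cfg: dict) -> None:
    workspace.mkdir(parents=True, exist_ok=True)
    config = _sim_config(cfg)
    annotation, sequences, regulon = sim.generate_genome(config)
    io_mod.write_annotation(annotation, workspace / "annotation.gff3")
    io_mod.write_fasta(sequences, workspace / "genome.fa")
    ip_tracks, input_track = sim.simulate_chip_coverage(annotation, regulon, config)
    for i, track in enumerate(ip_tracks, 1):
        io_mod.write_bedgraph(track, workspace / f"chip_ip_rep{i}.bedgraph")
    io_mod.write_bedgraph(input_track, workspace / "chip_input.bedgraph")
    counts, meta = sim.simulate_counts(annotation, regulon, config)
    io_mod.write_tsv(counts.reset_index(), workspace / "counts.tsv")
    io_mod.write_tsv(meta, workspace / "samples.tsv")
    io_mod.write_tsv(sim.simulate_dev_profiles(annotation, regulon, config),
                     workspace / "profiles.tsv")
    io_mod.write_tsv(sim.simulate_cilia_evidence(annotation, regulon, config),
                     workspace / "cilia_evidence.tsv")
    io_mod.write_json(regulon.to_dict(), workspace / "truth.json")
    io_mod.write_json({"config": cfg, "sim_config": config.to_dict()},
                      workspace / "config_used.json")


def stage_dge(workspace: Path, cfg: dict) -> None:
    counts = io_mod.read_tsv(_require(workspace, "counts.tsv", "simulate"),
                             index_col=0)
    meta = io_mod.read_tsv(_require(workspace, "samples.tsv", "simulate"))
    annotation = io_mod.read_annotation(
        _require(workspace, "annotation.gff3", "simulate"))
    lengths = pd.Series({g.gene_id: g.exonic_length for g in annotation.genes})
    th = dge_mod.DGEThresholds(alpha=cfg["dge"]["alpha"],
                               fold_tiers=tuple(cfg["dge"]["fold_tiers"]))
    results = dge_mod.run_dge(counts, meta, gene_lengths=lengths, thresholds=th,
                              pseudocount=cfg["dge"]["pseudocount"],
                              prior_df=cfg["dge"]["prior_df"])
    sets = {age: dge_mod.call_de_sets(res, th) for age, res in results.items()}
    summary = dge_mod.de_summary(results, sets, th)
    for age, res in results.items():
        io_mod.write_tsv(res, workspace / f"dge_{age}.tsv")
        for d in ("down", "up"):
            io_mod.write_tsv(summary["curves"][age][d],
                             workspace / f"de_curve_{age}_{d}.tsv")
        io_mod.write_tsv(summary["ma_tables"][age], workspace / f"ma_{age}.tsv")
    io_mod.write_tsv(summary["scatter_table"], workspace / "de_scatter.tsv")
    io_mod.write_json({age: {name: sorted(s) for name, s in sets[age].items()}
                       for age in sets}, workspace / "de_sets.json")
    io_mod.write_json({"tier_counts": summary["tier_counts"],
                       "venn": summary["venn"]},
                      workspace / "de_summary.json")


def stage_peaks(workspace: Path, cfg: dict) -> None:
    annotation = io_mod.read_annotation(
        _require(workspace, "annotation.gff3", "simulate"))
    input_track = io_mod.read_bedgraph(
        _require(workspace, "chip_input.bedgraph", "simulate"),
        chrom_lengths=annotation.chrom_lengths)
    rep_paths = sorted(workspace.glob("chip_ip_rep*.bedgraph"))
    if not rep_paths:
        raise PipelineError("no IP coverage tracks; run the 'simulate' stage first")
    peak_sets = []
    for i, p in enumerate(rep_paths, 1):
        track = io_mod.read_bedgraph(p, chrom_lengths=annotation.chrom_lengths)
        called = peak_mod.call_peaks(track, input_track,
                                     q_threshold=cfg["peaks"]["q_threshold"])
        io_mod.write_narrowpeak(called, workspace / f"peaks_rep{i}.narrowPeak")
        peak_sets.append(called)
    reproducible = peak_mod.filter_reproducible(
        peak_sets, min_overlap_frac=cfg["peaks"]["min_overlap_frac"])
    io_mod.write_narrowpeak(reproducible, workspace / "reproducible_peaks.narrowPeak")

    up, down = cfg["promoter"]["upstream"], cfg["promoter"]["downstream"]
    annotated = peak_mod.annotate_peaks(reproducible, annotation, up, down)
    rows = [{
        "peak": a.peak.name, "chrom": a.peak.chrom, "start": a.peak.start,
        "end": a.peak.end, "peak_p": a.peak.p_value, "region": a.region,
        "gene": a.gene_id if a.gene_id else "",
        "tss_distance": a.tss_distance if a.tss_distance is not None else "",
        "ambiguous": a.ambiguous,
    } for a in annotated]
    io_mod.write_tsv(pd.DataFrame(rows), workspace / "peak_annotation.tsv")
    io_mod.write_tsv(peak_mod.rank_fraction_curve(annotated),
                     workspace / "peak_rank_fractions.tsv")
    io_mod.write_tsv(peak_mod.tss_distance_histogram(annotated),
                     workspace / "peak_tss_distances.tsv")
    targets, ambiguous = peak_mod.promoter_target_genes(annotated)
    io_mod.write_json({
        "n_peaks_per_replicate": [len(s) for s in peak_sets],
        "n_reproducible": len(reproducible),
        "region_class_counts": peak_mod.region_class_counts(annotated),
        "chip_targets": sorted(targets),
        "ambiguous_targets": sorted(ambiguous),
    }, workspace / "peak_summary.json")


def promoter_sequences(annotation: GenomeAnnotation, genome: Dict[str, str],
                       upstream: int, downstream: int) -> Dict[str, str]:
    """Transcription-oriented promoter sequences with the TSS at index
    `upstream` (reverse-complemented for minus-strand genes)."""
    out = {}
    for g in annotation.genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
            seq = genome[g.chrom][max(0, s):e]
        else:
            s, e = g.tss - downstream + 1, g.tss + upstream + 1
            seq = sim.revcomp(genome[g.chrom][max(0, s):min(e, len(genome[g.chrom]))])
        out[g.gene_id] = seq
    return out


def stage_motifs(workspace: Path, cfg: dict) -> None:
    annotation = io_mod.read_annotation(
        _require(workspace, "annotation.gff3", "simulate"))
    genome = io_mod.read_fasta(_require(workspace, "genome.fa", "simulate"))
    peaks = io_mod.read_narrowpeak(
        _require(workspace, "reproducible_peaks.narrowPeak", "peaks"))
    mcfg = cfg["motifs"]
    width = int(mcfg["width"])
    flank = int(mcfg["summit_flank"])

    # de novo discovery on summit-centered windows of the strongest peaks
    ranked = sorted(peaks, key=lambda p: (p.p_value, p.chrom, p.start))
    seqs = []
    for pk in ranked[: int(mcfg["n_discovery_seqs"])]:
        chrom_seq = genome[pk.chrom]
        s = max(0, pk.summit - flank)
        seqs.append(chrom_seq[s : pk.summit + flank])
    if len(seqs) < 10:
        raise PipelineError("fewer than 10 reproducible peaks; cannot discover a motif")
    em_seed = int(sim.substream(cfg.get("seed", 0), "motif_em").integers(2 ** 31))
    result = motif_mod.discover_motif_em(seqs, width=width,
                                         n_restarts=int(mcfg["n_restarts"]),
                                         seed=em_seed)
    pwm = result.pwm
    pwm.score_threshold = float(mcfg["threshold_frac"]) * max(pwm.max_score, 0.0)
    io_mod.write_tsv(pwm.to_frame().reset_index(), workspace / "discovered_pwm.tsv")

    up, down = cfg["promoter"]["upstream"], cfg["promoter"]["downstream"]
    proms = promoter_sequences(annotation, genome, up, down)
    hit_rows = []
    for gid in sorted(proms):
        for h in motif_mod.scan_pwm(proms[gid], pwm, seq_id=gid):
            hit_rows.append({"gene": gid, "offset": h.offset - up,
                             "strand": h.strand, "score": h.score})
    hits_df = pd.DataFrame(hit_rows, columns=["gene", "offset", "strand", "score"])
    io_mod.write_tsv(hits_df, workspace / "xbox_hits.tsv")

    # positional profile of hits relative to the TSS (transcription frame)
    tss_hits = [motif_mod.MotifHit(r.gene, int(r.offset), r.strand, r.score)
                for r in hits_df.itertuples(index=False)]
    prof = motif_mod.positional_profile(tss_hits, {g: 0 for g in proms}, width)
    io_mod.write_tsv(prof, workspace / "motif_positions_tss.tsv")

    # enrichment of the motif in downregulated DE genes vs the rest
    de_sets = io_mod.read_json(_require(workspace, "de_sets.json", "dge"))
    down_genes = set()
    for age in de_sets:
        down_genes |= set(de_sets[age].get("down_2", []))
    background = set(proms) - down_genes
    enrichment = (motif_mod.motif_enrichment(down_genes, background, proms, pwm)
                  if down_genes else None)
    io_mod.write_json({
        "consensus": pwm.consensus,
        "width": width,
        "score_threshold": pwm.score_threshold,
        "gamma": result.gamma,
        "log_likelihood": result.log_likelihood,
        "inverted_repeat_score": pwm.inverted_repeat_score(),
        "n_discovery_sequences": len(seqs),
        "n_genes_with_xbox": int(hits_df["gene"].nunique()),
        "enrichment_down_vs_rest": enrichment,
    }, workspace / "motif_summary.json")


def stage_integrate(workspace: Path, cfg: dict) -> None:
    annotation = io_mod.read_annotation(
        _require(workspace, "annotation.gff3", "simulate"))
    peak_summary = io_mod.read_json(_require(workspace, "peak_summary.json", "peaks"))
    de_sets_raw = io_mod.read_json(_require(workspace, "de_sets.json", "dge"))
    de_sets = {age: {k: set(v) for k, v in d.items()}
               for age, d in de_sets_raw.items()}
    hits_df = io_mod.read_tsv(_require(workspace, "xbox_hits.tsv", "motifs"))
    profiles = io_mod.read_tsv(_require(workspace, "profiles.tsv", "simulate"))
    evidence = io_mod.read_tsv(_require(workspace, "cilia_evidence.tsv", "simulate"))

    chip_targets = set(peak_summary["chip_targets"])
    xbox_genes = set(hits_df["gene"]) if len(hits_df) else set()

    sim_cfg = io_mod.read_json(workspace / "config_used.json")["sim_config"]
    reference = sim.reference_trajectory(sim_cfg["timepoints"])
    crit = integ.ProfileCriteria(
        min_peak_rpkm=cfg["profiles"]["min_peak_rpkm"],
        min_correlation=cfg["profiles"]["min_correlation"],
        min_rise_fold=cfg["profiles"]["min_rise_fold"])
    profile_status = integ.classify_profiles(profiles, reference, crit)
    cilia_flags = integ.flag_cilia(annotation.gene_ids, evidence)

    # expression-matched universe: detectable in WT
    counts = io_mod.read_tsv(workspace / "counts.tsv", index_col=0)
    meta = io_mod.read_tsv(workspace / "samples.tsv")
    sf = dge_mod.compute_size_factors(counts)
    wt_cols = meta.loc[meta["genotype"] == "WT", "sample"].tolist()
    wt_mean = (counts[wt_cols] / sf[wt_cols]).mean(axis=1)
    floor = cfg["integration"]["expression_floor"]
    universe = [g for g in annotation.gene_ids if wt_mean.get(g, 0.0) >= floor]

    regulon = None
    truth_path = workspace / "truth.json"
    if truth_path.exists():
        regulon = RegulonSpec.from_dict(io_mod.read_json(truth_path))

    tiers = tuple(cfg["dge"]["fold_tiers"])
    table, summary = integ.call_direct_targets(
        chip_targets, de_sets, xbox_genes, profile_status, cilia_flags,
        universe, tiers=tiers, regulon=regulon)
    io_mod.write_tsv(table, workspace / "target_calls.tsv")

    uni = set(universe)
    de_any = set(table.loc[(table["de_p21"] != "none")
                           | (table["de_p30"] != "none"), "gene"])
    gold = set(evidence.loc[evidence["gold"], "gene"]) & uni
    summary["overlap_de_vs_gold_list"] = integ.compare_gene_sets(
        de_any & uni, gold, uni)
    summary["overlap_chip_vs_de"] = integ.compare_gene_sets(
        chip_targets & uni, de_any & uni, uni)
    io_mod.write_json(summary, workspace / "integration_summary.json")


def stage_report(workspace: Path, cfg: dict) -> None:
    table = io_mod.read_tsv(_require(workspace, "target_calls.tsv", "integrate"))
    results = {}
    for age in ("P21", "P30"):
        p = workspace / f"dge_{age}.tsv"
        if p.exists():
            results[age] = io_mod.read_tsv(p)
    ann = io_mod.read_tsv(_require(workspace, "peak_annotation.tsv", "peaks"))
    prom_peaks = ann.loc[ann["region"] == "promoter"].copy()
    hits = io_mod.read_tsv(_require(workspace, "xbox_hits.tsv", "motifs"))
    evidence = io_mod.read_tsv(_require(workspace, "cilia_evidence.tsv", "simulate"))
    master = integ.summary_report(table, results, prom_peaks, hits, evidence)
    io_mod.write_tsv(master, workspace / "master_table.tsv")
    io_mod.write_json({"n_rows": len(master),
                       "columns": list(master.columns)},
                      workspace / "report.json")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dge": stage_dge,
    "peaks": stage_peaks,
    "motifs": stage_motifs,
    "integrate": stage_integrate,
    "report": stage_report,
}


def run_stage(name: str, workspace, cfg: dict) -> None:
    if name not in STAGE_FUNCS:
        raise PipelineError(f"unknown stage {name!r}; choose from {STAGES}")
    STAGE_FUNCS[name](Path(workspace), cfg)


def run_all(workspace, cfg: dict) -> None:
    for name in STAGES:
        run_stage(name, workspace, cfg)
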