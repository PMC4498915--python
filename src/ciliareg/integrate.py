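"""Integration of the evidence streams into per-gene target calls.

A direct target is a gene with a reproducible binding peak in its promoter
window that is also differentially expressed in the knockout at either age.
Supporting evidence — an X-box in the promoter, a developmental expression
profile consistent with activation by the regulator, and membership in
cilia reference lists — is joined onto each call, and set-overlap statistics
(hypergeometric enrichment/depletion, Jaccard) quantify agreement with
external gene sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import RegulonSpec, TargetCall


@dataclass(frozen=True)
class ProfileCriteria:
    """Operational definition of "consistent with activation".

    A gene is not evaluable when its peak RPKM across the time course falls
    below `min_peak_rpkm` (unreliably low read values); otherwise it is
    consistent iff its Pearson correlation with the reference rising
    trajectory reaches `min_correlation` and its last/first-timepoint fold
    rise reaches `min_rise_fold`.
    """

    min_peak_rpkm: float = 1.0
    min_correlation: float = 0.8
    min_rise_fold: float = 4.0

    def __post_init__(self):
        if min(self.min_peak_rpkm, self.min_rise_fold) <= 0:
            raise ValueError("thresholds must be positive")


def classify_profiles(profiles: pd.DataFrame, reference: np.ndarray,
                      criteria: ProfileCriteria = ProfileCriteria()) -> pd.Series:
    """Per-gene {consistent, inconsistent, not_evaluable} classification.

    `profiles` has a 'gene' column and one column per timepoint; the
    reference trajectory must be on the same timepoints.
    """
    value_cols = [c for c in profiles.columns if c != "gene"]
    if len(value_cols) != len(reference):
        raise ValueError("profile timepoints must match the reference")
    ref = np.asarray(reference, dtype=float)
    mat = profiles[value_cols].to_numpy(dtype=float)
    out = []
    eps = 1e-12
    for row in mat:
        if row.max() < criteria.min_peak_rpkm:
            out.append("not_evaluable")
            continue
        if row.std() < eps or ref.std() < eps:
            r = 0.0
        else:
            r = float(np.corrcoef(row, ref)[0, 1])
        rise = row[-1] / max(row[0], eps)
        out.append("consistent"
                   if r >= criteria.min_correlation and rise >= criteria.min_rise_fold
                   else "inconsistent")
    return pd.Series(out, index=profiles["gene"].to_numpy(), name="profile_status")


def flag_cilia(genes: Iterable[str], evidence: pd.DataFrame) -> pd.Series:
    """Cilia flag per gene: on the gold-standard list OR >= 1 high-confidence
    citation. Genes missing from the evidence table are False."""
    ev = evidence.set_index("gene")
    flags = {}
    for g in genes:
        if g in ev.index:
            row = ev.loc[g]
            flags[g] = bool(row["gold"]) or int(row["high"]) >= 1
        else:
            flags[g] = False
    return pd.Series(flags, name="cilia")


def cilia_fraction(gene_set: Set[str], flags: pd.Series) -> float:
    if not gene_set:
        return float("nan")
    present = [g for g in gene_set if g in flags.index]
    return float(np.mean([flags[g] for g in present])) if present else float("nan")


# ---------------------------------------------------------------------------
# Direct-target calling
# ---------------------------------------------------------------------------

def _de_status(gene: str, sets: Dict[str, Set[str]],
               tiers: Sequence[float]) -> Tuple[str, int]:
    """Direction and highest nested fold tier met, for one age."""
    direction, best = "none", 0
    for d in ("down", "up"):
        for k in tiers:
            tier = str(int(k)) if float(k).is_integer() else str(k)
            if gene in sets.get(f"{d}_{tier}", set()):
                if int(k) > best:
                    direction, best = d, int(k)
    return direction, best


def call_direct_targets(chip_targets: Set[str],
                        de_sets: Dict[str, Dict[str, Set[str]]],
                        xbox_genes: Set[str],
                        profile_status: pd.Series,
                        cilia_flags: pd.Series,
                        universe: Sequence[str],
                        tiers: Sequence[float] = (2.0, 3.0, 10.0),
                        regulon: Optional[RegulonSpec] = None) -> Tuple[pd.DataFrame, dict]:
    """Join every evidence stream into TargetCall records plus summaries.

    Returns (per-gene table over `universe`, summary dict). When the
    planted RegulonSpec is available (synthetic runs), precision/recall of
    the direct-target set against the true regulon-and-affected set are
    appended to the summary.
    """
    ages = sorted(de_sets)
    calls: List[TargetCall] = []
    for g in universe:
        status = {age: _de_status(g, de_sets[age], tiers) for age in ages}
        d21, t21 = status.get("P21", ("none", 0))
        d30, t30 = status.get("P30", ("none", 0))
        calls.append(TargetCall(
            gene_id=g,
            is_chip_target=g in chip_targets,
            de_p21=d21, de_p21_tier=t21,
            de_p30=d30, de_p30_tier=t30,
            has_xbox=g in xbox_genes,
            profile_status=str(profile_status.get(g, "not_evaluable")),
            cilia=bool(cilia_flags.get(g, False)),
        ))
    table = pd.DataFrame([{
        "gene": c.gene_id,
        "is_chip_target": c.is_chip_target,
        "de_p21": c.de_p21, "de_p21_tier": c.de_p21_tier,
        "de_p30": c.de_p30, "de_p30_tier": c.de_p30_tier,
        "is_direct_target": c.is_direct_target,
        "has_xbox": c.has_xbox,
        "profile_status": c.profile_status,
        "cilia": c.cilia,
    } for c in calls])

    direct = set(table.loc[table["is_direct_target"], "gene"])
    de_any = set(table.loc[(table["de_p21"] != "none") | (table["de_p30"] != "none"), "gene"])
    down_direct = set(table.loc[table["is_direct_target"]
                                & ((table["de_p21"] == "down") | (table["de_p30"] == "down")),
                                "gene"])
    up_direct = direct - down_direct
    summary = {
        "n_chip_targets": len(chip_targets & set(universe)),
        "n_de_genes": len(de_any),
        "n_direct_targets": len(direct),
        "n_direct_down": len(down_direct),
        "n_direct_up": len(up_direct),
        "n_de_with_xbox": int(((table["gene"].isin(de_any)) & table["has_xbox"]).sum()),
        "venn_chip_de": {
            "chip_only": len((chip_targets & set(universe)) - de_any),
            "de_only": len(de_any - chip_targets),
            "shared": len(direct),
        },
        "cilia_fraction_direct": _frac(table, table["is_direct_target"]),
        "cilia_fraction_de_down": _frac(table, (table["de_p21"] == "down")
                                        | (table["de_p30"] == "down")),
        "profile_consistent_of_evaluable_direct": _profile_frac(table),
    }
    if regulon is not None:
        truth = {g for g in regulon.target_gene_ids
                 if regulon.effect_log2fc_p21.get(g, 0) != 0
                 or regulon.effect_log2fc_p30.get(g, 0) != 0}
        tp = len(direct & truth)
        summary["truth"] = {
            "n_true_direct": len(truth),
            "precision": tp / len(direct) if direct else float("nan"),
            "recall": tp / len(truth) if truth else float("nan"),
        }
    return table, summary


def _frac(table: pd.DataFrame, mask) -> float:
    sub = table.loc[mask]
    return float(sub["cilia"].mean()) if len(sub) else float("nan")


def _profile_frac(table: pd.DataFrame) -> float:
    sub = table.loc[table["is_direct_target"]
                    & (table["profile_status"] != "not_evaluable")]
    return float((sub["profile_status"] == "consistent").mean()) if len(sub) else float("nan")


# ---------------------------------------------------------------------------
# Gene-set overlap statistics
# ---------------------------------------------------------------------------

def compare_gene_sets(set_a: Set[str], set_b: Set[str],
                      universe: Set[str]) -> dict:
    """Overlap, hypergeometric enrichment/depletion p and Jaccard index.

    Enrichment p = P(overlap >= observed) drawing |A| genes from a universe
    containing |B| marked genes; depletion p = P(overlap <= observed).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_b), len(set_a)
    k = len(set_a & set_b)
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    union = len(set_a | set_b)
    return {
        "overlap": k,
        "n_a": n, "n_b": K, "n_universe": N,
        "p_enrichment": min(1.0, p_enrich),
        "p_depletion": min(1.0, p_deplete),
        "jaccard": k / union if union else float("nan"),
    }


# ---------------------------------------------------------------------------
# Master report
# ---------------------------------------------------------------------------

MASTER_COLUMNS = [
    "gene", "is_chip_target", "peak_chrom", "peak_start", "peak_end",
    "peak_p", "tss_distance",
    "log2fc_P21", "p_P21", "q_P21", "log2fc_P30", "p_P30", "q_P30",
    "de_p21", "de_p21_tier", "de_p30", "de_p30_tier", "is_direct_target",
    "has_xbox", "xbox_offset", "profile_status",
    "cilia", "cilia_gold", "cilia_high",
]


def summary_report(target_table: pd.DataFrame,
                   dge_results: Dict[str, pd.DataFrame],
                   peak_annotations: pd.DataFrame,
                   xbox_hits: pd.DataFrame,
                   cilia_evidence: pd.DataFrame) -> pd.DataFrame:
    """One row per gene in the union of ChIP targets and DE genes.

    Deterministic row order (gene id) and a documented, stable column order
    so reruns hash identically.
    """
    keep = target_table.loc[
        target_table["is_chip_target"]
        | (target_table["de_p21"] != "none") | (target_table["de_p30"] != "none")
    ].copy()
    master = keep.copy()
    for age, res in dge_results.items():
        sub = res[["gene", "log2fc", "p", "q"]].rename(columns={
            "log2fc": f"log2fc_{age}", "p": f"p_{age}", "q": f"q_{age}"})
        master = master.merge(sub, on="gene", how="left")
    if len(peak_annotations):
        best = (peak_annotations.sort_values(["gene", "peak_p"])
                .drop_duplicates("gene")
                .rename(columns={"chrom": "peak_chrom", "start": "peak_start",
                                 "end": "peak_end"}))
        master = master.merge(
            best[["gene", "peak_chrom", "peak_start", "peak_end", "peak_p",
                  "tss_distance"]],
            on="gene", how="left")
    else:
        for c in ("peak_chrom", "peak_start", "peak_end", "peak_p", "tss_distance"):
            master[c] = np.nan
    if len(xbox_hits):
        best_hit = (xbox_hits.sort_values(["gene", "score"], ascending=[True, False])
                    .drop_duplicates("gene")
                    .rename(columns={"offset": "xbox_offset"}))
        master = master.merge(best_hit[["gene", "xbox_offset"]], on="gene", how="left")
    else:
        master["xbox_offset"] = np.nan
    ev = cilia_evidence.rename(columns={"gold": "cilia_gold", "high": "cilia_high"})
    master = master.merge(ev[["gene", "cilia_gold", "cilia_high"]], on="gene", how="left")
    master = master.reindex(columns=MASTER_COLUMNS)
    return master.sort_values("gene").reset_index(drop=True)
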