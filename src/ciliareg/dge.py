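"""Differential expression between wild-type and knockout at each age.

The machinery is the classic small-n RNA-seq stack: median-of-ratios size
factors, per-gene method-of-moments negative-binomial dispersion shrunk
toward a mean-dispersion trend, and an exact conditional NB test on group
totals. Calls are thresholded on raw p < alpha combined with nested
fold-change tiers (2x, 3x, 10x); BH-adjusted q-values are reported
alongside but do not gate the calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DGEThresholds:
    alpha: float = 0.01
    fold_tiers: Tuple[float, ...] = (2.0, 3.0, 10.0)

    def __post_init__(self):
        tiers = self.fold_tiers
        if list(tiers) != sorted(tiers) or any(t <= 1 for t in tiers):
            raise ValueError("fold tiers must be increasing and > 1")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples, computed
    over genes with all-positive counts; each sample's factor is the median
    ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios undefined (consider a total-count fallback)"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                        groups: Sequence[Sequence[str]],
                        prior_df: float = 20.0,
                        floor: float = 1e-8,
                        n_bins: int = 20) -> pd.Series:
    """Per-gene NB dispersion, shrunk toward a mean-dispersion trend.

    The raw estimate pools within-group method-of-moments values on
    normalized counts: alpha_hat = (s^2 - c*mbar) / mbar^2 where c corrects
    for the size-factor rescaling of the Poisson part. The trend is the
    average of the (unclipped) raw estimates within mean-expression bins;
    each gene is shrunk with `prior_df` prior degrees of freedom and floored.
    """
    sf = size_factors.reindex(counts.columns).to_numpy()
    norm = counts.to_numpy(dtype=float) / sf
    raw = np.full(len(counts), np.nan)
    overall_mean = norm.mean(axis=1)
    num = np.zeros(len(counts))
    df_total = 0
    for group in groups:
        cols = [counts.columns.get_loc(s) for s in group]
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        c = np.mean(1.0 / sf[cols])  # Var(y/sf) = mu/sf + alpha*mu^2
        with np.errstate(divide="ignore", invalid="ignore"):
            est = (v - c * m) / np.maximum(m, 1e-12) ** 2
        est[m <= 0] = 0.0
        num += (len(cols) - 1) * est
        df_total += len(cols) - 1
    if df_total == 0:
        raise ValueError("need >= 2 replicates in at least one group")
    raw = num / df_total

    # mean-dispersion trend over expression bins (unclipped averages)
    order = np.argsort(overall_mean, kind="stable")
    trend = np.empty(len(counts))
    bins = np.array_split(order, min(n_bins, max(1, len(counts) // 10)))
    for b in bins:
        trend[b] = raw[b].mean()
    shrunk = (prior_df * trend + df_total * raw) / (prior_df + df_total)
    return pd.Series(np.maximum(shrunk, floor), index=counts.index)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _group_total_pmf(total_grid: np.ndarray, mean: float, size: float,
                     alpha: float) -> np.ndarray:
    if alpha < 1e-10:
        return stats.poisson.pmf(total_grid, mean)
    return stats.nbinom.pmf(total_grid, size / alpha, (size / alpha) / (size / alpha + mean))


def nb_exact_test(counts_a: Sequence[float], counts_b: Sequence[float],
                  sf_a: Sequence[float], sf_b: Sequence[float],
                  alpha_disp: float) -> float:
    """Two-sided exact NB test of equal means between two groups.

    Group totals are modelled as NB with effective sizes M_A = sum of size
    factors (so equal factors reduce to the iid-sum distribution), and the
    test conditions on the pooled total T: the p-value is the probability
    mass of all allocations of T between the groups that are no more likely
    than the observed one.
    """
    ya = float(np.sum(counts_a))
    yb = float(np.sum(counts_b))
    ma = float(np.sum(sf_a))
    mb = float(np.sum(sf_b))
    if ma <= 0 or mb <= 0:
        raise ValueError("effective group sizes must be positive")
    total = int(round(ya + yb))
    if total == 0:
        return 1.0
    mu = total / (ma + mb)
    grid = np.arange(total + 1)
    pa = _group_total_pmf(grid, mu * ma, ma, alpha_disp)
    pb = _group_total_pmf(grid, mu * mb, mb, alpha_disp)
    joint = pa * pb[::-1]
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    observed = joint[int(round(ya))]
    p = joint[joint <= observed * (1 + 1e-12)].sum() / denom
    return float(min(1.0, max(p, np.nextafter(0, 1))))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Per-age testing
# ---------------------------------------------------------------------------

def run_dge(counts: pd.DataFrame, sample_meta: pd.DataFrame,
            gene_lengths: Optional[pd.Series] = None,
            thresholds: DGEThresholds = DGEThresholds(),
            pseudocount: float = 0.5,
            prior_df: float = 20.0) -> Dict[str, pd.DataFrame]:
    """Test every gene for KO-vs-WT differential expression at each age.

    Returns {age: DataFrame(gene, log2fc, p, q, mean_norm_expr, rpkm_wt,
    rpkm_ko)} with log2fc = log2 of the pseudocounted normalized KO/WT mean
    ratio. RPKM columns are present when gene lengths are supplied.
    """
    meta = sample_meta.set_index("sample")
    size_factors = compute_size_factors(counts)
    ages = sorted(meta["age"].unique())
    groups = [
        meta.index[(meta["genotype"] == g) & (meta["age"] == a)].tolist()
        for g in ("WT", "KO") for a in ages
    ]
    dispersion = estimate_dispersion(counts, size_factors, groups, prior_df=prior_df)

    sf = size_factors
    norm = counts / sf
    results = {}
    for age in ages:
        wt = meta.index[(meta["genotype"] == "WT") & (meta["age"] == age)].tolist()
        ko = meta.index[(meta["genotype"] == "KO") & (meta["age"] == age)].tolist()
        if not wt or not ko:
            raise ValueError(f"age {age}: both genotypes required")
        mean_wt = norm[wt].mean(axis=1)
        mean_ko = norm[ko].mean(axis=1)
        log2fc = np.log2((mean_ko + pseudocount) / (mean_wt + pseudocount))
        cwt = counts[wt].to_numpy()
        cko = counts[ko].to_numpy()
        sfa = sf[wt].to_numpy()
        sfb = sf[ko].to_numpy()
        disp = dispersion.to_numpy()
        pvals = np.array([
            nb_exact_test(cwt[i], cko[i], sfa, sfb, disp[i])
            for i in range(len(counts))
        ])
        df = pd.DataFrame({
            "gene": counts.index,
            "log2fc": log2fc.to_numpy(),
            "p": pvals,
            "q": bh_adjust(pvals),
            "mean_norm_expr": ((mean_wt + mean_ko) / 2).to_numpy(),
            "dispersion": disp,
        })
        if gene_lengths is not None:
            lens_kb = gene_lengths.reindex(counts.index).to_numpy() / 1e3
            for label, cols in (("rpkm_wt", wt), ("rpkm_ko", ko)):
                depth_m = counts[cols].sum(axis=0).to_numpy() / 1e6
                rpkm = (counts[cols].to_numpy() / depth_m) / lens_kb[:, None]
                df[label] = rpkm.mean(axis=1)
        results[age] = df.reset_index(drop=True)
    return results


# ---------------------------------------------------------------------------
# Set calls and summaries
# ---------------------------------------------------------------------------

def call_de_sets(result: pd.DataFrame,
                 thresholds: DGEThresholds = DGEThresholds()) -> Dict[str, Set[str]]:
    """Nested fold-change tiers of significant genes for one age.

    down_k = {p < alpha and fold-change <= 1/k}; up_k analogous. Tiers are
    nested by construction (down_10 within down_3 within down_2).
    """
    sets: Dict[str, Set[str]] = {}
    sig = result["p"] < thresholds.alpha
    for k in thresholds.fold_tiers:
        lk = np.log2(k)
        tier = str(int(k)) if float(k).is_integer() else str(k)
        sets[f"down_{tier}"] = set(result.loc[sig & (result["log2fc"] <= -lk), "gene"])
        sets[f"up_{tier}"] = set(result.loc[sig & (result["log2fc"] >= lk), "gene"])
    return sets


def cumulative_fold_curve(result: pd.DataFrame, direction: str,
                          alpha: float = 0.01,
                          grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Count of significant genes at or beyond each fold threshold."""
    if grid is None:
        grid = np.round(np.arange(1.0, 16.5, 0.5), 3)
    sig = result[result["p"] < alpha]
    lfc = sig["log2fc"].to_numpy()
    vals = lfc <= -np.log2(grid)[:, None] if direction == "down" \
        else lfc >= np.log2(grid)[:, None]
    return pd.DataFrame({"fold_threshold": grid, "n_genes": vals.sum(axis=1)})


def de_summary(results: Dict[str, pd.DataFrame],
               sets: Dict[str, Dict[str, Set[str]]],
               thresholds: DGEThresholds = DGEThresholds()) -> dict:
    """Cross-age overlap counts, tier counts and plot-ready tables.

    Mirrors the standard presentation: cumulative downregulation curves per
    age, a cross-age Venn of down/up sets, a P21-vs-P30 fold-change scatter
    table and an MA-style (mean expression vs fold-change) table.
    """
    ages = sorted(results)
    out: dict = {"tier_counts": {}, "venn": {}}
    for age in ages:
        out["tier_counts"][age] = {name: len(s) for name, s in sorted(sets[age].items())}
    if len(ages) == 2:
        a, b = ages
        base = str(int(thresholds.fold_tiers[0]))
        for direction in ("down", "up"):
            sa = sets[a][f"{direction}_{base}"]
            sb = sets[b][f"{direction}_{base}"]
            out["venn"][direction] = {
                f"{a}_only": len(sa - sb), f"{b}_only": len(sb - sa),
                "shared": len(sa & sb),
            }
    merged = None
    for age in ages:
        cols = results[age][["gene", "log2fc", "p"]].rename(
            columns={"log2fc": f"log2fc_{age}", "p": f"p_{age}"})
        merged = cols if merged is None else merged.merge(cols, on="gene")
    out["scatter_table"] = merged
    out["ma_tables"] = {
        age: results[age][["gene", "mean_norm_expr", "log2fc", "p"]].copy()
        for age in ages
    }
    out["curves"] = {
        age: {d: cumulative_fold_curve(results[age], d, thresholds.alpha)
              for d in ("down", "up")}
        for age in ages
    }
    return out
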