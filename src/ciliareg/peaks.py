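"""Windowed Poisson peak calling against an input control, reproducibility
filtering across replicates, and genomic-region annotation of peaks.

Peaks are called per IP replicate by testing each bin's IP count against a
Poisson expectation derived from the depth-rescaled input (floored at the
genome-wide mean), correcting with Benjamini-Hochberg within the replicate,
and merging significant bins. Reproducible peaks require reciprocal overlap
with a peak in every other replicate. Each reproducible peak is then
classified by its center with precedence promoter > exon > intron >
intergenic against a strand-aware -500/+50 bp promoter window.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dge import bh_adjust
from .models import CoverageTrack, GeneModel, GenomeAnnotation, Peak

REGION_CLASSES = ("promoter", "exon", "intron", "intergenic")


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(Poisson(lam) >= k); the bin-level enrichment p-value."""
    return float(stats.poisson.sf(k - 1, lam))


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_peaks(ip_track: CoverageTrack, input_track: CoverageTrack,
               q_threshold: float = 0.05,
               min_gap_bins: int = 1) -> List[Peak]:
    """Call enriched intervals in one IP replicate against the input.

    Per bin, lambda is the input count rescaled to IP sequencing depth and
    floored at the genome-wide rescaled input mean; the bin p-value is the
    Poisson upper tail of the IP count. Bins significant after BH within
    the replicate are merged when gapped by <= `min_gap_bins` bins; the
    summit is the center of the max-IP bin and the peak p is the min bin p.
    """
    if ip_track.bin_size != input_track.bin_size:
        raise ValueError("IP and input tracks must share the same binning")
    total_input = input_track.total()
    if total_input <= 0:
        raise ValueError("empty input track")
    scale = ip_track.total() / total_input
    n_bins_total = sum(len(c) for c in input_track.counts.values())
    lam_floor = scale * total_input / n_bins_total

    bin_size = ip_track.bin_size
    chroms, pvals, ips, lams, positions = [], [], [], [], []
    for chrom in sorted(ip_track.counts):
        ip = np.asarray(ip_track.counts[chrom])
        inp = np.asarray(input_track.counts[chrom])
        if len(ip) != len(inp):
            raise ValueError(f"bin count mismatch on {chrom}")
        lam = np.maximum(inp * scale, lam_floor)
        p = stats.poisson.sf(ip - 1, lam)
        chroms.append(chrom)
        pvals.append(p)
        ips.append(ip)
        lams.append(lam)

    flat_p = np.concatenate(pvals)
    qvals = bh_adjust(flat_p)
    offsets = np.cumsum([0] + [len(p) for p in pvals])

    peaks: List[Peak] = []
    for ci, chrom in enumerate(chroms):
        q = qvals[offsets[ci]:offsets[ci + 1]]
        p = pvals[ci]
        ip = ips[ci]
        lam = lams[ci]
        sig = np.flatnonzero(q <= q_threshold)
        if len(sig) == 0:
            continue
        # merge runs of significant bins allowing small gaps
        breaks = np.flatnonzero(np.diff(sig) > min_gap_bins + 1)
        runs = np.split(sig, breaks + 1)
        length = ip_track.chrom_lengths[chrom]
        for run in runs:
            b0, b1 = run[0], run[-1]
            start = int(b0 * bin_size)
            end = int(min((b1 + 1) * bin_size, length))
            top = run[np.argmax(ip[run])]
            summit = int(min(top * bin_size + bin_size // 2, end - 1))
            enr = float(ip[run].sum() / max(lam[run].sum(), 1e-12))
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                              enrichment=enr,
                              p_value=float(max(p[run].min(), 1e-300))))
    for i, pk in enumerate(peaks):
        pk.name = f"peak_{i + 1}"
    return peaks


def _reciprocal_overlap(a: Peak, b: Peak) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def filter_reproducible(peak_sets: Sequence[List[Peak]],
                        min_overlap_frac: float = 0.5) -> List[Peak]:
    """Keep peaks supported by every replicate.

    The replicate with most peaks anchors the comparison; an anchor peak is
    kept if some peak in every other replicate reciprocally overlaps it by
    at least `min_overlap_frac` of both peak lengths. Kept
    coordinates are the union of the anchor peak with its matching partners.
    """
    if len(peak_sets) < 2:
        raise ValueError("reproducibility undefined with fewer than 2 replicates")
    anchor_idx = int(np.argmax([len(s) for s in peak_sets]))
    anchor = peak_sets[anchor_idx]
    others = [s for i, s in enumerate(peak_sets) if i != anchor_idx]
    trees = []
    for s in others:
        tree: Dict[str, IntervalTree] = {}
        for pk in s:
            tree.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, pk)
        trees.append(tree)

    kept: List[Peak] = []
    for pk in anchor:
        matches = []
        ok = True
        for tree in trees:
            candidates = [iv.data for iv in tree.get(pk.chrom, IntervalTree()).overlap(pk.start, pk.end)]
            best = max(candidates, key=lambda c: _reciprocal_overlap(pk, c), default=None)
            if best is None or _reciprocal_overlap(pk, best) < min_overlap_frac:
                ok = False
                break
            matches.append(best)
        if not ok:
            continue
        start = min([pk.start] + [m.start for m in matches])
        end = max([pk.end] + [m.end for m in matches])
        kept.append(Peak(chrom=pk.chrom, start=start, end=end, summit=pk.summit,
                         enrichment=pk.enrichment, p_value=pk.p_value, name=pk.name))
    for i, pk in enumerate(kept):
        pk.name = f"rpeak_{i + 1}"
    return kept


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class PeakAnnotation:
    peak: Peak
    region: str
    gene_id: Optional[str]
    tss_distance: Optional[int]  # signed, strand-aware; promoter peaks only
    ambiguous: bool = False


def _build_trees(annotation: GenomeAnnotation, upstream: int, downstream: int):
    promoters: Dict[str, IntervalTree] = {}
    exons: Dict[str, IntervalTree] = {}
    spans: Dict[str, IntervalTree] = {}
    for g in annotation.genes:
        ps, pe = g.promoter(upstream, downstream)
        promoters.setdefault(g.chrom, IntervalTree()).addi(max(0, ps), pe, g)
        spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        for s, e in g.exons:
            exons.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
    return promoters, exons, spans


def signed_tss_distance(center: int, gene: GeneModel) -> int:
    d = center - gene.tss
    return d if gene.strand == "+" else -d


def annotate_peaks(peaks: Sequence[Peak], annotation: GenomeAnnotation,
                   upstream: int = 500, downstream: int = 50) -> List[PeakAnnotation]:
    """Classify each peak center into promoter/exon/intron/intergenic.

    Precedence is promoter > exon > intron > intergenic so the classes
    partition the peak set. A center inside several promoter windows is
    assigned to the nearest TSS; an exact tie flags the peak ambiguous (one
    record per tied gene).
    """
    promoters, exons, spans = _build_trees(annotation, upstream, downstream)
    empty = IntervalTree()
    out: List[PeakAnnotation] = []
    for pk in peaks:
        c = pk.center
        hits = [iv.data for iv in promoters.get(pk.chrom, empty).at(c)]
        if hits:
            dists = [abs(c - g.tss) for g in hits]
            best = min(dists)
            tied = [g for g, d in zip(hits, dists) if d == best]
            for g in tied:
                out.append(PeakAnnotation(peak=pk, region="promoter", gene_id=g.gene_id,
                                          tss_distance=signed_tss_distance(c, g),
                                          ambiguous=len(tied) > 1))
            continue
        ex = [iv.data for iv in exons.get(pk.chrom, empty).at(c)]
        if ex:
            g = min(ex, key=lambda g: g.gene_id)
            out.append(PeakAnnotation(pk, "exon", g.gene_id,
                                      signed_tss_distance(c, g)))
            continue
        sp = [iv.data for iv in spans.get(pk.chrom, empty).at(c)]
        if sp:
            g = min(sp, key=lambda g: g.gene_id)
            out.append(PeakAnnotation(pk, "intron", g.gene_id,
                                      signed_tss_distance(c, g)))
            continue
        out.append(PeakAnnotation(pk, "intergenic", None, None))
    return out


def region_class_counts(annotated: Sequence[PeakAnnotation]) -> Dict[str, int]:
    """Counts per region class; each peak counted once (ambiguous promoter
    peaks contribute a single promoter count)."""
    seen: Set[int] = set()
    counts = {c: 0 for c in REGION_CLASSES}
    for ann in annotated:
        key = id(ann.peak)
        if key in seen:
            continue
        seen.add(key)
        counts[ann.region] += 1
    return counts


def rank_fraction_curve(annotated: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Cumulative region-class fractions with peaks ranked by increasing p."""
    uniq: Dict[int, PeakAnnotation] = {}
    for ann in annotated:
        uniq.setdefault(id(ann.peak), ann)
    anns = sorted(uniq.values(), key=lambda a: (a.peak.p_value, a.peak.name))
    rows = []
    counts = {c: 0 for c in REGION_CLASSES}
    for rank, ann in enumerate(anns, 1):
        counts[ann.region] += 1
        rows.append({"rank": rank, "p_value": ann.peak.p_value,
                     **{f"frac_{c}": counts[c] / rank for c in REGION_CLASSES}})
    return pd.DataFrame(rows)


def tss_distance_histogram(annotated: Sequence[PeakAnnotation],
                           bin_width: int = 50) -> pd.DataFrame:
    """Histogram of signed promoter-peak center distances to the TSS."""
    dists = [a.tss_distance for a in annotated
             if a.region == "promoter" and a.tss_distance is not None]
    if not dists:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lo = (min(dists) // bin_width) * bin_width
    hi = ((max(dists) // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})


def promoter_target_genes(annotated: Sequence[PeakAnnotation]) -> Tuple[Set[str], Set[str]]:
    """Genes with >= 1 reproducible peak center in their promoter window.

    Returns (target gene ids, ambiguous gene ids) — the latter are genes
    whose only support is a peak equidistant between two TSSs.
    """
    targets: Set[str] = set()
    ambiguous: Set[str] = set()
    for ann in annotated:
        if ann.region == "promoter" and ann.gene_id is not None:
            targets.add(ann.gene_id)
            if ann.ambiguous:
                ambiguous.add(ann.gene_id)
    return targets, ambiguous
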