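"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open (BED convention). GFF3's 1-based
closed coordinates are converted at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

Interval = Tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and sorted, non-overlapping exons.

    The TSS equals the leftmost exon start on the + strand and the
    rightmost exon end minus one on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: Tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def promoter(self, upstream: int = 500, downstream: int = 50) -> Interval:
        """Strand-aware promoter window around the TSS, half-open.

        On the + strand the window is [tss-upstream, tss+downstream); on the
        - strand it is [tss-downstream, tss+upstream) so that the same
        transcription-relative asymmetry holds. The window always contains
        the TSS and has length upstream + downstream.
        """
        if self.strand == "+":
            return (self.tss - upstream, self.tss + downstream)
        return (self.tss - downstream, self.tss + upstream)


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome lengths; validates bounds and id uniqueness."""

    genes: List[GeneModel]
    chrom_lengths: Dict[str, int]

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id}: outside chromosome bounds")

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def _by_id(self) -> Dict[str, GeneModel]:
        if not hasattr(self, "_by_id_cache"):
            object.__setattr__(self, "_by_id_cache", {g.gene_id: g for g in self.genes})
        return self._by_id_cache

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class Peak:
    """A binding interval with summit, IP/input enrichment and Poisson p-value."""

    chrom: str
    start: int
    end: int
    summit: int
    enrichment: float
    p_value: float
    name: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside peak [{self.start},{self.end})")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0,1]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "Peak") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CoverageTrack:
    """Binned read coverage: one integer vector of bin counts per chromosome.

    Bin i covers [i*bin_size, (i+1)*bin_size); the final bin may be truncated
    by the chromosome end when written out.
    """

    bin_size: int
    counts: Dict[str, "object"]  # chrom -> 1-D numpy integer array
    chrom_lengths: Dict[str, int]

    def total(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))


@dataclass
class RegulonSpec:
    """Planted ground truth for a synthetic run.

    Records which genes form the regulon (true direct targets), where their
    X-box instances were planted relative to the TSS, the planned knockout
    log2 fold-changes at each age (also covering indirect, non-bound DE
    genes), and the developmental profile class of every gene.
    """

    target_gene_ids: set
    planted_site_offsets: Dict[str, int]
    effect_log2fc_p21: Dict[str, float]
    effect_log2fc_p30: Dict[str, float]
    profile_class: Dict[str, str]  # rfx2_like | flat | declining
    indirect_gene_ids: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "target_gene_ids": sorted(self.target_gene_ids),
            "planted_site_offsets": dict(sorted(self.planted_site_offsets.items())),
            "effect_log2fc_p21": dict(sorted(self.effect_log2fc_p21.items())),
            "effect_log2fc_p30": dict(sorted(self.effect_log2fc_p30.items())),
            "profile_class": dict(sorted(self.profile_class.items())),
            "indirect_gene_ids": sorted(self.indirect_gene_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegulonSpec":
        return cls(
            target_gene_ids=set(d["target_gene_ids"]),
            planted_site_offsets=dict(d["planted_site_offsets"]),
            effect_log2fc_p21={k: float(v) for k, v in d["effect_log2fc_p21"].items()},
            effect_log2fc_p30={k: float(v) for k, v in d["effect_log2fc_p30"].items()},
            profile_class=dict(d["profile_class"]),
            indirect_gene_ids=set(d.get("indirect_gene_ids", [])),
        )


@dataclass
class TargetCall:
    """Per-gene integrated record combining every evidence stream."""

    gene_id: str
    is_chip_target: bool
    de_p21: str  # down | up | none
    de_p21_tier: int  # highest nested fold tier met (0 if none)
    de_p30: str
    de_p30_tier: int
    has_xbox: bool
    profile_status: str  # consistent | inconsistent | not_evaluable
    cilia: bool

    @property
    def is_direct_target(self) -> bool:
        return self.is_chip_target and (self.de_p21 != "none" or self.de_p30 != "none")
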