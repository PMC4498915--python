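"""Synthetic-data generation with planted ground truth.

Everything the downstream pipeline consumes is emulated here: a compact
genome of non-overlapping gene models, X-box motif instances planted in the
promoters of a designated regulon, ChIP IP/input coverage with Poisson
enrichment over the planted sites, negative-binomial RNA-seq counts with
knockout effects at two postnatal ages, a developmental expression
time-course, and cilia-evidence tables. The planted truth (RegulonSpec) is
written alongside so every stage can be scored against it.

Randomness: one master seed; each generator draws from a named substream so
modules can be regenerated independently and reproducibly.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CoverageTrack, GeneModel, GenomeAnnotation, RegulonSpec

BASES = np.frombuffer(b"ACGT", dtype="S1")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

X_BOX_CONSENSUS = "GTTGCCATGGCAAC"  # 14-bp perfect inverted repeat


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a master seed."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), child]))


@dataclass
class SimulationConfig:
    """Design constants of a synthetic run.

    Defaults follow the biological design being emulated: knockout-vs-wild-
    type contrasts at postnatal days 21 and 30, a strand-aware promoter
    window of -500/+50 bp around the TSS, and a 14-bp inverted-repeat X-box
    consensus planted in regulon promoters.
    """

    n_genes: int = 2000
    n_targets: int = 200
    n_indirect: int = 100
    chrom_lengths: Optional[Dict[str, int]] = None  # None -> auto-sized
    promoter_window: Tuple[int, int] = (500, 50)  # upstream, downstream bp
    motif_consensus: str = X_BOX_CONSENSUS
    exact_sites: bool = True  # plant the exact consensus (vs PWM-sampled)

    # RNA-seq
    n_reps_rna: int = 3
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 6.5
    baseline_log2_sd: float = 1.5
    library_sizes: Optional[Sequence[float]] = None  # relative, default all 1
    effect_log2fc: float = 2.0  # magnitude of planted knockout effects
    target_down_frac: float = 0.8  # regulon genes repressed in the knockout
    p21_effect_prob: float = 0.5  # chance an effect is already present at P21

    # ChIP-seq
    chip_enrichment: float = 10.0
    chip_depth: float = 30.0  # mean reads per bin in the input track
    bin_size: int = 50
    n_ip_reps: int = 2

    # developmental time course
    timepoints: Tuple[int, ...] = (7, 14, 17, 21, 30)
    profile_noise_sd: float = 0.2  # log-normal sigma
    low_expression_frac: float = 0.1  # background genes below reliability floor

    # cilia evidence
    cilia_target_frac: float = 0.6
    cilia_background_frac: float = 0.05

    seed: int = 0

    # genome layout (derived constants)
    gene_span: int = 2000
    gene_slot: int = 4000
    n_chroms: int = 4
    chrom_margin: int = 1000

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_targets < 0 or self.n_targets > self.n_genes:
            raise ValueError("need 0 <= n_targets <= n_genes and n_genes > 0")
        if self.chip_enrichment < 1:
            raise ValueError("chip_enrichment must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.motif_consensus) < 4 or set(self.motif_consensus) - set("ACGT"):
            raise ValueError("motif_consensus must be ACGT of length >= 4")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        up, down = self.promoter_window
        if up < 0 or down < 0:
            raise ValueError("promoter window sides must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["promoter_window"] = list(self.promoter_window)
        if self.library_sizes is not None:
            d["library_sizes"] = list(self.library_sizes)
        return d


# ---------------------------------------------------------------------------
# Genome + regulon
# ---------------------------------------------------------------------------

def _auto_chrom_lengths(config: SimulationConfig) -> Dict[str, int]:
    per_chrom = -(-config.n_genes // config.n_chroms)
    length = 2 * config.chrom_margin + per_chrom * config.gene_slot
    return {f"chr{i + 1}": length for i in range(config.n_chroms)}


def generate_genome(config: SimulationConfig):
    """Build annotation, genome sequence and planted regulon.

    Gene models are packed non-overlapping with room for every promoter
    window; strands are assigned ~50/50; the background sequence is i.i.d.
    uniform ACGT; exactly one motif instance is planted in each target
    promoter at a recorded TSS-relative offset (nowhere else).

    Returns (GenomeAnnotation, {chrom: sequence}, RegulonSpec).
    """
    chrom_lengths = config.chrom_lengths or _auto_chrom_lengths(config)
    up, down = config.promoter_window
    margin = max(config.chrom_margin, up + down)
    slots: List[Tuple[str, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        usable = length - 2 * margin
        capacity = max(0, usable // config.gene_slot)
        for j in range(capacity):
            slots.append((chrom, margin + j * config.gene_slot))
    if len(slots) < config.n_genes:
        raise ValueError(
            f"chromosomes can host only {len(slots)} gene slots; "
            f"{config.n_genes} requested (capacity error)"
        )

    rng = substream(config.seed, "genome")
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    width = len(str(config.n_genes))
    genes = []
    for i in range(config.n_genes):
        chrom, base = slots[i]
        # gene occupies [base+1000, base+1000+span) inside its slot, leaving
        # >= promoter-window clearance on both sides
        s0 = base + (config.gene_slot - config.gene_span) // 2
        exon_rel = [(0, 400), (800, 1200), (config.gene_span - 400, config.gene_span)]
        genes.append(
            GeneModel(
                gene_id=f"g{str(i + 1).zfill(width)}",
                chrom=chrom,
                strand=str(strands[i]),
                exons=tuple((s0 + a, s0 + b) for a, b in exon_rel),
            )
        )
    annotation = GenomeAnnotation(genes=genes, chrom_lengths=dict(chrom_lengths))

    # background sequence
    seqs = {}
    for chrom in sorted(chrom_lengths):
        arr = BASES[substream(config.seed, f"sequence:{chrom}").integers(0, 4, chrom_lengths[chrom])]
        seqs[chrom] = bytearray(arr.tobytes())

    # regulon membership + planted sites
    pick = substream(config.seed, "regulon")
    idx = pick.choice(config.n_genes, size=config.n_targets + config.n_indirect, replace=False)
    target_ids = {genes[i].gene_id for i in idx[: config.n_targets]}
    indirect_ids = {genes[i].gene_id for i in idx[config.n_targets :]}

    motif = config.motif_consensus
    L = len(motif)
    offsets: Dict[str, int] = {}
    site_rng = substream(config.seed, "sites")
    # offsets concentrate near the TSS (truncated normal), always inside the window
    lo, hi = -min(up, 480), down - L
    for g in sorted(target_ids):
        d = int(np.clip(round(site_rng.normal(-100, 120)), lo, hi))
        offsets[g] = d
        gene = annotation.gene(g)
        word = motif if config.exact_sites else _sample_site(motif, site_rng)
        if gene.strand == "+":
            start = gene.tss + d
            planted = word
        else:
            start = gene.tss - d - (L - 1)
            planted = revcomp(word)
        seqs[gene.chrom][start : start + L] = planted.encode()

    # planned knockout effects
    eff_rng = substream(config.seed, "effects")
    eff21: Dict[str, float] = {}
    eff30: Dict[str, float] = {}
    classes: Dict[str, str] = {}
    for g in sorted(target_ids | indirect_ids):
        down_gene = eff_rng.random() < config.target_down_frac
        eff = -config.effect_log2fc if down_gene else config.effect_log2fc
        eff30[g] = eff
        eff21[g] = eff if eff_rng.random() < config.p21_effect_prob else 0.0
        if g in target_ids:
            classes[g] = "rfx2_like" if down_gene else "declining"
    cls_rng = substream(config.seed, "profile_classes")
    for gene in genes:
        g = gene.gene_id
        if g in classes:
            continue
        u = cls_rng.random()
        classes[g] = "flat" if u < 0.7 else ("rfx2_like" if u < 0.85 else "declining")

    regulon = RegulonSpec(
        target_gene_ids=target_ids,
        planted_site_offsets=offsets,
        effect_log2fc_p21=eff21,
        effect_log2fc_p30=eff30,
        profile_class=classes,
        indirect_gene_ids=indirect_ids,
    )
    sequences = {c: seqs[c].decode() for c in seqs}
    return annotation, sequences, regulon


def _sample_site(consensus: str, rng: np.random.Generator, fidelity: float = 0.85) -> str:
    """Sample a site from a consensus-dominated PWM (per-base fidelity)."""
    out = []
    for b in consensus:
        if rng.random() < fidelity:
            out.append(b)
        else:
            out.append("ACGT"[rng.integers(0, 4)])
    return "".join(out)


def planted_site_interval(annotation: GenomeAnnotation, gene_id: str, offset: int,
                          motif_len: int) -> Tuple[str, int, int]:
    """Genomic half-open interval of a planted site given its TSS offset."""
    gene = annotation.gene(gene_id)
    if gene.strand == "+":
        start = gene.tss + offset
    else:
        start = gene.tss - offset - (motif_len - 1)
    return gene.chrom, start, start + motif_len


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def simulate_chip_coverage(annotation: GenomeAnnotation, regulon: RegulonSpec,
                           config: SimulationConfig):
    """Simulate binned IP replicates and one input track.

    Input bins are Poisson(depth); IP bins are Poisson(depth * enrichment)
    where the bin overlaps a planted site and Poisson(depth) elsewhere.

    Returns (list of IP CoverageTracks, input CoverageTrack).
    """
    if config.n_ip_reps < 2:
        raise ValueError("need >= 2 IP replicates")
    L = len(config.motif_consensus)
    enriched: Dict[str, np.ndarray] = {
        c: np.zeros(-(-length // config.bin_size), dtype=bool)
        for c, length in annotation.chrom_lengths.items()
    }
    for g, off in regulon.planted_site_offsets.items():
        chrom, s, e = planted_site_interval(annotation, g, off, L)
        enriched[chrom][s // config.bin_size : (e - 1) // config.bin_size + 1] = True

    def draw(name: str, enrich: bool) -> CoverageTrack:
        rng = substream(config.seed, name)
        counts = {}
        for chrom in sorted(annotation.chrom_lengths):
            lam = np.full(enriched[chrom].shape, config.chip_depth)
            if enrich:
                lam[enriched[chrom]] *= config.chip_enrichment
            counts[chrom] = rng.poisson(lam)
        return CoverageTrack(bin_size=config.bin_size, counts=counts,
                             chrom_lengths=dict(annotation.chrom_lengths))

    ip_tracks = [draw(f"chip:ip{r + 1}", True) for r in range(config.n_ip_reps)]
    input_track = draw("chip:input", False)
    return ip_tracks, input_track


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "KO"):
        for age in ("P21", "P30"):
            for r in range(1, config.n_reps_rna + 1):
                rows.append({"sample": f"{genotype}_{age}_r{r}",
                             "genotype": genotype, "age": age, "replicate": r})
    return pd.DataFrame(rows)


def simulate_counts(annotation: GenomeAnnotation, regulon: RegulonSpec,
                    config: SimulationConfig):
    """NB counts for genes x (genotype x age x replicate) samples.

    Per gene g and sample s: counts ~ NB(mean = mu_g * 2^effect * lib_s,
    dispersion alpha), with the planned effect applied only in knockout
    samples at the matching age.

    Returns (counts DataFrame indexed by gene, sample sheet DataFrame).
    """
    meta = sample_table(config)
    n_samples = len(meta)
    libs = np.asarray(config.library_sizes if config.library_sizes is not None
                      else np.ones(n_samples), dtype=float)
    if len(libs) != n_samples or np.any(libs <= 0):
        raise ValueError(f"library_sizes must be {n_samples} positive values")

    rng = substream(config.seed, "rnaseq")
    gene_ids = annotation.gene_ids
    base = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                             len(gene_ids))
    alpha = config.nb_dispersion
    r = 1.0 / alpha

    eff = {"P21": regulon.effect_log2fc_p21, "P30": regulon.effect_log2fc_p30}
    mat = np.zeros((len(gene_ids), n_samples), dtype=np.int64)
    for j, row in enumerate(meta.itertuples(index=False)):
        mu = base * libs[j]
        if row.genotype == "KO":
            fold = np.array([2.0 ** eff[row.age].get(g, 0.0) for g in gene_ids])
            mu = mu * fold
        mat[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"),
                          columns=meta["sample"].tolist())
    return counts, meta


# ---------------------------------------------------------------------------
# Developmental time course
# ---------------------------------------------------------------------------

def reference_trajectory(timepoints: Sequence[int]) -> np.ndarray:
    """The regulator-like rising trajectory (RPKM vs postnatal day).

    A logistic rise with half-maximum near day 19, i.e. a sharp increase
    between days 17 and 21, plateauing by day 30.
    """
    t = np.asarray(timepoints, dtype=float)
    return 1.0 + 49.0 / (1.0 + np.exp(-(t - 19.0) / 1.2))


def simulate_dev_profiles(annotation: GenomeAnnotation, regulon: RegulonSpec,
                          config: SimulationConfig) -> pd.DataFrame:
    """Per-gene RPKM across the postnatal time course.

    rfx2_like genes follow the reference rise, flat genes are constant,
    declining genes mirror the rise; all have multiplicative log-normal
    noise. A configurable fraction of background genes is scaled below the
    reliability floor to exercise the not-evaluable path.
    """
    t = np.asarray(config.timepoints, dtype=float)
    ref = reference_trajectory(t)
    dec = ref[::-1].copy()
    rng = substream(config.seed, "profiles")
    rows = []
    targets = regulon.target_gene_ids
    for g in annotation.gene_ids:
        cls = regulon.profile_class[g]
        scale = float(2.0 ** rng.normal(3.0, 1.0))  # median ~8 RPKM
        if g not in targets and rng.random() < config.low_expression_frac:
            scale *= 0.01
        if cls == "rfx2_like":
            shape = ref / ref.max()
        elif cls == "declining":
            shape = dec / dec.max()
        else:
            shape = np.ones_like(ref)
        noise = np.exp(rng.normal(0.0, config.profile_noise_sd, len(t))) \
            if config.profile_noise_sd > 0 else 1.0
        rows.append([g] + list(scale * shape * noise))
    cols = ["gene"] + [f"P{int(d)}" for d in config.timepoints]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Cilia evidence
# ---------------------------------------------------------------------------

def simulate_cilia_evidence(annotation: GenomeAnnotation, regulon: RegulonSpec,
                            config: SimulationConfig) -> pd.DataFrame:
    """Gold-list membership and low/medium/high citation counts per gene.

    Regulon genes are cilia-positive at the configured rate; every positive
    gene satisfies the calling rule (gold OR >= 1 high-confidence citation).
    """
    for frac in (config.cilia_target_frac, config.cilia_background_frac):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("cilia fractions must lie in [0, 1]")
    rng = substream(config.seed, "cilia")
    rows = []
    for g in annotation.gene_ids:
        frac = (config.cilia_target_frac if g in regulon.target_gene_ids
                else config.cilia_background_frac)
        positive = rng.random() < frac
        if positive:
            gold = bool(rng.random() < 0.5)
            high = int(rng.poisson(2.0))
            if not gold and high == 0:
                high = 1
        else:
            gold, high = False, 0
        rows.append({"gene": g, "gold": gold, "low": int(rng.poisson(1.0)),
                     "medium": int(rng.poisson(0.5)), "high": high})
    return pd.DataFrame(rows, columns=["gene", "gold", "low", "medium", "high"])
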