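"""Readers and writers for the standard formats the pipeline touches.

Conventions: everything internal is 0-based half-open. GFF3 (1-based,
closed) is converted at this boundary; BED-family formats pass through
unchanged. All tabular outputs carry a header row with a stable column
order so reruns are byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .models import CoverageTrack, GeneModel, GenomeAnnotation, Peak

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write gene/exon features as GFF3 (1-based, closed coordinates)."""
    lines = ["##gff-version 3"]
    for chrom in sorted(annotation.chrom_lengths):
        lines.append(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}")
    for g in annotation.genes:
        lines.append(
            "\t".join(
                [g.chrom, "ciliareg", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chrom, "ciliareg", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path) -> GenomeAnnotation:
    """Parse gene/exon GFF3 back into a GenomeAnnotation.

    Raises ValueError with the offending line number on malformed records
    (unknown strand, exon outside its gene span, bad coordinates).
    """
    chrom_lengths: Dict[str, int] = {}
    gene_rows: Dict[str, dict] = {}
    exon_rows: Dict[str, List[tuple]] = {}
    order: List[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if raw.startswith("##sequence-region"):
            _, chrom, _start, end = raw.split()
            chrom_lengths[chrom] = int(end)
            continue
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        start, end = int(start1) - 1, int(end1)  # to 0-based half-open
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: bad coordinates")
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        if ftype == "gene":
            gid = attr["ID"]
            gene_rows[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            order.append(gid)
        elif ftype == "exon":
            parent = attr["Parent"]
            exon_rows.setdefault(parent, []).append((start, end, lineno))
    genes = []
    for gid in order:
        row = gene_rows[gid]
        exons = sorted(exon_rows.get(gid, []))
        for s, e, lineno in exons:
            if s < row["start"] or e > row["end"]:
                raise ValueError(f"{path}:{lineno}: exon outside gene span of {gid}")
        genes.append(
            GeneModel(
                gene_id=gid, chrom=row["chrom"], strand=row["strand"],
                exons=tuple((s, e) for s, e, _ in exons) or ((row["start"], row["end"]),),
            )
        )
    if not chrom_lengths:
        # fall back to max end per chromosome when no sequence-region pragmas
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Read a whole FASTA into memory (indexed access via pyfaidx)."""
    fa = Fasta(str(path), rebuild=True, build_index=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            {
                "chrom": p.chrom, "start": p.start, "end": p.end,
                "name": p.name or f"peak_{i + 1}", "score": 0, "strand": ".",
                "signalValue": round(p.enrichment, 6),
                "pValue": round(-np.log10(max(p.p_value, 1e-300)), 6),
                "qValue": -1, "peak": p.summit - p.start,
            }
        )
    pd.DataFrame(rows, columns=NARROWPEAK_COLS).to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT
    )


def read_narrowpeak(path) -> List[Peak]:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLS,
                     dtype={"chrom": str})
    peaks = []
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(f"{path}: start >= end for {row.name}")
        summit_off = int(row.peak)
        summit = (row.start + row.end) // 2 if summit_off == -1 else row.start + summit_off
        if not (row.start <= summit < row.end):
            raise ValueError(f"{path}: summit outside peak for {row.name}")
        peaks.append(
            Peak(chrom=row.chrom, start=int(row.start), end=int(row.end),
                 summit=summit, enrichment=float(row.signalValue),
                 p_value=float(10 ** (-row.pValue)), name=str(row.name))
        )
    return peaks


def read_bed(path) -> List[tuple]:
    """Read BED3+ intervals as (chrom, start, end[, name]) tuples."""
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw or raw.startswith(("#", "track", "browser")):
            continue
        fields = raw.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        out.append((chrom, start, end) + tuple(fields[3:4]))
    return out


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            counts = track.counts[chrom]
            length = track.chrom_lengths[chrom]
            for i, v in enumerate(counts):
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{int(v)}\n")


def read_bedgraph(path, bin_size: Optional[int] = None,
                  chrom_lengths: Optional[Dict[str, int]] = None) -> CoverageTrack:
    """Read a uniformly binned bedGraph; overlapping bins are rejected."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).max())
    counts: Dict[str, np.ndarray] = {}
    lengths: Dict[str, int] = dict(chrom_lengths or {})
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping bedGraph bins on {chrom}")
        if np.any(starts % bin_size):
            raise ValueError(f"{path}: bins not aligned to {bin_size} bp on {chrom}")
        length = lengths.get(chrom, int(ends.max()))
        lengths[chrom] = length
        n_bins = -(-length // bin_size)
        arr = np.zeros(n_bins, dtype=np.int64)
        arr[starts // bin_size] = sub["value"].to_numpy()
        counts[str(chrom)] = arr
    return CoverageTrack(bin_size=bin_size, counts=counts, chrom_lengths=lengths)


# ---------------------------------------------------------------------------
# TSV / JSON helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
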