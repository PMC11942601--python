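"""ROH incidence, consensus ROH, and percentile-defined ROH islands.

The incidence track counts, per SNP, how many individuals carry a ROH over
that position. Consensus ROH are maximal runs of SNPs shared by at least a
stated fraction of individuals; ROH islands are runs whose incidence strictly
exceeds a genome-wide percentile (the candidate-selection-signature regions).
Regions can be annotated by interval overlap against a user-supplied gene
file (GFF3 or BED); no online lookups are performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import MarkerMap
from .roh import RohSegment

#: Consensus sharing thresholds reported for draught-horse panels.
DEFAULT_CONSENSUS_THRESHOLDS = (0.20, 0.25, 0.30, 0.40, 0.45)


@dataclass
class IncidenceTrack:
    """Per-SNP ROH coverage: count and fraction of individuals."""

    df: pd.DataFrame  # columns: chrom, pos_bp, count, fraction
    n_indiv: int


@dataclass
class IslandRegion:
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    kind: str  # "percentile_island" or "consensus_roh(<threshold>)"
    genes: list[str] | None = None

    @property
    def n_genes(self) -> int | None:
        return None if self.genes is None else len(self.genes)


def incidence(segments: list[RohSegment], markers: MarkerMap, n_indiv: int) -> IncidenceTrack:
    """Count, per SNP, the individuals whose ROH cover its position.

    A SNP is covered by a segment when its position lies within
    [start_bp, end_bp]; an individual counts at most once per SNP (segments
    of one individual never overlap).
    """
    counts = np.zeros(markers.n_snps, dtype=np.int64)
    chroms = markers.chroms
    pos = markers.positions
    # per-chromosome position index for searchsorted
    chrom_slices = {}
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        chrom_slices[int(chrom)] = (idx[0], pos[idx])
    for s in segments:
        if s.chrom not in chrom_slices:
            continue
        off, p = chrom_slices[s.chrom]
        a = np.searchsorted(p, s.start_bp, side="left")
        b = np.searchsorted(p, s.end_bp, side="right")
        counts[off + a: off + b] += 1
    df = pd.DataFrame({
        "chrom": chroms, "pos_bp": pos, "count": counts,
        "fraction": counts / n_indiv if n_indiv else 0.0,
    })
    return IncidenceTrack(df=df, n_indiv=n_indiv)


def _regions_from_mask(track: IncidenceTrack, mask: np.ndarray, kind: str,
                       max_bridge: int = 0) -> list[IslandRegion]:
    """Maximal qualifying runs per chromosome; gaps of ≤ max_bridge SNPs merged."""
    out = []
    df = track.df
    chroms = df["chrom"].to_numpy()
    pos = df["pos_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        m = mask[sel]
        p = pos[sel]
        runs = []
        start = None
        for j, ok in enumerate(m):
            if ok and start is None:
                start = j
            elif not ok and start is not None:
                runs.append((start, j - 1))
                start = None
        if start is not None:
            runs.append((start, len(m) - 1))
        if max_bridge > 0 and len(runs) > 1:
            merged = [runs[0]]
            for a, b in runs[1:]:
                if a - merged[-1][1] - 1 <= max_bridge:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
            runs = merged
        for a, b in runs:
            out.append(IslandRegion(
                chrom=int(chrom), start_bp=int(p[a]), end_bp=int(p[b]),
                n_snps=b - a + 1, kind=kind,
            ))
    return out


def consensus_roh(track: IncidenceTrack, threshold_fraction: float) -> list[IslandRegion]:
    """Maximal runs of SNPs whose ROH-sharing fraction is ≥ threshold."""
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    mask = track.df["fraction"].to_numpy() >= threshold_fraction
    return _regions_from_mask(track, mask, f"consensus_roh({threshold_fraction:g})")


def percentile_islands(track: IncidenceTrack, percentile: float = 99.0,
                       max_bridge: int = 0) -> list[IslandRegion]:
    """Runs of SNPs whose incidence strictly exceeds the genome-wide percentile.

    The percentile is computed over per-SNP incidence counts with linear
    interpolation. A degenerate (constant) incidence distribution yields no
    islands, with a warning.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    counts = track.df["count"].to_numpy()
    cut = np.percentile(counts, percentile)
    if counts.max() == counts.min():
        warnings.warn("incidence distribution is constant; no islands")
        return []
    mask = counts > cut
    return _regions_from_mask(track, mask, "percentile_island", max_bridge=max_bridge)


# ---------------------------------------------------------------------------
# Annotation by local file join
# ---------------------------------------------------------------------------

def _read_annotation(path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED into (chrom, start_bp, end_bp, gene)."""
    path = Path(path)
    rows = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2].lower() != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}-{f[4]}"
                rows.append((int(f[0]), int(f[3]), int(f[4]), name))
    else:  # BED: 0-based half-open
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                f = line.split()
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                rows.append((int(f[0]), int(f[1]) + 1, int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "gene"])


def annotate(regions: list[IslandRegion], annotation_file) -> list[IslandRegion]:
    """Attach the genes overlapping each region (each gene id counted once).

    If the annotation file is missing, regions are returned unannotated with
    a warning.
    """
    if annotation_file is None or not Path(annotation_file).exists():
        warnings.warn(f"annotation file {annotation_file!r} not found; regions left unannotated")
        return regions
    ann = _read_annotation(annotation_file)
    for r in regions:
        hit = ann[(ann["chrom"] == r.chrom)
                  & (ann["start_bp"] <= r.end_bp)
                  & (ann["end_bp"] >= r.start_bp)]
        r.genes = sorted(hit["gene"].unique())
    return regions


def regions_to_frame(regions: list[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
         "n_snps": r.n_snps, "n_genes": r.n_genes, "kind": r.kind,
         "genes": ";".join(r.genes) if r.genes else ""}
        for r in regions
    ], columns=["chrom", "start_bp", "end_bp", "n_snps", "n_genes", "kind", "genes"])


def write_regions_bed(regions: list[IslandRegion], path) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.kind}\t{r.n_snps}\n")
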