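"""Runs-of-homozygosity calibration and detection.

Detection follows the overlapping-window scheme popularised by PLINK's
``--homozyg``: every window of ``window_snps`` consecutive SNPs is scored
homozygous if it holds at most ``max_het_in_window`` heterozygous and
``max_missing_in_window`` missing calls; a SNP becomes ROH-eligible when the
fraction of windows covering it that scored homozygous reaches
``window_hit_fraction``; maximal runs of eligible SNPs, trimmed so that no
run starts or ends on a heterozygous or missing call, are then emitted as
segments subject to minimum SNP count, minimum length, SNP density and
maximum-gap constraints.

The minimum SNP count is calibrated from the data so that, genome- and
cohort-wide, a run of that many homozygous SNPs arises by chance with
probability below a chosen type-I error rate:

    l = floor( ln(alpha / (n_snps * n_indiv)) / ln(1 - het_mean) )

and the matching minimum segment length is ``l`` times the mean inter-SNP
spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix

#: Half-open length classes (Mb) used for the length distribution; the first
#: class starts at the calibrated minimum length (~2.2 Mb), so its label "2-4"
#: is nominal.
LENGTH_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("2-4", 0.0, 4.0),
    ("4-8", 4.0, 8.0),
    ("8-16", 8.0, 16.0),
    ("16-32", 16.0, 32.0),
    (">32", 32.0, math.inf),
)


@dataclass(frozen=True)
class RohParams:
    """Window and segment constraints for ROH detection (lengths in kb)."""

    window_snps: int = 15
    max_het_in_window: int = 1
    max_missing_in_window: int = 1
    min_snps_in_roh: int = 64
    min_length_kb: float = 2230.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 500.0
    window_hit_fraction: float = 0.05

    def __post_init__(self):
        if self.min_snps_in_roh < 2:
            raise ValueError("min_snps_in_roh must be >= 2")
        if self.min_length_kb <= 0:
            raise ValueError("min_length_kb must be positive")
        if not 0 < self.window_hit_fraction <= 1:
            raise ValueError("window_hit_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run; positions are 1-based inclusive SNP positions."""

    individual: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def min_snp_count(
    alpha: float, het_mean: float, n_snps: int, n_indiv: int, mean_spacing_kb: float | None = None
) -> tuple[int, float | None]:
    """Calibrate the minimum homozygous-SNP count (and length) for a ROH.

    Returns ``(l, min_length_kb)``; the length is ``None`` unless
    ``mean_spacing_kb`` is given, in which case it is ``l * spacing`` rounded
    to whole kb. The count is floored: a run must include *at least* that many
    SNPs to beat the multiple-testing-corrected chance level.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if not (0 < het_mean < 1):
        raise ValueError("het_mean must lie strictly between 0 and 1")
    if n_snps <= 0 or n_indiv <= 0:
        raise ValueError("n_snps and n_indiv must be positive")
    l = math.floor(math.log(alpha / (n_snps * n_indiv)) / math.log(1.0 - het_mean))
    min_len = round(l * mean_spacing_kb) if mean_spacing_kb is not None else None
    return l, min_len


def params_from_data(
    alpha: float, het_mean: float, n_snps: int, n_indiv: int, mean_spacing_kb: float, **overrides
) -> RohParams:
    """Build :class:`RohParams` with the calibrated SNP count and length."""
    l, min_len = min_snp_count(alpha, het_mean, n_snps, n_indiv, mean_spacing_kb)
    params = RohParams(min_snps_in_roh=max(l, 2), min_length_kb=float(min_len))
    return replace(params, **overrides) if overrides else params


def _eligible_snps(geno: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean ROH-eligibility per SNP for one individual on one chromosome."""
    n = geno.size
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)

    def winsum(x):
        c = np.concatenate(([0], np.cumsum(x)))
        return c[w:] - c[:-w]

    win_ok = (winsum(het) <= params.max_het_in_window) & (winsum(mis) <= params.max_missing_in_window)
    # windows covering SNP j are those starting in [j-w+1, j] clipped to [0, n-w]
    n_win = n - w + 1
    cum = np.concatenate(([0], np.cumsum(win_ok.astype(np.int64))))
    j = np.arange(n)
    lo = np.clip(j - w + 1, 0, n_win - 1)
    hi = np.clip(j, 0, n_win - 1)
    hits = cum[hi + 1] - cum[lo]
    denom = hi - lo + 1
    return hits / denom >= params.window_hit_fraction


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs of maximal True runs."""
    if mask.size == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    yield from zip(starts, ends)


def detect_roh(gm: GenotypeMatrix, params: RohParams) -> list[RohSegment]:
    """Detect ROH segments for every individual and autosome in ``gm``.

    Chromosomes with fewer SNPs than the window size yield no segments.
    Runs are split wherever adjacent eligible SNPs are more than
    ``max_gap_kb`` apart, then filtered on SNP count, length and density
    (mean kb per SNP within the segment).
    """
    segments: list[RohSegment] = []
    mdf = gm.markers.df
    chrom_arr = gm.markers.chroms
    pos_all = gm.markers.positions
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    for chrom in pd.unique(mdf["chrom"]):
        idx = np.nonzero(chrom_arr == chrom)[0]
        pos = pos_all[idx]
        gap_split = np.nonzero(np.diff(pos) > max_gap_bp)[0]  # split after these offsets
        for i, indiv in enumerate(gm.samples):
            geno = gm.calls[i, idx]
            elig = _eligible_snps(geno, params)
            for s, e in _runs(elig):
                # split the run at oversized gaps
                cuts = gap_split[(gap_split >= s) & (gap_split < e)]
                bounds = [s] + [int(c) + 1 for c in cuts] + [e + 1]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    b -= 1
                    # a run never starts or ends on a het or missing call
                    while a <= b and geno[a] != 0 and geno[a] != 2:
                        a += 1
                    while b >= a and geno[b] != 0 and geno[b] != 2:
                        b -= 1
                    if b < a:
                        continue
                    n_snps = b - a + 1
                    length = int(pos[b] - pos[a] + 1)
                    if n_snps < params.min_snps_in_roh:
                        continue
                    if length < min_len_bp:
                        continue
                    if length / n_snps > params.min_density_kb_per_snp * 1000.0:
                        continue
                    segments.append(RohSegment(indiv, int(chrom), int(pos[a]), int(pos[b]), n_snps))
    return segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp / 1e3) for s in segments],
        columns=["individual", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def classify_lengths(segments: list[RohSegment], by_chrom: bool = False) -> pd.DataFrame:
    """Count segments and mean/SD length per length class (optionally per chromosome).

    Percentages are of the total segment count and sum to 100 when any
    segments exist.
    """
    df = segments_to_frame(segments)
    df["length_mb"] = df["length_kb"] / 1e3 if len(df) else pd.Series(dtype=float)
    rows = []
    groups = df.groupby("chrom") if by_chrom and len(df) else [(None, df)]
    for chrom, sub in groups:
        total = len(sub)
        for label, lo, hi in LENGTH_CLASSES:
            sel = sub[(sub["length_mb"] >= lo) & (sub["length_mb"] < hi)] if total else sub
            n = len(sel)
            rows.append({
                "chrom": chrom,
                "length_class": label,
                "n_roh": n,
                "percent": 100.0 * n / total if total else 0.0,
                "mean_length_mb": sel["length_mb"].mean() if n else 0.0,
                "sd_length_mb": sel["length_mb"].std(ddof=1) if n > 1 else 0.0,
                "min_length_mb": sel["length_mb"].min() if n else 0.0,
                "max_length_mb": sel["length_mb"].max() if n else 0.0,
            })
    out = pd.DataFrame(rows)
    return out.drop(columns=["chrom"]) if not by_chrom else out


def per_individual_stats(segments: list[RohSegment], individuals: list[str]) -> pd.DataFrame:
    """Number, mean length and combined length (Mb) of ROH per individual.

    Individuals without segments report zeros.
    """
    df = segments_to_frame(segments)
    out = pd.DataFrame(index=pd.Index(individuals, name="individual"))
    if len(df):
        grp = df.groupby("individual")["length_kb"]
        out["n_roh"] = grp.size()
        out["mean_length_mb"] = grp.mean() / 1e3
        out["combined_length_mb"] = grp.sum() / 1e3
    else:
        out["n_roh"] = 0.0
        out["mean_length_mb"] = 0.0
        out["combined_length_mb"] = 0.0
    return out.fillna(0.0)


def write_segments_tsv(segments: list[RohSegment], path, params: RohParams | None = None) -> None:
    """Export segments as TSV with a provenance header echoing the parameters."""
    with open(path, "w") as fh:
        if params is not None:
            fh.write(f"# {params!r}\n")
        segments_to_frame(segments).to_csv(fh, sep="\t", index=False)


def write_segments_bed(segments: list[RohSegment], path) -> None:
    """Export segments as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.individual}\t{s.n_snps}\n")
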