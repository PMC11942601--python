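"""Effective population size from LD decay and from ROH closed forms.

The LD route bins squared dosage correlations (r²) of intra-chromosomal SNP
pairs by physical distance. With c the recombination distance in Morgans
(1 Morgan ≈ 100 Mb), each bin dates to t = 1/(2c) generations ago and yields

    Ne = (1 − r²) / (4 c r²),        ΔF = 1 / (2 Ne)   (Sved's relation).

The ROH route converts a mean genome fraction in ROH above a length cutoff
into a rate of inbreeding over the generations that cutoff captures:

    ΔF = 1 − (1 − F_ROH)^(1/(GE−1)),  Ne = 1/(2 ΔF),

with the generation horizon of a cutoff L (in Mb ≈ cM) given by g = 100/(2L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix

BP_PER_MORGAN = 100_000_000  # 1 cM/Mb genome-wide average

#: Generation horizons used with mean F_ROH at the standard length cutoffs
#: (all ROH, >4, >8, >16, >32 Mb). All but the first follow g = 100/(2L).
ROH_GE_CONSTANTS: dict[str, float] = {
    "all": 15.6691,
    ">4": 12.5,
    ">8": 6.25,
    ">16": 3.125,
    ">32": 1.5625,
}

#: Birth-year cohort boundaries: labels and (lo, hi) inclusive year ranges.
DEFAULT_COHORTS: tuple[tuple[str, float, float], ...] = (
    ("<=2007", -np.inf, 2007),
    ("2008-2011", 2008, 2011),
    ("2012-2015", 2012, 2015),
    ("2016-2019", 2016, 2019),
    (">=2020", 2020, np.inf),
)


def _pairwise_complete_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP columns, pairwise-complete."""
    x = calls.astype(np.float64)
    m = (calls != MISSING).astype(np.float64)
    x = x * m  # zero out missing
    n = m.T @ m
    sx = x.T @ m
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = n * sxx - sx**2
        denom = var * var.T
        r2 = np.where(denom > 0, cov**2 / np.where(denom > 0, denom, 1), np.nan)
    return r2


def pairwise_r2(
    gm: GenotypeMatrix, min_bp: float = 1_000, max_bp: float = 50_000_000
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and r² for all intra-chromosomal SNP pairs within a bp range.

    r² is the squared Pearson correlation of genotype dosages over individuals
    complete for both SNPs (no sample-size correction). Pairs involving a
    zero-variance SNP are skipped.
    """
    dists, r2s = [], []
    chroms = gm.markers.chroms
    pos = gm.markers.positions
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        if idx.size < 2:
            continue
        r2 = _pairwise_complete_r2(gm.calls[:, idx])
        p = pos[idx].astype(np.int64)
        d = np.abs(p[:, None] - p[None, :])
        iu = np.triu_indices(idx.size, k=1)
        d, r2 = d[iu], r2[iu]
        keep = (d >= min_bp) & (d <= max_bp) & np.isfinite(r2)
        dists.append(d[keep])
        r2s.append(r2[keep])
    if not dists:
        return np.array([], dtype=np.int64), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def default_bin_edges(
    min_bp: float = 10_000, max_bp: float = 50_000_000,
    start_width: float = 10_000, cap_width: float = 100_000, growth: float = 1.25,
) -> np.ndarray:
    """Distance-bin edges: widths grow geometrically from 10 kb, capped at 100 kb."""
    edges = [float(min_bp)]
    width = float(start_width)
    while edges[-1] < max_bp:
        edges.append(min(edges[-1] + width, float(max_bp)))
        width = min(width * growth, cap_width)
    return np.array(edges)


def bin_and_estimate(
    dists: np.ndarray, r2s: np.ndarray, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Mean r² per distance bin with c, generations, Ne and ΔF per bin.

    Empty bins are kept with ``n_pairs`` 0 and NaN estimates; r² of exactly 1
    yields Ne = 0 (the no-recombination limit).
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(dists, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        mean_r2 = float(r2s[sel].mean()) if n else np.nan
        mid = 0.5 * (bin_edges[b] + bin_edges[b + 1])
        c = mid / BP_PER_MORGAN
        t = 1.0 / (2.0 * c)
        if n and mean_r2 > 0:
            ne = (1.0 - mean_r2) / (4.0 * c * mean_r2)
            delta_f = 1.0 / (2.0 * ne) if ne > 0 else np.nan
        else:
            ne, delta_f = np.nan, np.nan
        rows.append({
            "dist_lo": bin_edges[b], "dist_hi": bin_edges[b + 1], "n_pairs": n,
            "mean_r2": mean_r2, "c_morgan": c, "t_generations": t,
            "ne": ne, "delta_f": delta_f,
        })
    return pd.DataFrame(rows)


def ld_ne_trajectory(gm: GenotypeMatrix, bin_edges=None, min_bp=1_000, max_bp=50_000_000) -> pd.DataFrame:
    """Convenience: r² pairs → binned Ne/ΔF trajectory for one genotype matrix."""
    d, r = pairwise_r2(gm, min_bp=min_bp, max_bp=max_bp)
    return bin_and_estimate(d, r, bin_edges)


# ---------------------------------------------------------------------------
# ROH-based closed forms
# ---------------------------------------------------------------------------

def delta_f_from_f(f: float, ge: float) -> float:
    """ΔF = 1 − (1 − F)^(1/(GE−1)); requires GE > 1."""
    if not 0 <= f < 1:
        raise ValueError("F must lie in [0, 1)")
    if ge <= 1:
        raise ValueError("GE must exceed 1")
    return 1.0 - (1.0 - f) ** (1.0 / (ge - 1.0))


def ne_from_delta_f(delta_f: float, digits: int | None = None) -> float:
    """Ne = 1/(2 ΔF); optionally rounded to ``digits`` decimals."""
    if delta_f <= 0:
        raise ValueError("delta_f must be positive")
    ne = 1.0 / (2.0 * delta_f)
    return round(ne, digits) if digits is not None else ne


def ne_from_roh_means(
    f_roh_means: dict[str, float], ge_constants: dict[str, float] = ROH_GE_CONSTANTS
) -> pd.DataFrame:
    """ΔF_ROH and Ne_ROH for each length-cutoff mean F_ROH.

    A mean of 0 yields ΔF 0 and an undefined (NaN) Ne.
    """
    rows = []
    for label, f in f_roh_means.items():
        ge = ge_constants[label]
        if f == 0:
            rows.append({"threshold": label, "f_roh_mean": f, "ge_roh": ge,
                         "delta_f_roh": 0.0, "ne_roh": np.nan})
            continue
        df = delta_f_from_f(f, ge)
        rows.append({"threshold": label, "f_roh_mean": f, "ge_roh": ge,
                     "delta_f_roh": df, "ne_roh": ne_from_delta_f(df)})
    return pd.DataFrame(rows)


def generations_from_length(len_mb: float) -> float:
    """Age (generations) of inbreeding captured by ROH of length L: g = 100/(2L)."""
    if len_mb <= 0:
        raise ValueError("length must be positive")
    return 100.0 / (2.0 * len_mb)


def length_from_generations(g: float) -> float:
    """ROH length (Mb) dating to g generations ago: L = 100/(2g)."""
    if g <= 0:
        raise ValueError("generations must be positive")
    return 100.0 / (2.0 * g)


def decline_rate(ne_a: float, ne_b: float, gen_a: float, gen_b: float, span: float | None = None) -> float:
    """Per-generation Ne decline between generations a > b: (Ne_a − Ne_b)/span.

    ``span`` defaults to (a − b); pass it explicitly to express the drop over
    a different number of steps (e.g. a whole listed cohort of generations).
    """
    if span is None:
        span = gen_a - gen_b
    if span <= 0:
        raise ValueError("generation span must be positive")
    return (ne_a - ne_b) / span


def assign_cohorts(birth_years: pd.Series, cohorts=DEFAULT_COHORTS) -> pd.Series:
    """Map birth years to cohort labels (NaN years → None)."""
    def label(y):
        if pd.isna(y):
            return None
        for name, lo, hi in cohorts:
            if lo <= y <= hi:
                return name
        return None
    return birth_years.map(label)


def trend_report(
    gm: GenotypeMatrix, birth_years: pd.Series, bin_edges=None,
    cohorts=DEFAULT_COHORTS, min_cohort_size: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-cohort Ne/ΔF trajectories from LD within each birth-year cohort.

    Cohorts with fewer than ``min_cohort_size`` genotyped individuals are
    skipped with a warning.
    """
    labels = assign_cohorts(birth_years.reindex(gm.samples), cohorts)
    out = {}
    for name, _, _ in cohorts:
        members = [s for s in gm.samples if labels.get(s) == name]
        if len(members) < min_cohort_size:
            warnings.warn(f"cohort {name}: only {len(members)} genotyped individuals; skipped")
            continue
        sub = gm.subset(sample_idx=[gm.samples.index(s) for s in members])
        out[name] = ld_ne_trajectory(sub, bin_edges)
    return out
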