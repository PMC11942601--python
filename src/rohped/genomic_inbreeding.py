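"""SNP-based inbreeding coefficients.

* ``f_roh`` — fraction of the SNP-covered autosomal genome inside ROH
  (McQuillan-style), overall, above a length threshold, or within a length
  class.
* ``f_hom`` — fraction of non-missing calls that are homozygous.
* ``f_is`` — individual excess of homozygosity relative to Hardy–Weinberg
  expectation at sample allele frequencies.
* ``f_hat`` — the three GCTA/Yang SNP-based estimators (variance-based,
  excess-homozygosity, and correlation-between-uniting-gametes forms).

Allele frequencies are always estimated from the full post-QC sample,
including the focal individual.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix
from .roh import LENGTH_CLASSES, RohSegment

#: Autosomal length covered by SNPs in the reference horse panel (bp); used
#: as the default F_ROH denominator when no matrix is at hand.
DEFAULT_L_AUTO_BP = 2_241_761_617

#: Default "recent inbreeding" thresholds (Mb). 6.739 Mb is 100/(2*GE) for a
#: pedigree depth of GE = 7.42 equivalent generations; see
#: :func:`rohped.popsize.length_from_generations`.
GT_THRESHOLDS_MB = (4.0, 6.739, 8.0, 16.0, 32.0)


def f_roh(
    segments: list[RohSegment],
    individuals: list[str],
    l_auto_bp: float = DEFAULT_L_AUTO_BP,
    min_len_mb: float = 0.0,
    max_len_mb: float = math.inf,
) -> pd.Series:
    """Per-individual genome fraction in ROH of length in [min_len_mb, max_len_mb).

    ``l_auto_bp`` is the SNP-covered autosomal length used as denominator.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    if min_len_mb < 0:
        raise ValueError("length threshold must be non-negative")
    total = dict.fromkeys(individuals, 0.0)
    for s in segments:
        if min_len_mb <= s.length_mb < max_len_mb and s.individual in total:
            total[s.individual] += s.length_bp
    return pd.Series({k: v / l_auto_bp for k, v in total.items()}, name="f_roh")


def f_roh_table(
    segments: list[RohSegment],
    individuals: list[str],
    l_auto_bp: float = DEFAULT_L_AUTO_BP,
    gt_thresholds_mb: tuple[float, ...] = GT_THRESHOLDS_MB,
) -> pd.DataFrame:
    """All F_ROH variants per individual: overall, >threshold, and per class."""
    out = {"f_roh": f_roh(segments, individuals, l_auto_bp)}
    for t in gt_thresholds_mb:
        out[f"f_roh_gt{t:g}"] = f_roh(segments, individuals, l_auto_bp, min_len_mb=t)
    for label, lo, hi in LENGTH_CLASSES:
        if math.isinf(hi):
            continue
        out[f"f_roh_{label}"] = f_roh(segments, individuals, l_auto_bp, min_len_mb=lo, max_len_mb=hi)
    return pd.DataFrame(out)


def f_hom(gm: GenotypeMatrix) -> pd.Series:
    """Homozygous fraction of non-missing calls per individual.

    Individuals with no non-missing calls are returned as NaN.
    """
    nonmiss = gm.calls != MISSING
    n_obs = nonmiss.sum(axis=1)
    hom = ((gm.calls == 0) | (gm.calls == 2)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        val = np.where(n_obs > 0, hom / np.maximum(n_obs, 1), np.nan)
    return pd.Series(val, index=gm.samples, name="f_hom")


def _allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    nonmiss = gm.calls != MISSING
    n_obs = nonmiss.sum(axis=0)
    counted = np.where(nonmiss, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_obs > 0, counted / (2 * np.maximum(n_obs, 1)), np.nan)


def f_is(gm: GenotypeMatrix) -> pd.Series:
    """Individual fixation index: 1 − observed het / expected het.

    Expected heterozygosity sums 2p(1−p) over the individual's non-missing
    SNPs, with p the sample allele frequency. Raises if the panel carries no
    polymorphic SNP.
    """
    p = _allele_freq(gm)
    exp_h = 2 * p * (1 - p)
    if np.nansum(exp_h) == 0:
        raise ValueError("panel is monomorphic; F_IS undefined")
    nonmiss = gm.calls != MISSING
    obs = ((gm.calls == 1) * nonmiss).sum(axis=1)
    exp = nonmiss @ np.nan_to_num(exp_h)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(exp > 0, 1 - obs / np.where(exp > 0, exp, 1), np.nan)
    return pd.Series(val, index=gm.samples, name="f_is")


def f_hat(gm: GenotypeMatrix) -> pd.DataFrame:
    """GCTA-style F̂1, F̂2, F̂3 per individual.

    With dosage x and sample frequency p at each SNP (monomorphic SNPs
    excluded), the per-SNP terms averaged over the individual's non-missing
    SNPs are::

        F̂1: (x − 2p)² / (2p(1−p)) − 1
        F̂2: 1 − x(2−x) / (2p(1−p))
        F̂3: (x² − (1+2p)x + 2p²) / (2p(1−p))
    """
    p = _allele_freq(gm)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; F-hat estimators undefined")
    x = gm.calls[:, poly].astype(float)
    miss = x == MISSING
    pp = p[poly]
    denom = 2 * pp * (1 - pp)

    t1 = (x - 2 * pp) ** 2 / denom - 1
    t2 = 1 - x * (2 - x) / denom
    t3 = (x**2 - (1 + 2 * pp) * x + 2 * pp**2) / denom
    for t in (t1, t2, t3):
        t[miss] = np.nan
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "f_hat1": np.nanmean(t1, axis=1),
                "f_hat2": np.nanmean(t2, axis=1),
                "f_hat3": np.nanmean(t3, axis=1),
            },
            index=gm.samples,
        )
    return out


def summary_table(coeffs: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/median/mode and 95%/75% central intervals per coefficient."""
    rows = []
    for col in coeffs.columns:
        v = coeffs[col].dropna()
        mode = v.round(3).mode()
        rows.append({
            "coefficient": col,
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "median": v.median(),
            "mode": mode.iloc[0] if len(mode) else np.nan,
            "ci95_lo": v.quantile(0.025), "ci95_hi": v.quantile(0.975),
            "ci75_lo": v.quantile(0.125), "ci75_hi": v.quantile(0.875),
        })
    return pd.DataFrame(rows).set_index("coefficient")
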