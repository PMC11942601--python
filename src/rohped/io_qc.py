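"""Genotype and pedigree input/output plus marker quality control.

Genotypes live in a :class:`GenotypeMatrix`: an (individuals x SNPs) array of
minor-allele dosages (0, 1, 2; -1 = missing) tied to a physical marker map.
The minor allele is defined within the loaded dataset; frequency ties are
broken by allele-symbol order so the coding is deterministic.

Supported formats are PLINK binary (.bed v1.00 SNP-major with .bim/.fam) and
PLINK text (.ped/.map). Pedigrees are 4-column delimited text
(id, sire, dam, birth_year) with 0/NA for unknown parents.
"""

from __future__ import annotations

import graphlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Internal dosage counts A1 (minor): 2 -> 00, -1 -> 01, 1 -> 10, 0 -> 11.
_CODE_TO_BITS = np.array([3, 2, 0], dtype=np.uint8)  # index by dosage 0,1,2
_BITS_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class FormatError(ValueError):
    """Raised when an on-disk genotype file is malformed or inconsistent."""


@dataclass
class MarkerMap:
    """Physical map of autosomal SNPs.

    ``df`` columns: chrom (int), snp_id (str), pos_bp (int, 1-based),
    a1, a2 (allele symbols; a1 is the dosage-counted allele).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with its marker map."""

    samples: list[str]
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.markers.n_snps):
            raise FormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.markers.n_snps} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def snp_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        mdf = self.markers.df
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            calls = calls[:, snp_idx]
            mdf = mdf.iloc[snp_idx]
        return GenotypeMatrix(samples=list(samples), markers=MarkerMap(mdf.copy()), calls=calls.copy())


@dataclass
class PedigreeTable:
    """Pedigree records (id, sire, dam, birth_year); None marks unknown parents."""

    df: pd.DataFrame  # columns: id, sire, dam, birth_year

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate individual id in pedigree: {dup}")
        self.validate_acyclic()

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        out = {}
        for rec in self.df.itertuples(index=False):
            out[rec.id] = (rec.sire, rec.dam)
        return out

    def validate_acyclic(self) -> list[str]:
        """Topologically sort (parents before offspring); raise on a cycle."""
        ts = graphlib.TopologicalSorter()
        known = set(self.df["id"])
        for rec in self.df.itertuples(index=False):
            preds = [p for p in (rec.sire, rec.dam) if p is not None and p in known]
            ts.add(rec.id, *preds)
        try:
            return list(ts.static_order())
        except graphlib.CycleError as exc:
            raise FormatError(f"pedigree contains a cycle: {exc.args[1]}") from exc


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

def _recode_minor(calls: np.ndarray, a1: np.ndarray, a2: np.ndarray):
    """Flip dosages so code 2 counts the within-dataset minor allele.

    Ties in allele frequency are broken by allele-symbol order (the
    lexicographically smaller symbol is counted).
    """
    calls = calls.copy()
    a1 = a1.astype(object).copy()
    a2 = a2.astype(object).copy()
    obs = np.ma.masked_equal(calls, MISSING)
    n_obs = obs.count(axis=0)
    with np.errstate(invalid="ignore"):
        freq1 = np.where(n_obs > 0, obs.sum(axis=0).filled(0) / (2 * np.maximum(n_obs, 1)), 0.5)
    tie = np.isclose(freq1, 0.5)
    symbol_flip = np.array([str(x) > str(y) for x, y in zip(a1, a2)])
    flip = (freq1 > 0.5) | (tie & symbol_flip)
    if flip.any():
        cols = calls[:, flip]
        cols = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        calls[:, flip] = cols
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    return calls, a1, a2


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam trio into a :class:`GenotypeMatrix`.

    Markers are sorted by (chrom, pos); dosages are recoded to the
    within-dataset minor allele; missing calls are preserved.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos_bp": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    n_snps, n_samples = len(bim), len(fam)

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK v1.00 SNP-major .bed file (bad magic bytes)")
    bytes_per_snp = (n_samples + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != n_snps * bytes_per_snp:
        raise FormatError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{n_snps} SNPs x {n_samples} samples from .bim/.fam"
        )
    blocks = payload.reshape(n_snps, bytes_per_snp)
    # expand 2-bit genotypes, sample-fastest within each SNP block
    shifts = np.arange(4, dtype=np.uint8) * 2
    geno2bit = (blocks[:, :, None] >> shifts[None, None, :]) & 3
    geno2bit = geno2bit.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    calls = _BITS_TO_CODE[geno2bit].T  # (samples, snps)

    order = np.lexsort((bim["pos_bp"].to_numpy(), bim["chrom"].to_numpy()))
    bim = bim.iloc[order].reset_index(drop=True)
    calls = calls[:, order]

    calls, a1, a2 = _recode_minor(calls, bim["a1"].to_numpy(), bim["a2"].to_numpy())
    mdf = pd.DataFrame(
        {"chrom": bim["chrom"], "snp_id": bim["snp_id"], "pos_bp": bim["pos_bp"], "a1": a1, "a2": a2}
    )
    markers = MarkerMap(mdf)
    markers.validate()
    return GenotypeMatrix(samples=list(fam["iid"]), markers=markers, calls=calls)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write .bed (v1.00 SNP-major), .bim and .fam files for ``gm``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mdf = gm.markers.df
    bim = pd.DataFrame(
        {"chrom": mdf["chrom"], "snp_id": mdf["snp_id"], "cm": 0,
         "pos_bp": mdf["pos_bp"], "a1": mdf["a1"], "a2": mdf["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": gm.samples, "iid": gm.samples, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_samples, n_snps = gm.calls.shape
    bits = np.where(gm.calls == MISSING, 1, _CODE_TO_BITS[np.maximum(gm.calls, 0)]).astype(np.uint8)
    bytes_per_snp = (n_samples + 3) // 4
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = bits.T
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(n_snps, bytes_per_snp, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint8
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def write_ped(gm: GenotypeMatrix, prefix) -> None:
    """Write PLINK text .ped/.map (missing alleles written as 0)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mdf = gm.markers.df
    pd.DataFrame(
        {"chrom": mdf["chrom"], "snp_id": mdf["snp_id"], "cm": 0, "pos_bp": mdf["pos_bp"]}
    ).to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)

    a1 = mdf["a1"].to_numpy(dtype=object)
    a2 = mdf["a2"].to_numpy(dtype=object)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(gm.samples):
            row = gm.calls[i]
            first = np.where(row >= 1, a1, a2)
            second = np.where(row == 2, a1, a2)
            first = np.where(row == MISSING, "0", first)
            second = np.where(row == MISSING, "0", second)
            alleles = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"{sid} {sid} 0 0 0 -9 {alleles}\n")


def read_ped(ped_path, map_path=None) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a :class:`GenotypeMatrix`."""
    ped_path = Path(ped_path)
    map_path = Path(map_path) if map_path else ped_path.with_suffix(".map")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": int, "snp_id": str, "pos_bp": int},
    )
    n_snps = len(mp)
    samples, rows, allele_pairs = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snps}"
                )
            samples.append(parts[1])
            rows.append(np.array(parts[6:], dtype=object).reshape(n_snps, 2))
    if not rows:
        raise FormatError(f"{ped_path}: empty .ped file")
    alleles = np.stack(rows)  # (samples, snps, 2)

    a1 = np.empty(n_snps, dtype=object)
    a2 = np.empty(n_snps, dtype=object)
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        seen = sorted({x for x in col.ravel() if x != "0"})
        if len(seen) > 2:
            raise FormatError(f"more than two alleles at SNP {mp['snp_id'][j]}")
        sym = (seen + ["A", "B"])[:2] if len(seen) < 2 else seen
        a1[j], a2[j] = sym[0], sym[1]
        obs = col[:, 0] != "0"
        calls[obs, j] = (col[obs, 0] == a1[j]).astype(np.int8) + (col[obs, 1] == a1[j]).astype(np.int8)

    order = np.lexsort((mp["pos_bp"].to_numpy(), mp["chrom"].to_numpy()))
    mp = mp.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    a1, a2 = a1[order], a2[order]
    calls, a1, a2 = _recode_minor(calls, a1, a2)
    markers = MarkerMap(pd.DataFrame(
        {"chrom": mp["chrom"], "snp_id": mp["snp_id"], "pos_bp": mp["pos_bp"], "a1": a1, "a2": a2}
    ))
    markers.validate()
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# Pedigree text
# ---------------------------------------------------------------------------

_UNKNOWN = {"0", "NA", "na", ".", ""}


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     names=["id", "sire", "dam", "birth_year"], header=None, comment="#")
    # tolerate a header row
    if df.iloc[0]["id"].lower() in {"id", "individual", "animal"}:
        df = df.iloc[1:].reset_index(drop=True)
    df["sire"] = df["sire"].map(lambda x: None if x is None or str(x).strip() in _UNKNOWN else str(x).strip())
    df["dam"] = df["dam"].map(lambda x: None if x is None or str(x).strip() in _UNKNOWN else str(x).strip())
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.df.copy()
    df["sire"] = df["sire"].map(lambda x: "0" if x is None else x)
    df["dam"] = df["dam"].map(lambda x: "0" if x is None else x)
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """What QC removed and why."""

    n_snps_in: int
    n_samples_in: int
    removed_snps: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    removed_non_autosomal: int = 0

    @property
    def n_snps_removed(self) -> int:
        return len(self.removed_snps) + self.removed_non_autosomal

    @property
    def n_samples_removed(self) -> int:
        return len(self.removed_samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [("non_autosomal_snps", self.removed_non_autosomal, "")]
        rows += [("snp_low_call_rate", 1, s) for s in self.removed_snps]
        rows += [("sample_low_call_rate", 1, s) for s in self.removed_samples]
        return pd.DataFrame(rows, columns=["reason", "n", "id"])


def apply_qc(
    gm: GenotypeMatrix,
    min_call_rate_snp: float = 0.90,
    min_call_rate_sample: float = 0.90,
    autosomes_only: bool = True,
    max_autosome: int = 31,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop non-autosomal markers, then SNPs and samples below the call-rate floors.

    Non-autosomes are removed before call rates are computed, so sample call
    rates are judged on autosomal content only. SNP and sample filters are
    re-applied until nothing more is removed, so every surviving SNP and
    sample meets its threshold on the final matrix (the filter is idempotent).
    """
    if not (0 <= min_call_rate_snp <= 1 and 0 <= min_call_rate_sample <= 1):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    report = QcReport(n_snps_in=gm.n_snps, n_samples_in=gm.n_samples)

    if autosomes_only:
        keep = (gm.markers.chroms >= 1) & (gm.markers.chroms <= max_autosome)
        report.removed_non_autosomal = int((~keep).sum())
        if report.removed_non_autosomal:
            gm = gm.subset(snp_idx=np.nonzero(keep)[0])

    while True:
        snp_ok = gm.snp_call_rate() >= min_call_rate_snp
        report.removed_snps += list(gm.markers.df.loc[~snp_ok, "snp_id"])
        if not snp_ok.all():
            gm = gm.subset(snp_idx=np.nonzero(snp_ok)[0])

        sample_ok = gm.sample_call_rate() >= min_call_rate_sample
        report.removed_samples += [s for s, ok in zip(gm.samples, sample_ok) if not ok]
        if not sample_ok.all():
            gm = gm.subset(sample_idx=np.nonzero(sample_ok)[0])
        if gm.n_samples == 0:
            raise ValueError("quality control removed every sample")
        if snp_ok.all() and sample_ok.all():
            return gm, report


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSummary:
    snp_heterozygosity: pd.Series  # indexed by snp_id
    sample_call_rate: pd.Series  # indexed by sample id
    covered_length_bp: pd.Series  # per chromosome: last pos - first pos
    total_covered_bp: int
    mean_spacing_bp: float
    mean_heterozygosity: float


def summarize(gm: GenotypeMatrix) -> GenotypeSummary:
    """Per-SNP heterozygosity, per-sample call rate, spacing and covered length.

    Covered length per chromosome is (last position − first position); the
    mean inter-SNP spacing is total covered length / number of SNPs.
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise ValueError("cannot summarize an empty genotype matrix")
    nonmiss = gm.calls != MISSING
    with np.errstate(invalid="ignore"):
        het = np.where(nonmiss.sum(axis=0) > 0,
                       ((gm.calls == 1) & nonmiss).sum(axis=0) / np.maximum(nonmiss.sum(axis=0), 1),
                       np.nan)
    covered = {}
    for chrom, sub in gm.markers.df.groupby("chrom", sort=True):
        pos = sub["pos_bp"].to_numpy()
        length = int(pos[-1] - pos[0])
        if len(pos) == 1:
            warnings.warn(f"chromosome {chrom} carries a single SNP; covered length is 0")
        covered[chrom] = length
    covered = pd.Series(covered, name="covered_bp")
    total = int(covered.sum())
    return GenotypeSummary(
        snp_heterozygosity=pd.Series(het, index=gm.markers.df["snp_id"].to_numpy()),
        sample_call_rate=pd.Series(gm.sample_call_rate(), index=gm.samples),
        covered_length_bp=covered,
        total_covered_bp=total,
        mean_spacing_bp=total / gm.n_snps,
        mean_heterozygosity=float(np.nanmean(het)),
    )
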