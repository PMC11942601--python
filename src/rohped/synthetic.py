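"""Synthetic pedigree + genotype generator with known autozygosity truth.

Founder haplotypes are drawn from a beta-shaped allele-frequency spectrum
(default Beta(0.5, 0.5) truncated away from fixation, which gives a mean SNP
heterozygosity near 0.27, typical of a commercial SNP array on a livestock
breed). Transmission follows Mendelian sampling with Haldane-model
recombination at 1 cM/Mb: between adjacent markers separated by d Morgans a
crossover switch occurs with probability (1 − e^(−2d))/2.

Every founder haplotype carries a unique label that recombination shuffles
but never alters, so identity-by-descent is exact: an individual is
autozygous wherever its two labels agree, and the recorded truth (tracts and
their genome fraction) is the gold standard for the ROH and inbreeding
estimators downstream.

Mating schemes:

* ``random`` — discrete generations, random sire/dam pairs, all individuals
  kept (a pedigreed study population).
* ``full_sib_loops`` — repeated founder-pair → full-sib → inbred-offspring
  loops; the terminal individuals have expected F = 0.25.
* ``wright_fisher`` — constant-size random-union generations; only the last
  generation is genotyped (for LD-based Ne benchmarking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, MarkerMap, PedigreeTable, _recode_minor

BP_PER_MORGAN = 100_000_000


@dataclass(frozen=True)
class SimConfig:
    n_chrom: int = 10
    snps_per_chrom: int = 2000
    spacing_bp: float = 30_000.0
    spacing_jitter_bp: float = 10_000.0
    founder_count: int = 50
    n_generations: int = 5
    offspring_per_generation: int = 50
    scheme: str = "random"  # random | full_sib_loops | wright_fisher
    wf_population_size: int = 100
    missing_rate: float = 0.0
    maf_beta: tuple[float, float] = (0.5, 0.5)
    maf_floor: float = 0.05
    first_birth_year: int = 2000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chrom, self.snps_per_chrom, self.founder_count, self.n_generations) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.scheme not in {"random", "full_sib_loops", "wright_fisher"}:
            raise ValueError(f"unknown mating scheme {self.scheme!r}")
        if self.scheme == "full_sib_loops" and self.founder_count < 2:
            raise ValueError("full_sib_loops needs at least two founders")
        if self.scheme == "wright_fisher" and self.wf_population_size < 2:
            raise ValueError("wright_fisher needs a population of at least 2")


@dataclass
class SyntheticTruth:
    """Gold standard emitted alongside the genotypes."""

    tracts: dict[str, list[tuple[int, int, int]]]  # id -> [(chrom, start_bp, end_bp)]
    true_f: pd.Series  # autozygous fraction of the covered genome
    founder_freqs: np.ndarray  # per-SNP founder allele frequency
    genome_covered_bp: int
    hap_alleles: np.ndarray | None = None  # (2*n_out, L) alleles of output individuals
    hap_labels: np.ndarray | None = None  # founder-haplotype labels, same shape

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, tr in self.tracts.items():
            for chrom, a, b in tr:
                rows.append({"individual": ind, "chrom": chrom, "start_bp": a,
                             "end_bp": b, "length_bp": b - a + 1})
        return pd.DataFrame(rows, columns=["individual", "chrom", "start_bp", "end_bp", "length_bp"])


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    frames = []
    for chrom in range(1, cfg.n_chrom + 1):
        gaps = rng.uniform(
            max(cfg.spacing_bp - cfg.spacing_jitter_bp, 1.0),
            cfg.spacing_bp + cfg.spacing_jitter_bp,
            cfg.snps_per_chrom,
        ).astype(np.int64)
        pos = np.cumsum(np.maximum(gaps, 1))
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "snp_id": [f"snp{chrom}_{j + 1}" for j in range(cfg.snps_per_chrom)],
            "pos_bp": pos,
            "a1": "A", "a2": "B",
        }))
    return MarkerMap(pd.concat(frames, ignore_index=True))


def _switch_probs(markers: MarkerMap) -> np.ndarray:
    """Per-site probability that a gamete switches parental haplotype.

    Index 0 (and every first SNP of a chromosome) is the fair starting
    choice, p = 1/2; within a chromosome the Haldane switch probability is
    (1 − e^(−2d))/2 for inter-marker distance d in Morgans.
    """
    pos = markers.positions.astype(float)
    chroms = markers.chroms
    r = np.empty(len(pos))
    r[0] = 0.5
    d = np.diff(pos) / BP_PER_MORGAN
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[np.concatenate(([True], np.diff(chroms) != 0))] = 0.5
    return r


def _gametes(alleles, labels, hap_a_idx, hap_b_idx, r, rng):
    """Form one gamete per (hap_a, hap_b) parent pair, vectorized over pairs."""
    switch = rng.random((len(hap_a_idx), len(r))) < r[None, :]
    use_b = (np.cumsum(switch, axis=1) % 2).astype(bool)
    ga = np.where(use_b, alleles[hap_b_idx], alleles[hap_a_idx])
    gl = np.where(use_b, labels[hap_b_idx], labels[hap_a_idx])
    return ga.astype(np.int8), gl.astype(np.int32)


def _founders(cfg: SimConfig, n: int, freqs: np.ndarray, rng, label_start=0):
    alleles = (rng.random((2 * n, freqs.size)) < freqs[None, :]).astype(np.int8)
    labels = np.repeat(np.arange(label_start, label_start + 2 * n, dtype=np.int32)[:, None],
                       freqs.size, axis=1)
    return alleles, labels


def _ibd_tracts(lab_pair: np.ndarray, markers: MarkerMap) -> list[tuple[int, int, int]]:
    """Maximal runs where the two haplotype labels agree, per chromosome.

    Run bounds are extended to the midpoints of the flanking non-IBD
    intervals (chromosome-end runs stop at the terminal SNP), so the summed
    tract length is an unbiased estimate of the IBD genome fraction at any
    marker density.
    """
    same = lab_pair[0] == lab_pair[1]
    chroms = markers.chroms
    pos = markers.positions
    out = []
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        m = same[sel]
        p = pos[sel]
        if not m.any():
            continue
        diff = np.diff(m.astype(np.int8))
        starts = list(np.nonzero(diff == 1)[0] + 1)
        ends = list(np.nonzero(diff == -1)[0])
        if m[0]:
            starts.insert(0, 0)
        if m[-1]:
            ends.append(m.size - 1)
        for a, b in zip(starts, ends):
            lo = p[0] if a == 0 else (p[a - 1] + p[a]) // 2
            hi = p[-1] if b == m.size - 1 else (p[b] + p[b + 1]) // 2
            out.append((int(chrom), int(lo), int(hi)))
    return out


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, PedigreeTable, SyntheticTruth]:
    """Run the generator; returns genotypes, pedigree and the IBD truth."""
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    L = markers.n_snps
    a, b = cfg.maf_beta
    freqs = rng.beta(a, b, L)
    freqs = np.clip(freqs, cfg.maf_floor, 1 - cfg.maf_floor)
    r = _switch_probs(markers)

    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    years: list[int] = []

    if cfg.scheme == "full_sib_loops":
        n_loops = cfg.founder_count // 2
        alle_rows, lab_rows = [], []
        for k in range(n_loops):
            fa, fl = _founders(cfg, 2, freqs, rng, label_start=4 * k)
            s, d = f"F{k}_s", f"F{k}_d"
            # two full sibs, then their offspring
            kids_a, kids_l = [], []
            for _ in range(2):
                pa, pl = _gametes(fa, fl, [0], [1], r, rng)
                ma, ml = _gametes(fa, fl, [2], [3], r, rng)
                kids_a.append(np.vstack([pa, ma]))
                kids_l.append(np.vstack([pl, ml]))
            sib_a = np.vstack(kids_a)
            sib_l = np.vstack(kids_l)
            ca, cl = _gametes(sib_a, sib_l, [0], [1], r, rng)
            cb, cbl = _gametes(sib_a, sib_l, [2], [3], r, rng)
            loop_a = np.vstack([fa, sib_a, np.vstack([ca, cb])])
            loop_l = np.vstack([fl, sib_l, np.vstack([cl, cbl])])
            alle_rows.append(loop_a)
            lab_rows.append(loop_l)
            ids += [s, d, f"F{k}_sib1", f"F{k}_sib2", f"F{k}_inbred"]
            sires += [None, None, s, s, f"F{k}_sib1"]
            dams += [None, None, d, d, f"F{k}_sib2"]
            years += [cfg.first_birth_year, cfg.first_birth_year,
                      cfg.first_birth_year + 1, cfg.first_birth_year + 1,
                      cfg.first_birth_year + 2]
        alleles = np.vstack(alle_rows)
        labels = np.vstack(lab_rows)
        out_rows = np.arange(len(ids))
        out_ids = list(ids)

    elif cfg.scheme == "wright_fisher":
        n = cfg.wf_population_size
        alleles, labels = _founders(cfg, n, freqs, rng)
        gen_ids = [f"G0_{i}" for i in range(n)]
        ids += gen_ids
        sires += [None] * n
        dams += [None] * n
        years += [cfg.first_birth_year] * n
        for g in range(1, cfg.n_generations + 1):
            pairs = np.array([rng.choice(n, 2, replace=False) for _ in range(n)])
            pa, pl = _gametes(alleles, labels, 2 * pairs[:, 0], 2 * pairs[:, 0] + 1, r, rng)
            ma, ml = _gametes(alleles, labels, 2 * pairs[:, 1], 2 * pairs[:, 1] + 1, r, rng)
            new_a = np.empty((2 * n, L), dtype=np.int8)
            new_l = np.empty((2 * n, L), dtype=np.int32)
            new_a[0::2], new_a[1::2] = pa, ma
            new_l[0::2], new_l[1::2] = pl, ml
            new_ids = [f"G{g}_{i}" for i in range(n)]
            ids += new_ids
            sires += [gen_ids[p] for p in pairs[:, 0]]
            dams += [gen_ids[p] for p in pairs[:, 1]]
            years += [cfg.first_birth_year + g] * n
            alleles, labels, gen_ids = new_a, new_l, new_ids
        out_rows = np.arange(len(gen_ids))  # rows within the final arrays
        out_ids = gen_ids

    else:  # random mating, all individuals genotyped
        n0 = cfg.founder_count
        alleles, labels = _founders(cfg, n0, freqs, rng)
        gen_ids = [f"G0_{i}" for i in range(n0)]
        ids += gen_ids
        sires += [None] * n0
        dams += [None] * n0
        years += [cfg.first_birth_year] * n0
        all_a, all_l = [alleles], [labels]
        for g in range(1, cfg.n_generations + 1):
            m = cfg.offspring_per_generation
            n_prev = len(gen_ids)
            pairs = np.array([rng.choice(n_prev, 2, replace=False) for _ in range(m)])
            pa, pl = _gametes(alleles, labels, 2 * pairs[:, 0], 2 * pairs[:, 0] + 1, r, rng)
            ma, ml = _gametes(alleles, labels, 2 * pairs[:, 1], 2 * pairs[:, 1] + 1, r, rng)
            new_a = np.empty((2 * m, L), dtype=np.int8)
            new_l = np.empty((2 * m, L), dtype=np.int32)
            new_a[0::2], new_a[1::2] = pa, ma
            new_l[0::2], new_l[1::2] = pl, ml
            new_ids = [f"G{g}_{i}" for i in range(m)]
            ids += new_ids
            sires += [gen_ids[p] for p in pairs[:, 0]]
            dams += [gen_ids[p] for p in pairs[:, 1]]
            years += [cfg.first_birth_year + g] * m
            all_a.append(new_a)
            all_l.append(new_l)
            alleles, labels, gen_ids = new_a, new_l, new_ids
        alleles = np.vstack(all_a)
        labels = np.vstack(all_l)
        out_rows = np.arange(len(ids))
        out_ids = list(ids)

    # dosages, missingness, truth; haplotype rows 2i, 2i+1 belong to output individual i
    sel = np.empty(2 * len(out_ids), dtype=np.int64)
    sel[0::2] = out_rows * 2
    sel[1::2] = out_rows * 2 + 1
    ha = alleles[sel]
    hl = labels[sel]
    dosage = (ha[0::2] + ha[1::2]).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = -1

    calls, a1, a2 = _recode_minor(dosage, markers.df["a1"].to_numpy(), markers.df["a2"].to_numpy())
    mdf = markers.df.copy()
    mdf["a1"], mdf["a2"] = a1, a2
    gm = GenotypeMatrix(samples=out_ids, markers=MarkerMap(mdf), calls=calls)

    ped = PedigreeTable(pd.DataFrame({"id": ids, "sire": sires, "dam": dams, "birth_year": years}))

    covered = int(sum(
        sub["pos_bp"].iloc[-1] - sub["pos_bp"].iloc[0] for _, sub in mdf.groupby("chrom")
    ))
    tracts = {}
    true_f = {}
    for i, ind in enumerate(out_ids):
        tr = _ibd_tracts(hl[2 * i: 2 * i + 2], gm.markers)
        tracts[ind] = tr
        true_f[ind] = sum(b - a + 1 for _, a, b in tr) / covered
    truth = SyntheticTruth(
        tracts=tracts,
        true_f=pd.Series(true_f, name="true_f"),
        founder_freqs=freqs,
        genome_covered_bp=covered,
        hap_alleles=ha,
        hap_labels=hl,
    )
    return gm, ped, truth


def plant_island(
    gm: GenotypeMatrix,
    region: tuple[int, int, int],
    share_fraction: float,
    seed: int = 0,
    insulate: int = 0,
) -> tuple[GenotypeMatrix, list[str]]:
    """Make a fraction of individuals homozygous for one haplotype over a region.

    Returns the modified matrix (a copy) and the carrier ids. The carriers all
    share the same homozygous template, so the region becomes a consensus ROH
    at any sharing threshold up to ``share_fraction``.

    ``insulate`` > 0 additionally sets that many SNPs immediately flanking the
    region to heterozygous in *every* individual, so no homozygous run can
    cross the boundary and the planted region has knife-edge limits (window
    detectors otherwise smear a few SNPs past a shared tract).
    """
    if not 0 <= share_fraction <= 1:
        raise ValueError("share_fraction must lie in [0, 1]")
    if share_fraction == 0:
        return gm, []
    chrom, start_bp, end_bp = region
    sel = (gm.markers.chroms == chrom) & (gm.markers.positions >= start_bp) \
        & (gm.markers.positions <= end_bp)
    cols = np.nonzero(sel)[0]
    if cols.size == 0:
        raise ValueError("region contains no SNPs")
    rng = np.random.default_rng(seed)
    n_carriers = int(round(share_fraction * gm.n_samples))
    carriers = rng.choice(gm.n_samples, n_carriers, replace=False)
    # template: one haplotype drawn at the dataset's allele frequencies
    obs = np.ma.masked_equal(gm.calls[:, cols], -1)
    freq = obs.mean(axis=0).filled(0.5) / 2.0
    template = (rng.random(cols.size) < freq).astype(np.int8) * 2
    calls = gm.calls.copy()
    calls[np.ix_(carriers, cols)] = template[None, :]
    if insulate > 0:
        on_chrom = np.nonzero(gm.markers.chroms == chrom)[0]
        lo, hi = cols[0], cols[-1]
        flank = [j for j in range(lo - insulate, lo) if j in set(on_chrom)]
        flank += [j for j in range(hi + 1, hi + 1 + insulate) if j in set(on_chrom)]
        calls[:, flank] = 1
    out = GenotypeMatrix(samples=list(gm.samples), markers=MarkerMap(gm.markers.df.copy()),
                         calls=calls)
    return out, [gm.samples[i] for i in carriers]
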