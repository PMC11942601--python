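# Methods

This note documents the models and numerical choices behind `rohped`, in the
spirit of a methods supplement: what each estimator assumes, which defaults
matter, what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Genotype representation and quality control

Genotypes are stored as minor-allele dosages (0/1/2, −1 missing) in an
individuals × SNPs `int8` matrix tied to a physical marker map. "Minor" is
defined within the loaded dataset; exact 50/50 frequency ties are broken by
allele-symbol order so the coding is deterministic and reading a file the
package wrote reproduces the codes bit-for-bit. All homozygosity-based
statistics are invariant under allele relabeling, so the convention only
matters for reproducibility of the stored codes.

QC drops non-autosomal markers first (call rates are judged on autosomal
content only), then removes SNPs and samples below the call-rate floors
(default 0.90 each). The two filters are re-applied until nothing more is
removed: removing a sample can push a surviving SNP below its threshold, and
iterating to the fixed point makes the filter idempotent and guarantees that
every survivor meets its threshold on the *final* matrix. On realistic
missingness patterns the loop converges in one or two passes.

## ROH detection

Detection follows the overlapping-window scheme of PLINK's `--homozyg`.
Parameters (defaults in brackets):

| parameter | default | role |
|---|---|---|
| `window_snps` | 15 | window length in SNPs |
| `max_het_in_window` | 1 | heterozygous calls tolerated per window |
| `max_missing_in_window` | 1 | missing calls tolerated per window |
| `window_hit_fraction` | 0.05 | fraction of covering windows that must be homozygous for a SNP to be ROH-eligible (the PLINK default; exposed because it is rarely reported) |
| `min_snps_in_roh` | calibrated | minimum SNPs per emitted run |
| `min_length_kb` | calibrated | minimum run length |
| `min_density_kb_per_snp` | 100 | maximum mean kb per SNP within a run |
| `max_gap_kb` | 500 | runs are split at larger inter-SNP gaps |

Two semantic details are under-specified in most write-ups and fixed here
explicitly:

1. **Eligibility → segments.** A SNP is eligible when the homozygous
   fraction of windows covering it reaches `window_hit_fraction`; maximal
   runs of eligible SNPs become candidate segments. Segment-level het or
   missing totals are *not* re-limited beyond the window rule.
2. **Endpoint trimming.** A run never starts or ends on a heterozygous or
   missing call: candidate runs are trimmed inward to homozygous endpoints
   before the count/length/density filters. Without trimming, the window
   rule lets a run bleed several SNPs past a homozygous tract (a window
   containing 14 tract SNPs plus one flanking heterozygote still passes),
   which blurs segment boundaries and, downstream, the edges of shared
   regions.

The minimum run size is calibrated from the data so that, after a
Bonferroni-style correction over all SNPs and individuals, a run of `l`
homozygous SNPs arises by chance with probability below α:

    l = floor( ln(α / (n_SNP · n_ind)) / ln(1 − het̄) )

with the matching minimum length `l ×` mean inter-SNP spacing (rounded to
whole kb). The floor is deliberate — the run must include *at least* `l`
SNPs. On a 64,373-SNP, 675-individual panel with het̄ = 0.273 and 34.84 kb
spacing this gives 64 SNPs / 2230 kb.

Covered autosome length `L_auto` — the `F_ROH` denominator — is the sum over
chromosomes of (last SNP position − first SNP position), i.e. the territory
the array can actually see.

## Genomic inbreeding coefficients

`F_ROH` sums segment lengths within a half-open length interval `[lo, hi)`
and divides by `L_auto`; the class decomposition therefore sums exactly to
the all-lengths value. Length thresholds (>4, >8, >16, >32 Mb) express
recency; the additional >6.739 Mb cutoff is not a constant but
`100/(2·GE)` evaluated at the pedigree depth of the studied population
(GE = 7.42 equivalent generations), so for another pedigree depth the
matching cutoff is recomputed.

`F_IS` compares an individual's observed heterozygote count with its
Hardy–Weinberg expectation `Σ 2p(1−p)` over its non-missing SNPs; `F̂1–F̂3`
are the standard SNP-based estimators (variance of dosage, excess
homozygosity, correlation of uniting gametes). Allele frequencies are
estimated from the full post-QC sample *including* the focal individual
(the GCTA convention); monomorphic SNPs are excluded from the F̂/F_IS sums.
With a modest sample the inclusion of the focal individual biases F̂
slightly toward zero — visible only in the third decimal at n ≥ 200.

## Pedigree coefficients

`F_PED` uses the Meuwissen–Luo tabular traversal: per individual, ancestor
contributions `L` are pushed up the pedigree youngest-first and
`F = Σ L² D − 1` with `D = 0.5 − 0.25(F_s + F_d)` (unknown parents enter
with F = −1, so a founder has D = 1 and F = 0). The test suite checks it
against an independent Wright path-counting oracle.

Equivalent generations follow the recursion
`GE(i) = Σ_known parents ½(1 + GE(parent))`; the depth-corrected individual
rate of inbreeding is `ΔF = 1 − (1−F)^{1/(GE−1)}`, reported as 0 when
GE ≤ 1.

The ancestral coefficients are estimated by gene drop: founder alleles are
uniquely labeled and transmitted with fair Mendelian sampling; an individual
is autozygous when its two labels coincide. Per *allele* (averaging the two
slots) the estimators are

- `F_a_Bal` — P(the allele was autozygous in at least one ancestor),
- `F_a_Kal` — P(individual autozygous AND that allele previously autozygous),
- `F_New`  — P(individual autozygous AND that allele never before autozygous),
- `Ahc`    — E(number of times the allele has been autozygous along its path).

These per-allele definitions make `F_New + F_a_Kal = F_PED` an identity
(exact under exhaustive enumeration, within Monte-Carlo error otherwise) and
imply `Ahc ≥ F_a_Bal ≥ F_a_Kal` pointwise. An individual's own autozygosity
updates the lineages its offspring inherit, not its own coefficients.
Unknown single parents are treated as fresh founders, so they can never
contribute autozygosity. Default 10⁵ rounds give a standard error ≈ 0.0014
on a coefficient of 0.25 — below the usual 3-decimal reporting precision;
the seed is recorded in output provenance. Exhaustive mode enumerates all
2^(2n) transmission patterns and is limited to ~11 individuals.

## Effective population size

The LD route computes squared Pearson correlations of genotype dosages for
intra-chromosomal SNP pairs (pairwise-complete over individuals; pairs with
a zero-variance member are skipped), bins them by physical distance, and
applies Sved's relation per bin: with `c` = bin midpoint / 100 Mb (1 cM/Mb),

    Ne(t) = (1 − r̄²) / (4 c r̄²),   t = 1/(2c),   ΔF = 1/(2 Ne).

Bin edges grow geometrically from 10 kb widths (capped at 100 kb) between
10 kb and 50 Mb; the edges are config-exposed and echoed in output since the
binning statement in most papers is ambiguous. No sample-size correction is
applied to r² by default (an optional `r² − 1/n` correction exists); with
n ≥ 100 the uncorrected estimator keeps recent-generation Ne within a few
percent. No MAF floor is applied, consistent with the no-pruning stance of
the detection step.

The ROH route converts the population mean `F_ROH` above a length cutoff
into a rate via the same `ΔF = 1 − (1−F)^{1/(GE−1)}` closed form, with the
generation horizon of each cutoff from `g = 100/(2L)`: 12.5, 6.25, 3.125 and
1.5625 generations for >4, >8, >16 and >32 Mb. The all-lengths horizon
(15.6691 generations) is a study-level constant that does not derive from
the dating rule; it is kept as a configurable given. Per-generation decline
rates are `(Ne_a − Ne_b)/(a − b)`; a `span` argument lets a drop be
expressed over a different number of steps (some reports divide by the
count of listed generations instead of the generation difference).

## Islands and consensus ROH

The incidence track counts, per SNP, the individuals whose ROH cover its
position. Consensus ROH are maximal runs with incidence fraction ≥ a sharing
threshold; islands are maximal runs whose incidence *strictly* exceeds the
99th percentile of the genome-wide per-SNP counts (linear interpolation).
Region bounds are the first/last qualifying SNP positions. Adjacent
qualifying runs separated by ≤ `max_bridge` SNPs can be merged; the default
is 0 (no merging) since published islands are reported as single contiguous
runs. Annotation is a local interval join against a user-supplied GFF3/BED
file (gene ids counted once per region); no online resources are queried.

## Synthetic generator

The generator emulates the shape of a medium-density array on a closed
breed: ~10–31 autosomes, ~30 kb mean spacing with uniform jitter, founder
allele frequencies from Beta(0.5, 0.5) clipped to [0.05, 0.95] (mean SNP
heterozygosity ≈ 0.26–0.27), Haldane-model recombination at a flat 1 cM/Mb
(so the `g = 100/(2L)` dating rule holds exactly in simulation), and
configurable genotype missingness. Founder-haplotype labels ride along
unchanged through recombination, so autozygosity is known exactly; truth
tracts extend to the midpoints of the flanking non-IBD intervals, which
makes the summed tract fraction an unbiased estimate of the IBD genome
fraction at any marker density (tracts clipped at outermost SNPs would be
systematically short).

Default desk scale is 10 chromosomes × 2,000 SNPs with 50 founders and 5
generations of 50 offspring (~300 genotyped individuals) — every stage runs
in seconds. Three mating schemes: `random` (pedigreed study population),
`full_sib_loops` (terminal individuals with E[F] = 0.25), and
`wright_fisher(N)` (constant-size benchmark for LD-Ne; only the final
generation is genotyped).

`plant_island` overwrites a stated fraction of individuals with one
homozygous template across a region. With `insulate=k` it additionally sets
`k` flanking SNPs to heterozygous in every individual, producing knife-edge
region boundaries; this exists because the window detector intrinsically
smears a shared tract's edges by a few SNPs (a flanking heterozygote does
not immediately break eligibility), so sharp-edge recovery can only be
asserted against a sharply bounded truth.

What the generator does *not* emulate: mutation, genotyping error,
non-uniform recombination maps, selection, overlapping generations and
realistic demography. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
array artefacts or demographic misspecification.

## Problem sizes used in the validation suite

The test suite favours many medium fixtures over few large ones: detector ↔
oracle equivalence on 200 random ≤500-SNP chromosomes; Meuwissen–Luo ↔ path
counting on 50 random 6-generation pedigrees; gene-drop decomposition at 10⁵
rounds on a 240-individual pedigree; LD-Ne recovery on ten seeded
Wright–Fisher replicates (N = 100, 200 generations, 10 × 400 SNPs) with the
recent-generation estimate required within ±25% of truth; planted-region
recovery at 30% sharing (consensus) and at 60% sharing with insulated edges
(percentile island), both within one SNP per edge.

## Known limitations

- Exhaustive gene drop is exponential and guarded at 2²² patterns.
- LD-based Ne inherits Sved's idealizations (linear c↔distance map, no
  admixture/structure); uncorrected r² overestimates ΔF slightly at large c
  with small samples.
- The island percentile is computed over SNP counts, so very large shared
  regions (>1% of SNPs) raise the threshold themselves; consensus ROH at a
  fixed sharing fraction are the robust alternative there.
- Sex chromosomes, VCF input and imputation are out of scope.
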