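# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic data do and do not emulate.

## The design being modelled

Two closed lines are founded from a common base population (default: 30
founder matings; 116 generation-0 males tested) and selected in opposite
directions on one trait for nine generations. Per line and generation, 96
males are tested and the 6 most extreme kept as sires (highest trait value
in the HRFI line, lowest in LRFI); 40 dams are chosen at random ("no
selection on females"). Each generation also produces *response animals* —
phenotyped sibs used to measure the response — which are never genotyped.
Their genotypes are predicted as the parental average (g_sire + g_dam)/2,
so all full sibs share one row of the dosage matrix, with a certainty class
per cell (0×0, 2×2 and 0×2 matings determine the offspring dosage exactly;
1×1 is right half the time for the dosage-1 class; 0×1 and 1×2 are
uncertain).

## Simulator

**Genome.** Biallelic SNPs on a configurable number of autosomes (default
5 × 100 Mb × 100 SNPs, a desk-scale stand-in for a medium-density chip;
the breeding structure, not the marker count, drives every population-
genetic quantity checked here). Founder allele frequencies are drawn
independently per SNP from `founder_maf_range` (default U(0.05, 0.5)), i.e.
founders carry **no ancestral LD**; LD then accrues from the pedigree
bottleneck (effective size ≈ 4·6·40/46 ≈ 21 per line), which is the LD the
downstream methods actually exercise. Meioses place a Poisson number of
crossovers per chromosome (mean = length_Mb × cM/Mb ÷ 100; Haldane, no
interference).

**Phenotypes.** Phenotypic variance is 1 per trait, so all effects are in
σ_P units. A phenotype is QTL term + polygenic value + fixed effects + iid
residual. Planted QTL (none by default — the real experiment's QTL are
unknown; tests plant them explicitly) act on the selected trait; their
variance 2p(1−p)α² is carved out of the selected trait's genetic variance
h² (error if it does not fit). Polygenic values follow the recursive
pedigree rule u_offspring = ½(u_s + u_d) + m, Var(m) = ½σ²_g(1 −
(F_s+F_d)/2), with inbreeding tracked on the fly from parental coancestry —
exactly the covariance structure the A-matrix model assumes downstream. The
24 traits of the design table (heritabilities from the experiment's own
table) are tied to the selected trait by a **single-factor genetic
correlation structure**: corr(t_i, t_j) = r_i·r_j with r_i the correlation
of trait i to the selected trait. The experiment does not publish those
correlations; the defaults infer them from the correlated responses, r_i ≈
(G9 line difference of trait i in σ_g) / 3.84, which is their expectation
under this one-factor model. The matrix is PSD whenever |r_i| ≤ 1
(validated, with the offending trait named otherwise).

**Fixed effects.** Sex (+0.25 σ_P for females), a pen-size covariate, and
contemporary-group effects (SD 0.30) for batches of ~45 animals born the
same weeks. **Contemporary groups span both lines within a generation**:
the lines were raised and tested together in one unit, so a testing batch
mixes them. This matters: if groups were line-specific, pre-adjusting for
them would subtract the line means and with them the entire between-line
component of any marker signal — we verified that no QTL of the size used
in the recovery tests is detectable under that (incorrect) coding.

**Outputs.** Pedigree (founder F0 parents are labelled generation −1, line
"F0"; unselected candidate males are not emitted — only breeders and
response animals are pedigree rows), complete breeder genotypes (missing
data are injected only by an explicit masking option), response phenotypes,
true response genotypes (withheld from the pipeline, kept for validation)
and the true-QTL table. One master seed; per-generation × per-line
substreams are derived through `SeedSequence` spawn keys.

## Quality control

Filter order: unmapped/sex-chromosome markers, individual call rate
(< 0.90), marker call frequency (< 0.95), MAF (< 0.01, orientation-free),
then a two-sided exact Hardy–Weinberg test (p < 10⁻¹⁰) on the retained
animals. The HWE enumeration is written in-house (log-space recurrence over
the Levene–Haldane conditional distribution, no mid-p) and is checked
against an independent log-factorial enumeration in the tests. Dosage
orientation (which allele is counted) is fixed at load time and never
re-polarized after subsetting, so "frequency" tracks one fixed allele
across generations — required for trajectories. The loader supports both
the chip convention of the source design (0 = minor homozygote) and the
usual 0 = major homozygote, and records which was used.

A caution discovered in simulation: pooling two diverged lines produces
Wahlund heterozygote deficits, so a pooled-sample HWE filter preferentially
deletes the *most diverged* markers — the very signals of interest. The
real experiment's HWE step removed zero markers; for simulated two-line
panels the pipeline therefore exposes `qc_hwe_p` (0 disables) and the
recovery analyses run with the HWE step off.

## Mixed-model association

Per marker: y = 1μ + xβ + u + ε with u ~ N(0, A λ τ⁻¹), ε ~ N(0, I τ⁻¹),
y the OLS-pre-adjusted phenotype and x the parental-average dosage used as
a continuous covariate without uncertainty weighting. One eigen-
decomposition of A per (trait × analysis) diagonalizes V = λA + I; λ is
estimated by REML (ML selectable) on the intercept-only model by bounded
scalar optimization of the profile likelihood over log λ ∈ [−5, 5]·ln 10.
A flat profile (A = I) is detected and flagged as a boundary fit. Markers
are then scored by GLS in the rotated coordinates — the rotated intercept
is a general vector, so the two-regressor normal equations are solved
explicitly, vectorized over markers — with a 1-df Wald χ² on β. Monomorphic
markers are skipped; missing dosages are mean-imputed per marker.

`refit_lambda_per_marker=True` re-maximizes the restricted likelihood under
the alternative model for every marker (the exact per-marker algorithm of
the standard mixed-model GWAS programs), at ~10× the scoring cost. The
default keeps λ fixed from the null fit. The difference is *not* always
negligible: a QTL carrying a large share of the genetic variance inflates
the null λ and thereby deflates its own test (in the recovery scenario
below, 14/20 vs 18/20 seeds reach the genome-wide threshold). Both paths
are oracle-checked (dense-V GLS; dense profile-likelihood search).

**Genomic control.** λ_GC = through-origin regression slope of the sorted
observed χ² on χ²₁ quantiles (median/0.4549 selectable; flooring at 1 off
by default, so deflation is corrected too); corrected statistic χ²/λ_GC
with p recomputed from χ²₁. Under the two-stage scheme (OLS pre-adjustment,
then LMM on residuals) calibration is only approximate; pure-null
simulations of the drift-only scheme give mean factors ≈1.0–1.1, and
selection pushes factors above 1 in proportion to the line divergence, as
in the source experiment's real-data factors.

**Analyses.** Global, HRFI-only and LRFI-only differ solely in the id
subset; A, λ and genomic control are re-derived per subset, with A built
over the full ancestral pedigree first so cross-line founder relationships
survive in the global analysis.

## Thresholds, regions, trajectories

Effective tests per chromosome: smallest k with Σ top-k eigenvalues of the
marker correlation matrix ≥ 99.6% of its trace; for m > n panels the n × n
dual spectrum is used (identical nonzero eigenvalues). Genome-wide
threshold −log₁₀(0.05/ΣM); 1690 tests give 4.5 at one decimal. The
suggestive threshold is fixed at 3.0 and is used only for cross-analysis
lookup.

Windows/regions: 0-based half-open 1-Mb bins (floor(bp/10⁶)); bins with ≥1
marker at/above threshold are kept, touching bins merge into QTL-windows
per trait; within an analysis, windows of all traits fuse by interval
overlap/adjacency into QTL-regions; per (trait × region) the most
significant marker tags the SNP-QTL (ties: smaller position, then marker
id). A one-bin bridging option exists, off by default.

Trajectories: cumulative frequencies f_g over response animals of
generations 1..g (the design's own accumulation scheme, kept despite the
autocorrelation it induces — a per-generation alternative exists for
sensitivity); unweighted least-squares slope of f on g (slope in frequency
per generation, matching the reported units); Wald test against t(n−2)
(normal approximation selectable); zero-variance series return slope 0,
p 1, and an exact line degenerates to p ≈ 0 via an ε-guarded SE. Categories:
no slope significant → `no_change`; both, same sign → `co_selected`; both,
opposite signs → `opposite`; one → `one_line_only`. Evolution score =
n_generations × (|slope_HRFI| + |slope_LRFI|), counting only significant
slopes, so score = 0 ⇔ `no_change`. The drift reference is the idealized
Wright–Fisher model (panmixia, no selection, N = 40): closed form
√(p₀(1−p₀)(1−(1−1/(2N))ᵗ)) plus a binomial-resampling companion; with
p₀ = 0.5, N = 40, t = 9 both give 0.164. Note the cumulative-mean slope
test rejects well above its nominal level under pure drift — the points
are autocorrelated — so "significant" means "inconsistent with a flat
trajectory", not a calibrated selection test; the suite measures and
documents this rate rather than hiding it.

## Problem sizes used by the test suite

The recovery checks simulate the full design scale on a reduced genome —
3 chromosomes × 120 SNPs, response cohorts 5×96 + 4×175 per line (n = 2360
with predicted genotypes; the experiment used 2426), one QTL at exactly 5%
of σ²_P (α = 0.316, p₀ = 0.5), 20 seeds, per-marker λ refit — chosen as the
smallest configuration that preserves the design's population structure.
Inbreeding checks run the pedigree scheme with small response cohorts
(16/generation/line), since an animal's F depends only on its parents'
coancestry, not on cohort size; 20–24 seeds give a mean G9 inbreeding of
≈18% (the experiment estimated 19%). Unit fixtures are smaller still.

## What the synthetic data do not emulate

No ancestral/founder LD, no mutation, no crossover interference, no sex
chromosomes, no maternal or litter environmental effects, no genotyping
error, no chip harmonization or statistical imputation (the simulator emits
complete breeder genotypes; missingness is an explicit masking option), and
trait correlations are single-factor. Passing tests therefore demonstrate
the correctness and calibration of the machinery on data satisfying the
stated models — not robustness to real-chip artefacts or to imputation
error in the parental genotypes.

## Known limitations

- The two-stage adjustment (OLS residuals into the LMM) is the design's own
  procedure; its test statistics are approximately, not exactly, calibrated
  (hence genomic control).
- Average parental genotypes halve the usable dosage variance and make full
  sibs statistically one observation for the marker term; power budgets
  should count litters, not animals.
- The printed RFI equation is implemented verbatim (sign pattern as
  published); `conventional_signs=True` gives the usual all-minus form, and
  the coefficients can be re-estimated from data. Which variant produced
  the published residuals is not recoverable from the text.
- `adjust_phenotypes` fits the full stated fixed-effect model per trait; it
  does not re-run the original significance-based model selection, whose
  outcome is likewise not recoverable.
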