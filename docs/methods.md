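# Methods

This note documents the models, numerical choices and limitations behind
metaboquant, in the order data flows through the toolkit.

## Flat-file dialect

Vendor quantification software emits "one block per compound" text exports
whose exact grammar varies by version and locale. The parser fixes one
deterministic dialect: blocks start with `Compound N: <name>`, followed by a
tab-separated header (`#`, `Name`, `Sample Text`, `Type`, `Std. Conc`, `RT`,
`Area`, `IS Area`, `Conc.`) and one line per injection. Empty fields and the
literal `N/F` both map to missing (both occur in practice); missing values
are never zero-filled. All blocks must list the same injections in the same
order — a divergence is a structural error naming the first divergent block,
because silently aligning on injection index would hide dropped rows.
Compounds absent from the panel are kept (keyed by compound name) with a
warning rather than dropped, so a stale panel file cannot silently discard
data. Adapters for other vendor dialects are future work; the synthetic
generator emits exactly this dialect.

Processed results go to an XLSX workbook (concentrations rearranged by
phenotype group with the randomized acquisition order kept in its own
column, QC summary, flags; 1-SD outliers filled yellow, 2-SD red) plus CSV
mirrors of each sheet, which are diff-able and preserve full float
precision.

## Calibration regression

Calibration responses over a 1000-fold dynamic range are heteroscedastic
with roughly proportional scatter. Two remedies are offered and made
mutually exclusive:

* **1/x weighting** — weighted least squares with weight `1/nominal` on the
  untransformed scale;
* **log-log transform** — OLS of ln(response) on ln(concentration).

Combining them would double-correct: the log transform already stabilises
proportional variance, so requesting both forces the weighting off with a
warning. R² is reported on the fitted scale (weighted where weights apply,
log-log where transformed) and labelled as such; fitted-scale R² is the
quantity that is comparable across batches for a fixed configuration.

Model selection among candidate (model, transform, weighting) triples
maximises the number of calibration levels whose back-calculated accuracy
(100·measured/nominal) is within ±15% (±20% at the lowest level, the
standard bioanalytical convention). Ties break by higher R², then by
simplicity: linear before quadratic, untransformed before log-log,
unweighted before 1/x. The default candidate set is
{linear/1x, linear/log-log, quadratic/1x}; per-metabolite overrides are a
YAML map.

Quadratic back-calculation selects the root inside the calibrated
concentration range; when both or neither root falls inside, the root
nearest the range midpoint is taken — deterministic, and correct whenever
the curve is monotone over the calibrated range, which model selection
enforces in practice. Responses outside the invertible region return NaN
(flagged non-quantifiable downstream) rather than raising, because a single
saturated injection must not abort a batch.

LLOQ/ULOQ are the endpoints of the *longest contiguous run* of
accuracy-passing levels. Contiguity matters: a stray passing level beyond a
failing gap does not extend the quantifiable window. A curve with no
passing level is rejected for that metabolite (flagged, not fatal).
Metabolites without an internal standard use the raw peak area as response
(denominator 1). Carryover is 100·blank_area/LLOQ_area with a 20% default
threshold.

## Correction chain and provenance

The chain is: intake (vendor ppb, or back-calculation from area ratios) →
molecular-weight normalization (µg/L ÷ g/mol = µmol/L) → process-efficiency
division → dilution multiplication → matrix normalization (×V_extract/m for
tissue µmol/g, ×V_extract·10⁶/N_cells for cells). All steps are
multiplicative, so the order is mathematically irrelevant; it is fixed
anyway so that provenance is reproducible. Each factor is derived by
applying the elementary operation to 1.0 (which runs its domain validation)
and the final value is the sequential product — consequently
`QuantTable.reconstruct()` reproduces the stored values bit-exactly, not
just to rounding.

The extraction volume defaults to 100 µL (a common reconstitution volume);
it is a metadata/protocol setting, required only for tissue and cell
matrices. Tissue weights are taken in grams and guarded to [0.001, 50] g —
values outside that window almost always mean a unit mix-up (mg or kg) and
are rejected rather than silently producing thousand-fold errors.

Values below LLOQ or above ULOQ are flagged and retained; nothing is
imputed or zeroed, since below-LLOQ is a reportable state. Outlier flags
use the group mean and sample SD *including* the candidate point (marking,
not trimming, and no iterative re-exclusion); a value beyond 1 SD gets
`outlier_1sd`, beyond 2 SD additionally `outlier_2sd`. Flags are invariant
to affine rescaling of a group's values. Groups of size 1 get no statistics
and no flags.

## Validation statistics

Recovery subtracts the endogenous background from *both* spiked-matrix arms
(both contain it): `100·(before − endog)/(after − endog)`. The aqueous arm
of the matrix-effect ratio is not background-subtracted — pure diluent
contains no endogenous analyte by construction. Process efficiency is
recovery × matrix effect; the correction chain divides by it, so
`apply_process_efficiency(conc × PE, PE) = conc` closes exactly. Default
acceptance bands (recovery 50–120% good, <30% unreliable; stability
85–115%; CV tiers 15/20/25%) are configuration defaults, all overridable.
Selectivity/specificity is a chromatographic visual check upstream and is
represented only as a per-metabolite status field, not computed.

## Batch design and QC surveillance

`build_layout` places calibration standards first, then interleaves: a
blank at every fifth post-standard position and a QC after every run of ten
experimental samples. When both rules claim a position the blank wins and
the QC shifts to the next free slot — a deterministic resolution of an
ambiguity the interleaving rules leave open. Blank cadence counts
post-standard positions only (standards excluded); this is an
interpretation and is stated here deliberately.

`double_randomize` draws two independent seeded permutations (extraction
order, injection order). Each is redrawn until no phenotype group occupies
a contiguous block longer than ceil(2·n_group/n_groups), a guard against
the rare shuffle that would reintroduce the confounding randomization is
meant to remove.

The QC history is a single append-only CSV
(`qc_lot,batch_id,run_date,hmdb_id,conc_umol_l`); at a few hundred records
per metabolite no database engine is warranted. Inter-day RSD is the CV of
per-batch mean concentrations across batches. A batch warns when its QC RSD
exceeds the historical inter-day RSD by more than the tolerance (default
20% relative excess — a monitoring default, chosen so that ordinary
sampling variation in a 3–6 replicate batch RSD does not page anyone).
Drift is monitored, not corrected: no batch-effect regression is applied to
sample values.

## Hierarchical log-normal reference model

Per metabolite, `log y_ij = μ + b_j + ε_ij` with lot effects
`b_j ~ N(0, σ_lot²)` and residuals `ε_ij ~ N(0, σ²)`; flat prior on μ,
inverse-gamma(0.001, 0.001) on both variances (the shape/scale are exposed
as `fit()` parameters). The population median is exp(μ), summarised by the
median of the exp(μ) draws — transformation-consistent, unlike exp(mean) —
with the 2.5/97.5 percentiles as the 95% credibility interval.

The sampler is blocked Gibbs: μ is drawn from its conditional *marginal of
the lot effects* (lot means are independent N(μ, σ_lot² + σ²/n_j) once b is
integrated out), then b, then the two variances from their conjugate
conditionals. The naive μ|b / b|μ alternation mixes very slowly under a
flat prior on μ because μ and the b's are strongly coupled; the collapsed
update samples the same posterior with fast mixing. Per-lot sufficient
statistics are precomputed, so one iteration is O(J) and 25,000 iterations
on a 540-record history take well under a second. Defaults are 20,000
retained draws after 5,000 burn-in, seeded. For a balanced design the
posterior lot deviations centre near zero without an explicit sum-to-zero
constraint, because μ tracks the average of the lot means.

Degenerate inputs: a single-lot history falls back to the no-lot normal
model with a warning; non-positive concentrations cannot be
log-transformed and are rejected with a count (no Tobit-style censoring
extension — below-LLOQ QC values are simply excluded, a known limitation
that biases medians upward for metabolites frequently below LLOQ).

Cross-platform agreement between two concentration tables is ordinary least
squares of one platform on the other over the intersection of metabolite
ids (≥ 3 matches), reporting R², slope, intercept and residuals.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, seed). Measurement noise is
multiplicative Gaussian, `x·(1 + ε)` with ε truncated at −1 — the
proportional-variance structure that motivates 1/x weighting — not
additive. QC concentrations are log-normal with lot-level random effects.
Retention times drift as a slow bounded linear trend plus jitter, tuned so
the RT CV stays below 4% at defaults. Blanks carry a configurable fraction
of the top standard's peak area. Vendor ppb values for samples are
`true_µM × MW × efficiency × matrix_factor / dilution` with noise, so the
correction chain can exactly undo the distortion when the panel's
process-efficiency column equals efficiency × matrix factor.

The default test preset uses 10 metabolites in 3 classes with 2 phenotype
groups of 6; a full-scale preset emits 100 metabolites × 85 experimental
samples. Not emulated: chromatographic peak shapes, m/z-domain
interference, integration errors, missing-at-random dropout structure, and
between-metabolite correlation. Passing tests therefore demonstrate the
correctness of the arithmetic, flagging and inference under the stated
statistical structure — they do not certify behaviour under peak-picking
pathologies, which live upstream of this toolkit.

## Packaged panel fixture

Molecular weights in the packaged panel are *average* (not monoisotopic)
molecular weights curated from public HMDB records; unit tests that depend
on MW use synthetic panels so correctness is independent of this fixture.
Internal standards are placeholder class-group slots (IS01–IS12, two panel
classes per slot in panel order) to be overridden with a lab's actual
labelled standards. Process-efficiency factors default to 1.0 (no
correction): correction must be explicit in the panel file, never silently
guessed. The packaged reference medians and credibility intervals are a
transcribed database, not a re-derivation.

## Problem sizes used in the automated checks

The acceptance script and test suite use: 200 seeded 11-point calibration
curves for the linearity rate; 100 random 6–11-point series per regression
variant for oracle agreement; 100 replicate six-lot QC histories
(6 lots × 9 batches × 10 replicates = 540 records) with 4,000 retained
Gibbs draws after 800 burn-in for recovery bias and interval coverage —
enough draws that the Monte-Carlo error of the posterior quantiles is an
order of magnitude below the 5% recovery band; and the 10-metabolite
preset batch for pipeline closure. The library defaults (20,000 draws)
remain for production fits.
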