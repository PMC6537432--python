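# Methods

This note documents the analysis model implemented by `lipidstress`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Data model and nomenclature

The interchange object is a `PeakTable`: a species × samples matrix of
non-negative peak intensities with an explicit missing marker (NaN),
carrying parsed species records and per-sample study metadata
(cell line, condition ∈ {Nor, LPDS, LS, Hyp, HypLS}, replicate). A blank
or non-numeric cell in an alignment export is *missing*; a literal 0 is a
measured zero — alignment gap-filling distinguishes the two, and the two
are treated differently throughout ("present" always means non-missing
*and* strictly positive).

Annotations are parsed from MS-DIAL-era shorthand. `/` and `_` chain
separators and parenthesised vs space-separated compositions are
equivalent dialects; `/` carries no sn-position information and none is
used downstream. `P-` (vinyl ether) chains move PC/PE species into the
dedicated plasmenyl classes PPC/PPE; `O-` (alkyl ether) chains stay in the
base class; the `d` sphingoid base of SM counts its double bond like any
chain. The vinyl-ether oxygen linkage is never counted as a double bond.
Each class fixes its chain count (TG 3; DG/PC/PE/PPC/PPE/PG/BMP/SM 2;
MG/lysoPC/lysoPE/CE/acylcarnitine/lanosteryl esters 1); only acyl, ether
and sphingoid chains are counted — backbones (glycerol, sterol, carnitine)
never are.

**Sum-composition fallback.** An annotation like `PC 34:1` gives only
total carbons and double bonds. The per-chain saturation split is then
inferred by assigning each double bond to a distinct chain until chains
run out (`n_unsat = min(total_db, chain_count)`), and the double-bond
stratum falls back to the total count. Both fallbacks are flagged, and
every class-level output carries the fraction of inferred species, so a
consumer can judge how much of an aggregate rests on the convention. The
fallback is this package's construction — shorthand sum compositions
simply do not contain the information — and is deliberately the most
unsaturation-generous assignment.

## Preprocessing chain

Fixed order: presence filter → per-sample median normalisation → class /
stratum aggregation on the ratio scale → log2 → baseline subtraction.
Summation happens *before* the log so that stratum sums are sums of
intensities, not of logs.

* **Presence filter** (default ≥ 90% of samples, boundary inclusive):
  species must be present in at least that fraction of all samples.
* **Median normalisation**: each intensity is divided by the median of
  its sample's non-missing positive intensities, removing differences in
  cell number / input amount; the transformed per-sample median is 1 by
  construction. The filter commutes with this step (it depends only on
  positivity), which the test suite checks as an invariant.
* **log2**: applied with pseudo-offset 0 by default and a guard error on
  zeros — a silent offset would distort fold changes; the offset is a
  configurable parameter for data where zero stratum sums can occur.
* **Baseline subtraction**: on the log2 scale, the mean of the Nor
  replicates of the same cell line and group is subtracted, so baseline
  group means map exactly to 0. The mean (not median) is used for
  compatibility with the t-tests downstream.

Inside stratum and SI sums, missing intensities contribute 0: after the
presence filter at most ~10% of a species' cells are missing, and NaN
propagation would otherwise destroy whole strata. For the multivariate
statistics (PCA, PLS-DA, per-species ANOVA), which need a complete,
strictly positive matrix, remaining missing/zero cells are imputed with
half the sample's minimum positive value before log2 — a standard
metabolomics convention; with the default generator no cell is ever
imputed.

## Class aggregates and saturation metrics

Classes enter the class-level analysis only with strictly more than 6
species (counted on the post-filter inventory, not a fixed list); on the
reference inventory this admits {PC, PE, PPE, PPC, CE, DG, TG}. An
explicit exclude-list option exists for narrowing the set further.

* **Double-bond strata**: exact integer values of the largest per-chain
  double-bond count; absent strata simply do not appear. Stratum sums are
  mass-conserving per (sample, class) and invariant to species order.
* **Saturation index**: SI = (Σ I·n_sat)/(Σ I·n_unsat) per (sample,
  class). Scale-invariant per sample; undefined (reported missing, with a
  logged count) when the unsaturated total is 0 — no epsilon is injected,
  since silent regularisation would bias small classes. SI is computed
  per sample and then summarised, which is what makes replicate-level
  t-tests possible at all.
* **TG SFA stratification**: species bucketed by saturated-chain count
  into 0 / 1 / ≥2 SFA (the bucket boundary is configurable and the
  operation generalises to any class); proportions sum to 1 per sample
  when total intensity is positive.

## Statistical layer

* **PCA** on log2, median-normalised data with feature centring only;
  deterministic sign convention (largest-magnitude loading positive).
* **PLS-DA**: PLS2 on one-hot cell-line membership with autoscaled
  features, 2 components by default (matching 2-D score plots);
  cumulative VIP, `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a
  SSY_a)`, with selection at VIP > 2.0. Mean VIP² = 1 is an algebraic
  identity and is asserted on every fit. Centring-only PCA and autoscaled
  PLS-DA follow common MetaboAnalyst defaults; the cumulative VIP variant
  is likewise the common convention — both are assumptions, recorded
  here, since reasonable alternatives exist.
* **Per-species repeated-measures ANOVA** within each cell line, pairing
  replicates across conditions, on log2 intensities; implemented as
  vectorised sums of squares and cross-checked against
  `statsmodels.stats.anova.AnovaRM` in the test suite. For two conditions
  F equals the squared paired t statistic exactly. Unbalanced pairings
  fall back to an unpaired one-way ANOVA with an explicit flag. Raw
  p-values are flagged at 0.001 (the classical per-species rule) and
  accompanied by Benjamini–Hochberg q-values.
* **SI contrasts**: two-sided t-tests per (cell line, class, stress
  condition vs baseline), star-coded at 0.05/0.01/0.001. The default is
  the *paired* test (replicates are repeated cultures measured across
  conditions; the paired t is exact under normality even when a condition
  inflates variance), with Welch's unpaired test as option and automatic
  fallback when replicates cannot be matched. Degenerate zero-variance
  groups resolve exactly: equal constants → p = 1; distinct constants →
  p = 0 with a `degenerate` flag, never NaN.

## Synthetic-data generator

The generator emulates the study design: 6 cell lines × 5 conditions ×
3 replicates (replicate count is a guess — the study never states it; its
qPCR used 3–6 samples) over a 244-species inventory whose per-class
counts reproduce the reference tallies. Chains are drawn from
even-carbon pools (14–22 carbons, 0–6 double bonds, low-unsaturation-
weighted) so inferred SI values stay in realistic ranges.

Log2 intensities are additive: class baseline (14.0) + per-species offset
(SD 1.5) + per-(species, cell line) offset (SD 0.5) + condition effects +
replicate noise (SD 0.25 log2). The three effect modes mirror the
qualitative stress phenomenology:

| condition | default effect | magnitude |
|---|---|---|
| LS, Hyp+LS | `db_slope` on TG | −0.5 log2 per double bond |
| LPDS | `uniform_shift` on CE | −1.0 log2 |
| LS | `uniform_shift` on DG | +0.5 log2 |
| Hyp, Hyp+LS | `species_random` on all | SD 0.3 log2 |

`species_random` draws zero-mean per-species shifts independently for
*every sample*: species-level variability with no coherent class-level
component. This is a deliberate design choice: a per-species shift held
constant across replicates has the same covariance structure as the
replicate noise and would provably inflate the class-level contrast rate,
i.e. hypoxia would *not* be a class-level null. The cost is that the
generator does not reproduce consistent single-species hypoxia effects;
it models them as non-reproducible fluctuation.

Ground truth (every deterministic per-species log2 shift, and the SD of
every random one) is returned and serialised next to the dataset, so
recovery tests never re-derive expectations from generator internals.

**What passing tests do not show.** The generator is log-normal,
homoscedastic within condition, with independent species (cell-line
structure enters only through additive offsets, so the block covariance
of real lipid profiles is not emulated), no retention-time or batch
drift, no adducts/isotopes, and missingness only by uniform masking.
Calibration and recovery results on it demonstrate correctness of the
computational chain under its assumptions, not performance on real LC-MS
data.

## Verification experiments

`lipidstress.experiments` (driven by `scripts/acceptance.py` and the test
suite) runs, on one core in a few minutes:

* inventory tallies (exact);
* the worked SI example (0.8) and a brute-force per-chain oracle on
  randomised small tables (exact to 1e-12);
* VIP mean-square identity and the closed-form single-component VIP;
* F = t² for two paired conditions (to 1e-8);
* hypoxia null calibration: 200 repeats × 7 analyzed classes of the
  paired SI contrast (nominal 0.05) and 200 × 244 per-species
  repeated-measures tests (nominal 0.001), both asserted within the
  binomial 95% band of the simulation size. The paired contrast's true
  size is mildly liberal (~0.055) because small-class SI is a skewed
  ratio at three replicates; this is a property of t-tests on ratio
  statistics at n = 3, documented rather than patched;
* slope recovery: the injected −0.5 log2/double-bond TG effect under LS,
  recovered through the full pipeline to within ±0.1 (5 independent
  scenario replicates);
* power: a +0.5 SI shift at noise SD 0.1 and n = 3 detected by the
  unpaired contrast in ≥95% of 200 repeats (the paired test at df = 2 has
  analytic power 0.85 at these settings, which is why the unpaired route
  is the stated setting for this experiment).

## Known limitations

* Sum-composition saturation counts are a convention, not a measurement;
  the inferred fraction should be checked before interpreting SI shifts
  in classes with many sum-composition annotations.
* SI is undefined for fully saturated classes (e.g. a single saturated
  species); such cells are excluded from group means with a logged count.
* The n > 6 inclusion rule is applied mechanically; single-species
  classes (MG, PG, lanosteryl esters) never reach the class-level layer.
* No cross-validation or permutation testing of the PLS-DA model: it is
  used descriptively, and VIP ranks on weakly separated data are
  unstable.
* The pipeline assumes one annotation per species name; duplicate
  annotations in an export are an error by design, not merged.
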