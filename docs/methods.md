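# Methods

This note documents the models and procedures implemented in `cilms`,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic cohort does and does not
emulate.

## Peak-pair model and mass arithmetic

Dansylation adds C₁₂H₁₁NO₂S (233.05105 Da) per tag; the heavy reagent
carries two ¹³C per tag, so each heavy tag weighs Δ = 2 × (m(¹³C) −
m(¹²C)) = 2.006710 Da more. A metabolite whose singly tagged, singly
protonated light ion has mass `m₁`, carrying `t` tags at charge `z`,
appears as a light ion at `m/z_L = (m₁ − 1.007276 + (t−1)·233.05105 +
z·1.007276)/z` and a heavy partner at `m/z_L + t·Δ/z`. Bis-dansylated ammonia
(C₂₄H₂₅N₃O₄S₂) is a ubiquitous reagent by-product; its doubly and
singly protonated all-light ions and the singly protonated proton-bound
dimer of the all-light and 2-heavy-tag monomers give three calibrant
masses spanning the scan range (242.57160, 484.13592, 971.27799). The
dimer composition is confirmed by brute force over tag compositions:
only two heavy tags in total reproduce the printed mass within 0.1 mDa.

## Calibration

Each run is corrected by a single global multiplicative ppm shift,
estimated as the mean signed deviation of the calibrant ions matched
within 20 ppm (configurable; an offset above 50 ppm is treated as a
failed calibration). A single global shift rather than an RT- or
mass-dependent model is used because only three anchors are available.

## Pair detection

Features are scanned in ascending m/z as light candidates; heavier
partners are searched at every supported tag/charge spacing (tags 1–3,
charge 1–2; degenerate spacings such as 1 tag z=1 vs 2 tags z=2 are
collapsed onto the simplest form) within 5 ppm — evaluated on the heavy
m/z, since instrument tolerances are ppm-scale — and 6 s RT. When
several partners qualify, the smallest |ppm error| wins, then the
largest heavy intensity; each feature joins at most one pair. The
lighter member is always taken as the ¹²C channel because the pooled
standard is always heavy. A pair-level filter removes pairs with a zero
heavy channel (undefined ratio) or sub-threshold intensity, and
collapses multiple tag/charge forms of the same light neutral mass
(within 10 ppm and 10 s) onto the most intense form. The whole detector
is property-tested against an O(n²) all-pairs oracle.

## Alignment, presence filter, normalization, identification

Pairs are clustered across runs by greedy centroid clustering: runs in
descending pair count; each pair joins the existing cluster with the
same ion form whose running centroid lies within 5 ppm and 20 s
(closest ppm first) or founds a new cluster; a run contributes at most
one observation per cluster. Features observed in ≤50% of samples are
dropped (the boundary itself is dropped: "more than 50%"). Ion forms
with equal mass but different (tags, charge) are never merged — they
are distinct ions.

Per-sample median normalization (each sample's ratios divided by that
sample's median observed ratio) is available and is the pipeline
default for drift handling; QC columns have median exactly 1
afterwards. Caveat: when a large fraction of features is genuinely
perturbed in a sample — as at the first post-injury window — the median
absorbs part of the biological signal. Ground-truth-recovery tests
therefore score raw ratios, and fold-change estimates from normalized
tables should be read as relative to the sample-median baseline.

Identification reduces each feature's light m/z to its 1-tag z=1
equivalent mass and searches the dansyl library within 5 ppm and 30 s;
the smallest ppm error wins.

Missing values: univariate tests use available values only (pairwise
deletion); multivariate methods (PLS-DA, logistic panels) impute half
the feature's minimum observed ratio.

## Statistics

* Fold change is the ratio of linear-scale group means; the p-value is
  a two-sided Welch t-test on log₂ ratios (switchable to pooled
  variance). Welch is the default because group variances are not
  assumed equal at n = 8–12.
* Benjamini–Hochberg q-values come from the standard step-up with
  monotonicity enforcement (statsmodels), cross-checked in tests
  against an independent hand-rolled oracle.
* ANOVA is the one-way fixed-effects F-test; post-hoc pairs use
  Tukey's HSD via the studentized-range distribution (scipy), at
  α = 0.05.
* PLS-DA fits a NIPALS partial-least-squares regression
  (scikit-learn backend) of the indicator-coded classes on the
  auto-scaled matrix. R² is explained class variance; Q² uses 7-fold
  cross-validation (the convention of the software the procedure
  mirrors; the fold assignment is seeded and deterministic). VIP for
  feature *j* is

  `VIP_j = sqrt( p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a )`,

  with SSY_a the y-variance captured by component *a*; this
  normalization guarantees mean(VIP²) = 1. Permutation validation
  refits with permuted labels (default 20), regresses R² and Q²
  against the absolute label correlation, and declares the model valid
  when both slopes are positive and every permuted Q² is below the
  original.
* Temporal patterns are called on log₂ deviations d_i = |mean(t_i) −
  mean(control)|: **pattern 1** (gradual drift) requires non-decreasing
  deviations with a consistent sign and d₃ above the noise floor ε;
  **pattern 2** (acute excursion and restoration) requires the largest
  deviation at t₁, non-increasing thereafter within ε, and d₃ < d₁ − ε.
  ε defaults to 0.1 log₂ units; this is an explicit operationalization
  of a qualitative description, and pattern 1 takes precedence in the
  rare boundary cases where both rules fire.
* The Venn partition marks a metabolite significant in a
  grade-vs-control comparison when FC > 1.5 or FC < 1/1.5 and
  p < 0.05, and assigns each selected metabolite to one of the 7
  regions over {A, B, C}.

## Classification

Binary logistic regression is fitted by IRLS (Newton) with a 1e-8
log-likelihood tolerance and 100-iteration cap. Quasi-separation is
detected when the deviance collapses to zero or coefficients diverge;
the model is then refitted with a small L2 penalty (1e-4, intercept
unpenalized) and flagged `converged=False`. The small ridge keeps
coefficients finite without materially moving non-separable fits; at
n ≈ 29 separation is a real possibility, so this path is routine.

ROC analysis uses the tie-corrected Mann–Whitney AUC, the Youden-J
optimal cutoff, and the Hanley–McNeil variance for the 95% CI (DeLong
could be substituted; Hanley–McNeil matches the era of the reference
workflow). Panel scores are fitted class-1 probabilities from the
logistic model on the panel ("combined probability").

The greedy stepwise ranking pre-filters features by ANOVA p < 0.05
across the three grades, then forward-selects up to 6 features by
LOOCV accuracy of the logistic panel; ties break toward the smaller
ANOVA p, then input order.

The cascade predicts grade A vs non-A by LOOCV over all graded
t1 samples; predicted non-A samples enter a second LOOCV of C vs
non-C, and predicted non-C becomes B. Feature selection is performed
once on the full data before LOOCV — mirroring the reference
procedure, and optimistic in the usual way; `nested=True` repeats the
selection inside every fold and is the honest-error option. Reported
models are refitted on all samples involved in each step. Accuracies
are printed as percentages rounded to one decimal
(trace of the 3×3 confusion matrix over its total).

## Synthetic cohort generator

The generator emulates the study conditions: 10/12/8 patients of grades
A/B/C, each sampled at the three windows; 8 non-injured controls (the
number of controls is not fixed by the study description; 8 is the
package's default and a free parameter); QC runs after every 20
analytical runs; CSF and serum arms generated independently. Per
metabolite it draws a 1-tag z=1 light mass (280–780 Th, ≥0.2 Th
spacing), 1–2 tags (3:1), charge 1–2 (9:1), a reference RT in
100–1500 s and a control level spanning 2.5 decades. Six metabolites
are severity markers: pattern-2 trajectories with t1 log₂ effects
1.6/1.0/0.5 for A/B/C (jointly scaled ±10% per metabolite, preserving
the ordering). Remaining metabolites receive pattern 1 up/down
(15% + 15%), pattern 2 (40%) or no effect (30%), with one shared
|log₂ FC| in 0.8–2.0 across grades; pattern 1 ramps the effect over
(1/3, 2/3, 1) of its full size across windows, pattern 2 decays over
(1, 0.45, 0.1).

The heavy channel carries the pooled-standard level — the mean of every
individual sample's expected level, matching a pooled aliquot mix — so
QC runs (pooled light vs pooled heavy) have expected ratio 1. Intensity
noise is log-normal with 15% CV per channel. Mass error per run is a
uniform ±8 ppm calibration offset (recoverable from the three spiked
calibrant ions, which carry only 0.2 ppm residual error) plus
per-pair Gaussian error with 2 ppm marginal sd, split into a component
shared by the two peaks of a pair (sd 1.8 ppm) and an independent
residual: the light and heavy ions of a pair sit in the same spectra
under the same calibration, so their mass errors are strongly
correlated, and the spacing error (sd ≈ 1.2 ppm) stays well inside the
5 ppm pairing tolerance while the absolute error is ppm-scale. RT
jitter across runs is Gaussian with sd 4 s; co-eluting partners differ
by sd 0.5 s. Features go missing feature-wise per sample, uniformly at
random (5%), and 200 unpaired background singlets are added per run.
All randomness derives from one seed through independent per-stage,
per-run streams, so adding background peaks does not perturb
metabolite draws and identical configs reproduce byte-identical files.

What the generator does **not** emulate: chromatographic peak shapes
and integration, isotopologue envelopes beyond the light/heavy pair,
adducts, RT drift or batch effects, intensity-dependent (non-random)
missingness, and between-metabolite correlation. Passing tests
therefore demonstrate that the algorithms recover the structure they
assume at realistic noise scales — not that they are robust to every
artifact of real instrument data.

## Problem sizes and numerical choices

Tests and the end-to-end examples run the CSF arm of the default design
(102 runs, 60 metabolites, ~400 features per run), which exercises
every stage in seconds; statistical-calibration checks use 2000 null
simulations, and oracle comparisons cap inputs at a few hundred
features where the O(n²) reference is exact. Tolerances: calibration
match 20 ppm, pairing 5 ppm/6 s, alignment 5 ppm/20 s, identification
5 ppm/30 s, all configurable. Ties are broken deterministically
everywhere (documented above), and every stochastic routine takes an
explicit seed.

## Known limitations

* The greedy stepwise criterion and the "level 1" pair-quality notion
  of the original processing software are not fully specified upstream;
  both are explicit, documented operationalizations here.
* Default (non-nested) feature selection before LOOCV overstates
  cross-validated accuracy; use `nested=True` for unbiased estimates.
* Sample-median normalization assumes most features are unperturbed in
  each sample (see above).
* PLS-DA Q² depends on the fold assignment at these sample sizes; the
  seeded 7-fold scheme makes it reproducible rather than unique.
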