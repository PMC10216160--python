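# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `bntvbm`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Item-level scoring

The 30 administered items are the odd trials 1–59. Three items (13 OCTOPUS,
23 VOLCANO, 57 TRELLIS) have no sensorimotor-interaction (SMI) norm and are
excluded from both scores; the packaged norm table carries the remaining 27
values, including RACQUET scored under its American spelling and RHINOCEROS
at 3.680 (the long-form rating rather than the 3.875 RHINO variant).

Raw responses use the four-code dialect `1` correct-first-attempt, `2`
correct-after-cue, `0` incorrect, `999` missing. Scoring collapses cued
successes into "incorrect" — only spontaneous naming counts — but the raw
representation keeps the distinction so no information is destroyed on
ingest.

Cleaning applies two rules in order: any record with one or more missing
item outcomes is dropped (`missing_items`); any record with fewer than two
first-attempt successes on SMI-rated items is dropped (`too_few_correct`).
A "mean SMI" over zero or one items is not treated as a score, which is why
the qualitative score is undefined exactly below two correct items.

A flawless 27/27 performance scores a qualitative mean of **4.913**, the
arithmetic mean of the packaged SMI values (4.921 if the RHINO variant is
substituted). Published accounts of the same table have also quoted 4.931
for this case; the package always reports the mean of its own norm table
and treats the third-decimal discrepancy as a transcription issue upstream,
not something to reproduce.

### Per-item group statistics

Per-item naming frequencies are compared between groups with a Pearson
chi-square on the 2×2 table (1 df, no continuity correction), with counts
reconstructed from printed proportions by nearest-integer rounding of
`p × n`. This convention reproduces the reference table's printed p values
essentially exactly (e.g. BEAVER p = 0.003 at 3 d.p.). Items at ceiling in
both groups are "not assessed" (NaN).

The SMI–difficulty association is summarised by the Spearman rank
correlation between SMI and per-item proportion correct, with mid-rank
(average) tie handling — the dominant software convention. On the packaged
reference proportions this yields **0.339 (controls) and 0.364 (MCI)**.
Published values of 0.455/0.488 for the same
table could not be reproduced under any standard rank, transform or
subset convention we tried; the chi-square column of the same table *is*
reproduced exactly, so the package treats its own computed coefficients as
the values consistent with these data.

## Synthetic cohort generator

The generator's defaults are the study conditions of the reference cohorts
and were fixed by a one-off calibration before the test suite was written.

**Item-response model.** A one-parameter logistic (Rasch-type) model:

    logit P(correct first attempt)_ij = θ_i − d_j + κ · s_i · h_j
    d_j = α − β·smi_j + ε_j,   ε_j ~ N(0, σ_d²)
    h_j = (mean(smi) − smi_j) / sd(smi)

with θ_i ~ N(μ_group, σ_θ²) the general naming ability and s_i ~ N(0, 1) a
semantic-specific latent, independent of θ_i by construction. High `s_i`
raises success odds specifically on hard, low-SMI items, lowering the
qualitative score without changing the expected count much — this is the
recoverable ground truth behind the "independent qualitative information"
claim. Failures become correct-after-cue with probability 0.3; each outcome
is independently missing with probability 0.0015 (≈4% of participants hit
at least one missing item, matching the reference exclusion fractions).

Defaults: β = 0.5, σ_d = 1.0, κ = 0.6, μ_control = 1.0 (σ 0.8),
μ_MCI = 0.4 (σ 1.1), n = 197/350. These give group score means/SDs close to
the reference descriptives (≈24.4 (2.1) vs ≈22.6 (3.5) on the 27-item
count) and an emergent negative quantitative–qualitative correlation in the
MCI group (≈ −0.4; the reference cohorts show −0.72), the by-product of
ceiling-adjacent performers having named the hard low-SMI words.

**Items are a fixed test form.** The difficulty offsets ε_j are drawn from
a dedicated stream keyed by `item_seed` (default 13), not by the cohort
seed: replicate cohorts answer the *same* 30 items, as real cohorts would.
The default item draw was selected, by a Monte-Carlo calibration over
candidate draws, so the realized SMI/naming-frequency rank correlation sits
mid-range of the empirically observed coefficients (expected ≈0.46 per
group); across cohort replicates the observed coefficient then stays within
0.30–0.65 in ≳95% of draws. With item offsets redrawn per cohort instead,
the sampling spread of a 27-pair rank correlation (SD ≈ 0.15) makes any
such band statement impossible — that modelling choice, not a tuned
constant, is what the calibration fixed.

**Volumes and maps.** Scalar gm/wm/csf volumes are drawn around adult means
(600/500/350 ml), giving intracranial volume and brain parenchymal ratio.
The grey-matter phantom is a 24³ grid of 4 mm voxels: background density
0.35, eight disjoint box regions at 0.55, voxelwise N(0, 0.05²) noise,
Gaussian-smoothed at FWHM 6 mm (σ = FWHM/(2√(2 ln 2)) per axis; reflective
boundaries, so total mass is conserved). Planted subject effects, in
density units per SD of the standardized latent:

* temporal and both hippocampi: `γ_quant · z(θ_i)`, default 0.015;
* both perirhinal boxes: `γ_qual · z(−s_i)`, default −0.008 — the negative
  sign couples a *lower* mean-SMI tendency with *larger* perirhinal volume;
* entorhinal boxes and a control region: no planted effect (specificity
  controls).

Scalar ROI volumes are the expected post-smoothing mask integrals
(background + contrast × a per-region smoothing-retention factor computed
by smoothing the region indicator once), so the scalar path and the image
path agree within voxel noise (≤5%). `γ_qual = −0.008` was calibrated so
the planted residualized qualitative–perirhinal correlation is ≈ −0.26,
inside the −0.1…−0.3 range judged realistic for a modest ROI effect at this
scale; the real-data analogue is weaker (−0.089) but undetectable at
phantom size, so the planted value trades realism of magnitude for testable
recovery.

What the generator does **not** emulate: MRI physics (bias fields,
registration error, partial volume), anatomically shaped regions,
spatially varying smoothness, longitudinal drift, genotype structure.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated generative model, not performance on real scans.

## Voxelwise GLM and cluster inference

Per voxel, ordinary least squares with a single-column contrast; the t
statistic uses the standard closed form and is converted to z by
tail-probability matching (computed in log space so large t does not
saturate). Voxels with zero residual variance (relative tolerance 1e-10)
are flagged and excluded from clustering. Covariates are mean-centred —
this changes no contrast t value, only the conditioning of XᵀX — and rank
deficiency is reported with the names of the collinear columns.

Cluster formation: one-sided t threshold at the configured `p_form`
(default 0.01), 18-neighbour connectivity (faces + edges, the convention
of the major VBM packages). Cluster-level family-wise error is controlled
by Freedman–Lane permutation: the data are residualized on the nuisance
columns, residual rows are permuted, the full model is refitted, and the
maximum suprathreshold cluster extent per permutation forms the null;
`p_FWE = (1 + #{null ≥ extent}) / (1 + n_perm)`. For n ≤ 9 (or whenever
`n_perm ≥ n!`) all row permutations are enumerated and the p value is
exact. This permutation scheme is a deliberate substitution for
random-field-theory cluster correction: it is assumption-light,
implementable from first principles, and exactly testable against
brute-force enumeration. The permutation loop runs in single precision;
extents are integer counts, so this affects only voxels within float32
resolution of the forming threshold.

On null *smoothed* maps (n = 60, 24³ grid, 200 permutations) the realized
family-wise false-positive rate at nominal 0.05 is ≈0.03–0.07. On
unsmoothed white noise the max-extent null is so discrete (extents of 2–5
voxels) that the test becomes conservative (≈0.015); the calibration is
therefore stated, and checked, for smoothed maps, which is the only regime
the pipeline uses.

Report tables list, for each surviving cluster (default FWE α 0.05), its
extent, FWE p, and the in-cluster local maxima with z above a floor of
3.50, annotated with the ROI masks containing each peak and mm coordinates
from the diagonal voxel affine.

## ROI analysis

Volumes are density integrals: `Σ density × voxel volume / 1000` ml;
intracranial volume is the sum of the three tissues and the brain
parenchymal ratio is (GM+WM)/ICV. Residualization regresses qualitative on
quantitative with an intercept and divides the residuals by their sample
SD (ddof 1); the result has mean 0, SD 1, and is orthogonal to the
quantitative score to numerical precision. ROI correlations are Pearson r
with a one-tailed p from `t = r√((n−2)/(1−r²))`, the tail fixed a priori
by the whole-brain contrast direction (negative for the qualitative
score). No multiple-testing correction is applied across the six
mediotemporal ROIs — mirroring the reference analysis — and the output
table flags this. The sample-size convention follows the `r_n` subscript
as printed (n = 350): the closed form gives p = 0.0482 there and 0.0477 at
n = 352; both round to the published 0.048.

## Pipeline

The two sub-cohorts are analysed separately end to end; no fitted quantity
crosses groups (verified by a drop-one-group invariance test). Descriptive
group comparisons use a pooled-variance t when a Levene check accepts
variance equality at 0.05 and Welch's t otherwise, recording the rule per
row (reference descriptives show both integer and fractional dfs,
indicating exactly such mixed use). All randomness flows from one master
seed through fixed-key substreams, so reruns are byte-identical.

## Problem sizes used in the checks

Acceptance-level checks run at: 50 random small designs for the closed-form
GLM oracle; exhaustive enumeration at n = 6 (720 permutations) for the
permutation oracle; 200 null replicates × 200 permutations for FWE
calibration; 100 replicates (n = 350, 99 permutations each) for
planted-effect recovery plus 50 null replicates for specificity; 20–40
replicates for the scalar Monte-Carlo summaries in the acceptance script.
These sizes keep the complete suite in the minutes range on one CPU while
leaving binomial uncertainty well inside the asserted margins.

## Known limitations

* The phantom geometry is box-shaped and stationary; cluster extents and
  smoothing leakage do not transfer quantitatively to real VBM data.
* The Rasch link is the simplest model reproducing the SMI–difficulty
  coupling; real item-response data show guessing and discrimination
  structure this ignores.
* The published rank correlations for the reference item table (0.455 /
  0.488) are not reproducible from that table's printed columns (see the
  scoring section); the package's values are 0.339 / 0.364.
* Permutation inference assumes exchangeability of reduced-model residuals;
  heteroscedastic or spatially nonstationary noise is not modelled.
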