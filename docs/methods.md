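# Methods

## Scope and data model

`rvcpipe` analyzes longitudinal, standard-space ROI volumes. Everything
upstream of the ROI volume table — acquisition, registration to the
ICBM152 template, construction of the tissue atlases — is out of scope;
the package ingests either a long-format volume CSV or integer-labeled
NIfTI images plus a parcellation spec. Label images are interpreted in
voxel space (volume = voxel count × header voxel volume, in mm³); no
resampling is performed.

The parcellation assigns each ROI to one of four tissue classes: GM,
WM, CSF, and dCSF (ventricular CSF). dCSF is anatomically part of CSF
but is carried as an independent aggregation set because ventricular
change is the exposure-sensitive signal of interest; the whole-brain
summary (rBVC) uses GM/WM/CSF only, whose fixed weights
(0.4262/0.3912/0.1826, the ICBM152 mask fractions) sum to 1. The
within-tissue weights `c_i` come from atlas voxel counts, not from any
subject's measured volumes, so they are identical across athletes and
sessions.

All relative changes are dimensionless fractions internally; percent
appears only at reporting boundaries (the post-hoc matrix and the CSV
report layer). Baseline sessions never appear as follow-up rows, and
athletes missing a session simply lack rows — downstream stages define
their own completeness rules (listwise deletion for the rANOVA and
sphericity checks, pairwise for the post-hoc matrix, with per-cell n
reported).

## Exposure processing

Raw telemetry (HITS and xPatch sensors, pooled without cross-sensor
calibration) is pruned by two rules, in order: the event timestamp must
fall inside a declared practice/game activity window, and the PTA must
be at least 20 G. Window membership is decided from the timestamp
against the window table, not from any window id recorded by the
sensor. The pruning log partitions the raw count exactly into
retained / out-of-window / sub-threshold.

Counting uses the Heaviside convention `u(0) = 1`: an event exactly at
a threshold counts. Cutoff times are explicit inputs (one per follow-up
session, strictly increasing); events strictly before the cutoff accrue
to the session, making counts non-decreasing in session and
non-increasing in threshold by construction. Athletes flagged as having
incomplete telemetry are removed from the exposure matrix (and hence
from the screen and the linear predictor) before analysis; they retain
their imaging rows.

## Inferential battery

- **Unpaired t-tests** default to the classical pooled-variance form;
  Welch's correction is a flag. Zero-variance degenerate inputs raise
  rather than returning an arbitrary statistic.
- **Mauchly's W** is computed from the covariance of orthonormal
  (Helmert) within-subject contrasts; the p-value uses the chi-square
  approximation with the standard second-order correction term (the
  form used by ezANOVA and SPSS). With two sessions sphericity is
  vacuous (W = 1).
- **KS normality** tests against a normal with mean and SD estimated
  from the sample. The returned p-value is the standard one-sample KS
  p, which is anti-conservative under estimated parameters; this
  Lilliefors caveat is recorded in the result note. The check is a
  gate-keeping diagnostic, not a reported endpoint.
- **rANOVA** is the one-way repeated-measures partition
  `SS_total = SS_subject + SS_session + SS_error` over complete cases,
  F with df `(k−1, (k−1)(n−1))`. A Greenhouse–Geisser df correction
  exists behind a flag and is off by default; sphericity or normality
  failures are reported but do not halt the pipeline.
- **Bonferroni families**: 6 for the within-cohort paired matrix over
  `{In1, In2, Post1, Post2}`, 4 for the across-cohort comparisons
  against `Retest`, and thresholds × sessions (48 when the full grid is
  non-degenerate) per tissue for the Pearson screen. Degenerate screen
  cells (zero exposure variance, typically the highest thresholds) are
  excluded from the family; family sizes are configurable and always
  reported. `Post3` is excluded from the rANOVA and the pairwise matrix
  (it exists to probe prolonged recovery) but included in deviation
  maps.
- **Linear predictor**: ordinary least squares of tissue change on
  event count, intended only for screen-significant cells, with the
  textbook pointwise 95% band for the mean response,
  `ŷ ± t_{0.975,n−2}·s·sqrt(1/n + (x−x̄)²/Sxx)`.

## Deviation maps

For each tissue, the control cohort's rTVC at `Retest` defines a 95%
reference interval; each collision-cohort ROI is flagged per session
when its mean rRVC across athletes lies strictly outside it (means
exactly on a bound are within reference). The comparison of ROI-level
means against a tissue-level interval is a deliberate fidelity choice
and is logged as a scale mismatch.

The default interval is population-style, `mean ± 1.96 s`. The
alternative — the t-based CI of the control mean,
`mean ± t_{0.975,n−1}·s/√n` — is available as `method="mean_ci"` but is
not the default for a sampling-theoretic reason: the mean-level CI
half-width shrinks as `1/√n`, the same rate at which the two cohorts'
session means fluctuate, so under a null cohort the difference between
a collision session mean and the control interval is of the same order
as the interval itself at every n. The consequence (observed in
simulation) is bimodal null behavior — most seeds flag almost nothing,
while occasional seeds flag entire tissues wholesale. The population
interval keeps null maps stably sparse, leaves WM maps empty, and makes
the GM negative count peak sharply at `Post1` rather than saturating
across all in-season sessions.

Map serialization writes one NIfTI label image per non-empty
(tissue, session, direction) map — an all-clear tissue (WM, in both the
motivating data and the default simulation) produces no image file —
plus a tidy CSV of all flags.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults encode the
study design the analysis assumes. Roster: 38 male football and 19
female soccer collision athletes (sessions
`Pre/In1/In2/Post1/Post2`, a 21-athlete non-senior subset adding
`Post3`), 29 controls (`Test/Retest`), and 2 football athletes with
incomplete telemetry.

Observed volume for athlete *j*, ROI *i*, session *k*:

    Vol = scale_j · atlas_i · (1 + effect_ijk) · g_jk · e_ijk

- `scale_j`: lognormal per-athlete head-size factor (σ = 0.10).
- `g_jk`: lognormal per-scan global scale jitter shared by all ROIs of
  the scan (σ = 0.008). This component is what gives tissue-level
  aggregates a realistic variance floor; without it, averaging over
  ROIs would shrink control tissue variance as `1/√N_ROIs` and every
  reference interval would be implausibly narrow. It emulates
  positioning/registration-like error, which is global, not per-ROI.
- `e_ijk`: independent lognormal per-ROI measurement noise (σ = 0.008).
- `effect`: zero for controls and for WM/CSF. GM carries a concave-up
  per-session trajectory, parameterized as per-session offsets because
  the analysis is session-indexed: 0 at `Pre`, −0.89% at `In1`, −1.80%
  at `In2`, −2.44% at `Post1`, −0.01% at `Post2`, 0 at `Post3`
  (magnitudes follow the across-cohort session contrasts the design
  targets). dCSF carries `slope × nHAE_latent(j,k)` during the exposure
  sessions with slope 0.0025 per event above the latent 50 G threshold,
  reverting to baseline at `Post2`/`Post3`.

Both noise factors are mean-one, and follow-up volumes carry the
deterministic factor `exp(−(σ_g² + σ_e²))` cancelling the lognormal
ratio bias, so the expected relative change of a follow-up equals the
injected fractional effect exactly — the property the Monte-Carlo
generator tests assert.

Telemetry: Poisson event counts per activity window (mean 4; 15
windows per inter-session interval across `Pre→In1→In2→Post1`, none
afterwards), lognormal PTA magnitudes (median 25 G, shape 0.5), 5%
spurious out-of-window events, HITS for football and xPatch for soccer.
These magnitudes are stated placeholders — no distributional facts
about the motivating study's telemetry are available — chosen so that a
season yields a few hundred retained events per athlete, of which ~15
exceed 50 G, and the resulting dCSF–exposure correlation at `Post1`
(r ≈ 0.6 at n = 55) is strong enough to survive a 48-cell Bonferroni
screen, as the motivating analysis reports. Incomplete-telemetry
athletes lose all *observed* events from a random mid-season window
onward (encoder failure); the complete stream still drives their
volumes, since the athlete experienced the events whether or not the
sensor recorded them.

What the generator does **not** emulate: per-ROI biological effect
heterogeneity (the GM effect is uniform across a tissue, so effect
sessions flag most GM ROIs rather than the scattered subsets real data
show), spatial correlation between neighboring ROIs, sensor
measurement error on individual PTAs, athlete-specific impact-rate
heterogeneity beyond Poisson variation, and attrition other than the
`Post3` subset rule. Passing tests therefore demonstrate that the
pipeline's statistics are wired correctly and recover injected
parameters under the assumed error structure — not that the pipeline
would detect effects of any particular size in real data.

## Numerical and degenerate-input choices

- Bonferroni is always `min(1, m·p)` with `m` reported; corrected p is
  monotone in raw p by construction.
- Pearson cells with zero variance in either variable are marked
  degenerate and excluded from the family rather than silently skipped.
- Paired comparisons with fewer than two complete pairs are reported as
  unavailable, not dropped.
- rANOVA with zero error SS returns F = 0 (p = 1) when the session SS
  is also zero, else F = ∞ (p = 0).
- Exact threshold ties count as exceedances (`u(0) = 1`), and exact
  reference-bound ties are within reference (strict inequalities), both
  stated conventions rather than float accidents.
- Replicate-loop tests use a reduced parcellation (6 GM / 2 WM / 2 CSF
  ROIs) that keeps the default 15-ROI dCSF granularity, since dCSF
  tissue-level noise — the quantity that matters for recovery tests —
  depends on its ROI count; the default 300-ROI atlas is used wherever
  a single cohort suffices.

## Known limitations

- The sex-effect check tests each tissue separately with no correction
  across tissues (they are partitions of one brain, not independent).
- The KS p-value's Lilliefors bias is documented, not corrected.
- No mixed-effects, covariate-adjusted, or errors-in-variables
  modeling; the linear predictor treats counts as fixed.
- The deviation-map procedure compares ROI-level means against a
  tissue-level interval by design; its flags are descriptive, not
  inference-corrected for 300 simultaneous comparisons.
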