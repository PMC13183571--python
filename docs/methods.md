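# Methods

This note records the models, conventions and numerical choices behind
the package, including the places where the design was genuinely open.

## Gait metrics from footfall events

The unit of analysis is a *walk*: the pooled step data of two walkway
trials for one subject and condition (trial pairs (1,2) and (3,4) in
recording order — the pairing of four recorded trials into two walks is
a convention; consecutive pairing is the natural reading of a recording
session). Pooling exists to accumulate enough gait cycles for stable
variability and asymmetry estimates (we warn below 15 cycles and require
at least 4 strides per foot); strides are never formed across the trial
boundary, and each trial keeps its own clock and spatial frame.

**Progression axis.** The walkway's y-axis is only nominally the
lateral direction. Each walk's progression axis is re-estimated as the
principal axis of the heel point cloud after centering each
(trial, foot) group separately. Per-group centering matters: without
it, the lateral offset between the feet and the spatial reset between
trials tilt the axis systematically. The residual, sampling-driven tilt
is the dominant error term of the spatial metrics (stride length,
base of support) and shrinks with the number of steps; temporal metrics
are unaffected.

**The 13 metrics.**

- *Pace*: velocity = progression distance / ambulation time computed
  per trial and combined weighted by trial duration (a pooled walk
  contains a spatial reset, so end-to-end displacement would be wrong);
  stride length and stride time are means over all strides of both feet.
- *Phase*: swing and double support as a percentage of each stride's
  cycle time, then averaged. Double support is computed by the temporal
  identity `cycle − swing(own) − swing(opposite stride initiated within
  the cycle)`. For a well-formed alternating footfall pattern this
  equals the sum of the two bipedal overlap intervals (verified in the
  tests on a hand-built fixture); unlike interval intersection it stays
  well defined when the left–right contact phase wanders, which any
  sustained left–right stride-time difference forces (a per-foot mean
  difference d drifts the phase by m·d over m strides — a physical
  constraint of alternating gait, not an artifact).
- *Variability*: CV = 100·SD/mean with sample SD (ddof = 1), strides of
  both feet pooled into one sample per walk (pooling maximizes cycles
  per estimate).
- *Asymmetry*: the absolute symmetry index
  100·|mean_L − mean_R| / (0.5·(mean_L + mean_R)). Walkway vendors
  differ here; a log-ratio form (100·|ln(mean_L/mean_R)|) is available
  behind the `asym_formula` switch, the symmetry index being the default
  because it matches the magnitude scale on which such tables are
  usually reported.
- *Postural control*: base of support per step is the lateral heel
  distance to the opposite foot's line of progression within the same
  trial, the line taken at the opposite foot's mean lateral offset along
  the walk's progression axis. We use the fitted line rather than a
  local two-point construction because the local line inherits the
  lateral noise of its two support points (≈ √1.5 inflation of the
  base-of-support SD), confounding the width-variability estimate.

**Outliers.** Per metric × condition, a subject's walk pair is removed
when either walk value lies beyond the cohort mean ± 3 SD for that walk;
both walks leave together, and removal in one metric does not affect
another. Removal fractions are logged in the run manifest.

## Reliability

Two-way ANOVA mean squares (subjects × walks) feed both single-measure
ICC forms. The published convention for this design is ambiguous — the
label "absolute agreement ICC(3,1)" mixes the Shrout–Fleiss
consistency numbering with the McGraw–Wong agreement definition — so
both are implemented and the pipeline records which form produced each
number; the default is absolute agreement, honoring the words over the
numbering. With k = 2 and a small walk effect the two forms nearly
coincide. Confidence intervals: exact F for consistency; McGraw–Wong
with Satterthwaite degrees of freedom for absolute agreement (validated
against pingouin and, for the point estimates, against an independent
least-squares variance-components computation). Band edges assign 0.5
and 0.75 upward and keep 0.9 in "good". A zero residual mean square
yields ICC 1 under consistency with a degenerate F (p reported as 0,
below any representable tail); subjects with a missing walk are dropped
listwise per metric × condition and counted in the manifest.

## Change thresholds

SEM = SD·√(1 − ICC) and MDC95 = 1.96·√2·SEM use the cohort SD pooled
over the two walks of the condition after outlier removal — consistent
with reporting a single mean ± SD per condition. Values entering the
anchor regressions are each subject's mean of the two walks (averaging
halves measurement error in a cross-sectional anchor design). Anchors
whose improvement is a decrease (FES-I) enter as a signed change (−8),
so B × ΔA always carries the metric's improvement direction; report
tables sign every estimate the same way (positive: velocity, stride
length, swing; negative: stride time, double support, variabilities,
asymmetries, base-of-support metrics). Report rounding is 2 decimals,
half away from zero. The triangulated MCID averages the medium-effect
distribution estimate with whichever anchor estimates cleared the
|r| > 0.3 gate (at least 10 complete pairs required); with no members it
is absent, never zero.

## The synthetic cohort generator

The generator emulates the data-generating process the analysis assumes,
at two levels.

**Metric level** (`simulate_metric_cohort`). For metric with population
mean μ, SD σ and target ICC ρ: subject true values carry variance ρσ²
and each walk adds noise of variance (1 − ρ)σ², so the expected
two-walk ICC is exactly ρ. Defaults calibrate all 39 metric × condition
cells to a chronic-vestibulopathy cohort (e.g. PWS velocity
98.27 ± 21.27 cm/s at ICC 0.98; cycle counts 21.8 ± 4.5 / 29.2 ± 4.8 /
30.4 ± 8.5 per walk for PWS/SWS/EC). Subject effects load (λ = 0.75 by
default) on one latent mobility factor, on which the anchor scores are
linear: FGA = 22 + 4z (residual SD 3, clipped to 0–30),
FES-I = 36 − 8z (SD 6, 16–64), PCS-12 = 38 + 6z (SD 4.5),
MCS-12 = 50 + noise (carried, unused). These put the default
metric–anchor correlations near |r| ≈ 0.5 — deliberately above the 0.3
gate so the anchor-based path is exercised by default; real cohorts gate
out many more cells. The magnitudes of real metric–anchor correlations
are not published; these slopes are this package's own choice.

**Step level** (`synthesize_step_stream`). Per-cycle stride times,
stride lengths and swing fractions are drawn per foot and *moment
matched*: affinely standardized so the realized per-foot means, the
pooled sample SD and hence the symmetry index hit the walk's targets
exactly. Lateral heel noise (standardized per trial and foot) realizes
the base-of-support CV. Moment matching is what makes round-trip
testing meaningful at realistic walk lengths — the sampling error of a
free CV estimate at 20–40 cycles would swamp any extraction defect.
Two quantities are structural rather than free: velocity
(≈ stride length / stride time) and double support
(≈ 100 − 2·swing %). The generator derives them from the other targets
and rejects requests that conflict with the identities (as it rejects
swing ≥ 50 %, which would imply negative double support, and asymmetry
targets exceeding the variability that must carry them). The default
calibration is internally consistent to ~1.3 % (velocity) and ~0.5 %
(double support).

Consequences worth knowing: (i) extracted velocity and double support
track their structural values, so their realized reliabilities follow
the metrics they derive from rather than their own nominal targets
(velocity lands near its target because stride length and time are
highly reliable; double support inherits swing's reliability); (ii) in
full-study rendering, drawn walk targets are clamped into the physically
realizable region before synthesis (rare-event guards for normal draws
that leave the domain — negative CVs, infeasible asymmetry, out-of-range
swing), and both requested and effective targets are written to the
ground-truth file.

**What the generator does not model.** No joint kinematics or
ground-reaction forces; no turning, no fatigue or learning drift across
trials; heavy-tailed or skewed metric distributions (all draws are
normal, so the Shapiro–Wilk stage sees clean data); anchor floor/ceiling
behavior beyond simple clipping; correlations between different metrics
beyond the single latent factor. Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
every pathology of real walkway data. The MDC-versus-MCID balance also
depends on the ICC calibration: synthesizing at printed (rounded) ICCs
yields somewhat larger MDCs, and hence more below-MDC flags, than tables
computed from unrounded reliabilities.

## Group comparison

Welch's t-test by default (groups of 60 and 30 with no variance
guarantee); Student's pooled form behind a switch; two-sided p-values,
no multiplicity adjustment across the 13 × 3 grid (raw per-metric
reporting). Shapiro–Wilk p-values are attached per group as normality
flags. The healthy-control calibration is the patient calibration under
normative shifts (≈ +18 % velocity, ~45 % lower variability and
asymmetry, ~20 % narrower base of support, 20 % smaller SDs) — controls
have no published table, so these are this package's own choice with
magnitudes typical of healthy-versus-vestibulopathy contrasts.

## Problem sizes and numerical conventions

Default study size is 60 patients + 30 controls × 3 conditions × 2
walks (the full pipeline runs in a few seconds). Monte-Carlo validation
sizes were chosen so the sampling error of each checked statistic sits
well inside its assertion band: 5000 subjects for calibration recovery,
1000 replicates for CI coverage, 200 cycles for stochastic round trips,
with a handful of replicate seeds averaged where a single draw's error
would be comparable to the band. All randomness flows from explicit
seeds; fixed seed means byte-identical output files. Ties in report
rounding go away from zero via decimal arithmetic (binary floats would
otherwise misround exact halves). Degenerate inputs (constant samples,
zero variance, too few strides or pairs) are reported as absent values
or raised as typed errors, never silently coerced to zero.
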