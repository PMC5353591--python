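# Methods

This note documents the models, conventions and design choices behind
`vqlung`, in the order data flows through the pipeline.

## Grid model and geometry

All volumes live on axis-aligned 3D grids: voxel indices are 0-based, axes
are ordered (x, y, z), and the origin names the patient-frame position (mm)
of the *center* of voxel (0, 0, 0). Two volumes are considered aligned when
shapes match exactly, spacings agree within 1e-6 mm and origins within
1e-3 mm per component; the tolerances absorb format round-tripping noise
(NIfTI stores affines in float32-ish precision) without hiding real
misregistration, and are exposed in `RunConfig`. Registration itself is out
of scope: inputs are assumed co-registered, as they would be after fusion in
a treatment planning system.

Resampling onto the dose grid uses trilinear interpolation for activity
(smooth fields) and nearest-neighbor for masks (preserves binarity). Voxels
of the target grid whose centers fall outside the source extent are filled
with 0 — no dose and no activity outside the imaged volume, conservative for
both. Linear resampling requires at least two voxels along every source
axis; the degenerate axis is named in the error. Nearest-neighbor index
rounding uses `np.rint` (ties to even), a fixed, documented tie-break.

Only diagonal NIfTI affines are accepted. Negative diagonal entries (axis
flips, common in RAS exports) are repaired by flipping the array so that
in-memory spacing is always positive; oblique affines are rejected outright
because a rotated volume cannot be represented losslessly on this grid
model, and silently resampling at load time would hide a processing step.

## Functional segmentation

Perfusion- or ventilation-functional lung is the set of lung-mask voxels
with activity ≥ t · A_ref, with threshold fraction t = 0.30 by default.
Two conventions needed fixing where common usage is loose:

* **Reference maximum.** A_ref is the maximum activity *within the lung
  mask*, not the global field-of-view maximum. Injection-site, cardiac or
  airway hot spots outside the lung would otherwise depress the functional
  region arbitrarily. A robust alternative (percentile of in-lung activity,
  e.g. 99th) is available via `reference_percentile` but off by default,
  since the plain maximum is the convention this analysis follows.
* **Boundary rule.** Inclusion at the threshold is closed (≥). A strict
  (>) flag exists; the closed rule makes the uniform-activity case
  degenerate cleanly (every voxel at 100% of max ⇒ functional lung =
  anatomical lung).

The segmentation is a binary mask, not an activity-weighted map. An
activity-weighted alternative (fMLD = Σ a·d / Σ a, and the analogous fVx)
is provided in `dosimetry.activity_weighted_metrics` as an explicit
non-default mode; with uniform activity it reduces exactly to the
unweighted metrics. The binary 30%-of-max region is the primary definition
throughout.

Whether the lung mask includes the gross tumor volume is the caller's
decision; the pipeline takes the mask as given.

## Dosimetry

The cumulative DVH for region Ω uses bin edges 0, w, 2w, … up to
⌈max dose/w⌉·w (default w = 0.1 Gy); the value at each edge e is
100 · |{i ∈ Ω : d(i) ≥ e}| / |Ω|. Relative volume is by voxel count —
within one grid all voxels have equal volume. Vx uses the same ≥ comparison,
so `vx` evaluated at any DVH edge equals the curve exactly. The ≥ convention
(rather than a literal "more than") matches standard treatment-planning
DVH behavior; a strict-inequality flag exists in `RunConfig`.

Functional V20 uses the functional region as its own denominator (a
functional DVH therefore starts at 100%, like the anatomical one). MLD is
the plain arithmetic mean over the region. Useful identities, all enforced
by tests: MLD equals the integral of the cumulative DVH fraction over dose
(within one bin of trapezoid error, shrinking under refinement); metrics are
equivariant under dose rescaling; with uniform activity all functional
metrics collapse to the anatomical ones exactly.

## Cohort statistics

RILT is an input CTCAE grade 0–5; the analysis outcome is the binary event
grade ≥ 2 (an ordinal-grade mode exists behind `outcome="grade"`). Spearman
correlation is computed as the Pearson correlation of average-rank vectors
(tie-corrected by construction); p-values use the t approximation
t = r·√((n−2)/(1−r²)) on n−2 df, or a seeded permutation test with the
add-one estimator (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1). Strata with
n < 3 or a constant outcome are reported with an explicit not-computable
flag rather than dropped. No multiple-testing correction is applied by
default; a Holm column is available behind a flag.

**Dominance labels.** To summarize a stratum, each metric family — CT
(V20, MLD), Q (Q-V20, Q-MLD), V (V-V20, V-MLD) — is reduced to the mean of
its two |r| values; families are sorted descending and adjacent pairs within
ε = 0.05 are joined with "≈", otherwise ">". At exact equality the print
order is V, Q, CT. The ≈ relation is symmetric, so `V ≈ Q > CT` and
`Q ≈ V > CT` describe the same ordering; `dominance_groups` parses labels
into ordered ≈-groups for order-insensitive comparison.

**Characteristic comparisons.** Each covariate is tested against the event
in a 2×k contingency table: 2×2 tables use the continuity-corrected
chi-square in the clamped textbook form
χ² = n(max(0, |ad−bc| − n/2))²/((a+b)(c+d)(a+c)(b+d)) — the clamp makes
near-homogeneous tables give χ² = 0, p = 1 deterministically — switching to
Fisher's exact test when any expected count is below 5; k > 2 tables use the
plain chi-square with a small-sample flag.

## Synthetic data

The generators define the study conditions the tests run under; they are
first-class, tested code.

**Phantoms.** Two ellipsoidal lungs on a 40×40×32 grid at 4 mm isotropic
(grid resolutions are not dictated by anything upstream; these are working
defaults, overridable in `PhantomSpec`). Dose is a sum of rectangular or
Gaussian fields with peaks in the 60–66 Gy prescription range (default one
63 Gy Gaussian field). Activity is a uniform baseline (100 counts) times
mean-preserving multiplicative lognormal noise (σ = 0.15), times a residual
fraction inside each ellipsoidal defect region; a ventilation-only defect
with preserved perfusion is the COPD-typical V/Q mismatch pattern. Defects
must lie inside the lung. No SPECT physics (collimator blur, attenuation,
scatter) is modeled: phantoms exercise the pipeline's arithmetic, and
passing tests say nothing about segmentation robustness to real acquisition
artifacts.

**Worked-example fixture.** The two-case fixture is built combinatorially,
not by tuning a realistic phantom: the lung is a 25×20×20 voxel block
(N = 10,000, 3 mm isotropic), exactly 2,500 voxels receive 25 Gy (the rest
5 Gy), and the functional regions are allocated by exact voxel counts —
toxicity case |Q| = 2000 with 700 in the high-dose region (35%) and
|V| = 3000 with 990 (33%); non-toxicity case |Q| = 2000/400 (20%) and
|V| = 2500/550 (22%). Activity is two-level (1.0 inside the intended
region, 0.1 outside) so 30%-of-max segmentation recovers the construction
voxel for voxel. A build-time brute-force recount asserts all six
proportions before the fixture is returned.

**Cohort simulator.** A latent toxicity propensity z ~ N(0,1) drives
everything. Each metric is a monotone map of ρ_f·z + √(1−ρ_f²)·ε (ε
standard normal, independent per metric), transformed by the normal CDF
into plausible clinical ranges — V20-type metrics into 10–45%, MLD-type
into 8–25 Gy (invented ranges, documented as such). Because
(metric latent, z) is bivariate normal with Pearson correlation ρ_f, the
metric-vs-propensity rank correlation is analytically (6/π)·arcsin(ρ_f/2);
the defaults ρ_CT = 0.3, ρ_Q = ρ_V = 0.7 plant a strong functional and weak
anatomical association. The event model is P(grade ≥ 2 | z) =
expit(a + 4·z), the intercept a root-solved so the expected event count
matches the target (15 of 57). The slope 4.0 was chosen because observed
functional-metric correlations with a binary 15/57 outcome in this setting
plateau near |r| ≈ 0.47–0.50 as the dose–response steepens, and a steep
(near-threshold) response is the only regime producing event-based
correlations of the magnitude such studies report; it is a fixed default,
not a fitted quantity. Covariates are assigned by seeded permutation to
match marginal level counts (defaults mirror the fixture cohort's margins;
rescaled by largest-remainder rounding for other cohort sizes).

The deterministic fixture cohort assigns the event to the 15 largest
propensities (exact count) and distributes every covariate within the
event/non-event groups to match the tabulated conditional cells exactly;
grades and ages are deterministic functions of the propensity order and the
assigned age group.

What the simulator does *not* model: metric–metric correlation beyond the
shared latent (real V20 and MLD are strongly coupled through the plan),
covariate–outcome and covariate–metric dependence (COPD status is assigned
independently of z), and within-patient consistency between the phantom
and cohort arms. Cohort-level results on simulated data therefore validate
the statistical machinery, not clinical effect sizes.

## Numerical and statistical notes

* Vx/DVH counting is exact integer counting on float comparisons; no
  epsilon is applied at the 20 Gy (or threshold) boundary — the inclusive/
  strict choice is explicit instead.
* Spearman r is clipped to [−1, 1] after the rank-Pearson computation to
  absorb last-bit float excursions; |r| = 1 short-circuits the t p-value
  to 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; permutation p-values require a seed, there is
  no hidden global state.
* One known statistical limitation, kept deliberately visible: at n = 57
  the sampling noise of a family-mean |r| difference between the two
  functional families is ≈ 0.07–0.09 sd, so with ε = 0.05 the all-patients
  dominance label lands in the "functional families tied above CT" pattern
  in roughly 45% of simulated replicates, not near-always, even though the
  planted effects are identical (ρ_Q = ρ_V). Equivalence calls between
  families at this sample size are unstable by construction; the
  corresponding acceptance test documents this by failing, and the stable
  quantities (mean recovered rank correlation per family; functional
  families beating CT) are asserted separately.
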