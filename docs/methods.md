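# Methods

## The two-timepoint ICED model

Intra-class effect decomposition treats two repeated measurements of the
same quantity as indicators of a single between-subjects factor.  Both
loadings are fixed to 1; the factor variance σ²B captures stable individual
differences and the occasion-specific residual variances capture everything
else — scanner noise, segmentation error, within-person fluctuation, and
(over long intervals) individual differences in true change.  The default
specification constrains the two error variances to be equal
("strict invariance" across occasions), giving the compound-symmetric
implied covariance

    Sigma = [[σ²B + σ²E, σ²B], [σ²B, σ²B + σ²E]].

Means are saturated and ignored: a uniform developmental shift between
occasions (everyone's cortex thinning by the same amount) does not affect
any quantity this model estimates.  What the model *cannot* do with two
timepoints is separate measurement error from individual differences in the
rate of change; both land in σ²E, which is why estimates from long-interval
data are read as **longitudinal stability** rather than pure reliability.

### Estimation

Only the 2×2 sample covariance S and n are needed.  We minimise the
normal-theory discrepancy

    F(θ) = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − 2

by BFGS on (σ²B, σ²E) with analytic gradients, started from the moment
estimates, followed by a damped-Newton polish with the analytic Hessian
(parameter accuracy ~1e-10).  Variances are unbounded during optimisation,
mirroring common SEM practice: a negative estimate is reported with a
warning rather than silently truncated, and the ICC is clipped to [0, 1]
only at the reporting stage.  A box-constrained mode
(`ModelSpec(nonnegative=True)`) is available.  For interior solutions the
minimiser coincides with the closed form σ̂²B = s12,
σ̂²E = (s11 + s22)/2 − s12, which the test suite verifies against an
independent grid-search oracle.

χ² is computed as (n − 1)·F at the minimum (Wishart likelihood of the
sample covariance).  Users cross-checking against SEM software that weights
by n should expect proportional differences of (n−1)/n.

The unconstrained (free error variances) model is saturated — three
parameters for three moments — so it reproduces S exactly with χ² = 0,
df = 0, CFI = 1.  Comparing it with the constrained model
(ΔCFI = 1 − CFI_constrained, threshold .02 by convention) is the built-in
check of equal error variances across occasions.

### Fit indices

CFI = 1 − max(0, χ²m − dfm) / max(0, χ²m − dfm, χ²b − dfb), with both
excesses zero defined as CFI = 1.  The baseline is the independence model
(zero covariance, two free variances, df = 1), whose ML discrepancy has the
closed form −log(1 − r²).

### ICC, ICC2, and intervals

ICC = σ²B/(σ²B + σ²E) is the stability of one measurement.  ICC2
substitutes the *effective error* σ²E/N of the average of N independent
occasions: ICC2 = σ²B/(σ²B + σ²E/N).  It equals ICC at N = 1, exceeds it
for N ≥ 2, and tends to 1 as N grows whenever σ²B > 0.

Confidence intervals for the ICC use the profile likelihood under the
reparameterisation (total variance T, ICC ρ): for fixed ρ the discrepancy
is minimised analytically at T̂(ρ) = tr(S C(ρ)⁻¹)/2 with C(ρ) the implied
correlation matrix, leaving a one-dimensional likelihood-ratio function
inverted at the χ²(1) quantile by bracketed root-finding.  Boundary
estimates (ICC pinned at 0 or 1, e.g. error-free data) yield a flagged
one-sided interval.  Calibration: at n = 5,000 and true ICC = .5, 200
simulated replicates cover the truth 95.5% of the time at the nominal 95%
level (recomputed by the test suite).

## Multigroup models

Across G groups (sites, or scanner manufacturers — same code path,
different grouping column), four nested models localise where stability
differs: both components equal across groups (p = 2), σ²B free (p = G+1),
σ²E free (p = G+1), both free (p = 2G).  Each group contributes three
moments, so df = 3G − p, and the error variances at the two occasions stay
equal within each group.  The joint discrepancy Σg (ng − 1)·Fg is minimised
by BFGS with analytic gradients on the stacked parameter vector (scaled by
total weight so convergence tolerances are sample-size invariant); the
fully free model factorises into independent per-group fits.  The CFI
baseline is the sum of per-group independence models (df = G), consistent
with the single-group baseline.

Five ΔCFI comparisons, oriented toward the less constrained model, follow:
A (free σ²B), C (free σ²E), B/D (the complementary relaxations), and E
(free both).  ΔCFI > .02 (configurable) flags a meaningful difference.
Because the models are nested, χ² is monotone along each arm and
ΔCFI_E ≥ max(ΔCFI_A, ΔCFI_C) up to numerical tolerance.

## Stability maps and their second-order summaries

`fit_region_map` batch-fits every measure × region × group cell, degrading
per-cell failures (too few cases, constant values, non-convergence) to
status codes so batches always complete.  Downstream:

- **Dispersion decomposition** — per-region medians (over sites) of each
  component, then the variance of those medians across regions, and the
  transposed computation across sites.  A large between/error variance
  ratio on the region axis and a large error/between ratio on the site axis
  reproduce the qualitative finding that region differences are
  people-driven while site differences are noise-driven.  With all-equal
  generating components both numerator and denominator collapse to sampling
  noise — whose magnitudes differ between the two estimators — so the null
  ratio is not 1; tests therefore compare heterogeneous against homogeneous
  runs rather than against unity.
- **Rank-order stability** — Shrout–Fleiss ICC(2,1) (absolute agreement)
  and ICC(3,1) (consistency) of an estimate matrix, from two-way ANOVA mean
  squares.  "By region" puts regions in rows with sites as raters (are the
  same regions stable everywhere?); "by site" transposes (are the same
  sites good everywhere?).  The two orientations are genuinely different
  questions and the tests assert the asymmetry.
- **Lobe aggregation** — unweighted mean for thickness, sums for area and
  volume, per participant per timepoint, hemispheres separate.  The shipped
  `dk_lobes.yaml` groups the 34 standard parcellation labels per hemisphere
  into five lobes (insula kept with frontal); it is editable data.  A
  surface-area-weighted thickness mean is deliberately not the default
  (plain means match the usual convention); total volume is preserved
  exactly by construction.

Preprocessing applies an arbitrary rescaling constant (default .001) to
area- and volume-like measures so all three measures fit on comparable
numeric scales; the model is scale-equivariant (components scale by c²,
ICC/ICC2/χ²/CFI invariant), so this affects conditioning only.  An
optional holdout withholds a configurable number of participants for
exploratory model tuning before final fits.

## Design planning

- **Required timepoints**: ICC2 > t rearranges to the strict bound
  N > (t/(1−t))·σ²E/σ²B (for t = .9: N > 9·σ²E/σ²B).  The smallest integer
  strictly above the bound is returned, with near-integer bounds snapped
  before flooring so exact-equality cases (ICC = .9, target .9 → N = 2) are
  not corrupted by float noise.  σ²B = 0 is unattainable (∞); σ²E = 0
  needs one timepoint.
- **Attenuation**: r_observed = r_true·√rel_x·√rel_y (Spearman) —
  symmetric, multiplicative, and never amplifying.
- **Sample size**: Fisher z without small-sample correction,
  n = 3 + ((z_{1−α/2} + z_power)/atanh r)², reporting the integer part by
  default (`rounding="ceil"` for the conservative choice).  The report
  helper rounds attenuated correlations to two decimals before the power
  step — power figures are conventionally quoted at the printed precision
  of the correlation — with `r_decimals=None` opting out; at full precision
  the weaker-region example yields n = 177 rather than 175.

## The synthetic generator

`generate_dataset` draws value_t = μ_r + Δ_r·1[t=2] + b_i + s_i·1[t=2] + e_it
with Gaussian b_i, s_i, e_it, independently per (participant, region,
measure).  It emulates the *structure* of a large multi-site developmental
cohort — 21 sites at ~350 participants with a 13/3/5 Siemens/Philips/GE
manufacturer split (proportionally rescaled for other site counts), 68
regions, three measures, two occasions — with per-region σ²B and
per-site×region σ²E under user control.  A desk-scale profile (5 sites ×
400, 8 regions) serves fast iteration; tests run at sizes from 60 to
50,000 participants chosen so each check's Monte-Carlo error is well below
its assertion tolerance.

Deliberate simplifications: no cross-region correlation of random effects
(real cortical measures are spatially correlated; irrelevant to the
per-region fits computed here, but lobe aggregates of synthetic regions are
"best case" noise-averagers), no missingness, no artifacts or heavy tails,
no site-by-demographics confounding.  `slope_sd > 0` adds per-subject
random change, which the two-timepoint model correctly absorbs into error —
tests use it to verify the stability-vs-reliability confound — but it is
off by default.  Passing tests on these data demonstrate correctness of
the estimators under the model's own assumptions, not robustness to
real-data pathologies.

Determinism: one `numpy` generator seeded from the config drives all draws
in a fixed site-major order, so a seed fixes the dataset bit-for-bit;
pipeline sub-stages (e.g. holdout sampling) derive their own seeds from the
run seed.

## Numerical conventions and degenerate inputs

- Convergence: BFGS gradient tolerance 1e-10 (weight-scaled for multigroup),
  Newton polish to ~1e-14 gradient norm; non-convergence is an explicit
  status ("non_converged"), never a silent result.
- Singular sample covariances (perfectly correlated or constant data) are
  handled as degenerate fits: components from the moment forms, ICC 1 or
  missing, flagged status — so map batches complete.
- Zero total variance → ICC/ICC2 reported missing with a warning.
- CFI with zero numerator and denominator → 1 by convention.
- Rank-order ICCs with zero between-target variance → missing.

## Limitations

Two timepoints only (no within-session nesting, no latent growth curves);
equal-error default can be inappropriate when acquisition changes between
waves — the ΔCFI check exists precisely to catch that; profile-likelihood
intervals assume the ML asymptotics of the Gaussian model; the multigroup
baseline convention (sum of independence models) matters to absolute CFI
values near the boundary, though ΔCFI comparisons are insensitive to it in
practice; region tables are user-supplied and atlas-agnostic — nothing is
hard-coded to a particular parcellation.
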