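# Methods

## Imaging model

A pQCT acquisition is represented as a single axial slice: a rectangular
grid of volumetric density values in mg/cm³ with square pixels (default
0.8 mm, the resolution of the XCT-class scanners this trait set comes
from). Slice thickness never enters: every mass-like trait is per unit
bone length (mg/mm, or mg/cm for polar bins).

### Segmentation

The outer bone border is found by thresholding at the site-specific level
(169 mg/cm³ for the distal tibia, 280 mg/cm³ for the midshaft), keeping
the largest 8-connected component (ties broken deterministically by the
smallest top-left pixel index) and filling interior holes; the filled
region is the periosteal envelope and defines CSA_TOT, marrow included.
Pixels below 100 mg/cm³ inside the envelope form the medullary mask.
Cortical bone is separated by a fixed density threshold, default
710 mg/cm³, followed by one pass of 2×2 binary opening to remove speckle
(a 2×2 block structuring element leaves any solid rectangle, and hence a
clean cortex, untouched — a 3×3 element would clip corners). The
commercial contour-detection mode used by scanner vendors is proprietary
and undocumented; a fixed threshold plus opening is the standard
reproducible substitute, and the threshold is exposed in the API. Absolute
cortical traits from real scans therefore need not match vendor software
bit for bit; the trabecular/subcortical compartment is defined by the
density window (above marrow, below cortex) rather than as the complement
of the cleaned cortical mask, so a speckle pixel dropped from the cortex
is not misread as trabecular bone.

An empty segmentation (no pixel reaches the threshold) yields flagged
empty masks and *missing* traits — never zeros.

### Traits

With pixel area a and density ρ_i:

* CSA_X = (pixel count of mask X) × a, and CSA_M ≡ CSA_TOT − CSA_CO holds
  exactly by construction.
* BMC_TOT = Σ ρ_i a × 10⁻³ (mg/mm); at the shaft the sum excludes
  medullary pixels, at the distal site marrow is included and
  BMC_TOT = vBMD_TOT × CSA_TOT × 10⁻³.
* BSI_COMP = (vBMD_TOT/1000)² × (CSA_TOT/100) in g²/cm⁴.
* I_max/I_min are the eigenvalues of the density-weighted second-moment
  tensor Σ ρ_i a [[dy², −dx dy], [−dx dy, dx²]] over the cortical mask,
  coordinates in cm about the density-weighted cortical centroid, pixel
  area in cm² — units mg·cm.
* The polar profile assigns each mass-bearing pixel's ρ_i a (mg/cm) to the
  5° bin containing its angle about the density-weighted centre (a
  geometric-centre option exists; which centre the original descriptions
  intend is ambiguous). Angle 0 is anterior, increasing toward medial; for
  a left leg the medial axis is mirrored. Sector j sums bins 9j…9j+8,
  spanning [45j, 45j+45) from the anterior axis — sectors aligned to bin
  borders make 90° grid rotations and left/right mirroring exact
  permutations, which a "centred" sector (±22.5°) built from 5° bins could
  not be. Pixels exactly on a bin border are snapped to the upper bin with
  a 10⁻⁹-degree tolerance so the assignment is stable under grid rotation
  round-off. An `angular_supersample` option splits each pixel's mass over
  an s×s subgrid before binning; it leaves bin and sector totals unchanged
  but smooths the jagged assignment of border-straddling pixels (used in
  rotational-symmetry checks; default off so one pixel lands in one bin).
* Muscle CSA counts ROI pixels with density in [11, 280) mg/cm³ — fat
  below, bone above. The ROI stands in for a manually drawn calf outline.
* CV_RMS = sqrt(mean over subjects of (100·SD_i/mean_i)²) with sample SDs;
  undefined (NaN) if any subject mean is zero.

### Phantoms

The phantom is an elliptical annulus: outer semi-axes a ≥ b, wall
thickness t (inner semi-axes a−t, b−t), cortical density ρ_co, interior
ρ_tr, background ρ_bg, optional rotation, centre offset and additive
Gaussian noise truncated at zero (density is physical). A pixel belongs to
a compartment when its centre lies inside the continuous boundary;
optional supersampling averages an s×s subgrid for anti-aliased edges.
Defaults (a = b = 13.8 mm, t = 6.3 mm, ρ_co = 1095) give a male
tibia-midshaft-like section: CSA_TOT ≈ 600 mm², CSA_CO ≈ 420 mm²,
CSA_M ≈ 180 mm².

Closed forms for the annulus (`analytic_phantom_traits`) provide exact
oracles: ellipse areas, BMC = ρ × area × 0.1 (mg/mm from mg/cm³ × cm²) and
I about a central axis = ρ (π/4)(a b³ − a_i b_i³) in mg·cm. Tests verify
that discrete estimates converge monotonically to these values as pixels
shrink from 0.8 to 0.2 mm, with ≤2% area and ≤3% moment error already at
the native 0.8 mm. The convergence fixtures use odd grid dimensions so the
phantom centre falls on a pixel centre at every scale; with even grids the
centre sits on a pixel corner and boundary-lattice resonance makes the
discretisation error oscillate instead of shrinking smoothly. What the
phantom does not model: projection/reconstruction physics, beam
hardening, partial-volume blur beyond pixel averaging, or realistic
peri-tibial soft-tissue anatomy.

## Cohort model

The generator draws a two-group (well-trained n₁ = 36, less-trained
n₂ = 33 by default), two-occasion cohort over K outcomes:

    y_i0k = μ_k + a_k (age_i − mean age) + b_ik + e_i0k
    y_i1k = y_i0k + Δ_k + δ_k·1[well-trained] + w_ik

with between-subject heterogeneity b_ik ~ N(0, σ_bk²), measurement error
e_i0k ~ N(0, σ_ek²), and a multivariate-normal change increment w with
per-outcome SD σ_dk and common correlation R. Building the follow-up on
the baseline residual makes each subject's change score exactly
Δ_k + δ_k·group + w_ik, so the change-score correlation matrix — the
input to the multiplicity correction — is exactly R. When
σ_d = √2·σ_e (the default when no change SD is given) the two occasions
are marginally exchangeable, i.e. the compound-symmetry covariance the
mixed model assumes holds exactly; the calibration simulations use this
regime. The shipped 19-outcome configuration instead widens the change SD
to 3.5% of the baseline mean, matching the magnitude of published
change CIs (biological heterogeneity in 10-year change exceeds √2× the
0.4–1.6% short-term measurement CV).

Parameter choices in the bundled configuration: baseline means/SDs and
per-group changes mirror the published table values for the 19 tibial
outcomes; measurement error is 1% of the baseline mean (mid-range of the
reported CV_RMS); the change correlation is exchangeable with r = 0.4,
which over 19 outcomes gives M_eff = 1 + 18(1 − 19r²/19) ≈ 16, the
effective test count reported for the real (unpublished) correlation
matrix; the baseline age gradient is −3.4%/decade, the cross-sectionally
reported trend; ages are truncated-normal 60.6 ± 11.1 on [40, 85];
follow-up records are missing at random at 1.5% per outcome. Because one
between-group difference per outcome shifts both outcomes of a pair, a
nonzero δ induces a small extra positive change correlation on top of R;
independence checks therefore set δ = 0. The generator does not model
training histories, dropout mechanisms related to health, skewed outcome
distributions, or scanner drift — passing tests show the statistics
recover what this generative model encodes, not that real cohorts satisfy
the model.

## Mixed model

Per outcome, a random-intercept model with fixed effects intercept, group
(well-trained = 1), time (0/1 per decade, so estimates read as 10-year
changes; non-standard occasions are treated as continuous time in
decades), group×time, and baseline age centred at the sample mean. With at
most two occasions the within-subject covariance is compound symmetry, so
(RE)ML profiles to a one-dimensional search over γ = σ_b²/σ_e²: for each γ
the GLS fixed effects and the residual scale are closed-form (per-subject
block inverses), and a bounded scalar minimisation over log γ (with the
γ = 0 boundary checked explicitly, which also handles zero-variance
outcomes) finds the optimum deterministically. REML is the default;
records are sorted canonically before accumulation so permuting input
rows is bit-identical. All available records contribute — subjects missing
follow-up still inform baselines and variance components. On balanced
complete data the fixed effects coincide with OLS, and the interaction
equals the difference of the groups' mean change scores; tests verify
this, the dense-GLS closed form, and agreement with an independent
general-purpose mixed-model fitter.

Inference is Wald-based with a t reference using containment degrees of
freedom for within-subject terms, df = N_obs − N_subjects − 2 — the df a
nested-levels mixed-model fitter assigns to level-1 effects. A normal
reference is asymptotically equivalent but measurably anticonservative at
these sample sizes (null rejection 5.3% vs 4.9% at 35/group over 3000
simulations), so the t reference is used for interaction p-values and
change CIs. No Satterthwaite or Kenward–Roger corrections are attempted;
random slopes and >2 occasions are out of scope. Baseline group contrasts
use Welch's t test.

## Effects and multiplicity

Percent changes divide each group's estimated 10-year change by its
estimated baseline mean (at the mean age) — this, rather than raw sample
means, is what reproduces published-style percentages from reported
estimates — and the group difference is reported in percentage points.
Standard errors come from the multiparameter delta method with central
differences (step 10⁻⁶ × max(|θ_k|, 1)); the delta-method CIs use a normal
reference (the approximation is itself asymptotic). A non-positive
baseline estimate makes the percent effect undefined and it is reported
missing. The delta SE is validated against a 10⁵-draw parametric
bootstrap.

M_eff uses the eigenvalues of the Pearson correlation matrix of
per-subject change scores (pairwise-complete; outcomes with fewer than
three complete pairs or zero change variance are excluded with a
warning). The eigenvalue variance uses divisor K − 1, which makes the
perfect-correlation limit give M_eff = 1 exactly (divisor K does not).
Pairwise-complete matrices can be slightly non-PSD; negative eigenvalues
are clipped at zero with a warning. The adjusted level is
1 − (1 − α)^(1/M_eff), adjusted p-values are min(1, 1 − (1 − p)^M_eff)
(computed via expm1/log1p for accuracy), and adjusted CIs simply pass the
adjusted α to the change-CI routine.

## Cross-sectional projection

Per outcome, OLS of baseline value on continuous age (pooled over groups
by default; per-group behind a flag) gives a slope and an estimated
marginal mean at the sample mean age; the predicted per-decade change is
100 × 10 × slope / EMM. The longitudinal counterpart divides the
group-size-weighted mean of the two groups' estimated changes by the
equally weighted baseline. On cohorts generated without a birth-cohort
effect the two agree; a baseline age gradient steeper than true
within-person aging by c points/decade reproduces as a discrepancy of
about c — the mechanism by which cross-sectional trends misstate
longitudinal aging.

## Problem sizes in tests

Calibration suites use 500 replicates at 200/group for interaction
recovery and CI coverage, 1000 replicates at 35/group for null rejection,
1000 random correlation matrices for the M_eff bounds, and phantom grids
up to 271×271 (0.2 mm pixels); the full suite runs in well under a
minute on one CPU.

## Known limitations

* Trait values from real scans will differ from vendor-software output
  (unrecoverable contour algorithm; fixed cortical threshold).
* The polar sector labelled "A" spans anterior→anteromedial rather than
  being centred on the anterior axis (bin-aligned convention above);
  rotate the profile by 22.5° if a centred reading is needed.
* The mixed model assumes normal outcomes and a common residual variance
  across groups and occasions; the reference-magnitude generator deliberately
  violates strict compound symmetry (change SD > √2 σ_e), which the REML
  fit absorbs into its variance components but which makes σ̂_b², σ̂_e²
  reparameterisations of the marginal covariance rather than physical
  quantities.
* M_eff-Šidák controls the error rate only approximately for correlated
  non-normal statistics; no permutation or FDR alternatives are provided.
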