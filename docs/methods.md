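# Methods

This package re-creates, end to end, a quantitative diffuse-reflectance
analysis of breast tumor margins: a Monte Carlo forward model of
probe-measured reflectance, an inverse model extracting tissue absorbers and
scattering, a simulation study of patent-blue-dye interference, and a
longitudinal mixed-effects analysis of how the optical endpoints drift after
excision. No clinical spectra are distributed with the original work, so a
seeded synthetic cohort generator stands in for the specimens; its defaults
encode the published cohort structure, and every analysis stage is exercised
against it.

## Optical model

Tissue absorption over 450–600 nm is composed by Beer's law from four
chromophores — oxy-hemoglobin, deoxy-hemoglobin, β-carotene, and patent blue
(sentinel lymph node mapping) dye:

    µ_a(λ) = Σ_i ε_i(λ) · c_i        [cm⁻¹; ε in cm⁻¹µM⁻¹, natural log]

Reduced scattering follows a wavelength power law anchored at λ₀ = 500 nm:

    µ_s'(λ) = a · (λ/λ₀)^(−b)

whose band average over 450–600 nm, ⟨µ_s'⟩, is the scalar scattering
endpoint. The derived endpoints per measurement are [THb] = [HbO₂] + [HbH],
HbSat = [HbO₂]/[THb], [β-carotene], [dye], ⟨µ_s'⟩, and the ratios
[β-carotene]/⟨µ_s'⟩ and [THb]/⟨µ_s'⟩.

**Extinction tables.** The packaged tables (`data/extinction/`, files
prefixed `synthetic_`) are Gaussian band models, not laboratory
measurements: HbO₂ carries the α/β bands at 542/577 nm over a Soret tail,
HbH a broad 556 nm band, β-carotene its vibronic structure below ~520 nm
(452/478/505 nm sub-bands), and the dye a long-wavelength edge rising toward
a ~635 nm peak that overlaps the Hb α/β bands. All analyses here are
forward/inverse **self-consistent** — the same table generates and inverts
every spectrum — so conclusions depend on the tables' band structure and
consistent use, not on their absolute accuracy. Absolute concentrations are
therefore nominal, which is the main caveat when comparing dye levels to
clinical values. The vibronic sub-structure is not cosmetic: unmixing
degrades measurably if the curves are reduced to single smooth bands,
because β-carotene and the Hb Soret tail then become nearly collinear over
the analysis band.

## Forward Monte Carlo

A homogeneous semi-infinite medium is illuminated through the face of a
contact probe: a 19-fiber illumination core (200 µm fibers, NA 0.22,
modeled as a uniform 0.5 mm-radius emission disc) ringed by four 200 µm
collection fibers at 0.65 mm from the axis, giving fiber-to-fiber
separations of 0.25–1.05 mm, inside the instrument's 0.23–1.10 mm span.
Photons launch within the NA cone (n_tissue sin θ ≤ NA), scatter by
Henyey–Greenstein with g = 0.9 (the walk is parameterized by µ_s' through
the similarity relation µ_s = µ_s'/(1−g)), and reflect/refract at the flat
boundary by unpolarized Fresnel sampling with n_tissue = 1.37 and
n_ext = 1.45 (fiber face). A photon exiting inside a collection fiber
footprint within the NA is collected; the azimuthal-overlap kernel converts
each exit radius into a collection probability, exploiting the ensemble's
symmetry about the probe axis. The probe instrument does not state photon
counts, phase function, anisotropy or indices for its simulations; the
values above are declared package defaults, all configurable.

**Absorption and rescaling.** The walk itself is absorption-free; absorption
enters as continuous weight attenuation exp(−µ_a·L) applied to the stored
pathlength. One *baseline* run at the median clinical scattering level
(µ_s' = 6.68 cm⁻¹) stores per-photon exit records (launch radius,
displacement, their included angle, pathlength), and any target (µ_a, µ_s')
is evaluated by similarity rescaling: displacements and pathlengths scale by
µ_s'_ref/µ_s'_target about each photon's own launch point (the launch optics
are hardware and do not scale), then Beer attenuation applies to the
rescaled pathlength. The rescaling is validated against direct simulation
within 3 Monte Carlo standard errors across a 0.25–4× scattering range; the
default study baseline uses 10⁶ photons (≈17 000 NA-accepted records).
Batch means over 10 photon blocks provide standard errors.

Termination: pathlength cutoff (60 cm), Russian roulette below weight 10⁻⁴
(survival 0.1), and geometric kill bounds (depth > 2 cm or lateral
excursion > 3 cm from the launch point) — photons beyond those bounds
cannot re-enter the sub-millimeter collection zone with relevant weight.
The kill bounds truncate the *total*-reflectance tally slightly; the
low-absorption diffusion-theory comparison therefore relaxes them and uses
an index-matched boundary, where the dipole boundary condition is exact.
The residual ~10% gap at one transport length is the known near-field
difference between a pencil beam and the equivalent isotropic point source.

## Inverse model

Each spectrum is fit by bounded nonlinear least squares over
θ = (c_HbO₂, c_HbH, c_βc, c_dye, a, b), bounds [0, 200] µM for Hb species,
[0, 100] µM for β-carotene and dye, a ∈ [1, 30] cm⁻¹, b ∈ [0, 3] — covering
the clinical quartiles and the 72.7 µM maximum observed dye level with
headroom. The objective compares **log-reflectance** by default: collected
reflectance spans an order of magnitude across the band, and the log metric
conditions the fit evenly (a linear-reflectance flag is retained). The
model inside the fit is the same rescaled-baseline forward model.

Optimization is the part that required real care. The cost surface has a
curved, narrow valley coupling Hb, dye and the scattering power, and two
failure modes had to be engineered away:

- **Seeding.** A deterministic lookup stage scans a coarse (a, b) grid; at
  each cell the monotone per-wavelength map µ_a → R is inverted by
  vectorized bisection and the resulting µ_a*(λ) unmixed by non-negative
  least squares (which parks absent absorbers exactly at zero). The
  best three cells seed the trust-region fit, followed by a clinical
  mid-range start and optional Latin-hypercube starts (`n_starts`).
- **Trust-region hygiene.** The finite-difference Jacobian must use a step
  (10⁻³ relative) large enough to average over the per-record kinks of the
  collection kernel — the model is C⁰ where records cross fiber edges, and
  the default √ε step produces erratic Jacobians and chaotic premature
  stops. Adaptive Jacobian scaling (`x_scale='jac'`) handles the three
  orders of magnitude spread in parameter sensitivity, and re-solving from
  the incumbent (trust-region restart, up to 3 times per start) frees
  solutions stranded mid-valley. A final polish snaps near-zero absorbers
  to the bound and refits. With all of this, noiseless self-consistent
  round trips converge to machine precision across the full factorial
  range (worst observed endpoint error ≈ 2.5%, most points exact).

Calibration of raw counts divides by integration time, ratios against a
99% reflectance standard spectrum, and applies the standard's reflectance.

## Dye-robustness study

The factorial crosses the clinical site-level quartiles — ⟨µ_s'⟩ ∈ {4.85,
6.68, 9.15} cm⁻¹, [THb] ∈ {16.97, 31.03, 55.09} µM, [β-carotene] ∈ {10.29,
16.29, 24.37} µM — with dye from 0 to 70 µM in 10 µM steps: 216 spectra,
each simulated (THb split 50/50 between HbO₂/HbH) and inverted with the
shared library and baseline. Percent errors are recorded signed per design
point and endpoint; summaries report means and max |error| per dye level.
The phantom analogue titrates dye 0–79 µM in 12 steps into a single
worst-case phantom (⟨µ_s'⟩ 5.81 cm⁻¹, [THb] 16.69 µM, [β-carotene]
11.23 µM — minimum absorber levels, where dye dominates), with
multiplicative Gaussian measurement noise (σ = 1% of signal by default,
standing in for experimental error; crocin, the phantom β-carotene
surrogate, is modeled by the β-carotene table).

## Synthetic cohorts

Each site gets a per-endpoint linear truth (intercept + slope·t), observed
at the published cadence — lumpectomies: first measurement 7±3 min
(truncated to 2–12), ~0.93 min intervals, 10–21 min series; mastectomies:
17±4 min (10–27), ~0.42 min intervals, 10–32 min — with multiplicative
Gaussian noise (σ = 2%, a declared default; the source study does not
report its measurement noise) and a floor at zero. Baseline endpoint
distributions are log-normal matched to the clinical quartiles (endpoints
are positive and right-skewed; the real intercept distributions are
unpublished, so this is an assumption). Site counts and histology follow
the published breakdown (59 benign + 2 malignant lumpectomy sites, 13 + 7
mastectomy sites).

**Rate calibration.** The published summaries over-determine an independent
slope/intercept model: class rate means ± SDs, baseline quartiles, and
median 30-minute percent changes (percent change = 100·slope/|intercept|·t)
cannot hold simultaneously if slopes and intercepts are drawn
independently (in the real data they are correlated). For benign lumpectomy
sites the generator therefore draws a fractional rate r ~ N(µ_r, σ_r) per
minute and sets slope = r·intercept: the median percent change is then
exactly 3000·µ_r (fixing µ_r from the published medians: −8.2% β-carotene,
−13.8% ⟨µ_s'⟩, −44.2% THb, −228.7% dye at 30 min), the intercept scale is
fixed by the class rate mean (E[slope] = µ_r·E[B]), and σ_r is solved from
the rate SD. Mastectomy classes draw slopes independently from the
published class distributions. Dye has no published rate row; its washout
uses σ_r = 0.2|µ_r| and a 3 µM log-normal baseline, reproducing the
observed negative first-measurement-vs-delay correlation.

The dye decline crosses zero within the measurement window for most sites;
floored observations are treated as below the detection limit and excluded
from the dye kinetics fit (sites retain ≥ 2 positive points essentially
always). Without this censoring rule the floor biases the fitted washout
slope toward zero and the −228.7% calibration is unrecoverable by
construction. HbSat is generated as a static per-site level — the source
analysis excludes it (with oxy-/deoxy-Hb) from linear kinetics as
non-linear over the window, and this package does the same.

Margin maps are smooth Gaussian random fields (σ = size/8, 10% relative
amplitude) around class means; positive-margin means apply the published
adipose-vs-positive percent differences (sign convention: negative
difference means positive sites are greater). They emulate only smooth
spatial variation, not real histological texture.

## Longitudinal analysis

Per endpoint, a linear mixed model with fixed effects for time and
histological subtype and correlated random intercept + slope per site
(REML) yields per-site BLUP lines; percent change at 10/20/30-minute
horizons is computed per site and summarized by the cohort median. The
exact statistic is linear in the horizon. Contrast-crossing time
extrapolates t* = horizon·|difference|/|change| (reported rounded to the
minute; full precision retained). Cautery comparisons use Wilcoxon
rank-sum tests (exact for small untied samples, tie-corrected normal
otherwise) on first-measurement values and on per-site rates restricted to
10 minutes from each site's first measurement. Diagnosis-dependence of
rates uses a likelihood-ratio test between ML fits with and without a
diagnosis × time interaction (χ², 1 df). Spearman correlations between
first measurements and their delays use exact permutation p-values for
n ≤ 8 and the asymptotic approximation otherwise. Significance is α = 0.05
with no multiplicity correction, matching the source analysis; reports say
so.

**Numerical stabilization.** statsmodels' MixedLM maximum-likelihood
optimizer routinely strands far from the optimum on these data (uncentered
time makes the random intercept/slope nearly collinear, and multiplicative
noise is heteroscedastic across sites). All mixed fits therefore center
time, standardize the response, and start the variance components from the
empirical covariance of per-site OLS lines; the likelihood-ratio statistic
and the back-transformed coefficients are invariant to the transforms.
Without the starts, observed LRT statistics were wrong by an order of
magnitude. The LRT's χ²₁ reference is asymptotic in the number of sites;
its type-I error is calibrated in tests at 25 sites per class (at 10 per
class the usual small-sample anti-conservatism appears, ~0.09 at nominal
0.05 — a property of the reference distribution, not of the
implementation).

## Problem sizes and defaults

The shipped configuration runs the full 216-point factorial with a 10⁶
photon baseline (~6 min on one CPU), 20-seed kinetics replicates of the
59-site cohort (~2 min), and 200-seed null calibrations (~2 min); these
sizes are the package's accuracy/runtime compromise and are all arguments.
Direct-MC validation points use 4×10⁵ photons. Default analysis grid:
450–600 nm at 5 nm (31 points) — dense enough to resolve the Hb α/β bands.

## Known limitations

- Extinction curves are constructed band models; absolute concentrations
  and absolute dye-level comparability to clinical values are nominal.
- Homogeneous semi-infinite medium; no layering, lateral heterogeneity,
  probe-contact failure, instrument drift or stray light.
- One collection geometry models all 8 probe channels (they are stated to
  be similar); sensing-depth mapping is out of scope.
- The cohort generator's linear-kinetics truth matches the analysis model
  by construction; passing recovery tests demonstrates correct estimation
  machinery, not that real tissue kinetics are linear.
- Clinical significance levels that depend on unpublished patient data
  (cautery p-values, the dye–delay Spearman p) are covered only by
  direction-of-effect checks on synthetic cohorts.
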