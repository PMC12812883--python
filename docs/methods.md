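# Methods

This note documents the models, estimators and numerical conventions the
package implements, the study conditions its synthetic-data generators
encode, and the design choices made where the underlying protocols leave
the design open.

## Hydrodynamic forcing

The orbital-shaker energy dissipation rate uses the empirical
shake-flask correlation ε = 1.94 n³D⁴/V_f^(2/3) · Re^(−0.2) with the
rotational Reynolds number Re = ρ_f n D²/μ_f.  The Reynolds exponent is
**negative**: the correction must decrease with increasing Re, and only
the negative sign reproduces the reference value ≈ 9.53×10⁻⁴ W kg⁻¹ at
the standard operating point (110 rpm, D = 23.0 mm, V_f = 27 mL,
seawater at 22 °C: ρ = 1025 kg m⁻³, μ = 1.1 mPa s).  Because a silent
rpm/s⁻¹ confusion changes ε by 60^2.8 ≈ 10⁵, the speed's unit must be
declared explicitly (`n_unit="rpm"` or `"per_s"`).

Photon flux treats the LED as monochromatic:
flux = I·λ/(N_A·h·c)·10⁶ µmol photons m⁻² s⁻¹ with CODATA constants
from `scipy.constants`; 1.35 mW cm⁻² at 535 nm gives 60.4, i.e. the
rounded "≈60" of the culturing protocol.

## Cell counting

Cells swimming in a chamber of known volume are counted per frame and
averaged; concentration = mean count / chamber volume (µL) × 1000 ×
dilution factor.  Defaults and conventions:

* **Background** is the per-pixel median across the stack: the chamber
  walls are stationary while cells move, so the median cancels static
  structure.  A per-frame rolling-ball background is available for
  drifting illumination.
* **Threshold** is Otsu on the background-subtracted frame, with a
  fixed-value override.  Otsu always returns *some* split, so the
  threshold is accepted only if it exceeds `min_snr` (default 5) robust
  noise standard deviations (1.4826×MAD of the residual); otherwise the
  frame is declared spot-free.  Without this floor a blank noisy frame
  yields hundreds of spurious components.
* Components with area outside [`min_area_px`, `max_area_px`]
  (defaults 4–500 px) are ignored; these defaults are calibrated
  against the synthetic generator since the instrument's spot size is a
  free parameter.
* Frames are treated as independent snapshots — no tracking or
  deduplication — matching the protocol of averaging 160 frames
  (10 s × 16 fps).  Two cells closer than the threshold footprint merge
  into one component; at the generator's conditions this costs ≈0.5% of
  counts at the typical density (~34 cells/frame) and ≈1.4% at
  100 cells/frame.  Dense cultures should be diluted before imaging
  (the estimator back-multiplies by the dilution factor), and a fully
  saturated frame raises an error advising exactly that.

The inoculation concentration of a culture seeded with 2 mL of mother
culture in 27 mL total is C0 = N_mother × 2/27.

## Logistic growth fitting

P(t) = K/(1+((K−P0)/P0)e^(−rt)) is fitted per replicate by nonlinear
least squares (`scipy.optimize.curve_fit`, trust-region reflective,
non-negative bounds).  Initialization: K₀ = 1.05×max(obs),
P0₀ = first observation, r₀ = steepest positive slope of
log-concentration.  Counting error is relative (roughly constant CV),
so residuals are weighted by 1/y by default (`weighting="relative"`);
the unweighted linear-scale fit is available via
`weighting="absolute"`.  With the weighted default, the median relative
error of r̂ under 10% multiplicative noise on the protocol's sampling
grid (0, 24, 48, 72, 96, 192, 264, 336, 384 h) is ≈3%; the unweighted
fit lets the plateau points dominate and roughly triples that.  On
noiseless logistic data both variants recover the parameters exactly
(model-class identity).

Fits are refused (NonIdentifiableError) for fewer than 5 time points or
monotone-decreasing data.  Doubling time Td = ln 2/r.  The growth index
IG(t) is the ratio of the two fitted model curves (perturbed/static),
evaluated pointwise; its late-time limit is K_perturbed/K_static.
Replicate-level K and Td are compared with Welch's unequal-variance
two-sample t-test (the safer default when the variance assumption is
unstated); degenerate zero-variance groups use the conventions p = 1
for equal means and |t| = ∞, p = 0 otherwise.  Per-replicate fits (not
one pooled fit) feed the tests, matching replicate-based error bars;
pooling is possible by concatenating tables upstream.

## Lipid-droplet quantification

Segmentation is two-stage thresholding: the **cell body** is the
largest connected component above a background/cytoplasm threshold
(holes filled), the **droplets** are components above a second,
within-cell threshold, clipped to the cell mask and filtered by
`min_droplet_area_px` (default 20 px).  Both thresholds default to Otsu
with fixed-value overrides.  Two guards make the automatic mode robust:

* when very bright droplets occupy a large area fraction, plain Otsu
  splits at the cytoplasm/droplet boundary; if the class *below* the
  first split is itself strongly bimodal, the cell threshold is that
  sub-split (recursive Otsu);
* within-cell Otsu on a droplet-free cell would split the cytoplasm
  noise in half, so droplets are only accepted when the two classes
  separate by at least `separation_guard` (default 4) pooled standard
  deviations.

**Feret diameters** are measured on the pixel outline polygon (pixel
corners, the ImageJ convention): the maximum Feret is the largest
pairwise distance over convex-hull vertices, the minimum Feret the
smallest projected extent over a 1° rotation sweep (the test oracle
uses an exhaustive 0.1° sweep over all boundary corners).  A
single-pixel mask reports 1 px for both diameters by convention.  Areas
are pixel counts × pixel_size².

**Geometry.**  With a = max and b = min Feret, the droplet is modelled
as a prolate spheroid (long axis a, two equal short axes b):
V = (π/6)ab² — the only volume consistent with that geometry from two
projected diameters.  The equivalent-volume sphere radius
r_eq = (3V/4π)^(1/3) gives the standardized cross-sectional area
A = πr_eq², which removes elongation from cross-sample comparisons.
Per cell: total volume ΣV, normalized lipid area A_norm = ΣA/cell area
(standardized areas by design; raw mask areas would change magnitudes
but not the perturbed/static ratio appreciably).  Population summaries
subsample 20 cells per replicate (seeded, without replacement; fewer
cells ⇒ use all, flagged).  The lipid index IL is the ratio of mean
normalized areas, perturbed over static.

**Known bias.**  Rendering includes a pixel when its center is inside
the droplet ellipse, while the outline-polygon measurement adds roughly
half a pixel per diameter; at 0.1 µm px⁻¹ with ~4–6 µm droplets this
overestimates volumes by ≈5%.  This digitization bias is shared by any
outline-based Feret pipeline at comparable sampling and is left
uncorrected; the per-cell recovery tolerance (10%) and the 2-standard-
error population check both accommodate it.

The average lipid production rate over an interval is ΔV/Δt; 180 µm³
accumulated over 350 h sustains ≈0.51 µm³ h⁻¹ per cell.

## Photophysiology

Fv/Fm, Y(II), NPQ and rETR follow the standard PAM definitions with the
PSI/PSII partition factor 0.5 as a named constant.  An inverted dark
reference (F0 > Fm) is flagged, not fatal, and yields a negative Fv/Fm
as instruments report it; negative NPQ values are kept.  The rETR–E
curve is fitted with the Eilers–Peeters form rETR = E/(aE²+bE+c)
(a, c > 0; b may be negative), initialized by the standard EP
linearization: α from the first three lit steps gives c = 1/α, the
empirical maximum and its location give b and a.  Derived quantities
use the closed forms rETR_max = 1/(b+2√(ac)), E_opt = √(c/a), α = 1/c;
the closed-form maximum agrees with a dense numeric scan to <0.01%.  On
optimizer failure the fit is flagged and the empirical maximum is
reported.

NPQ at the 500 µmol m⁻² s⁻¹ reference irradiance (a typical
near-surface light level) is an ordinary least-squares line through the
two steps bracketing 500 plus one nearest neighbour per side (window
size 4, configurable; a step exactly at 500 joins the window),
evaluated at 500.  Targets outside the measured range are refused
rather than extrapolated.

## Synthetic data: what it emulates, and what it does not

Every generator is deterministic given its seed and writes ground truth
alongside its artifact.

* **Growth tables** — logistic trajectories with independent
  multiplicative lognormal noise per point (η ~ N(0, √ln(1+CV²))),
  CV-parameterized because counting error is relative; default CV 10%,
  3 replicates, sampling grid as in the protocol above.
* **Single-cell micrographs** — one bright disk (default diameter
  18 µm, the upper range of *H. akashiwo* and appropriate for
  lipid-laden stationary-phase cells) containing non-overlapping bright
  ellipses whose in-plane axes are the Feret pair of a sampled prolate
  spheroid; per-droplet volumes lognormal, aspect ratios uniform
  (default 1.0–1.6), pixel size 0.1 µm px⁻¹ (free parameter; the
  imaging calibration is not part of the protocol), 16-bit intensities
  background/cytoplasm/droplet = 500/4000/9000 with Gaussian noise
  (σ = 50).  The droplet level is kept far below saturation so the
  background/cytoplasm Otsu split dominates the histogram.  Placement
  is rejection sampling (100 retries per droplet, largest first) with a
  deterministic coarse grid-scan fallback, because heavy lognormal
  draws can jam plain rejection sampling even when a feasible
  non-overlapping arrangement exists; ≥2 px inter-droplet gaps keep
  segmentation from merging droplets.  The helper
  `cell_spec_for_total_volume(mean, sd, n_droplets=4)` matches a target
  per-cell *total* volume distribution exactly in mean and SD by giving
  each of the n i.i.d. droplets mean/n and sd/√n.
* **Frame stacks** — per-frame counts Poisson with mean concentration ×
  chamber volume (3×2×0.56 mm ≈ 3.36 µL); Gaussian spots (σ = 1.2 px,
  a cell at low stereomicroscope magnification subtends a few pixels)
  at uniform positions on a 512×512 field; spots are static within a
  frame and redrawn each frame (no motility model — snapshot counting
  does not use trajectories).
* **Light curves** — fluorescence traces constructed by *inverting* the
  PAM equations from an EP rETR curve and a saturating NPQ model
  NPQ(E) = NPQ_max·E/(E+E_half), so noiseless traces round-trip through
  the analysis equations at machine precision.  Defaults are
  photophysiologically consistent (Fv/Fm = 0.65, α = 0.3125,
  rETR_max ≈ 70 at E_opt = 600); the effective yield is clamped at
  Fv/Fm, with a warning if the clamp is active at more than half the
  steps (the coefficients then contradict the dark reference).  Noise
  is a per-step lognormal gain shared by the (F′, Fm′) pulse pair plus
  an independent lognormal perturbation of Y(II): fully independent
  noise on the two yields would make the rETR error diverge wherever
  Fm′−F′ is small, i.e. at high irradiance, which is not how
  saturation-pulse noise behaves.  The 16-step PAR ladder
  (0…2500 µmol m⁻² s⁻¹) is denser at low light and brackets 500 with
  steps at 450/550, as instrument ladders place steps around the
  reference level.

**Scenario presets** encode the two perturbation-onset regimes for
end-to-end tests: `scenario1` (onset at inoculation) doubles r at equal
K (r 0.035 → 0.070 h⁻¹, K = 2×10⁵ cells mL⁻¹, P0 = 2×10³); `scenario2`
(onset at 120 h, mid-exponential) keeps r and lowers K to 0.69 of the
control.  Lipid per-cell total-volume distributions at the
late-stationary sampling point: scenario 1 static 22.0±18.1, perturbed
170.3±58.6 µm³; scenario 2 static 21.6±4.1, perturbed 48.2±3.5 µm³.
Growth rates correspond to doubling times of ≈20 h and ≈10 h,
realistic for this organism.

The generators emulate geometry, counting statistics and noise
character — not photorealism: no point-spread blur, chlorophyll
autofluorescence, cell motility within stacks, focus drift or uneven
illumination.  Passing tests therefore demonstrate correctness of the
estimators under the stated noise models, not robustness to every
imaging artifact of real micrographs.

## Pipeline and statistics

A scenario run derives all stage seeds from one master seed via
`numpy.random.SeedSequence.spawn`, making the full report deterministic
and byte-identical on repetition.  Lipid and photophysiology parameters
are compared with paired t-tests, paired by replicate within the time
point; carrying capacities and doubling times with Welch two-sample
t-tests; significance at α = 0.05 on raw p-values (no multiple-testing
correction by default, reproducing per-time-point reporting; Holm
adjustment via `p_adjust="holm"`).  Zero-variance paired differences
use the same degenerate conventions as above.

Problem sizes in the shipped tests and acceptance script are chosen to
make the statistical checks sharp yet quick: 50 replicate pairs for the
growth-rate-ratio recovery, 60 cells for the lipid-distribution
recovery (matching the n = 60 of the reference distribution), 100 seeds
for median-error checks, 200–1000 repeats for type-I-error checks at
widened binomial tolerances, and 8–20 cells per replicate in
pipeline-level tests.

## Known limitations

* Droplet volumes assume prolate geometry from a single 2-D projection;
  oblate or irregular droplets bias V in opposite directions.
* The ~5% outline-digitization bias above shrinks with pixel size but
  is not corrected.
* Frame-stack counting has a small negative merge bias growing with
  density; dilute dense cultures.
* The EP fit assumes the 0.5 partition factor and relative (not
  absolute) ETR; no wavelength-dependent absorption cross-section.
* Growth fitting supports only the logistic model (no Gompertz/Baranyi,
  no explicit lag phase).
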