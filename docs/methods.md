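# Methods

Scope: the models, unit conventions, numerical choices and known
limitations of the `azphys` package. Everything quantitative stated here
is computed by the test suite or the analysis scripts; nothing is quoted
from external measurements except as generator defaults, which are
listed with their rationale.

## Units

mV, ms, pA, nS, and pF internally (so `pA = nS·mV` and
`pF·mV/ms = pA` hold without conversion factors); capacitance is
expressed in fF at API boundaries. Lengths in nm; images carry their
pixel size (default 10 nm/px). Inward currents are negative in storage;
reported amplitudes are magnitudes.

## Patched-bouton circuit and sine+DC estimation

The terminal is a three-element circuit: access conductance `Gs`
(R_s 30–70 MΩ in the emulated recordings; default 20 nS = 50 MΩ)
feeding the parallel membrane conductance `Gm` (1 nS) and capacitance
`Cm` (1000 fF, a mossy-fiber-bouton scale). The command potential is
V_hold −80 mV plus a 30 mV, 1 kHz sine; a square depolarizing pulse
(default to +10 mV) interrupts it, and exocytosis is modeled as a step
increase of `Cm` at pulse end.

The membrane-potential ODE is linear with sinusoidal/constant forcing,
so the simulator evaluates the closed-form solution (particular response
plus a decaying exponential with rate `(Gs+Gm)/Cm`) segment by segment.
Steady-state phasors are therefore exact to machine precision, which is
what the lock-in estimator is validated against. The sine is suspended
during the pulse (its samples are flagged invalid anyway), with an
absolute-time phase reference so it resumes coherently.

Estimation: per block of an integer number of sine cycles (default 1
cycle = 1 ms, the time resolution of the capacitance trace), the block
mean is removed and A, B obtained by sin/cos correlation;
`G_dc = (mean current − leak)/V_hold`. A calibration step processes a
known-resistor trace through the same chain and rotates/scales Y so that
a pure resistor yields B = 0 (recording chains add low-pass filter phase;
for the ideal simulated chain the factor is 1, but the hook exists for
real hardware). The closed-form inversion (README) requires `B > 0` and
`A > G_dc ≥ 0`; blocks violating this under noise are flagged invalid,
never clipped.

Capacitance jumps: baseline = 50 ms ending at pulse start; post window
starts 10 ms after pulse end (dead time for tail currents) and spans
50 ms; windows are half-open and must not touch invalid blocks. The
window lengths are conventions, not measured facts; they are parameters.

## Ca²⁺ current and release models

`I(t) = g_max · m(t) · (V − E_rev)` with
`m∞(V) = 1/(1+exp(−(V−V_half)/k))`, `m` relaxing exponentially
(τ_act 1.4 ms). Defaults (V_half −5 mV, k 7 mV, E_rev +65 mV,
g_max 0.894 nS) put the activation threshold near −20 mV and the peak
inward current at +10 mV at ~44 pA; the knockout condition scales
`g_max` by 0.7 (a ~30% current reduction).

Pool depletion: `ΔC_m(T) = RRP·(1 − e^(−T/τ_eff))` with
`τ_eff = τ_release / h(I)`, `h(I) = I³/(I³+K³)` — smaller currents slow
release with third-power cooperativity. Defaults RRP 52 fF,
τ_release 45 ms, K 30 pA, chosen so that τ_eff at the wild-type peak
current (44 pA) is ≈59 ms; K itself is not a measured value, only the
(RRP, τ_eff) pair is anchored.

Fitting: unweighted least squares (optional 1/SEM² weights), time
constants parameterized as log τ, multi-start (τ ∈ {10, 50, 200} ms for
depletion; K starts at data quantiles for Hill), SSE tolerance 1e-12.
The Hill fit fixes n = 3 with C_max free by default and an optional
fixed-C_max mode (whether the original analysis constrained the plateau
is not determinable, so both are provided).

τ̂ caveat: when the longest pulse (100 ms) is only ~1.7 τ, a single noisy
5-point dataset gives a right-skewed τ̂ (median-centred, mean +~30% at
5 fF noise) — the familiar non-plateau identifiability problem. The
published design fits n = 9 terminals together; Monte-Carlo replicates
of that design recover τ with ~2–3% mean bias and an SD (~14 ms)
matching the reported uncertainty. Both behaviours are asserted in
tests.

## EPSC trains

Generator: Tsodyks–Markram-style recursion — facilitation u increments
by U at each stimulus (decay τ_f 400 ms), resources R deplete by the
released fraction (recovery τ_rec 2 s), amplitude ∝ u·R, difference-of-
exponentials kernel (0.3/4 ms), biphasic stimulus artifact in the first
0.6 ms. U = 0.05 gives ~1.8–2× paired-pulse facilitation at 20 ms
(wild-type-like); U = 0.005 gives strong (several-fold, approaching an
order of magnitude) train facilitation — the low-release-probability
knockout phenotype. Amplitudes scale linearly with driving force
assuming a 0 mV reversal.

Extraction conventions (the data do not dictate them, so they are
parameters): blank [t_stim, t_stim+1 ms); search [t_stim+1, t_stim+15) ms
truncated at the next stimulus; local baseline [t_stim−2, t_stim). No
summation correction during trains — amplitudes are measured from the
local pre-stimulus baseline, which includes residual decay (a measured-
amplitude convention, documented rather than deconvolved). Absolute
amplitudes are flagged multi-fiber; cross-group inference should use
normalized or within-cell ratio quantities. The peak-picking statistic
(window minimum) has a positive noise bias of order 2 SD; tests bound it
explicitly.

## Synthetic STED fields

The scene: large VGLUT1-positive boutons (unions of 2–4 ellipses,
~2 µm², mossy-fiber scale) containing Poisson-many AZs (disks,
log-normal area, median 0.07 µm² — the emulated study does not state AZ
size; 0.04 µm² leaves the programmed cluster counts without geometric
room at the programmed separations, see below), plus small VGLUT1 blobs
(0.3 µm²) under the terminal-size filter. Each AZ carries:

* a diffuse Munc13-1 "carpet" (pedestal 25 counts/px, soft 30 nm edge,
  extending 20 nm past the nominal rim) — this is what makes the AZ a
  single connected component in the raw binarization;
* Munc13-1 clusters (zero-truncated Poisson, mean 2.5; ≥110 nm apart);
* Cav clusters (zero-truncated Poisson, mean 2.5 WT / 2.3 KO), each
  offset from a parent Munc13-1 centroid by N(61, 10) nm in a direction
  chosen so the parent remains its nearest Munc13-1 cluster — the drawn
  offset *is* the ground-truth nearest-neighbor distance. Pairwise Cav
  separation ≥100 nm, relaxed (radial slack first) only when geometry
  forces it, with an 80 nm floor at the deconvolution resolution. The
  offset magnitude is drawn once per cluster; redrawing per placement
  attempt would select small distances in tight geometry.
* a PSD-95 punctum apposed to the AZ center.

Cluster photometry: integrals are Gamma(shape 4) with means 6000 (Cav)
and 1400 (Munc13-1) counts; the spot footprint scales as √intensity
(constant protein surface density), which keeps peak heights comparable
and dim clusters detectable by a global threshold. The KO per-cluster
Cav factor is calibrated analytically (gamma-mixture median) so that
`ko_intensity_scale = 0.78` programs the *per-AZ total* median intensity
ratio — the quantity the pipeline measures and the 22%-reduction result
refers to; with the count reduction compounding, the per-cluster factor
works out to ≈0.86.

STED channels are blurred with a 50 nm FWHM Gaussian PSF, confocal with
250 nm; Poisson plus Gaussian (SD 2) noise; 16-bit quantization with
clipping flagged. All randomness flows from one seeded generator:
rendering is bit-identical under (params, condition, seed). Geometry is
drawn in pixel coordinates, so the same seed at a different pixel size
is a different (statistically equivalent) scene; resolution invariance
of the *pipeline* is tested with constructed two-resolution images.

What a green recovery test does and does not establish: it shows the
pipeline returns programmed population parameters from images with
realistic blur, noise, crowding and gating structure. It does not
emulate STED photophysics (depletion-beam profiles, intensity
nonlinearity), z-dimension blur, labeling stochasticity, chromatic
misregistration, or tissue background texture — on real data the
absolute intensities are explicitly qualitative.

## Quantification pipeline choices

* Unsharp mask = `img + amount·(img − G_σ(img))`, clipped at zero
  (negative overshoot is meaningless intensity and, left in place, forms
  its own Otsu class), then Otsu. The binned Otsu picks the **last** of
  tied maxima of the between-class variance; the first-tie convention
  (skimage) can land inside a background point-mass bin on clean images.
  AZ step: σ 5 px, amount 1, min area 0.01 µm². Cluster step (on the
  deconvolved image): σ 3 px, amount 8, min area 400 nm² — the stronger
  high-pass is what lets one global threshold separate cluster peaks
  from the diffuse intra-AZ signal; detection of ground-truth clusters
  is ~0.97 for both channels at these defaults.
* Deconvolution: Richardson–Lucy, 20 iterations, Gaussian kernel of
  "radius" 40 nm interpreted as σ = 20 nm — Mathematica's
  `GaussianFilter[img, r]` convention (σ = r/2), the platform such
  custom pipelines are written in; `sigma_nm` overrides it. Updates run
  in the Fourier domain with a precomputed OTF (periodic boundaries;
  the symmetric PSF makes correlation = convolution), matching the
  spatial-domain reference implementation away from borders at a
  fraction of the cost, plus a σ = 1 px regularizing smooth (RL
  amplifies pixel-scale noise into speckle that fragments under
  thresholding). Mass is conserved to <1%.
* Cluster intensity, centroids (intensity-weighted) and ellipse axes are
  measured on the **raw** channel over the deconvolved-derived masks:
  deconvolved pixels are mask evidence, not photometry.
* Gates: AZ centroid inside the VGLUT1 mask dilated by d_coloc
  (100 nm); a PSD-95-positive pixel within d_coloc of the AZ mask; the
  containing VGLUT1 component ≥1 µm². Masks are closed (boundary pixels
  belong); 8-connectivity; 0-based indices.
* Background: median over non-AZ pixels outside a 100 nm guard ring
  (median rather than mean: robust to unmasked faint structure).
  Negative background-subtracted integrals clamp to 0 and are flagged.
* NND direction is Cav→Munc13-1 (each channel cluster to its nearest
  release-site marker); a symmetric option exists. AZs lacking clusters
  in either set are skipped and logged.
* Group inference runs on per-animal means (n = animals) via the exact
  Mann–Whitney test — pseudo-replication over hundreds of AZs per animal
  is the failure mode the unit-of-analysis tag guards against.

## Statistics

Exact Mann–Whitney: full enumeration of C(n₁+n₂, n₁) labelings with
mid-ranks for ties; two-sided p = 2·min(P(U≤u), P(U≥u)) capped at 1
(this reproduces the 2/70 lattice pattern of 4-vs-4 animal
comparisons); enumeration limited to combined n ≤ 20. t tests from raw
data or mean ± SEM summaries (SD = SEM·√n) agree to machine precision.
The permutation curve test (statistic: Σ squared group-mean differences
across the x-grid; whole curves relabeled) is a pragmatic stand-in for
ANOVA-style repeated-measures curve comparisons, which are out of scope
— it is not a reproduction of any specific mixed-model p-value.

## Known limitations

* The circuit model has no pipette capacitance, no R_s compensation
  circuitry, and no frequency-dependent filter chain; the phase/gain
  calibration hook is where real-hardware corrections would enter.
* Square-wave (dual-pulse) capacitance estimation is not implemented.
* The depletion model is a single pool; no two-pool or sequential
  priming kinetics, no Ca²⁺ microdomain diffusion, no explicit EGTA
  buffering (chelator conditions enter as labels).
* EPSC analysis does no quantal or deconvolution-based release-rate
  estimation.
* Imaging is 2D; see the generator caveats above. The binarization-based
  segmentation, like the workflow it mirrors, undercounts clusters
  closer than ~80 nm and misses a few percent of dim edge clusters —
  visible as the ≈0.05–0.1 shortfall of recovered count means, still
  inside the stated recovery tolerance.
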