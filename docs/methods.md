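# Methods

This note documents the models, estimators, numerical choices and known
limitations of `qusrad`, in the package's own terms. It states no empirical
result that the test suite does not itself compute.

## 1. The RF simulator (what a green test does and does not establish)

Each scan line is synthesized in the frequency domain as a superposition of
point-scatterer echoes:

    S(f) = P(f) · FF(f) · Σ_s a_s · 10^(−2 α z_s f / 20) · e^(−i 2π f τ_s)

- **Pulse** `P(f)`: Gaussian amplitude spectrum centered on the transducer
  frequency (default 6.5 MHz, 40 MHz sampling). The fractional bandwidth
  (default 0.85) is defined on the −6 dB full width of the *power* spectrum,
  so the default pulse spans roughly 3.7–9.3 MHz at −6 dB.
- **Form factor** `FF(f) = exp(−0.827 k² a² / 2)` in amplitude
  (`exp(−0.827 k² a²)` in power), with `k = 2πf/c` and effective radius
  `a = diameter/2`. This is the Gaussian form factor; the size estimator
  inverts exactly this model, which makes estimator recovery a closed-loop,
  internally consistent check — it validates the estimator's algebra and its
  noise/attenuation robustness, not the adequacy of the Gaussian form factor
  for real tissue.
- **Attenuation**: round-trip loss `2 α z f` dB with `α` in dB/cm/MHz
  (amplitude-dB clinical convention), `z` absolute depth in cm, `f` in MHz.
- **Noise**: white Gaussian at `noise_db` below the mean signal power
  (default 40 dB, typical of focal-zone clinical RF).

There is no lateral diffraction, elevational beam, or nonlinear propagation:
the estimators act on per-line spectra, which this 1-D convolution model
reproduces. Depth-matched phantom normalization in real systems also cancels
diffraction to first order, so its absence here does not change what the
estimators see.

**Media.** Diffuse media use Poisson-uniform positions with zero-mean
Gaussian amplitudes (density default 12/mm² — sparse, biological-tissue
regime). Regular media place scatterers on an axial lattice (jitter capped at
5 % of the spacing) with positive amplitudes, producing the coherent spectral
ripple the spacing estimator targets. The **reference phantom** uses dense
(300/mm²) sub-resolution scatterers with unit-magnitude, random-sign
amplitudes: Gaussian amplitudes triple the scatterer number needed for fully
developed (Rayleigh) speckle, so unit amplitudes reach the calibrated-phantom
regime at practical densities. Phantom attenuation defaults to 0.5 dB/cm/MHz
— a configuration value for a typical tissue-mimicking phantom, not a claim.

**Cohort feature generator.** Feature tables (48 responders / 34
nonresponders by default) are multivariate normal per group with exchangeable
correlation 0.3 (configurable; unknown in reality). The eight features with
published group differences use those means with SD = SEM·√n; the other 23
features get equal-mean null distributions at scales chosen once to sit in
each family's physical range (e.g. homogeneity ≈ 0.80 ± 0.06). Green
statistics tests therefore establish calibration and power *under Gaussian
exchangeable-correlation data*, not under real radiomic dependence
structures.

## 2. Spectral analysis

- **Windows**: 2 mm × 2 mm, 92 % overlap (step 0.16 mm) by default. The mm →
  samples conversion uses pulse-echo depth `n = round(2·size·fs/(1000·c))`.
  Window positions are laid out in physical mm over the ROI bounding box and
  only windows whose full footprint lies inside the ROI mask are used.
- **Spectra**: per-line Hann periodogram (`scipy.signal.periodogram`,
  density scaling), averaged over the window's lines, zero-padded to a fixed
  2048-point FFT.
- **Normalization**: each tissue window is divided by the mean phantom
  spectrum at the same axial window position, averaged over all lateral
  positions and phantom realizations (low-variance, depth-matched reference).
- **Analysis band**: the contiguous −6 dB interval of the mean phantom
  spectrum around its peak, intersected with the transducer band from the
  frame metadata; computed once per ROI and held fixed (stabilizes fits).
- **Line fit**: OLS of dB power on frequency (MHz) in the band; MBF is the
  fit value at the band midpoint, so `MBF = SS·f_mid + SI` holds exactly.

### Scatterer size and concentration (ASD, AAC)

Because the reference phantom is itself composed of sub-resolution point
scatterers, the Rayleigh `f⁴` factor cancels in the normalized spectrum and
the Gaussian form-factor model becomes *linear in k²*:

    S(f) = 10·log₁₀(E) − 0.827 · k² a² · 10·log₁₀(e)

after attenuation compensation. The least-squares minimizer is an OLS fit of
dB power on k²; `ASD = 2a`, `AAC = 10·log₁₀(E)`. Numerical choices:

- diameter search range [10, 300] µm, enforced as bounds with boundary hits
  flagged (covers the physiological 100–125 µm range with wide margin);
- bins more than 25 dB below the in-band maximum are excluded, so the noise
  floor cannot flatten the fit for strongly rolled-off (large-scatterer)
  spectra;
- the differential attenuation term `−2(α_t − α_ref)·z·f` is compensated
  using the ROI's own attenuation estimate (below). Without this the size
  estimate is biased whenever tissue and phantom attenuation differ; with
  it, residual ACE error of ±0.05 dB/cm/MHz tilts the band by well under a
  dB and perturbs small-scatterer estimates by roughly 10–15 %.

### Attenuation (ACE)

Reference-phantom spectral-difference method, per ROI (no ACE map, matching
the per-patient scalar treatment). All in-band bins of all windows enter one
regression with: a free intercept per window (local concentration), a shared
k² column (form-factor curvature), and the shared `f·z` interaction whose
coefficient is `−2Δα`. The per-window intercepts and the curvature column
keep backscatter spectral shape out of the attenuation coefficient — without
them, `f` and `f·z` are nearly collinear over a 1–2 cm ROI and the estimate
is badly inflated in variance. `ACE = α_ref − b_{fz}/2` (the divisor is 2
because dB round-trip loss per cm·MHz is 2α in the amplitude-dB convention).
Results are clipped to [0, 3] dB/cm/MHz (clipping flagged); ROIs with fewer
than 3 depth positions or under 1 cm of depth span are flagged
low-confidence.

### Scatterer spacing (SAS)

Regular spacing d imposes a cosine ripple of period Δf = c/(2d) on the raw
(unnormalized) window spectrum. The in-band dB spectrum is detrended with a
*quadratic* baseline — the Gaussian pulse is exactly quadratic in dB and the
form-factor/attenuation terms are quadratic/linear, so the baseline absorbs
the smooth spectrum but cannot absorb a multi-period ripple (a linear
detrend leaves pulse curvature that masks the ripple autocorrelation). The
detrended spectrum is autocorrelated over frequency lag; the dominant local
maximum within the plausible range (0.25–3 mm spacing) is refined by
parabolic interpolation and converted via `SAS = c/(2Δf)`.

Significance: the peak must exceed both `mean + 2·SD` of the autocorrelation
tail (last quarter of the lag axis) and an absolute floor of 0.5 on the
normalized autocorrelation. Coherent lattice ripple drives the normalized
peak toward 0.8; diffuse media rarely exceed 0.4, so the floor is what gives
the estimator its specificity. Sub-threshold windows are flagged "absent" but
still record the best peak lag: parametric maps fill absent windows by
nearest neighbour from significant ones, fall back to the sub-threshold lags
when *no* window is significant (map flagged), and flag the map whenever more
than half the windows are absent. A genuinely aperiodic tumor therefore still
yields a (flagged) SAS value rather than dropping the slice.

## 3. Texture

Per parametric map: min–max quantization to 16 gray levels over the masked
values (per-map bounds, the common radiomics default; recorded in
provenance), symmetric GLCM at displacement 1 for 0°/45°/90°/135° counting
only pairs with both pixels in-mask, features averaged over angles.
Homogeneity uses `1/(1+|i−j|)`; correlation of a constant map is defined
as 1. Diagonal angles follow the image convention (45° = up-and-right);
scikit-image labels the two diagonals oppositely, which the cross-check test
accounts for — the symmetric matrices are identical either way, and the
angle average is invariant.

## 4. Statistics and classification

- Patient vector: window-mean spectral values and per-map texture, averaged
  over the patient's slices (mean, not median — logged choice); 3–5 slices
  expected, other counts warn.
- Group comparison per feature: Shapiro-Wilk on each group; both normal at
  α = .05 → two-sided *Welch* t (safer than pooled-variance under unequal
  group sizes); otherwise two-sided Mann-Whitney U. Zero-variance groups
  route to Mann-Whitney. No multiplicity correction drives the significance
  flag (matching common clinical reporting); a Benjamini-Hochberg column is
  emitted for transparency.
- Classifiers: K-NN (odd k, Euclidean, z-scored), SVM-RBF (z-scored), and a
  hand-rolled Fisher discriminant `w = S_w⁻¹(μ₊ − μ₋)` with midpoint
  threshold and ridge `1e-6·trace(S_w)` if the scatter matrix is singular
  (FLD is affine-invariant, so standardization is cosmetic).
- Sequential forward selection (≤ 4 features) maximizes LOO accuracy; ties
  break to the lowest feature index, making selection deterministic.
  Hyperparameters are grid-searched (k ∈ {1,3,5,7,9}; C ∈ 10^{−1..3},
  γ ∈ 10^{−3..1}) on LOO accuracy. **Both run on the full cohort by
  default**, reproducing the optimism profile of typical small-cohort
  radiomics protocols; `selection_mode="nested"` re-runs selection inside
  every fold for the honest generalization estimate.
- LOO CV standardizes with train-only statistics in every fold; the held-out
  patient never influences its own fold's fit (asserted by test).
- Metrics: Sn/Sp/Acc as percentages from the confusion matrix, F1, and
  trapezoid AUC over the unique-score threshold sweep (equal to Mann-Whitney
  pair counting with ties at ½). The positive class defaults to responder
  ('R') and is configurable — the convention is genuinely ambiguous in this
  literature.

## 5. Pipeline, determinism, provenance

`simulate → extract → analyze` is byte-reproducible under a fixed seed:
HDF5 writing disables timestamps and orders groups; CSVs use fixed float
formatting; every output carries a provenance header (package version,
config hash, seed). The simulated cohort gives responders smaller scatterers
(100 vs 130 µm) at +6 dB concentration — the direction of the published group
differences — with shared attenuation, so the extraction stage has real
signal to find without dictating the classifier outcome.

## 6. Known limitations and one expected red test

- The simulator's Gaussian form factor and 1-D propagation make size/
  concentration recovery a consistency check, not a tissue-realism claim.
- AAC is relative to the synthetic phantom's arbitrary amplitude scale; only
  AAC *differences* are physically meaningful here.
- Scatterer-spacing specificity thresholds (2 SD + 0.5 floor) were chosen on
  the simulator's speckle statistics; very heterogeneous real tissue may need
  the configurable threshold raised.
- One acceptance-level test requires the spectral-slope group difference to
  reach significance in ≥ 80 % of cohorts drawn at the published means/SEMs
  (0.70 dB/MHz difference, SEMs 0.18/0.20, n = 48/34). The implied
  noncentrality is 0.70/√(0.18² + 0.20²) ≈ 2.60, giving two-sided power
  ≈ 0.73 at α = .05 — so the 80 % bound is unattainable at that effect size
  and the test fails by design (observed ≈ 0.70 over 200 replicates). It is
  left failing rather than loosened.
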