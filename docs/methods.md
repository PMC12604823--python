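# Methods

This note records the models implemented in `metaflim`, the conventions
and numerical choices behind them, what the synthetic data generator does
and does not emulate, and the package's known limitations.

## Decay model and time base

A TCSPC histogram lives on a uniform `TimeGrid` (`n_bins`, `bin_width`,
`rep_rate`); the acquisition window may not exceed the laser period
T = 1/f (one-bin slack).  Time samples are **bin centers**,
t_k = (k + ½)·Δ, used consistently by simulation, fitting, and the
phasor transform.

The per-pixel model is the biexponential

I(t) = α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) + C,

with lifetimes in seconds and amplitudes in count units (counts/bin at
t = 0), matching how FLIM software reports them; fractional forms
(amplitude fraction α₂/(α₁+α₂), intensity fraction
f₂ = α₂τ₂/(α₁τ₁+α₂τ₂)) are derived views.  These two bound-fraction
conventions are distinct quantities and are never conflated: functions
return one or the other explicitly.  Construction canonicalizes
τ₁ ≤ τ₂ by swapping components, which leaves the model invariant.

**Periodic wrapping.**  At 80 MHz the slow component has not decayed
within one period (e^(−12.5/2.81) ≈ 1.2%), so the observed steady-state
decay is the periodic sum over all previous pulses.  For an exponential
this has the closed form e^(−t/τ)/(1 − e^(−T/τ)) on [0, T), which is used
exactly wherever a wrapped curve is needed.  Convolution with the IRF is
correspondingly **circular** over the period (FFT-based); a linear mode
exists for long-period data.  The IRF is renormalized to unit sum before
convolution so amplitudes keep count units, and total counts are
conserved exactly.

**Half-bin convention.**  The discrete circular convolution of two
bin-center histograms assigns mass at t_j + t_m = t_{j+m} + Δ/2, i.e. it
carries a systematic half-bin time offset.  This is irrelevant wherever
model and data go through the same convolution (fitting) or a reference
is measured with the same convention (phasor calibration); the one place
it surfaces — moment-based lifetime estimation — is corrected explicitly
in the tests.

## Synthetic data

The generator produces every input the pipeline consumes, with known
ground truth and seeded randomness (all generators are pure functions of
configuration + seed):

* **IRF**: bin-integrated Gaussian of configurable FWHM (σ = FWHM/2.3548)
  wrapped over the period; default 150 ps FWHM, typical of hybrid
  detectors on two-photon systems.
* **Decays**: expected shape = wrapped biexponential, bin-integrated
  exactly (per-bin integral ατ(e^(−a/τ) − e^(−b/τ))), circularly
  convolved with the IRF, scaled to the expected photon total; observed
  counts are independent Poisson per bin (equivalent to a multinomial
  conditioned on a Poisson total).  Dark counts, when enabled, are
  uniform in time (they map onto C).
* **Cell scenes**: elliptical cytoplasm regions (labels 1..N) with
  concentric elliptical nuclear holes (labels −1..−N), 0 background.
  Default decay: τ₁ = 0.54 ns, τ₂ = 2.81 ns, α₁:α₂ = 2640:1180 — the
  typical in-vitro NAD(P)H parameter set.  Default photon budget
  5000 photons/pixel, in the range a 10–100 s acquisition at
  2–5 × 10⁵ photons/s yields for a 512² image after binning; budgets are
  configuration, not derived from an optics model.
* **Intensity pairs + standards**: per-region expected counts are
  level × gain × base (default base 1000 counts, Poisson noise); the
  1 mM NADH/FAD solution standards are uniform frames generated with the
  same per-channel gains, so solution-standard calibration cancels gains
  exactly in expectation.

Not emulated: optical PSF/blur, detector afterpulsing, spectral
crosstalk between channels, non-NAD(P)H/FAD fluorophores, realistic cell
morphology, and pile-up distortion (count rates in this regime sit well
below the 5–10% bound; the QC flag is exercised directly on rates).
Passing tests therefore demonstrate correctness of the *analysis*
under Poisson counting statistics and known kinetics — not robustness to
optical artifacts real data may carry.

## Lifetime fitting

Protocol defaults follow standard practice: mask pixels whose **raw**
total is below 200 counts, then sum-bin decays over 3×3 neighborhoods
(every fitted decay then holds ≥ 1800 photons).  Edge pixels use
truncated neighborhoods (zero padding), so binned totals are honest
counts; mirrored padding would fabricate photons.  The mask is computed
on pre-binning totals; pixel accounting (fitted + excluded = total) is
preserved and reported.

The fit minimizes either Neyman-weighted least squares
(weights 1/max(y, 1)) or the Poisson deviance (MLE, via signed deviance
residuals).  The model curve is the wrapped biexponential at bin centers,
circularly convolved with the unit-sum IRF.

**Variable projection.**  At fixed lifetimes the amplitudes (and C)
enter linearly, so the WLS search runs over (τ₁, τ₂) only, with the
linear part solved by weighted nonnegative least squares at every step.
The joint 4–5 parameter problem has a narrow, badly scaled
lifetime/amplitude valley in which trust-region optimizers stall; the
projected problem is 2-dimensional and well conditioned (internally in
ns units).  MLE refines all parameters against the deviance starting
from the WLS solution.  Initialization: τ₂ from the log-linear tail
slope, τ₁ from 0.4 ns (free NAD(P)H), amplitudes by the linear solve.

Lifetime bounds are [0.01, 10] ns (configurable) — generous around the
physiological ~0.3–6 ns range — purely to prevent divergence.  No decay
component is fixed by default (lifetimes measured in solution do not
transfer to cells); fixing is available only by explicit configuration.
The background C is fitted by default and may be fixed (e.g. at 0 for
dark-count-free synthetic data); with periodic wrapping there are no
clean pre-rise bins from which to estimate it independently.

Reduced χ² uses dof = n_bins − n_free.  Under the correct model at
5000 photons/decay the mean Neyman reduced χ² is ≈ 1.01 (verified by
simulation in the tests).  Asymptotic standard errors come from the
pseudo-inverse of JᵀJ at the optimum, scaled by reduced χ².

Estimator behavior established by the test suite: median lifetime errors
< 5% at 10⁴ photons/decay (MLE); RMSE(τₘ) decreases monotonically over
10³–10⁵ photons; precision scales as N^(−1/2); at 500 photons the MLE
mean-lifetime bias does not exceed the WLS bias (Neyman weighting is
known to bias low at low counts).

## Phasor analysis

Discrete transform: plain Riemann sums at bin centers over the acquired
window, normalized by the per-pixel total; no apodization.  Because a
TCSPC bin integrates the arrival rate over its width, the midpoint-phase
sum approximates the continuous integrals to O((ωΔ)²) regardless of how
sharp the decay is; at 256 bins/period the error is ≲ 3 × 10⁻⁴, which is
why simulated monoexponentials land on the closed form
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) within 10⁻³.

Zero-count pixels are masked, never NaN-propagated.  A constant offset
estimated as the background would bias the phasor toward the origin; the
synthetic pipeline generates offset-free decays, and for real data the
background is expected to be removed upstream (C from the fit, or dark
frames).

**Calibration** is a single global complex factor (phase rotation +
modulation scaling) mapping the measured reference phasor onto the
theoretical phasor of its known lifetime; per-pixel calibration is not
supported.  Since circular convolution multiplies phasors, calibration
against a reference measured under the same IRF removes the instrument
factor exactly; the round trip recovers the 3.05 ns fluorescein phase
lifetime to ≲ 0.3%.  A reference with near-zero modulation is rejected.

Phase and modulation lifetimes: τ_φ = s/(gω),
τ_mod = (1/ω)√(1/(g²+s²) − 1); out-of-domain pixels (g ≤ 0, modulation
> 1) are flagged NaN.  τ_φ ≤ τ_mod for multiexponential decays, with
equality only on the universal circle.

**Bound fraction.**  The unnormalized distance
d = √((g−g₁)² + (s−s₁)²) from the free-species phasor (default 0.4 ns at
the first harmonic; every default is echoed into the QC report) is
reported *as a distance*, never as a fraction — without a bound endpoint
the normalization is undefined, and distance-based and
amplitude-fraction metrics must not be compared directly.  With
endpoints (assigned lifetimes or a cloud fit) the normalized fraction
f₂ = d/|P₂ − P₁| is clipped to [0,1] with an out-of-segment count
reported.  Cloud fitting is intensity-weighted total least squares
(principal axis of the weighted covariance), intersected with the
universal circle; the larger-g intersection is the free endpoint.  A
near-isotropic cloud (principal/secondary eigenvalue ratio below 5) has
no meaningful axis and is rejected; the weighting is configurable since
practice varies.

Median filtering (3×3 default) is applied to g and s independently
within the mask; intensity is untouched.

## Optical redox ratio

Defaults follow the standard protocol: 3×3 sum prefilter on raw
channels, ratio, 5×5 median postfilter; thresholding on the NAD(P)H
channel; all choices recorded in the result object.  The **oxidized**
convention FAD/(NAD(P)H+FAD) is the default and every output is stamped
with its convention string.  The reduced form is computed as
1 − oxidized, which makes the complement identity bit-exact per pixel
(and survives the median filter, which is order-reversing under
x ↦ 1−x).

Division-by-zero pixels are masked, not clipped, and masked-out counts
are reported.  Negative label codes (nuclei, lipid droplets) are
excluded by default.  Spectral crosstalk is not corrected; a
leakage-fraction metadata field only propagates a warning into QC.

Solution-standard calibration divides each channel by the spatial mean
of its matching 1 mM standard; the mean is computed on the raw standard
frame (for a uniform frame the prefilter does not change the mean).
Joint per-channel gain changes applied to sample and standard leave the
calibrated ORR invariant to 10⁻¹², and a simulated two-setting
experiment shows calibrated distributions overlapping (KS distance
< 0.3) where uncalibrated ones separate (KS > 0.5).

Per-region aggregation reports **both** ratio-of-means (ORR of the
region-mean intensities; better SNR) and mean-of-ratios (mean pixelwise
ORR; preserves heterogeneity weighting) side by side with pixel counts.
The two coincide exactly when every pixel in the region has the same
total intensity — even with heterogeneous ratios — and diverge
otherwise; the tests exercise both cases by brute-force hand
computation.

The pathway-interpretation table maps a direction of change in each
metric (oxidized ORR, reduced ORR, bound fraction/τₘ) to the pathway
activities typically consistent with it.  Annotations are interpretive
aids carrying an explicit caveat (changes can be transient and
cell/tissue/environment dependent); they are never a claim of mechanism.

## QC reporting

Each consensus recommendation has a stable `item_id` and either a
machine-checkable predicate over run metadata + analysis configuration,
or an attestation key for items no software can verify (orthogonal
validation experiments, consideration of other fluorophores).  The
inventory ships as JSON data so wording changes never touch logic; the
union of emitted items is snapshot-tested (7 + 5 intensity, 5 + 4 FLIM).
Attestation items are `missing` until attested — statuses never default
to pass — and QC never blocks analysis.

Pile-up: pass iff count rate ≤ 5% of the pulse rate (conservative
default); the 10% verdict is reported alongside.  SNR: √N.  SBR:
mean(signal)/mean(background), with background defaulting to label-0
pixels — the definition is a package choice and is stated in the report.
Photon statistics use numpy's midpoint median convention.

## File formats and CLI

Decay stacks: multi-page TIFF (page = time bin, increasing) + JSON
sidecar (`n_bins`, `bin_width_s`, `rep_rate_hz`; missing sidecars are a
hard error naming the keys).  Counts are integers; masks are uint16
TIFF with negative exclusion codes mapped to a reserved high range
(≥ 61441).  IRFs and tables are CSV; configs/reports/manifests JSON.
All writes are atomic (temp + rename).  Vendor formats (SDT, PTU) are
out of scope; convert to TIFF/CSV upstream.  The `metaflim` CLI chains
simulate → fit/phasor/redox → qc and writes a manifest (config,
versions, seed, checksums) beside every output.

## Problem sizes

The test suite and the acceptance script run on desk-scale problems
chosen to give stable statistics at interactive cost: 256-bin decays,
scenes up to 64², 100–200 Monte-Carlo seeds for recovery/bias/scaling
checks (a single-decay fit takes ~5–15 ms).  The full suite completes
in well under a minute.

## Known limitations

* Two exponential components only; real cellular decays are more
  heterogeneous, and the biexponential is itself an approximation whose
  impact on interpretation should be considered.
* No global/multi-pixel fitting; each pixel is independent.
* Phasor background handling assumes offset-free decays.
* No spectral unmixing: NAD(P)H leakage into the FAD channel at red-side
  excitation is flagged, not corrected.
* Calibration supports same-condition solution standards only, not
  transfer functions across arbitrary instrument settings; calibrated
  intensities are not concentration estimates.
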