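# metaflim

Analysis tools for label-free optical metabolic imaging of the intrinsic
fluorophores NAD(P)H and FAD: calibrated **optical redox ratio (ORR)**
imaging, time-domain **FLIM** analysis by biexponential fitting and by
**phasor** transformation, and machine-checkable **QC reporting** of the
community's consensus recommendations — together with a synthetic
TCSPC/intensity-image generator so the whole pipeline is testable without
instrument data.

It is written for microscopists and image analysts working with
two-photon autofluorescence data (TCSPC decay stacks, intensity channel
pairs, calibration-solution frames) who want a transparent, scriptable
alternative to vendor analysis software.

## The quantities it computes

**Optical redox ratio.**  Two normalized conventions, always labeled:

    ORR_oxidized = FAD / (NAD(P)H + FAD)        ORR_reduced = 1 − ORR_oxidized

Channel intensities can be calibrated by the mean intensity of 1 mM NADH
and FAD solution standards imaged under identical settings, which cancels
gain/power/collection differences and makes ORR comparable across
acquisition conditions and instruments.  Per-region aggregates are
reported both as ratio-of-means and mean-of-ratios, which differ on
heterogeneous regions.

**Biexponential FLIM.**  Each pixel's decay is modeled as

    I(t) = α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) + C

convolved with the instrument response function (IRF) and wrapped over
the laser period.  Derived quantities: the amplitude-weighted mean
lifetime τₘ = (α₁τ₁ + α₂τ₂)/(α₁ + α₂) and the bound intensity fraction
f₂ = α₂τ₂/(α₁τ₁ + α₂τ₂).  Fitting is weighted least squares (Neyman
weights) via variable projection, or Poisson maximum likelihood; reduced
χ² and parameter distributions are reported.

**Phasor analysis.**  The fit-free alternative: each decay maps to
g = ∫I cos(ωt)/∫I, s = ∫I sin(ωt)/∫I at harmonics of the 80 MHz
repetition rate.  Monoexponential decays fall on the universal circle
s² = g(1−g); mixtures fall on the chord between component phasors.
Calibration against a reference dye (fluorescein in ethanol, 3.05 ns)
removes the instrument phase/modulation shift.  Bound-fraction maps come
from the distance to the free-NAD(P)H phasor (0.4 ns) or, with assigned
or cloud-fitted endpoints, as the normalized fraction along the chord.

**QC.**  Photon statistics pre/post binning, the pile-up bound (count
rate ≤ 5–10% of the pulse rate), Poisson SNR (√N), and the four consensus
reporting checklists (7 + 5 intensity items, 5 + 4 FLIM items) evaluated
automatically from run metadata where possible, emitted as `missing`
where only a human can attest.

## Worked example

```python
import numpy as np
from metaflim import (TimeGrid, BiexpParams, make_gaussian_irf,
                      simulate_decay, BiexponentialDecayModel)

grid = TimeGrid(n_bins=256, bin_width=12.5e-9 / 256, rep_rate=80e6)
irf = make_gaussian_irf(grid, fwhm=150e-12, center=1.0e-9)

# typical cellular NAD(P)H decay: 0.54 ns free / 2.81 ns bound
truth = BiexpParams(tau1=0.54e-9, tau2=2.81e-9, alpha1=2640.0, alpha2=1180.0)
decay = simulate_decay(truth, grid, irf, n_photons=10_000, seed=42)

res = BiexponentialDecayModel(decay, grid, irf, method="mle",
                              fix_background=0.0).fit()
print(res.summary())
```

prints

```
Biexponential decay fit
==============================================
method:          MLE
converged:       True
photons in fit:  9910
bins used:       256   free params: 4
reduced chi^2:   1.1009
----------------------------------------------
tau1             0.5435 +/- 0.03545 ns
tau2              2.836 +/- 0.07497 ns
alpha1            273.3 +/- 10.98 counts
alpha2            118.3 +/- 6.285 counts
background            0 counts/bin
----------------------------------------------
tau_m (amplitude-weighted): 1.236 ns
bound intensity fraction f2: 0.6930
```

The fitted lifetimes recover the ground truth (0.54 / 2.81 ns) within
their standard errors at 10⁴ photons; reduced χ² ≈ 1 says the Poisson
noise model is consistent; τₘ and f₂ are the derived metabolic metrics
(a higher bound fraction indicates more protein-bound NAD(P)H, typically
more oxidative metabolism).  The same decay analyzed by phasor lands at
a point whose distance from the free-NAD(P)H phasor (g = 0.9611,
s = 0.1932 at 80 MHz) encodes the same information without fitting.

A command-line interface chains the steps on files
(`metaflim simulate | fit | phasor | redox | qc`); every run writes a
manifest with its configuration, seed, and output checksums.

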