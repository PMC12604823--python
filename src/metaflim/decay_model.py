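"""Mathematical core for time-domain fluorescence decay analysis.

Everything downstream — simulation, per-pixel fitting, phasor analysis —
shares the objects defined here: the timing grid of a TCSPC histogram, the
biexponential decay model

    I(t) = alpha1 * exp(-t / tau1) + alpha2 * exp(-t / tau2) + C,

the instrument response function (IRF), and convolution of a model decay
with the IRF.  All times are seconds; amplitudes are in photon-count units
(counts per time bin at t = 0), matching how TCSPC software reports them.

Under repetitive excitation at repetition rate ``f`` (period ``T = 1/f``)
the fluorescence from earlier pulses wraps into the observation window.
For a single exponential the periodically wrapped decay has the closed
form ``exp(-t/tau) / (1 - exp(-T/tau))`` on ``[0, T)``, which this module
uses wherever a period-wrapped curve is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "BiexpParams",
    "IRFCurve",
    "DegenerateDecayError",
    "GridMismatchError",
    "InvalidParameterError",
    "evaluate_biexp",
    "bin_integrated_biexp",
    "amplitude_weighted_mean_lifetime",
    "intensity_fraction_bound",
    "amplitude_fraction_bound",
    "convolve_with_irf",
]


class InvalidParameterError(ValueError):
    """A model parameter is non-finite or outside its physical domain."""


class DegenerateDecayError(ValueError):
    """The decay carries no intensity (both amplitudes zero)."""


class GridMismatchError(ValueError):
    """Two curves that must share a TimeGrid do not."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time base of a TCSPC histogram.

    Parameters
    ----------
    n_bins : int
        Number of time bins in the histogram.
    bin_width : float
        Width of one bin in seconds.
    rep_rate : float
        Laser repetition rate ``f`` in Hz; the period is ``T = 1/f``.
    """

    n_bins: int
    bin_width: float
    rep_rate: float

    def __post_init__(self) -> None:
        if not (self.n_bins >= 1 and int(self.n_bins) == self.n_bins):
            raise InvalidParameterError(f"n_bins must be a positive integer, got {self.n_bins}")
        if not (np.isfinite(self.bin_width) and self.bin_width > 0):
            raise InvalidParameterError(f"bin_width must be > 0, got {self.bin_width}")
        if not (np.isfinite(self.rep_rate) and self.rep_rate > 0):
            raise InvalidParameterError(f"rep_rate must be > 0, got {self.rep_rate}")
        # the acquisition window may not exceed the laser period (one-bin slack)
        if self.n_bins * self.bin_width > self.period + self.bin_width:
            raise InvalidParameterError(
                f"window {self.n_bins * self.bin_width:.3e} s exceeds the laser period "
                f"{self.period:.3e} s"
            )

    @property
    def period(self) -> float:
        """Laser period T = 1 / rep_rate, seconds."""
        return 1.0 / self.rep_rate

    def omega(self, harmonic: int = 1) -> float:
        """Angular frequency ``2 * pi * rep_rate * harmonic`` in rad/s."""
        if harmonic < 1:
            raise InvalidParameterError(f"harmonic must be >= 1, got {harmonic}")
        return 2.0 * np.pi * self.rep_rate * harmonic

    @property
    def bin_centers(self) -> np.ndarray:
        """Time at the center of each bin: ``(k + 1/2) * bin_width``."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def to_dict(self) -> dict:
        return {
            "n_bins": int(self.n_bins),
            "bin_width_s": float(self.bin_width),
            "rep_rate_hz": float(self.rep_rate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeGrid":
        missing = {"n_bins", "bin_width_s", "rep_rate_hz"} - set(d)
        if missing:
            raise KeyError(f"TimeGrid metadata missing required keys: {sorted(missing)}")
        return cls(int(d["n_bins"]), float(d["bin_width_s"]), float(d["rep_rate_hz"]))


@dataclass(frozen=True)
class BiexpParams:
    """Parameters of the biexponential decay model.

    ``tau1 <= tau2`` is enforced as a canonical ordering: constructing with
    the components swapped relabels them (the model is symmetric under
    component exchange).  Amplitudes are in count units, not normalized
    fractions; the fractional views are :func:`amplitude_fraction_bound`
    and :func:`intensity_fraction_bound`.
    """

    tau1: float
    tau2: float
    alpha1: float
    alpha2: float
    background: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.tau1, self.tau2, self.alpha1, self.alpha2, self.background)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidParameterError("lifetimes must be > 0")
        if self.alpha1 < 0 or self.alpha2 < 0 or self.background < 0:
            raise InvalidParameterError("amplitudes and background must be >= 0")
        if self.alpha1 == 0 and self.alpha2 == 0:
            raise DegenerateDecayError("both amplitudes are zero")
        if self.tau1 > self.tau2:  # canonicalize: short component first
            object.__setattr__(self, "tau1", vals[1])
            object.__setattr__(self, "tau2", vals[0])
            object.__setattr__(self, "alpha1", vals[3])
            object.__setattr__(self, "alpha2", vals[2])

    @classmethod
    def monoexponential(cls, tau: float, alpha: float = 1.0, background: float = 0.0) -> "BiexpParams":
        """Single-component decay expressed in the biexponential container."""
        return cls(tau1=tau, tau2=tau, alpha1=alpha, alpha2=0.0, background=background)

    @property
    def mean_lifetime(self) -> float:
        return amplitude_weighted_mean_lifetime(self)

    @property
    def intensity_fraction_bound(self) -> float:
        return intensity_fraction_bound(self)

    def to_dict(self) -> dict:
        return {
            "tau1_s": self.tau1,
            "tau2_s": self.tau2,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "background": self.background,
        }


@dataclass(frozen=True)
class IRFCurve:
    """Instrument response function sampled on a :class:`TimeGrid`.

    ``fwhm`` is metadata (seconds) carried for reporting; the shape used in
    computation is ``values``.
    """

    values: np.ndarray
    grid: TimeGrid
    fwhm: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.shape[0] != self.grid.n_bins:
            raise GridMismatchError(
                f"IRF has {values.shape} values but the grid has {self.grid.n_bins} bins"
            )
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise InvalidParameterError("IRF values must be finite and nonnegative")
        if values.sum() <= 0:
            raise InvalidParameterError("IRF must have positive total")
        object.__setattr__(self, "values", values)

    @property
    def normalized(self) -> np.ndarray:
        """IRF rescaled to unit sum, the form used in convolution."""
        return self.values / self.values.sum()

    @classmethod
    def impulse(cls, grid: TimeGrid, bin_index: int = 0) -> "IRFCurve":
        """Ideal (delta-function) IRF: all weight in a single bin."""
        v = np.zeros(grid.n_bins)
        v[bin_index] = 1.0
        return cls(values=v, grid=grid, fwhm=0.0)


def _wrap_factor(tau: float, period: float) -> float:
    # geometric sum over all previous excitation pulses
    return 1.0 / (1.0 - np.exp(-period / tau))


def evaluate_biexp(params: BiexpParams, grid: TimeGrid, periodic: bool = False) -> np.ndarray:
    """Evaluate the biexponential model at the bin centers of *grid*.

    With ``periodic=True`` each exponential component is replaced by its
    periodically wrapped counterpart (incomplete decay from previous laser
    pulses folded into the window), the steady-state shape a TCSPC system
    at high repetition rate actually observes.
    """
    t = grid.bin_centers
    w1 = _wrap_factor(params.tau1, grid.period) if periodic else 1.0
    w2 = _wrap_factor(params.tau2, grid.period) if periodic else 1.0
    return (
        params.alpha1 * w1 * np.exp(-t / params.tau1)
        + params.alpha2 * w2 * np.exp(-t / params.tau2)
        + params.background
    )


def bin_integrated_biexp(params: BiexpParams, grid: TimeGrid, periodic: bool = True) -> np.ndarray:
    """Exact per-bin integrals of the (optionally wrapped) biexponential.

    Returns expected counts per bin when the model amplitude is interpreted
    as an instantaneous rate in counts/second; the per-component integral
    over bin ``[a, b]`` is ``alpha * tau * (exp(-a/tau) - exp(-b/tau))``.
    This is the right expectation for simulated photon histograms, since a
    TCSPC bin integrates the arrival-rate over its width.
    """
    edges = grid.bin_edges
    out = np.zeros(grid.n_bins)
    for tau, alpha in ((params.tau1, params.alpha1), (params.tau2, params.alpha2)):
        if alpha == 0:
            continue
        w = _wrap_factor(tau, grid.period) if periodic else 1.0
        e = np.exp(-edges / tau)
        out += alpha * w * tau * (e[:-1] - e[1:])
    out += params.background * grid.bin_width
    return out


def amplitude_weighted_mean_lifetime(params: BiexpParams) -> float:
    """Amplitude-weighted mean lifetime (alpha1*tau1 + alpha2*tau2)/(alpha1 + alpha2)."""
    denom = params.alpha1 + params.alpha2
    if denom <= 0:
        raise DegenerateDecayError("mean lifetime undefined: both amplitudes zero")
    return (params.alpha1 * params.tau1 + params.alpha2 * params.tau2) / denom


def intensity_fraction_bound(params: BiexpParams) -> float:
    """Intensity fraction of the long-lifetime component.

    f2 = alpha2*tau2 / (alpha1*tau1 + alpha2*tau2) — the relative
    fluorescence-intensity contribution of the slow (protein-bound)
    component; distinct from the amplitude fraction alpha2/(alpha1+alpha2)
    and the two must not be conflated.
    """
    denom = params.alpha1 * params.tau1 + params.alpha2 * params.tau2
    if denom <= 0:
        raise DegenerateDecayError("intensity fraction undefined: zero total intensity")
    return params.alpha2 * params.tau2 / denom


def amplitude_fraction_bound(params: BiexpParams) -> float:
    """Amplitude fraction of the long-lifetime component, alpha2/(alpha1+alpha2)."""
    denom = params.alpha1 + params.alpha2
    if denom <= 0:
        raise DegenerateDecayError("amplitude fraction undefined: both amplitudes zero")
    return params.alpha2 / denom


def convolve_with_irf(decay: np.ndarray, irf: IRFCurve, periodic: bool = True) -> np.ndarray:
    """Convolve a model decay with the IRF (normalized to unit sum).

    With ``periodic=True`` (default) the convolution is circular over the
    laser period, matching repetitive excitation where the IRF tail wraps
    around the window.  With ``periodic=False`` a linear convolution is
    used and truncated to the grid (appropriate for long-period data where
    the decay is complete well before the window ends).

    Total counts are conserved in periodic mode because the kernel has unit
    sum.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 1 or decay.shape[0] != irf.grid.n_bins:
        raise GridMismatchError(
            f"decay has {decay.shape} samples but the IRF grid has {irf.grid.n_bins} bins"
        )
    kernel = irf.normalized
    if periodic:
        n = decay.shape[0]
        out = np.fft.irfft(np.fft.rfft(decay) * np.fft.rfft(kernel), n=n)
        # counts are nonnegative; clip FFT round-off
        return np.where(np.abs(out) < 1e-12 * max(decay.max(), 1.0), np.maximum(out, 0.0), out)
    return np.convolve(decay, kernel)[: decay.shape[0]]
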