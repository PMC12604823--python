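"""Fit-free phasor analysis of TCSPC decay stacks.

Each pixel's decay ``I(t)`` is mapped to normalized Fourier coordinates at
harmonic ``n`` of the laser repetition rate (angular frequency
``omega = 2*pi*f*n``)::

    g = integral I(t) cos(omega t) dt / integral I(t) dt
    s = integral I(t) sin(omega t) dt / integral I(t) dt

Monoexponential decays fall on the universal semicircle
``s^2 = g * (1 - g)``; mixtures fall inside it, on the chord joining the
component phasors, weighted by their intensity fractions.  Because the
measured decay is the true decay convolved with the IRF, the raw phasor is
rotated and scaled by the instrument; a reference of known lifetime
(e.g. fluorescein, 3.05 ns) supplies the single complex correction factor
that undoes this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .containers import DecayStack
from .decay_model import TimeGrid

__all__ = [
    "PhasorField",
    "PhasorEndpoints",
    "CalibrationError",
    "monoexp_phasor",
    "phasor_of_decay",
    "phasor_transform",
    "calibrate_phasor",
    "lifetimes_from_phasor",
    "bound_fraction_distance",
    "bound_fraction_normalized",
    "fit_phasor_line",
    "median_filter_phasor",
]


class CalibrationError(RuntimeError):
    """Phasor calibration is impossible or has not been applied."""


def monoexp_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Closed-form phasor of a monoexponential decay:
    g = 1/(1+(omega*tau)^2), s = omega*tau/(1+(omega*tau)^2)."""
    wt = omega * tau
    den = 1.0 + wt * wt
    return 1.0 / den, wt / den


@dataclass
class PhasorField:
    """Per-pixel (g, s) phasor coordinates at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    harmonic: int
    omega: float
    intensity: np.ndarray
    calibrated: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.intensity > 0

    @property
    def z(self) -> np.ndarray:
        """Complex phasor g + i s."""
        return self.g + 1j * self.s

    def masked_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(g, s, intensity) restricted to valid pixels, flattened."""
        m = self.mask & np.isfinite(self.g) & np.isfinite(self.s)
        return self.g[m], self.s[m], self.intensity[m]


@dataclass(frozen=True)
class PhasorEndpoints:
    """Free and bound pure-species phasor positions for two-component mixing."""

    free_point: tuple[float, float]
    bound_point: tuple[float, float]
    provenance: str = "assigned-lifetime"

    def __post_init__(self) -> None:
        f = np.asarray(self.free_point, dtype=float)
        b = np.asarray(self.bound_point, dtype=float)
        if np.allclose(f, b):
            raise ValueError("free and bound endpoints coincide")

    @classmethod
    def from_lifetimes(cls, tau_free: float, tau_bound: float, omega: float) -> "PhasorEndpoints":
        return cls(
            free_point=monoexp_phasor(tau_free, omega),
            bound_point=monoexp_phasor(tau_bound, omega),
            provenance="assigned-lifetime",
        )

    @property
    def separation(self) -> float:
        f, b = np.asarray(self.free_point), np.asarray(self.bound_point)
        return float(np.hypot(*(b - f)))


def _phase_weights(grid: TimeGrid, harmonic: int) -> np.ndarray:
    # e^{i omega t_k} at bin centers; Riemann sums over the acquired window
    return np.exp(1j * grid.omega(harmonic) * grid.bin_centers)


def phasor_of_decay(decay: np.ndarray, grid: TimeGrid, harmonic: int = 1) -> tuple[float, float]:
    """Phasor coordinates of a single 1-D decay histogram."""
    decay = np.asarray(decay, dtype=float)
    total = decay.sum()
    if total <= 0:
        raise ValueError("cannot transform a zero-count decay")
    z = (decay @ _phase_weights(grid, harmonic)) / total
    return float(z.real), float(z.imag)


def phasor_transform(stack: DecayStack, harmonic: int = 1) -> PhasorField:
    """Phasor-transform every pixel of a decay stack (uncalibrated).

    Zero-count pixels are excluded via the mask rather than propagating
    NaN.
    """
    w = _phase_weights(stack.grid, harmonic)
    counts = stack.counts.astype(float)
    total = counts.sum(axis=0)
    num = np.tensordot(w, counts, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(total > 0, num / np.where(total > 0, total, 1.0), np.nan + 0j)
    return PhasorField(
        g=z.real.copy(),
        s=z.imag.copy(),
        harmonic=harmonic,
        omega=stack.grid.omega(harmonic),
        intensity=total,
        calibrated=False,
        mask=total > 0,
    )


def calibrate_phasor(
    field: PhasorField,
    reference: DecayStack | np.ndarray,
    reference_lifetime: float,
    grid: TimeGrid | None = None,
) -> PhasorField:
    """Calibrate a phasor field with a reference of known lifetime.

    The measured reference phasor is mapped onto the theoretical
    monoexponential phasor of ``reference_lifetime`` by one global complex
    factor (phase rotation + modulation scaling), which is then applied to
    every pixel.  The reference may be a DecayStack (pixels are pooled) or
    a single 1-D decay (then *grid* is required).
    """
    if isinstance(reference, DecayStack):
        ref_decay = reference.counts.sum(axis=(1, 2))
        ref_grid = reference.grid
    else:
        if grid is None:
            raise ValueError("grid is required when the reference is a bare decay")
        ref_decay = np.asarray(reference, dtype=float)
        ref_grid = grid
    g_ref, s_ref = phasor_of_decay(ref_decay, ref_grid, field.harmonic)
    z_ref = g_ref + 1j * s_ref
    if abs(z_ref) < 1e-6:
        raise CalibrationError(
            f"reference modulation {abs(z_ref):.2e} is too small to calibrate against"
        )
    g_th, s_th = monoexp_phasor(reference_lifetime, field.omega)
    factor = (g_th + 1j * s_th) / z_ref
    z = field.z * factor
    return replace(field, g=z.real, s=z.imag, calibrated=True)


def lifetimes_from_phasor(
    g: np.ndarray | float, s: np.ndarray | float, omega: float
) -> tuple[np.ndarray, np.ndarray]:
    """Phase and modulation lifetimes from phasor coordinates.

    tau_phase = (1/omega) * s/g;
    tau_mod = (1/omega) * sqrt(1/(g^2 + s^2) - 1).

    Out-of-domain pixels (g <= 0 or modulation beyond the unit circle by
    more than a small tolerance) yield NaN.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    mod2 = g * g + s * s
    ok = (g > 0) & (mod2 > 0) & (mod2 <= 1.0 + 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_phi = np.where(ok, s / np.where(g != 0, g, 1.0) / omega, np.nan)
        inv = np.clip(1.0 / np.where(mod2 > 0, mod2, 1.0) - 1.0, 0.0, None)
        tau_mod = np.where(ok, np.sqrt(inv) / omega, np.nan)
    if tau_phi.ndim == 0:
        return float(tau_phi), float(tau_mod)
    return tau_phi, tau_mod


def bound_fraction_distance(
    field: PhasorField, free_point: tuple[float, float] | None = None, free_tau: float = 0.4e-9
) -> np.ndarray:
    """Euclidean distance of each pixel's phasor from the free-species point.

    d = sqrt((g - g1)^2 + (s - s1)^2).  Reported as a *distance*, not a
    fraction: without an assigned bound endpoint the normalization is
    undefined and distances must not be read as fractions.  The free point
    defaults to the monoexponential phasor of 0.4 ns (free NAD(P)H) at the
    field's frequency.  Requires a calibrated field — distances in an
    uncalibrated (instrument-rotated) phasor space are meaningless.
    """
    if not field.calibrated:
        raise CalibrationError("bound-fraction distance requires a calibrated phasor field")
    if free_point is None:
        free_point = monoexp_phasor(free_tau, field.omega)
    g1, s1 = free_point
    return np.hypot(field.g - g1, field.s - s1)


def bound_fraction_normalized(
    field: PhasorField, endpoints: PhasorEndpoints
) -> tuple[np.ndarray, int]:
    """Normalized bound fraction along the free-bound chord.

    f2 = |P - P_free| / |P_bound - P_free|, clipped to [0, 1].  Returns
    the f2 map and the number of masked pixels that fell outside the
    segment before clipping.
    """
    if not field.calibrated:
        raise CalibrationError("normalized bound fraction requires a calibrated phasor field")
    d = bound_fraction_distance(field, free_point=endpoints.free_point)
    sep = endpoints.separation
    f2 = d / sep
    valid = field.mask & np.isfinite(f2)
    n_outside = int(np.sum((f2[valid] < 0) | (f2[valid] > 1)))
    return np.clip(f2, 0.0, 1.0), n_outside


def fit_phasor_line(
    field: PhasorField,
    mask: np.ndarray | None = None,
    intensity_weighted: bool = True,
    min_pixels: int = 10,
    eigen_ratio_floor: float = 5.0,
) -> PhasorEndpoints:
    """Endpoints from a total-least-squares line through the phasor cloud.

    Fits the principal axis of the (optionally intensity-weighted) (g, s)
    cloud and intersects it with the universal circle s^2 = g(1 - g); the
    intersection with larger g is the free (shorter-lifetime) endpoint.
    A near-isotropic cloud (principal/secondary eigenvalue ratio below
    *eigen_ratio_floor*) has no meaningful axis and raises ValueError.
    """
    g, s, w = field.masked_arrays()
    if mask is not None:
        mm = (field.mask & mask & np.isfinite(field.g))
        g, s, w = field.g[mm], field.s[mm], field.intensity[mm]
    if g.size < min_pixels:
        raise ValueError(f"need at least {min_pixels} pixels to fit the phasor cloud, got {g.size}")
    weights = w if intensity_weighted else np.ones_like(w)
    weights = weights / weights.sum()
    mu = np.array([np.sum(weights * g), np.sum(weights * s)])
    dg, ds = g - mu[0], s - mu[1]
    cov = np.array(
        [
            [np.sum(weights * dg * dg), np.sum(weights * dg * ds)],
            [np.sum(weights * dg * ds), np.sum(weights * ds * ds)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0 and evals[1] / max(evals[0], 1e-300) < eigen_ratio_floor:
        raise ValueError(
            f"degenerate phasor cloud: eigenvalue ratio {evals[1] / evals[0]:.2f} "
            f"below floor {eigen_ratio_floor}"
        )
    d = evecs[:, 1]  # principal axis
    # intersect p = mu + t*d with s^2 = g(1-g)  =>  quadratic in t
    a = d[0] ** 2 + d[1] ** 2
    b = 2.0 * (mu[0] * d[0] + mu[1] * d[1]) - d[0]
    c = mu[0] ** 2 + mu[1] ** 2 - mu[0]
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(
            f"phasor-cloud line does not intersect the universal circle "
            f"(discriminant {disc:.3e}); cloud centroid ({mu[0]:.3f}, {mu[1]:.3f})"
        )
    t1 = (-b - np.sqrt(disc)) / (2 * a)
    t2 = (-b + np.sqrt(disc)) / (2 * a)
    p1 = mu + t1 * d
    p2 = mu + t2 * d
    free, bound = (p1, p2) if p1[0] > p2[0] else (p2, p1)
    return PhasorEndpoints(
        free_point=(float(free[0]), float(free[1])),
        bound_point=(float(bound[0]), float(bound[1])),
        provenance="cloud-fit",
    )


def median_filter_phasor(field: PhasorField, kernel: int = 3) -> PhasorField:
    """Median-filter g and s independently; intensity is untouched.

    Standard SNR enhancement for low-photon phasors: the median over a
    small window suppresses shot-noise scatter with little loss of spatial
    resolution.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be an odd positive integer, got {kernel}")
    if kernel == 1:
        return field
    g = field.g.copy()
    s = field.s.copy()
    m = field.mask & np.isfinite(g)
    # fill invalid pixels with the masked median so the filter window
    # never ingests NaN, then restore the mask
    if m.any():
        gf = np.where(m, g, np.median(g[m]))
        sf = np.where(m, s, np.median(s[m]))
        g_new = ndimage.median_filter(gf, size=kernel)
        s_new = ndimage.median_filter(sf, size=kernel)
        g = np.where(m, g_new, g)
        s = np.where(m, s_new, s)
    else:
        warnings.warn("median_filter_phasor: empty mask, field unchanged", stacklevel=2)
    return replace(field, g=g, s=s)
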