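"""Synthetic data generation for the full imaging pipeline.

Everything the analysis consumes can be generated here with known ground
truth: Gaussian IRFs, single-decay TCSPC histograms, cell-like TCSPC image
stacks, and NAD(P)H/FAD intensity channel pairs with matching 1 mM
solution-standard frames.

Photon statistics follow the counting physics of TCSPC: the expected
histogram shape is the period-wrapped, IRF-convolved biexponential, and
observed counts are independent Poisson draws per bin (equivalent to a
multinomial over bins conditioned on a Poisson total).  All generators are
pure functions of their configuration and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ChannelPair, DecayStack, SolutionFrame
from .decay_model import (
    BiexpParams,
    IRFCurve,
    TimeGrid,
    bin_integrated_biexp,
    convolve_with_irf,
)

__all__ = [
    "CellScene",
    "make_gaussian_irf",
    "expected_decay_shape",
    "simulate_decay",
    "make_cell_scene",
    "simulate_tcspc_image",
    "simulate_channel_pair",
    "FLUORESCEIN_LIFETIME_S",
    "FREE_NADH_LIFETIME_S",
]

# fluorescein in ethanol (pH 6.5), the usual phasor calibration standard
FLUORESCEIN_LIFETIME_S = 3.05e-9
# free NAD(P)H in solution, the usual assigned free-species lifetime
FREE_NADH_LIFETIME_S = 0.4e-9


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CellScene:
    """Ground truth for a synthetic field of view.

    ``label_mask`` codes: 0 background, 1..N cell cytoplasm, negative codes
    for excluded sub-regions (nucleus of cell *i* is labeled ``-i``).  Each
    positive label carries the decay parameters of its NAD(P)H
    fluorescence, an expected photon budget per pixel, and
    concentration-proxy levels for the two intensity channels.
    """

    label_mask: np.ndarray
    decay_params: dict[int, BiexpParams]
    photon_budget: dict[int, float]
    nadph_level: dict[int, float] = field(default_factory=dict)
    fad_level: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.label_mask)
        if mask.ndim != 2:
            raise ValueError("label_mask must be 2-D")
        if not np.all(np.isfinite(mask)):
            raise ValueError("labels must be finite")
        self.label_mask = mask.astype(np.int32)
        for lab in self.positive_labels:
            if lab not in self.decay_params:
                raise ValueError(f"region {lab} has no ground-truth decay parameters")
            if self.photon_budget.get(lab, 0.0) < 0:
                raise ValueError(f"region {lab} has a negative photon budget")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape

    @property
    def positive_labels(self) -> list[int]:
        labs = np.unique(self.label_mask)
        return [int(l) for l in labs if l > 0]


def make_gaussian_irf(grid: TimeGrid, fwhm: float, center: float) -> IRFCurve:
    """Gaussian IRF histogram on *grid*, bin-integrated and unit-sum.

    The histogram value in each bin is the integral of a Gaussian of the
    requested full width at half maximum (sigma = fwhm / 2.3548) centered
    at *center* seconds, wrapped over the laser period so no weight is
    lost at the window edges.  A requested fwhm below half a bin cannot be
    resolved on the grid; a warning is raised and an impulse at the
    nearest bin is returned.
    """
    if fwhm <= 0 or center < 0 or center > grid.period:
        raise ValueError("fwhm must be > 0 and center within the laser period")
    if fwhm < grid.bin_width / 2:
        warnings.warn(
            f"IRF fwhm {fwhm:.3e} s is below half a bin ({grid.bin_width:.3e} s); "
            "returning an impulse",
            stacklevel=2,
        )
        idx = min(int(center / grid.bin_width), grid.n_bins - 1)
        return IRFCurve.impulse(grid, bin_index=idx)
    from scipy.special import erf

    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    edges = grid.bin_edges
    values = np.zeros(grid.n_bins)
    # wrap tails over neighboring periods (±3 is ample for fwhm << T)
    for k in range(-3, 4):
        z = (edges - center + k * grid.period) / (sigma * np.sqrt(2.0))
        cdf = 0.5 * (1.0 + erf(z))
        values += cdf[1:] - cdf[:-1]
    values /= values.sum()
    return IRFCurve(values=values, grid=grid, fwhm=fwhm)


def expected_decay_shape(params: BiexpParams, grid: TimeGrid, irf: IRFCurve | None) -> np.ndarray:
    """Unit-sum expected histogram shape: wrapped biexponential (x) IRF."""
    shape = bin_integrated_biexp(params, grid, periodic=True)
    if irf is not None:
        shape = convolve_with_irf(shape, irf, periodic=True)
    total = shape.sum()
    if total <= 0:
        raise ValueError("expected decay shape has zero total")
    return shape / total


def simulate_decay(
    params: BiexpParams,
    grid: TimeGrid,
    irf: IRFCurve | None,
    n_photons: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one TCSPC histogram with *n_photons* expected total counts.

    Counts per bin are independent Poisson with mean proportional to the
    IRF-convolved, period-wrapped decay shape.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    if n_photons == 0:
        return np.zeros(grid.n_bins, dtype=np.int64)
    rng = _rng(seed)
    mean = expected_decay_shape(params, grid, irf) * n_photons
    return rng.poisson(mean).astype(np.int64)


def make_cell_scene(
    shape: tuple[int, int] = (64, 64),
    n_cells: int = 4,
    decay_params: dict[int, BiexpParams] | None = None,
    photons_per_pixel: float = 5000.0,
    nadph_level: float = 1.0,
    fad_level: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> CellScene:
    """Random field of elliptical cells with elliptical nuclear holes.

    Each cell gets cytoplasm label ``i`` and nucleus label ``-i``.  If
    *decay_params* is omitted, every cell shares a typical in-vitro
    NAD(P)H decay (tau1 = 0.54 ns free, tau2 = 2.81 ns bound, amplitude
    ratio 2640:1180).
    """
    rng = _rng(seed)
    ny, nx = shape
    mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for i in range(1, n_cells + 1):
        cy, cx = rng.uniform(0.15, 0.85) * ny, rng.uniform(0.15, 0.85) * nx
        ry, rx = rng.uniform(0.10, 0.18) * ny, rng.uniform(0.10, 0.18) * nx
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        u = ((yy - cy) * c + (xx - cx) * s) / ry
        v = (-(yy - cy) * s + (xx - cx) * c) / rx
        cell = u * u + v * v <= 1.0
        # nucleus: concentric ellipse at ~45% of the cell's linear size
        nucleus = (u / 0.45) ** 2 + (v / 0.45) ** 2 <= 1.0
        mask[cell & (mask == 0)] = i
        mask[nucleus & (mask == i)] = -i
    labels = [int(l) for l in np.unique(mask) if l > 0]
    if decay_params is None:
        default = BiexpParams(tau1=0.54e-9, tau2=2.81e-9, alpha1=2640.0, alpha2=1180.0)
        decay_params = {l: default for l in labels}
    return CellScene(
        label_mask=mask,
        decay_params={l: decay_params[l] for l in labels},
        photon_budget={l: photons_per_pixel for l in labels},
        nadph_level={l: nadph_level for l in labels},
        fad_level={l: fad_level for l in labels},
    )


def simulate_tcspc_image(
    scene: CellScene,
    grid: TimeGrid,
    irf: IRFCurve | None,
    seed: int | np.random.Generator | None = None,
    dark_counts_per_pixel: float = 0.0,
) -> DecayStack:
    """Simulate a full TCSPC image stack from a cell scene.

    Pixels inside each cytoplasm region draw from that region's decay
    shape at its photon budget; background and excluded (negative-label)
    pixels contain only uniform-in-time dark counts.
    """
    rng = _rng(seed)
    ny, nx = scene.shape
    mean = np.zeros((grid.n_bins, ny, nx))
    for lab in scene.positive_labels:
        budget = scene.photon_budget[lab]
        if budget == 0:
            continue
        shape_t = expected_decay_shape(scene.decay_params[lab], grid, irf) * budget
        mean[:, scene.label_mask == lab] = shape_t[:, None]
    if dark_counts_per_pixel > 0:
        mean += dark_counts_per_pixel / grid.n_bins
    counts = rng.poisson(mean).astype(np.int64)
    return DecayStack(counts=counts, grid=grid)


def simulate_channel_pair(
    scene: CellScene,
    gains: tuple[float, float] = (1.0, 1.0),
    base_counts: float = 1000.0,
    standard_shape: tuple[int, int] | None = None,
    seed: int | np.random.Generator | None = None,
    metadata: dict | None = None,
) -> tuple[ChannelPair, SolutionFrame, SolutionFrame]:
    """Simulate a registered NAD(P)H/FAD intensity pair plus solution standards.

    Per-pixel expected counts in a region are
    ``level[region] * gain[channel] * base_counts``; the 1 mM solution
    standards are uniform frames at ``gain[channel] * base_counts``
    (concentration proxy 1.0), generated with the same gains so that
    solution-standard calibration cancels the gains exactly in
    expectation.  All images carry Poisson noise.
    """
    g_nadph, g_fad = gains
    if g_nadph <= 0 or g_fad <= 0:
        raise ValueError("gains must be > 0")
    rng = _rng(seed)
    ny, nx = scene.shape
    mean_n = np.zeros((ny, nx))
    mean_f = np.zeros((ny, nx))
    for lab in scene.positive_labels:
        sel = scene.label_mask == lab
        mean_n[sel] = scene.nadph_level.get(lab, 1.0) * g_nadph * base_counts
        mean_f[sel] = scene.fad_level.get(lab, 1.0) * g_fad * base_counts
    nadph = rng.poisson(mean_n).astype(float)
    fad = rng.poisson(mean_f).astype(float)
    meta = dict(metadata or {})
    meta_n = {"excitation_nm": 750.0, "emission_band_nm": (415.0, 485.0), **meta}
    meta_f = {"excitation_nm": 750.0, "emission_band_nm": (535.0, 605.0), **meta}
    pair = ChannelPair(
        nadph_image=nadph,
        fad_image=fad,
        nadph_metadata={**meta_n, "gain": g_nadph},
        fad_metadata={**meta_f, "gain": g_fad},
        label_mask=scene.label_mask.copy(),
    )
    sshape = standard_shape or (ny, nx)
    nadh_std = SolutionFrame(
        channel="NADH",
        intensity_image=rng.poisson(np.full(sshape, g_nadph * base_counts)).astype(float),
        metadata={**meta_n, "gain": g_nadph},
    )
    fad_std = SolutionFrame(
        channel="FAD",
        intensity_image=rng.poisson(np.full(sshape, g_fad * base_counts)).astype(float),
        metadata={**meta_f, "gain": g_fad},
    )
    return pair, nadh_std, fad_std
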