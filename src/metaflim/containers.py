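"""Shared data containers for the imaging pipeline.

These are thin, validated wrappers around numpy arrays plus the metadata
the analysis needs: a TCSPC decay cube with its time base, a uniform
calibration-solution frame, and a registered NAD(P)H/FAD intensity pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .decay_model import GridMismatchError, InvalidParameterError, TimeGrid

__all__ = ["DecayStack", "SolutionFrame", "ChannelPair"]


@dataclass
class DecayStack:
    """3-D photon-count histogram cube, time x y x x, with its time base.

    ``counts[t, i, j]`` is the number of photons recorded in time bin ``t``
    at pixel ``(i, j)``.
    """

    counts: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise InvalidParameterError(f"counts must be 3-D (time, y, x), got shape {counts.shape}")
        if counts.shape[0] != self.grid.n_bins:
            raise GridMismatchError(
                f"stack has {counts.shape[0]} time pages but the grid has {self.grid.n_bins} bins"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise InvalidParameterError("photon counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if counts.min() < 0:
            raise InvalidParameterError("photon counts must be nonnegative")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def total_image(self) -> np.ndarray:
        """Per-pixel total photon counts (sum over time)."""
        return self.counts.sum(axis=0)

    def pixel_decay(self, i: int, j: int) -> np.ndarray:
        return self.counts[:, i, j]


@dataclass
class SolutionFrame:
    """Intensity image of a uniform fluorophore solution standard.

    A 1 mM NADH or FAD solution imaged under the same acquisition settings
    as the sample; its spatial mean intensity normalizes the matching
    sample channel.
    """

    channel: Literal["NADH", "FAD"]
    intensity_image: np.ndarray
    concentration_molar: float = 1e-3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity_image, dtype=float)
        if img.ndim != 2:
            raise InvalidParameterError(f"solution frame must be 2-D, got shape {img.shape}")
        if img.min() < 0:
            raise InvalidParameterError("intensities must be nonnegative")
        if self.channel not in ("NADH", "FAD"):
            raise InvalidParameterError(f"channel must be 'NADH' or 'FAD', got {self.channel!r}")
        self.intensity_image = img

    @property
    def mean_intensity(self) -> float:
        return float(self.intensity_image.mean())


@dataclass
class ChannelPair:
    """Registered NAD(P)H and FAD intensity images with acquisition metadata."""

    nadph_image: np.ndarray
    fad_image: np.ndarray
    nadph_metadata: dict = field(default_factory=dict)
    fad_metadata: dict = field(default_factory=dict)
    label_mask: np.ndarray | None = None
    calibrated: bool = False
    calibration_provenance: dict | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.nadph_image, dtype=float)
        b = np.asarray(self.fad_image, dtype=float)
        if a.ndim != 2 or b.ndim != 2:
            raise InvalidParameterError("channel images must be 2-D")
        if a.shape != b.shape:
            raise InvalidParameterError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if a.min() < 0 or b.min() < 0:
            raise InvalidParameterError("intensities must be nonnegative")
        if self.label_mask is not None:
            m = np.asarray(self.label_mask)
            if m.shape != a.shape:
                raise InvalidParameterError("label mask shape must match the channel images")
            self.label_mask = m.astype(np.int32)
        self.nadph_image = a
        self.fad_image = b

    @property
    def shape(self) -> tuple[int, int]:
        return self.nadph_image.shape

    def missing_metadata(self, required: tuple[str, ...] = ("excitation_nm", "emission_band_nm", "power_mw", "dwell_time_s")) -> dict:
        """Names of required acquisition-metadata fields absent per channel (QC input)."""
        return {
            "nadph": [k for k in required if k not in self.nadph_metadata],
            "fad": [k for k in required if k not in self.fad_metadata],
        }
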