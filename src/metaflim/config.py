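"""Validated run configuration.

Every analysis parameter that affects numbers lives here, is
schema-validated (unknown keys rejected), and is echoed into output
manifests — no silent defaults.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_bins: int = Field(256, ge=1)
    bin_width_s: float = Field(12.5e-9 / 256, gt=0)
    rep_rate_hz: float = Field(80e6, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration for a pipeline run."""

    model_config = ConfigDict(extra="forbid")

    grid: GridConfig = GridConfig()
    seed: int = 0

    # lifetime fitting
    fit_method: str = "wls"
    bin_size: int = 3
    min_photons: int = 200
    fix_background: float | None = None

    # phasor
    harmonic: int = 1
    free_tau_s: float = 0.4e-9
    calibration_lifetime_s: float = 3.05e-9
    median_kernel: int = 3

    # redox
    orr_convention: str = "oxidized"
    prefilter: int = 3
    postfilter: int = 5
    min_intensity: float = 0.0

    # checklist attestations (human-only items)
    attestations: dict[str, str] = {}

    def to_grid(self):
        from .decay_model import TimeGrid

        return TimeGrid(self.grid.n_bins, self.grid.bin_width_s, self.grid.rep_rate_hz)
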