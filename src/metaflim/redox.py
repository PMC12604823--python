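"""Optical redox ratio (ORR) computation from NAD(P)H and FAD intensities.

Two normalized conventions are supported and always labeled explicitly:

* ``oxidized``: ORR = FAD / (NAD(P)H + FAD)
* ``reduced``:  ORR = NAD(P)H / (NAD(P)H + FAD)

The two are complements (oxidized + reduced = 1 pixelwise) but move in
opposite directions with metabolism, so every result carries its
convention string.  Channel intensities may be calibrated against 1 mM
NADH / FAD solution standards imaged under the same settings: dividing
each channel by the mean intensity of its matching standard cancels
instrument gain, power, and collection-efficiency differences, making
ORR values comparable across acquisition conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ChannelPair, SolutionFrame

__all__ = [
    "ORRResult",
    "calibrate_channels",
    "compute_orr",
    "aggregate_orr",
    "interpret_metric_change",
    "PATHWAY_TABLE",
]

_CONVENTIONS = ("oxidized", "reduced")

_CALIB_MATCH_KEYS = ("excitation_nm", "emission_band_nm", "power_mw", "dwell_time_s", "gain")


def calibrate_channels(
    pair: ChannelPair, nadh_standard: SolutionFrame, fad_standard: SolutionFrame
) -> ChannelPair:
    """Normalize each channel by the mean intensity of its solution standard.

    Metadata mismatches between sample and standard (excitation, gain, ...)
    are surfaced as warnings and recorded in the calibration provenance,
    but are not fatal — the caller may have a legitimate reason.
    """
    if nadh_standard.channel != "NADH" or fad_standard.channel != "FAD":
        raise ValueError("standards must be the NADH and FAD solution frames, in that order")
    mean_n = nadh_standard.mean_intensity
    mean_f = fad_standard.mean_intensity
    if mean_n <= 0 or mean_f <= 0:
        raise ValueError("solution standard has zero mean intensity; cannot calibrate")
    mismatches = []
    for key in _CALIB_MATCH_KEYS:
        for label, meta, std in (
            ("NADH", pair.nadph_metadata, nadh_standard.metadata),
            ("FAD", pair.fad_metadata, fad_standard.metadata),
        ):
            if key in meta and key in std and meta[key] != std[key]:
                mismatches.append(f"{label}:{key} sample={meta[key]} standard={std[key]}")
    if mismatches:
        warnings.warn(
            "sample/standard acquisition metadata mismatch: " + "; ".join(mismatches),
            stacklevel=2,
        )
    provenance = {
        "nadh_standard_mean": mean_n,
        "fad_standard_mean": mean_f,
        "nadh_standard_concentration_molar": nadh_standard.concentration_molar,
        "fad_standard_concentration_molar": fad_standard.concentration_molar,
        "metadata_mismatches": mismatches,
    }
    return replace(
        pair,
        nadph_image=pair.nadph_image / mean_n,
        fad_image=pair.fad_image / mean_f,
        calibrated=True,
        calibration_provenance=provenance,
    )


@dataclass
class ORRResult:
    """Pixelwise ORR image plus the configuration that produced it."""

    orr_image: np.ndarray  # NaN where masked out
    mask: np.ndarray
    convention: str
    calibrated: bool
    config: dict = field(default_factory=dict)
    n_masked_out: int = 0
    label_mask: np.ndarray | None = None
    calibration_provenance: dict | None = None

    def complement(self) -> "ORRResult":
        """The same result under the opposite convention (1 - ORR)."""
        other = "reduced" if self.convention == "oxidized" else "oxidized"
        return replace(self, orr_image=np.where(self.mask, 1.0 - self.orr_image, np.nan), convention=other)


def _sum_filter(img: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return img
    return ndimage.uniform_filter(img, size=size, mode="constant", cval=0.0) * (size * size)


def compute_orr(
    pair: ChannelPair,
    convention: str = "oxidized",
    prefilter: int = 3,
    postfilter: int = 5,
    min_intensity: float = 0.0,
    threshold_channel: str = "nadph",
) -> ORRResult:
    """Pixelwise optical redox ratio.

    Raw channels are summed with a *prefilter* x *prefilter* spatial
    filter before the ratio, and the ORR image is median filtered with a
    *postfilter* kernel to remove outliers (the conventional 3x3 / 5x5
    defaults).  Pixels below *min_intensity* in the thresholding channel
    (NAD(P)H by default) or with zero total signal are masked out, never
    set to 0 or NaN-divided.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    if threshold_channel not in ("nadph", "fad"):
        raise ValueError("threshold_channel must be 'nadph' or 'fad'")
    for name, k in (("prefilter", prefilter), ("postfilter", postfilter)):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"{name} must be an odd positive integer, got {k}")
    n = _sum_filter(pair.nadph_image, prefilter)
    f = _sum_filter(pair.fad_image, prefilter)
    total = n + f
    thr_img = n if threshold_channel == "nadph" else f
    mask = (total > 0) & (thr_img >= min_intensity)
    if pair.label_mask is not None:
        # negative codes mark excluded sub-regions (nuclei, lipid droplets)
        mask &= pair.label_mask >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        # the reduced form is computed as 1 - oxidized so the complement
        # identity oxidized + reduced = 1 holds bit-exactly per pixel
        orr = np.where(mask, f / np.where(mask, total, 1.0), np.nan)
        if convention == "reduced":
            orr = np.where(mask, 1.0 - orr, np.nan)
    if postfilter > 1 and mask.any():
        filled = np.where(mask, orr, np.nanmedian(orr[mask]))
        orr_f = ndimage.median_filter(filled, size=postfilter)
        orr = np.where(mask, orr_f, np.nan)
    return ORRResult(
        orr_image=orr,
        mask=mask,
        convention=convention,
        calibrated=pair.calibrated,
        config={
            "prefilter": prefilter,
            "postfilter": postfilter,
            "min_intensity": min_intensity,
            "threshold_channel": threshold_channel,
        },
        n_masked_out=int((~mask).sum()),
        label_mask=pair.label_mask,
        calibration_provenance=pair.calibration_provenance,
    )


def aggregate_orr(
    pair: ChannelPair,
    result: ORRResult,
    label_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region ORR aggregates, both conventions of averaging side by side.

    * ``ratio_of_means``: the ORR formula applied to region-mean channel
      intensities — better SNR, robust to dim pixels.
    * ``mean_of_ratios``: the average of pixelwise ORR values — preserves
      the heterogeneity weighting of every pixel.

    Rows are labeled regions (positive labels only); empty or fully
    masked-out regions are absent, with a warning.
    """
    labels = label_mask if label_mask is not None else result.label_mask
    if labels is None:
        labels = np.ones(result.orr_image.shape, dtype=np.int32)
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        sel = (labels == lab) & result.mask
        if not sel.any():
            warnings.warn(f"region {lab} has no pixels passing the mask; omitted", stacklevel=2)
            continue
        mean_n = pair.nadph_image[sel].mean()
        mean_f = pair.fad_image[sel].mean()
        if result.convention == "oxidized":
            rom = mean_f / (mean_n + mean_f)
        else:
            rom = mean_n / (mean_n + mean_f)
        rows.append(
            {
                "region_id": int(lab),
                "n_pixels": int(sel.sum()),
                "orr_ratio_of_means": float(rom),
                "orr_mean_of_ratios": float(np.nanmean(result.orr_image[sel])),
                "convention": result.convention,
                "calibrated": result.calibrated,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "n_pixels", "orr_ratio_of_means", "orr_mean_of_ratios", "convention", "calibrated"])


# Typical directional responses of the optical metrics to increased
# activity of each pathway.  These are population-level tendencies that
# can be transient and cell/tissue/environment dependent; the annotations
# are interpretive aids, never a claim of mechanism.
_CAVEAT = "can be transient and cell/tissue/environment dependent"

PATHWAY_TABLE: list[dict] = [
    {"pathway": "↑ ETC activity", "orr_oxidized": "up", "orr_reduced": "down", "bound_fraction_or_tau_m": "up"},
    {"pathway": "↑ glutaminolysis", "orr_oxidized": "up", "orr_reduced": "down", "bound_fraction_or_tau_m": "up"},
    {"pathway": "↑ ETC uncoupling", "orr_oxidized": "up", "orr_reduced": "down", "bound_fraction_or_tau_m": "up_or_down"},
    {"pathway": "↑ glycolysis", "orr_oxidized": "down", "orr_reduced": "up", "bound_fraction_or_tau_m": "down"},
    {"pathway": "↑ fatty acid oxidation", "orr_oxidized": "down", "orr_reduced": "up", "bound_fraction_or_tau_m": "down"},
    {"pathway": "↑ fatty acid synthesis", "orr_oxidized": "down", "orr_reduced": "up", "bound_fraction_or_tau_m": "up"},
    {"pathway": "↑ TCA relative to ETC activity", "orr_oxidized": "down", "orr_reduced": "up", "bound_fraction_or_tau_m": "down"},
]

_METRICS = ("orr_oxidized", "orr_reduced", "bound_fraction_or_tau_m")


def interpret_metric_change(metric: str, direction: str) -> list[dict]:
    """Pathway annotations consistent with an observed metric change.

    Returns the rows of the pathway table whose expected direction for
    *metric* matches *direction* ("up" or "down"); entries marked
    "up_or_down" match either.  Each annotation carries the standing
    caveat that these changes {caveat}.
    """.format(caveat=_CAVEAT)
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    out = []
    for row in PATHWAY_TABLE:
        expected = row[metric]
        if expected == direction or expected == "up_or_down":
            out.append({"pathway": row["pathway"], "expected": expected, "caveat": _CAVEAT})
    return out
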