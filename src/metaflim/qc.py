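"""Quality control and consensus reporting checklists.

Turns the community reporting recommendations for intensity-based redox
and FLIM-based metabolic measurements into machine-checkable QC: photon
statistics, the pile-up count-rate bound, Poisson SNR, and a structured
checklist in which every recommendation is either evaluated automatically
from the run's metadata/configuration or emitted as ``missing`` until a
human attests to it.  QC never blocks analysis; it only reports.

The item inventory ships as data (``data/checklist_items.json``) so the
wording can evolve without touching logic; each item has a stable
``item_id``, its source section, and either an auto predicate or an
attestation key.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .containers import DecayStack

__all__ = [
    "QCReport",
    "ChecklistItem",
    "pileup_check",
    "photon_stats",
    "snr_estimate",
    "signal_to_background",
    "build_checklist",
    "checklist_inventory",
]

#: conservative (lower) and permissive (upper) pile-up bounds: maximum
#: acceptable detected-photon rate as a fraction of the excitation rate
PILEUP_BOUNDS = (0.05, 0.10)


def _load_items() -> list[dict]:
    with resources.files("metaflim.data").joinpath("checklist_items.json").open() as fh:
        return json.load(fh)["items"]


def checklist_inventory(mode: str | None = None) -> list[dict]:
    """The fixed enumeration of checklist items, optionally per mode."""
    items = _load_items()
    if mode is None:
        return items
    if mode not in ("intensity", "flim"):
        raise ValueError(f"mode must be 'intensity' or 'flim', got {mode!r}")
    return [it for it in items if it["mode"] == mode]


def pileup_check(
    count_rate: float, rep_rate: float, max_fraction: float = PILEUP_BOUNDS[0]
) -> dict:
    """Check the detected photon rate against the pile-up bound.

    Pile-up biases lifetimes short when the chance of more than one photon
    per excitation pulse becomes non-negligible; the accepted bound is a
    count rate of 5% (conservative) to 10% of the pulse rate.  Returns the
    ratio, the pass flag at *max_fraction* (default 5%), and the verdicts
    at both conventional bounds.
    """
    if count_rate < 0 or rep_rate <= 0:
        raise ValueError("count_rate must be >= 0 and rep_rate > 0")
    ratio = count_rate / rep_rate
    return {
        "count_rate_hz": count_rate,
        "rep_rate_hz": rep_rate,
        "ratio": ratio,
        "max_fraction": max_fraction,
        "passed": bool(ratio <= max_fraction),
        "passed_at_5pct": bool(ratio <= PILEUP_BOUNDS[0]),
        "passed_at_10pct": bool(ratio <= PILEUP_BOUNDS[1]),
    }


def photon_stats(
    stack: DecayStack,
    mask: np.ndarray | None = None,
    binned_stack: DecayStack | None = None,
) -> dict:
    """Per-decay photon-count statistics, pre- and post-binning.

    Reports min/mean/median and quartiles of the per-pixel totals over the
    mask.  An empty mask yields a record with ``status='missing'`` rather
    than an error, so QC reporting never crashes.
    """
    total = stack.total_image()
    if mask is None:
        mask = total > 0
    if not mask.any():
        return {"status": "missing", "detail": "empty mask: no decays to summarize"}

    def summarize(tot: np.ndarray) -> dict:
        v = tot[mask].astype(float)
        return {
            "min": float(v.min()),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "max": float(v.max()),
            "n_decays": int(v.size),
        }

    out = {"status": "ok", "raw": summarize(total)}
    if binned_stack is not None:
        out["binned"] = summarize(binned_stack.total_image())
    return out


def snr_estimate(photon_count: float) -> float:
    """Poisson-limited SNR of a photon-counting measurement: sqrt(N)."""
    if photon_count < 0:
        raise ValueError("photon count must be >= 0")
    return float(np.sqrt(photon_count))


def signal_to_background(
    image: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray | None = None, label_mask: np.ndarray | None = None
) -> float | None:
    """SBR = mean(signal pixels) / mean(background pixels).

    The background region defaults to label-0 pixels of *label_mask*.
    Returns None when no background region is available.
    """
    if background_mask is None:
        if label_mask is None:
            return None
        background_mask = np.asarray(label_mask) == 0
    if not background_mask.any() or not signal_mask.any():
        return None
    bg = float(np.asarray(image)[background_mask].mean())
    if bg <= 0:
        return None
    return float(np.asarray(image)[signal_mask].mean()) / bg


@dataclass
class ChecklistItem:
    item_id: str
    source_section: str
    kind: str
    status: str  # pass | fail | missing | not_applicable
    detail: str
    text: str


@dataclass
class QCReport:
    """Structured QC record: photon statistics, pile-up, SNR, checklist."""

    mode: str
    checklist: list[ChecklistItem]
    photon_statistics: dict = field(default_factory=dict)
    pileup: dict | None = None
    snr: dict | None = None
    analysis_defaults: dict = field(default_factory=dict)
    schema_version: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        d = dict(d)
        d["checklist"] = [ChecklistItem(**it) for it in d["checklist"]]
        return cls(**d)

    def render_text(self) -> str:
        lines = [f"QC report (mode: {self.mode})", "=" * 50]
        if self.pileup:
            verdict = "PASS" if self.pileup["passed"] else "FAIL"
            lines.append(
                f"pile-up: {verdict} — count rate {self.pileup['count_rate_hz']:.3g} Hz is "
                f"{self.pileup['ratio']:.3%} of the {self.pileup['rep_rate_hz']:.3g} Hz pulse rate "
                f"(bound {self.pileup['max_fraction']:.0%})"
            )
        ps = self.photon_statistics
        if ps.get("status") == "ok":
            for phase in ("raw", "binned"):
                if phase in ps:
                    s = ps[phase]
                    lines.append(
                        f"photons/decay ({phase}): min {s['min']:.0f}, mean {s['mean']:.0f}, "
                        f"median {s['median']:.0f}"
                    )
        if self.snr:
            lines.append(f"SNR estimate (sqrt N at median counts): {self.snr.get('snr_median', float('nan')):.1f}")
        lines.append("-" * 50)
        for it in self.checklist:
            lines.append(f"[{it.status:>7s}] {it.item_id} ({it.source_section}): {it.detail}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# predicates: each inspects run metadata + analysis configuration and
# returns (status, detail)

_ACQ_KEYS = ("power_mw", "excitation_nm", "emission_band_nm", "detector_gain", "pixel_size_um", "dwell_time_s")


def _have(meta: dict, keys) -> list[str]:
    return [k for k in keys if meta.get(k) is None]


def _p_acquisition_metadata_complete(meta, cfg):
    missing = _have(meta, _ACQ_KEYS)
    if missing:
        return "fail", f"missing acquisition metadata fields: {', '.join(missing)}"
    return "pass", "all acquisition metadata fields recorded"


def _p_power_normalization_recorded(meta, cfg):
    if meta.get("power_mw") is None:
        return "fail", "incident power not recorded; cannot normalize by power"
    if cfg.get("power_normalized") or cfg.get("solution_standards_used"):
        return "pass", "signals normalized for illumination/instrument settings"
    return "fail", "no power/instrument normalization recorded in the analysis config"


def _p_same_day_controls(meta, cfg):
    flag = meta.get("controls_same_day")
    if flag is None:
        return "missing", "same-day control acquisition not attested"
    return ("pass", "controls acquired same day") if flag else ("fail", "controls not acquired same day")


def _p_normalized_orr_form(meta, cfg):
    conv = cfg.get("orr_convention")
    if conv in ("oxidized", "reduced"):
        return "pass", f"normalized ORR form in use ({conv} convention, bounded in [0,1])"
    return "fail", "no normalized ORR convention configured"


def _p_orr_definition_stated(meta, cfg):
    if cfg.get("orr_convention") in ("oxidized", "reduced"):
        return "pass", "ORR definition fixed in configuration and echoed into all outputs"
    return "fail", "ORR definition not configured"


def _p_orr_convention_stamped(meta, cfg):
    if cfg.get("orr_convention_stamped", cfg.get("orr_convention") is not None):
        return "pass", "convention string stamped on result objects and tables"
    return "fail", "outputs are not stamped with the ORR convention"


def _p_solution_standard_calibration(meta, cfg):
    if cfg.get("solution_standards_used"):
        return "pass", "channels normalized by 1 mM NADH/FAD solution-standard means"
    return "fail", "no solution-standard calibration applied"


def _p_segmentation_applied(meta, cfg):
    if cfg.get("label_mask_used"):
        return "pass", "label mask applied; negative-coded regions (nuclei etc.) excluded"
    just = cfg.get("segmentation_omission_reason")
    if just:
        return "pass", f"segmentation omitted with justification: {just}"
    return "fail", "no segmentation mask and no justification for its absence"


def _p_snr_or_sbr_reported(meta, cfg):
    if cfg.get("snr_reported") or cfg.get("sbr_reported"):
        return "pass", "SNR/SBR values computed and included in this report"
    return "fail", "no SNR or SBR values computed"


def _p_irf_and_standard_reported(meta, cfg):
    if meta.get("irf_fwhm_s") is None:
        return "fail", "IRF not provided or FWHM not recorded"
    if meta.get("calibration_standard") is None:
        return "fail", "no fluorescence calibration standard recorded"
    detail = (
        f"IRF FWHM {meta['irf_fwhm_s'] * 1e12:.0f} ps; standard: {meta['calibration_standard']}"
    )
    if meta.get("standard_same_day") is False:
        return "fail", detail + "; standard NOT acquired same day"
    return "pass", detail


def _p_photon_counts_reported(meta, cfg):
    if cfg.get("photon_stats_available"):
        return "pass", "minimum and typical photon counts per decay included in this report"
    return "fail", "photon-count statistics not computed"


def _p_analysis_details_reported(meta, cfg):
    needed = ("min_photons", "bin_size", "fit_method_or_harmonic")
    missing = [k for k in needed if cfg.get(k) is None]
    if missing:
        return "fail", f"analysis configuration incomplete: missing {', '.join(missing)}"
    return "pass", (
        f"threshold {cfg['min_photons']} counts, {cfg['bin_size']}x{cfg['bin_size']} binning, "
        f"{cfg['fit_method_or_harmonic']}"
    )


def _p_pure_species_locations_reported(meta, cfg):
    tau = cfg.get("free_species_lifetime_s")
    if tau is None:
        return "fail", "free/bound species lifetime or phasor assumptions not recorded"
    prov = cfg.get("free_species_provenance", "assigned")
    return "pass", f"free species at {tau * 1e9:.2g} ns, {prov}"


def _p_fit_distributions_exported(meta, cfg):
    if cfg.get("fit_distributions_exported"):
        return "pass", "per-pixel fit parameters and chi-square distributions exported"
    return "fail", "fit parameter / chi-square distributions not exported"


_PREDICATES = {
    "acquisition_metadata_complete": _p_acquisition_metadata_complete,
    "power_normalization_recorded": _p_power_normalization_recorded,
    "same_day_controls": _p_same_day_controls,
    "normalized_orr_form": _p_normalized_orr_form,
    "orr_definition_stated": _p_orr_definition_stated,
    "orr_convention_stamped": _p_orr_convention_stamped,
    "solution_standard_calibration": _p_solution_standard_calibration,
    "segmentation_applied": _p_segmentation_applied,
    "snr_or_sbr_reported": _p_snr_or_sbr_reported,
    "irf_and_standard_reported": _p_irf_and_standard_reported,
    "photon_counts_reported": _p_photon_counts_reported,
    "analysis_details_reported": _p_analysis_details_reported,
    "pure_species_locations_reported": _p_pure_species_locations_reported,
    "fit_distributions_exported": _p_fit_distributions_exported,
}


def build_checklist(
    run_metadata: dict,
    analysis_config: dict,
    mode: str = "flim",
    attestations: dict | None = None,
    photon_statistics: dict | None = None,
    pileup: dict | None = None,
    snr: dict | None = None,
) -> QCReport:
    """Evaluate the reporting checklist for one analysis run.

    Auto items are evaluated by their predicate over the run metadata and
    analysis configuration.  Attestation items (orthogonal validation
    experiments and the like, which no software can verify) are
    ``missing`` unless the corresponding key in *attestations* is truthy.
    A report is always produced; no status silently defaults to pass.
    """
    attestations = attestations or {}
    items = []
    for spec_item in checklist_inventory(mode):
        if spec_item["kind"] == "attestation":
            key = spec_item["predicate"]
            if attestations.get(key):
                status, detail = "pass", f"attested: {attestations[key]}"
            else:
                status, detail = "missing", "requires human attestation (cannot be auto-checked)"
        else:
            status, detail = _PREDICATES[spec_item["predicate"]](run_metadata, analysis_config)
        items.append(
            ChecklistItem(
                item_id=spec_item["item_id"],
                source_section=spec_item["source_section"],
                kind=spec_item["kind"],
                status=status,
                detail=detail,
                text=spec_item["text"],
            )
        )
    return QCReport(
        mode=mode,
        checklist=items,
        photon_statistics=photon_statistics or {},
        pileup=pileup,
        snr=snr,
        analysis_defaults=dict(analysis_config),
    )
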