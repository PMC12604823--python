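{
  "schema_version": 1,
  "items": [
    {
      "item_id": "intensity_essential_1",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "acquisition_metadata_complete",
      "text": "Consistent light sources, incident power, excitation/emission wavelengths, objectives, detectors and gains used and reported, with pixel size and dwell time / frame rate."
    },
    {
      "item_id": "intensity_essential_2",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "power_normalization_recorded",
      "text": "NAD(P)H and FAD signals normalized by incident illumination power and other variable instrumentation settings."
    },
    {
      "item_id": "intensity_essential_3",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "same_day_controls",
      "text": "Control-group measurements acquired on the same day and reported when group differences in ORR are an outcome."
    },
    {
      "item_id": "intensity_essential_4",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "normalized_orr_form",
      "text": "A normalized redox ratio form bounded in [0, 1] is adopted."
    },
    {
      "item_id": "intensity_essential_5",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "orr_definition_stated",
      "text": "The adopted ORR definition and its relationship to oxidative phosphorylation and glycolysis is defined, acknowledging alternative definitions and other contributing pathways."
    },
    {
      "item_id": "intensity_essential_6",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "orr_convention_stamped",
      "text": "The adopted ORR definition appears prominently in all relevant figures/captions and outputs."
    },
    {
      "item_id": "intensity_essential_7",
      "source_section": "2.5",
      "mode": "intensity",
      "kind": "attestation",
      "predicate": "other_fluorophores_considered",
      "text": "Potential impacts of other fluorophores and cellular features beyond mitochondria and cytosol acknowledged and considered."
    },
    {
      "item_id": "intensity_best_practice_1",
      "source_section": "2.6",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "solution_standard_calibration",
      "text": "NAD(P)H and FAD signals normalized with corresponding NADH and FAD solution images for cross-study / cross-system comparability."
    },
    {
      "item_id": "intensity_best_practice_2",
      "source_section": "2.6",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "segmentation_applied",
      "text": "Segmentation removes nuclear, lipid-droplet, and lipofuscin-rich/lysosomal regions before ORR reporting (or the omission is justified)."
    },
    {
      "item_id": "intensity_best_practice_3",
      "source_section": "2.6",
      "mode": "intensity",
      "kind": "attestation",
      "predicate": "signal_origin_controls",
      "text": "Measurements confirm that observed autofluorescence changes are due to NAD(P)H and FAD (cofactor concentrations or positive/negative metabolic controls)."
    },
    {
      "item_id": "intensity_best_practice_4",
      "source_section": "2.6",
      "mode": "intensity",
      "kind": "auto",
      "predicate": "snr_or_sbr_reported",
      "text": "SNR or SBR (signal-to-background ratio) values of NAD(P)H and FAD images reported."
    },
    {
      "item_id": "intensity_best_practice_5",
      "source_section": "2.6",
      "mode": "intensity",
      "kind": "attestation",
      "predicate": "orthogonal_validation",
      "text": "Validation with orthogonal techniques (respirometry, mass spectrometry, omics, metabolite assays) confirms origins of observed ORR changes."
    },
    {
      "item_id": "flim_essential_1",
      "source_section": "3.7",
      "mode": "flim",
      "kind": "auto",
      "predicate": "acquisition_metadata_complete",
      "text": "Consistent light sources, incident power, wavelengths, objectives, detectors and gains used and reported, with pixel size, binning, and dwell time / frame rate."
    },
    {
      "item_id": "flim_essential_2",
      "source_section": "3.7",
      "mode": "flim",
      "kind": "auto",
      "predicate": "irf_and_standard_reported",
      "text": "System calibration ensured and IRF details (incl. FWHM) and fluorescence standard samples reported; performed same-day under matching acquisition settings."
    },
    {
      "item_id": "flim_essential_3",
      "source_section": "3.7",
      "mode": "flim",
      "kind": "auto",
      "predicate": "photon_counts_reported",
      "text": "Sufficient photon counts achieved; minimum and typical photon counts per analyzed decay reported."
    },
    {
      "item_id": "flim_essential_4",
      "source_section": "3.7",
      "mode": "flim",
      "kind": "auto",
      "predicate": "analysis_details_reported",
      "text": "Analysis details reported: thresholding, fit model, binning, filtering approaches, phasor harmonic/frequency."
    },
    {
      "item_id": "flim_essential_5",
      "source_section": "3.7",
      "mode": "flim",
      "kind": "auto",
      "predicate": "pure_species_locations_reported",
      "text": "Lifetime or phasor locations of the pure molecular species used to compute relative fractions reported."
    },
    {
      "item_id": "flim_best_practice_1",
      "source_section": "3.8",
      "mode": "flim",
      "kind": "auto",
      "predicate": "fit_distributions_exported",
      "text": "Fit parameters (tau1, tau2, alpha1, alpha2) with their distributions and the chi-square distribution reported for the FLIM image."
    },
    {
      "item_id": "flim_best_practice_2",
      "source_section": "3.8",
      "mode": "flim",
      "kind": "auto",
      "predicate": "segmentation_applied",
      "text": "Nuclear, lipid-droplet, lipofuscin-rich/lysosomal regions removed before reporting FLIM metrics attributed to NAD(P)H and/or FAD (or the omission is justified)."
    },
    {
      "item_id": "flim_best_practice_3",
      "source_section": "3.8",
      "mode": "flim",
      "kind": "attestation",
      "predicate": "signal_origin_controls",
      "text": "Measurements confirm that most of the signal is due to NAD(P)H and FAD under all relevant conditions."
    },
    {
      "item_id": "flim_best_practice_4",
      "source_section": "3.8",
      "mode": "flim",
      "kind": "attestation",
      "predicate": "orthogonal_validation",
      "text": "Validation with orthogonal techniques (respirometry, mass spectrometry, omics, metabolite assays) confirms origins of observed FLIM changes."
    }
  ]
}
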