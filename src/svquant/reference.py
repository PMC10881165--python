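"""Published group means of the pS129 α-synuclein lamprey study.

These printed values are inputs to the report stage: the derived headline
quantities (fold changes, percent depletion, percent membrane loss) are
recomputed from them, and the population presets of
:mod:`svquant.synthetic` are anchored to them.  Values are mean ± SEM as
printed; units in the key names.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_MEANS"]

PUBLISHED_MEANS: dict[str, dict] = {
    # in vitro synaptic-membrane binding (band intensity, normalized AU)
    "membrane_binding": {"wt": 0.99, "ps129": 2.16},
    "oligomer_monomer_ratio": {"wt": 0.22, "ps129": 0.93},
    # IF colocalization and density partition
    "mcc_syn_to_sv2": {"wt": 0.924, "ps129": 0.904},
    "mcc_sv2_to_syn": {"wt": 0.827, "ps129": 0.868},
    "axoplasm_synapse_ratio_pct": {"wt": 15.3, "ps129": 24.3},
    "peak_offset_um": {"wt": 0.085, "ps129": 0.013},
    # EM morphometry, unstimulated series
    "sv_per_synapse_unstim": {"control": 145.5, "low": 146.9, "high": 150.5},
    "pm_evagination_um_unstim": {"control": 1.91, "low": 2.05, "high": 2.47},
    "total_membrane_um2_unstim": {"control": 1.46, "low": 1.49, "high": 1.56},
    # EM morphometry, stimulated (20 Hz, 5 min) series
    "sv_per_synapse": {"control": 135.9, "low": 103.1, "high": 51.03},
    "sv_diameter_nm": {"control": 53.20, "low": 53.23, "high": 55.65},
    "pm_evagination_um": {"control": 2.07, "low": 1.98, "high": 2.48},
    "cist_per_synapse": {"control": 3.02, "low": 3.72, "high": 6.3},
    "cist_perimeter_um": {"control": 0.41, "low": 0.41, "high": 0.52},
    "ccpv_per_synapse": {"control": 3.16, "low": 2.83, "high": 2.93},
    "total_membrane_um2": {"control": 1.62, "low": 1.35, "high": 1.11},
    # SV spatial statistics (stimulated; WT and pS129 at high concentration)
    "nn_mean_nm": {"control": 58.12, "wt": 68.47, "ps129": 82.60},
    "nn_az_slope": {"control": 0.017, "wt": 0.016, "ps129": 0.064},
    "nn_az_r_squared": {"control": 0.0227, "wt": 0.0111, "ps129": 0.0654},
    "ellipse_area_log_um2": {"control": 2.65, "wt": 3.83, "ps129": 5.11},
    "ellipse_eccentricity": {"control": 0.921, "wt": 0.905, "ps129": 0.85},
    # FM 1-43 live imaging
    "destain_tau_s": {"control": 213.0, "wt": 5056.0, "ps129": 8403.0},
    "mobile_puncta": {"control": 2.3, "wt": 4.5, "ps129": 17.8},
}
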