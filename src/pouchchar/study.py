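"""Reference measurements for the seven commercial nicotine pouch products.

These are the published characterization values for *on!*, *Zyn*, *Velo*,
*Dryft*, *Rogue*, *Volt*, and *Loop* pouches that the analysis scripts take as
inputs: first-order release parameters, nicotine contents, particle-size
intercepts (volume- and count-weighted), bulk/true densities, DSC transition
summaries, and the physicochemical panel. Derived columns (Carr index,
Hausner ratio, porosity, span, predicted release) are *not* stored here — they
are recomputed by the package so every reported number is traceable to one
operation.

Units: masses mg or g as labelled, densities g/mL, diameters µm, rate
constants 1/min, enthalpies J/g, temperatures °C.
"""

from __future__ import annotations

PRODUCTS = ["on!", "Zyn", "Velo", "Dryft", "Rogue", "Volt", "Loop"]

#: First-order release model parameters per product: total releasable
#: nicotine M0 (mg/pouch) and rate constant k (1/min), estimated from
#: 12-replicate flow-through-cell dissolution runs.
KINETICS: dict[str, tuple[float, float]] = {
    "on!": (8.380, 0.080),
    "Zyn": (5.350, 0.103),
    "Velo": (4.297, 0.057),
    "Dryft": (5.695, 0.042),
    "Rogue": (4.595, 0.078),
    "Volt": (8.225, 0.056),
    "Loop": (4.740, 0.021),
}

#: Sampling grid of the dissolution fractions, minutes.
TIME_GRID_MIN: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 30.0, 40.0, 50.0, 60.0)

#: Labelled and GC-FID-measured nicotine content (mg/pouch) and pouch mass (g).
NICOTINE_CONTENT: dict[str, dict[str, float]] = {
    "on!": {"pouch_weight_g": 0.25, "labeled_mg": 8.0, "experimental_mg": 8.2},
    "Zyn": {"pouch_weight_g": 0.38, "labeled_mg": 6.0, "experimental_mg": 5.4},
    "Velo": {"pouch_weight_g": 0.33, "labeled_mg": 7.0, "experimental_mg": 4.6},
    "Dryft": {"pouch_weight_g": 0.37, "labeled_mg": 7.0, "experimental_mg": 5.7},
    "Rogue": {"pouch_weight_g": 0.69, "labeled_mg": 6.0, "experimental_mg": 6.2},
    "Volt": {"pouch_weight_g": 0.64, "labeled_mg": 8.3, "experimental_mg": 8.9},
    "Loop": {"pouch_weight_g": 0.60, "labeled_mg": 9.4, "experimental_mg": 9.1},
}

#: Measured percent of pouch nicotine content released in 60 min (n=12 mean).
PCT_RELEASED_FROM_CONTENT: dict[str, float] = {
    "on!": 98.0, "Zyn": 96.0, "Velo": 88.0, "Dryft": 90.0,
    "Rogue": 72.0, "Volt": 89.0, "Loop": 38.0,
}

#: f1/f2 pairs computed from the experimental 12-replicate curves with on! as
#: reference, and the matching pairs from the first-order model estimates.
#: Stored because the underlying replicate curves are not published; the
#: package re-applies only the decision rule to these numbers.
F1F2_EXPERIMENTAL: dict[str, tuple[float, float]] = {
    "Zyn": (14.3, 52.9),
    "Velo": (14.5, 47.3),
    "Dryft": (22.6, 38.2),
    "Rogue": (2.9, 81.0),
    "Volt": (14.9, 46.6),
    "Loop": (34.4, 27.8),
}
F1F2_MODEL: dict[str, tuple[float, float]] = {
    "Zyn": (12.4, 54.3),
    "Velo": (16.5, 45.5),
    "Dryft": (25.0, 35.9),
    "Rogue": (3.2, 80.4),
    "Volt": (15.2, 46.8),
    "Loop": (47.2, 21.6),
}

#: Dynamic-image-analysis EQPC intercepts (µm), mean of n=12, by weighting.
#: Keys: mean, d10, d50, d90.
PSD_INTERCEPTS: dict[str, dict[str, dict[str, float]]] = {
    "q3": {
        "on!": {"mean": 334.45, "d10": 167.20, "d50": 314.11, "d90": 515.85},
        "Zyn": {"mean": 367.57, "d10": 233.18, "d50": 352.54, "d90": 511.95},
        "Velo": {"mean": 503.85, "d10": 143.33, "d50": 494.91, "d90": 876.30},
        "Dryft": {"mean": 537.65, "d10": 191.04, "d50": 399.79, "d90": 1121.36},
        "Rogue": {"mean": 562.28, "d10": 248.44, "d50": 583.91, "d90": 753.03},
        "Volt": {"mean": 658.83, "d10": 242.16, "d50": 430.56, "d90": 1543.75},
        "Loop": {"mean": 626.74, "d10": 108.76, "d50": 444.42, "d90": 1468.33},
    },
    "q0": {
        "on!": {"mean": 166.31, "d10": 66.70, "d50": 147.86, "d90": 292.63},
        "Zyn": {"mean": 246.59, "d10": 99.75, "d50": 245.56, "d90": 383.52},
        "Velo": {"mean": 110.16, "d10": 33.54, "d50": 92.94, "d90": 184.68},
        "Dryft": {"mean": 91.32, "d10": 16.58, "d50": 57.22, "d90": 223.70},
        "Rogue": {"mean": 80.83, "d10": 16.45, "d50": 52.69, "d90": 153.37},
        "Volt": {"mean": 196.02, "d10": 44.85, "d50": 172.68, "d90": 370.39},
        "Loop": {"mean": 73.81, "d10": 18.36, "d50": 63.01, "d90": 137.37},
    },
}

#: Published distribution spans (mean of per-replicate spans, n=12). Kept for
#: comparison only; recomputing span from the mean intercepts above does not
#: match every row because span averaging and intercept averaging commute only
#: approximately.
PSD_SPAN_PUBLISHED: dict[str, dict[str, float]] = {
    "q3": {"on!": 1.11, "Zyn": 0.76, "Velo": 1.49, "Dryft": 2.35,
           "Rogue": 0.86, "Volt": 2.99, "Loop": 3.07},
    "q0": {"on!": 1.53, "Zyn": 1.16, "Velo": 1.62, "Dryft": 3.62,
           "Rogue": 2.60, "Volt": 1.91, "Loop": 1.89},
}

#: Untapped bulk, tapped bulk, and helium-pycnometry true densities (g/mL).
DENSITIES: dict[str, dict[str, float]] = {
    "on!": {"rho_UB": 0.6319, "rho_TB": 0.790, "rho_T": 1.523},
    "Zyn": {"rho_UB": 0.4768, "rho_TB": 0.572, "rho_T": 1.555},
    "Velo": {"rho_UB": 0.7100, "rho_TB": 0.848, "rho_T": 1.566},
    "Dryft": {"rho_UB": 0.6485, "rho_TB": 0.852, "rho_T": 1.560},
    "Rogue": {"rho_UB": 0.7762, "rho_TB": 0.891, "rho_T": 1.451},
    "Volt": {"rho_UB": 0.3882, "rho_TB": 0.782, "rho_T": 1.283},
    "Loop": {"rho_UB": 0.3874, "rho_TB": 0.614, "rho_T": 1.387},
}

#: Major DSC melting transition per product: onset (°C), enthalpy (J/g),
#: peak melting temperature (°C); glass transition where observed.
DSC_MAJOR: dict[str, dict[str, float]] = {
    "on!": {"onset_C": 147.10, "dH_J_per_g": 38.254, "peak_C": 150.82},
    "Zyn": {"onset_C": 146.43, "dH_J_per_g": 67.401, "peak_C": 150.52},
    "Velo": {"onset_C": 145.71, "dH_J_per_g": 84.891, "peak_C": 151.29},
    "Dryft": {"onset_C": 144.10, "dH_J_per_g": 99.852, "peak_C": 149.58},
    "Rogue": {"onset_C": 55.29, "dH_J_per_g": 200.94, "peak_C": 102.51},
    "Volt": {"onset_C": 104.05, "dH_J_per_g": 637.07, "peak_C": 112.11},
    "Loop": {"onset_C": 78.45, "dH_J_per_g": 515.32, "peak_C": 109.94},
}
GLASS_TRANSITIONS_C: dict[str, float] = {
    "on!": 104.19, "Zyn": 105.50, "Velo": 82.83, "Loop": 46.77,
}

#: Solubility / moisture / pH / water-activity panel (n=3 means). Loop filler
#: could not be filtered, so its percent-soluble value is missing (None).
PHYSCHEM_PANEL: dict[str, dict[str, float | None]] = {
    "on!": {"percent_soluble": 66.35, "ov_pct_mc": 4.48, "pH": 8.62, "aw": 0.57},
    "Zyn": {"percent_soluble": 78.26, "ov_pct_mc": 3.52, "pH": 7.62, "aw": 0.56},
    "Velo": {"percent_soluble": 64.41, "ov_pct_mc": 6.62, "pH": 8.98, "aw": 0.56},
    "Dryft": {"percent_soluble": 68.03, "ov_pct_mc": 3.71, "pH": 8.31, "aw": 0.56},
    "Rogue": {"percent_soluble": 41.21, "ov_pct_mc": 14.70, "pH": 7.43, "aw": 0.65},
    "Volt": {"percent_soluble": 59.75, "ov_pct_mc": 37.18, "pH": 8.47, "aw": 0.92},
    "Loop": {"percent_soluble": None, "ov_pct_mc": 26.64, "pH": 8.62, "aw": 0.87},
}

#: Instrument measuring range of the M8 dynamic-image-analysis lens, µm.
DIA_RANGE_UM: tuple[float, float] = (10.0, 6820.0)
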