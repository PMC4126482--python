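"""Versioned parameter file support.

Every model coefficient ships embedded as a default (with a citation
string naming the originating fit), and the same set can be dumped to or
loaded from a YAML file so a revised coefficient set is a data change, not
a code change. :func:`models_from_parameters` rebuilds the risk-model
instances from a (possibly edited) parameter mapping.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from . import risk_models as rm

__all__ = ["default_parameters", "dump_parameters", "load_parameters",
           "models_from_parameters"]

PARAMETERS_VERSION = 1

_DEFAULTS = {
    "version": PARAMETERS_VERSION,
    "hic15": {
        "shape": 4.34, "scales": {1: 671.0},
        "citation": "Funk et al. 2007 football mTBI Weibull fit",
    },
    "bric": {
        "shape": 2.84, "scales": {},
        "citation": "Takhounts et al. BrIC; per-AIS scale parameters unpublished",
    },
    "neck_tension": {
        "cut_points": {1: 6.30, 2: 8.56, 3: 9.28, 4: 10.19}, "slope": 0.0053,
        "citation": "Philippens et al. PMHS ordered probit",
    },
    "chest_deflection": {
        "cut_points": {1: 4.17, 2: 5.61, 3: 6.29, 4: 7.32}, "slope": 0.103,
        "citation": "Mertz et al. sternal compression ordered probit re-analysis",
    },
    "ankle_inversion_eversion": {
        "cut_points": {2: 4.0}, "slope": 0.10,
        "citation": "Kuppa et al. digitized inversion/eversion probit",
    },
    "ankle_dorsiflexion": {
        "location": 60.23, "scale": 9.217,
        "citation": "Kuppa et al. dorsiflexion logistic",
    },
    "thor_lateral_force": {
        "intercept": 6.403, "slope": 0.0011,
        "citation": "Kuppa EuroSID-2re pelvic logistic mapped to THOR",
    },
    "eurosid_pelvis": {
        "intercept": 6.403, "slope": 0.00163,
        "citation": "Kuppa EuroSID-2re pelvic logistic",
    },
    "bass_forearm": {
        "location": 66.2, "scale": 15.0,
        "citation": "Bass et al. SAE 5th-female instrumented-arm logistic",
    },
    "duma_forearm": {
        "location": 58.0, "scale": 6.62,
        "citation": "Duma et al. 5th-female PMHS forearm logistic",
    },
    "adfs_pmhs": {
        "intercept": 6.749, "slope": 0.645,
        "citation": "Hardy et al. average distal forearm speed logistic",
    },
    "adfs_thor": {
        "intercept": 9.845, "slope": 0.645,
        "citation": "Hardy et al. ADFS mass-scaled to the 4.27 kg THOR arm",
    },
    "neck_compression": {
        "beta0": 934.2, "beta1": 8.9, "beta2": 11.0, "beta3": 665.0,
        "beta4": -0.134, "beta5": None,
        "citation": "Pintar et al. cervical compression tolerance; "
                    "logistic steepness beta5 unpublished",
    },
    "dri_spinal": {
        "slope": 3.73, "intercept": 15.8,
        "citation": "Brinkley ejection-data DRI log-linear fit (risk in percent)",
    },
    "shoulder_age": {
        "intercept": 8.14, "age_slope": 0.0055, "shape": 7.41, "thor_gain": 2.016,
        "citation": "Petitjean et al. WorldSID shoulder risk x THOR transfer",
    },
    "hip_fracture": {
        "c0": -0.2141, "c1": 0.0114, "sigma": 0.1991,
        "citation": "Rupp et al. NHTSA frontal acetabular risk",
    },
    "ncap_chest": {
        "a0": 12.597, "a1": 0.05861, "a2": 1.568, "a3": 0.4612,
        "citation": "NHTSA NCAP age-adjusted AIS3+ chest risk",
    },
}


def default_parameters() -> dict:
    """Deep copy of the embedded coefficient set."""
    return copy.deepcopy(_DEFAULTS)


def dump_parameters(path: str | Path, params: dict | None = None) -> None:
    """Write a parameter mapping to YAML (defaults if none given)."""
    Path(path).write_text(
        yaml.safe_dump(params or default_parameters(), sort_keys=True))


def load_parameters(path: str | Path) -> dict:
    """Load a YAML parameter file, layering it over the defaults so a
    partial file overrides only the coefficients it names."""
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    merged = default_parameters()
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _strip(entry: dict) -> dict:
    return {k: v for k, v in entry.items() if k != "citation"}


def models_from_parameters(params: dict | None = None) -> dict:
    """Instantiate every risk model from a parameter mapping."""
    p = params or default_parameters()
    return {
        "hic15": rm.WeibullRiskModel(**_strip(p["hic15"])),
        "bric": rm.WeibullRiskModel(**_strip(p["bric"])),
        "neck_tension": rm.OrderedProbitRiskModel(**_strip(p["neck_tension"])),
        "chest_deflection": rm.OrderedProbitRiskModel(**_strip(p["chest_deflection"])),
        "ankle_inversion_eversion": rm.OrderedProbitRiskModel(
            **_strip(p["ankle_inversion_eversion"])),
        "ankle_dorsiflexion": rm.LogisticRiskModel.from_location_scale(
            p["ankle_dorsiflexion"]["location"], p["ankle_dorsiflexion"]["scale"]),
        "thor_lateral_force": rm.LogisticRiskModel(
            p["thor_lateral_force"]["intercept"], p["thor_lateral_force"]["slope"]),
        "eurosid_pelvis": rm.LogisticRiskModel(
            p["eurosid_pelvis"]["intercept"], p["eurosid_pelvis"]["slope"]),
        "bass_forearm": rm.LogisticRiskModel.from_location_scale(
            p["bass_forearm"]["location"], p["bass_forearm"]["scale"]),
        "duma_forearm": rm.LogisticRiskModel.from_location_scale(
            p["duma_forearm"]["location"], p["duma_forearm"]["scale"]),
        "adfs_pmhs": rm.LogisticRiskModel(
            p["adfs_pmhs"]["intercept"], p["adfs_pmhs"]["slope"]),
        "adfs_thor": rm.LogisticRiskModel(
            p["adfs_thor"]["intercept"], p["adfs_thor"]["slope"]),
        "neck_compression": rm.NeckCompressionModel(**_strip(p["neck_compression"])),
        "dri_spinal": rm.DRISpinalRiskModel(**_strip(p["dri_spinal"])),
        "shoulder_age": rm.ShoulderAgeModel(**_strip(p["shoulder_age"])),
        "hip_fracture": rm.HipFractureModel(**_strip(p["hip_fracture"])),
        "ncap_chest": rm.NCAPChestModel(**_strip(p["ncap_chest"])),
    }
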