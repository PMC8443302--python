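"""Run configuration and seeded reproducibility.

Every tunable parameter of every stage has a documented default here;
YAML configs may override any subset but unknown keys are rejected so a
typo cannot silently fall back to a default.  A single global seed is
expanded into independent per-stage generators through a counter-based
scheme, so re-running one stage reproduces its stream regardless of what
ran before it.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULTS", "PipelineConfig", "stage_rng", "MMH2O_TO_PA"]

#: 1 mmH2O in pascal (conventional water column at standard gravity).
MMH2O_TO_PA = 9.80665

DEFAULTS: dict = {
    "seed": 0,
    "physical": {
        # dynamic viscosity of the interstitial fluid, Pa*s (aqueous
        # buffer at 37 C); always echoed in outputs
        "mu_pa_s": 0.7e-3,
        # channel-to-channel gap L in um; no default on purpose - must
        # be supplied to convert velocity to hydraulic permeability
        "gap_l_um": None,
    },
    "geometry": {
        "threshold_method": "otsu",      # or "fixed"
        "fixed_threshold": None,
        "min_object_px": 10,             # speckle removal before continuity
        "connectivity": 2,               # 2 = 8-connectivity
        "min_valid_columns": 10,
    },
    "permeability": {
        "guard_px": 2,                   # wall guard band for both ROIs
        "background": "first-frame-exterior",
        "fixed_background": None,
        "window": "auto",                # or [a, b] frame indices
        "auto_window_fraction": 0.2,     # early-time cutoff vs final value
        "auto_window_min_frames": 5,
        "use_mean_intensity": False,     # per-area variant for comparison
    },
    "frap": {
        "search_radius_px": 30,
        "noise_k": 3.0,                  # detection floor: bg - k*noise_sd
        "max_consecutive_failures": 3,
        "min_track_frames": 5,
        "porosity": 1.0,                 # superficial velocity assumption
    },
    "alignment": {
        "patch_px": 64,
        "low_freq_cycles": 6.0,          # DC/low-frequency exclusion radius
        "high_freq_frac": 0.9,           # keep below 0.9 * Nyquist
        "radial_weight_power": 2.0,      # angular-sharpness radial weighting
        "n_orientation_bins": 36,
    },
    "extravasation": {
        "min_nucleus_diam_um": 5.0,
        "max_nucleus_diam_um": 15.0,
        "peak_snr": 5.0,
        "monocyte_max_diam_um": 9.0,
        "monocyte_min_sphericity": 0.75,
        "wall_tolerance_um": 5.0,
        "match_radius_um": 5.0,          # truth matching for validation
    },
    "stats": {
        "outlier_iqr_factor": 1.5,
        "bonferroni": False,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise TypeError(f"config section {here!r} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


class PipelineConfig:
    """Validated parameter tree with dotted access.

    >>> cfg = PipelineConfig()
    >>> cfg["permeability"]["guard_px"]
    2
    """

    def __init__(self, overrides: dict | None = None):
        self._tree = _merge(DEFAULTS, overrides or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise TypeError("config YAML must be a mapping at top level")
        return cls(data)

    def __getitem__(self, key: str):
        return self._tree[key]

    def get(self, dotted: str, default=None):
        node = self._tree
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node

    def as_dict(self) -> dict:
        return copy.deepcopy(self._tree)

    def digest(self) -> str:
        """Stable hash of the full parameter tree, for run summaries."""
        blob = json.dumps(self._tree, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def seed(self) -> int:
        return int(self._tree["seed"])


#: stable stage indices for the counter-based seed expansion
_STAGE_INDEX = {
    "simulate": 0,
    "geometry": 1,
    "permeability": 2,
    "frap": 3,
    "align": 4,
    "extravasation": 5,
    "report": 6,
}


def stage_rng(seed: int, stage: str, counter: int = 0) -> np.random.Generator:
    """Independent generator for (seed, stage, counter).

    The same triple always yields the same stream; distinct triples are
    statistically independent (SeedSequence entropy pooling).
    """
    if stage not in _STAGE_INDEX:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_INDEX)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_INDEX[stage], int(counter)))
    return np.random.default_rng(ss)
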