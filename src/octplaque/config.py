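"""Single-YAML configuration covering every pipeline parameter block.

Every constant of the method surfaces here under a named, defaulted
key: the 7×7 σ=1 despeckling filter, the 1 mm / 200 px ROI, the size-5
structuring element, the CRF parameters (σ_r = 1.2, σ_θ = 1.1,
ω = 0.5, 10 iterations), the training schedule (lr 0.001, drop ×0.2
every 5 epochs, ≤50 epochs, patience 5), and the network shapes.
"""

from __future__ import annotations

import copy

import yaml

DEFAULT_CONFIG: dict = {
    "preprocess": {
        "roi_depth_px": 200,
        "smooth_sigma": 1.0,
        "smooth_truncate": 3.0,  # σ=1 → 7×7 kernel
        "guidewire_threshold_frac": 0.35,
        "lumen_max_jump": 3,
    },
    "detector": {
        "conv_filters": [96, 128, 256, 324, 324],
        "kernel": [3, 5, 5],
        "fc1_units": 1024,
        "dropout_rate": 0.5,
        "seed": 0,
    },
    "cleanup": {"se_size": 5},
    "segmenter": {
        "encoder_stages": [[64, 64], [128, 128], [256, 256, 256],
                           [512, 512, 512], [512, 512, 512]],
        "loss": "tversky",
        "tversky_alpha": 0.7,
        "tversky_beta": 0.3,
        "smooth": 1.0,
        "seed": 0,
    },
    "crf": {"sigma_r": 1.2, "sigma_theta": 1.1, "weight": 0.5, "iterations": 10},
    "train": {
        "lr": 0.001,
        "drop_factor": 0.2,
        "drop_period": 5,
        "max_epochs": 50,
        "patience": 5,
        "batch_size": 8,
        "seed": 0,
    },
    "quantify": {"r_pitch_mm": 0.005, "frame_pitch_mm": 0.2},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path=None) -> dict:
    """Load a YAML config, recursively overlaying the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(base: dict, over: dict) -> dict:
        for key, val in over.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                merge(base[key], val)
            else:
                base[key] = val
        return base

    return merge(cfg, user)
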