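"""Run configuration: defaults, config-file loading, and resolution.

Precedence is CLI flag > config file > documented default.  Every run
writes its fully resolved configuration as JSON next to its outputs so
results are reproducible from the output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

#: documented defaults for every tunable threshold in the pipeline
DEFAULTS: dict = {
    "seed": 1,
    # variants
    "depth_bounds": None,          # None -> [0.5x, 2x] genome-wide mean depth
    "min_call_rate": 0.9,
    "oar_window_bp": 10_000,
    "oar_step_bp": 5_000,
    "oar_depth_z": 3.0,
    "oar_het_z": 3.0,
    "min_agree": 1,
    "balance_bounds": [0.25, 0.75],
    "min_reads_per_allele": 3,
    # sds
    "maf_min": 0.05,
    "bin_width": 0.05,
    "max_censored_individuals": 10,
    "side": "upper",
    "alpha": 0.05,
    "gene_flank_bp": 10_000,
    # polygenic
    "qtl_window_bp": 10_000,
    "min_pops": 6,
    "n_perm": 10_000,
    "sign_rule": "random",
    "drop_outlier": False,
    # coalsim
    "model": "high_N0",
    "generation_time_years": 5.0,
    "tipage_n": [10, 20, 50, 100, 204, 500],
    "tipage_replicates": 200,
    "predict_n": 204,
    "region_length": 10_000_000,
    "selection_coefficient": 0.05,
    "current_frequency": 0.5,
    "mu": 1.2e-8,
    "mu_multiplier": 1.0,
    "recombination_rate": None,    # None -> mu / 3.25
    "n_diploids": 102,
    "replicates": 100,
}


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def resolve(config_file: str | Path | None = None, **cli_overrides) -> dict:
    """Merge defaults, config file and CLI overrides (None = not given)."""
    cfg = dict(DEFAULTS)
    cfg.update(load_config(config_file))
    cfg.update({k: v for k, v in cli_overrides.items() if v is not None})
    return cfg


def write_resolved(cfg: dict, out_dir: str | Path, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(cfg)
    if extra:
        payload.update(extra)
    path = out_dir / "resolved_config.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path
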