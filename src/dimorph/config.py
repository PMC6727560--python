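"""Pipeline configuration with the published thresholds as defaults.

The soft-threshold power is deliberately not a configuration default: it is
data-derived and returned by the soft-threshold selection step.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "fpkm_not_expressed": 1.0,
    "sex_ratio_female": 1.5,
    "sex_ratio_male": 1.0,
    "de_alpha": {"single_cell": 0.05, "cardiac_precursor": 0.01},
    "wgcna": {
        "powers": list(range(1, 21)),
        "r2_cut": 0.8,
        "min_module_size": 50,
        "merge_cut": 0.25,
    },
    "ppi": {"min_score": 0.7, "drop_textmining": True},
    "motif": {"p_cutoff": 1e-5, "window": [-5000, 1000]},
    "paths": {},
}

_RANGES = {
    ("fpkm_not_expressed",): lambda v: v >= 0,
    ("sex_ratio_female",): lambda v: v > 0,
    ("sex_ratio_male",): lambda v: v > 0,
    ("seed",): lambda v: isinstance(v, int) and v >= 0,
    ("de_alpha", "single_cell"): lambda v: 0 < v < 1,
    ("de_alpha", "cardiac_precursor"): lambda v: 0 < v < 1,
    ("wgcna", "r2_cut"): lambda v: 0 < v <= 1,
    ("wgcna", "min_module_size"): lambda v: isinstance(v, int) and v >= 2,
    ("wgcna", "merge_cut"): lambda v: 0 < v < 1,
    ("ppi", "min_score"): lambda v: 0 <= v <= 1,
    ("motif", "p_cutoff"): lambda v: 0 < v < 1,
}


@dataclass
class PipelineConfig:
    settings: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]

    @property
    def seed(self) -> int:
        return self.settings["seed"]

    def stage_seed(self, stage_name: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage_name}".encode()).digest()
        return int.from_bytes(digest[:4], "big")

    def to_dict(self) -> dict:
        return copy.deepcopy(self.settings)


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(raw: Mapping | None = None) -> PipelineConfig:
    """Merge user settings over defaults; strict keys and range checks."""
    merged = _merge(DEFAULTS, raw or {})
    for keys, check in _RANGES.items():
        value: Any = merged
        for k in keys:
            value = value[k]
        if not check(value):
            raise ValueError(f"config value {'.'.join(keys)}={value!r} out of range")
    powers = merged["wgcna"]["powers"]
    if len(powers) < 2 or any(p < 1 for p in powers):
        raise ValueError("wgcna.powers must be >= 2 powers, all >= 1")
    return PipelineConfig(merged)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return validate_config({})
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Synthetic end-to-end run: simulate per-stage panels, sex cells, test
    per stage, build the bias trajectory table, and classify.

    Writes all stage outputs plus a ``manifest.json`` recording thresholds,
    seeds, file digests, and per-stage summaries; reruns with the same config
    are byte-identical.
    """
    from . import __version__
    from .core import write_expression_tsv
    from .de import stage_de
    from .sexing import sex_cells
    from .synth import simulate_bulk_panel, simulate_cells
    from .trajectory import build_bias_table, classify_table, write_bias_table_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "digests": {},
    }
    alpha_sc = config["de_alpha"]["single_cell"]
    alpha_cp = config["de_alpha"]["cardiac_precursor"]

    stage_results = {}
    presence = {}
    bulk_stages = {"ES": alpha_sc, "CP": alpha_cp, "Adult": alpha_sc}
    cell_stages = {"E8.5": alpha_sc, "E9.5": alpha_sc, "E10.5": alpha_sc, "P1": alpha_sc}

    from .core import filter_not_expressed

    for stage, alpha in bulk_stages.items():
        m, truth = simulate_bulk_panel(
            n_per_sex=6, n_genes=200, n_biased=20, effect=3.0, module_size=0,
            noise_sd=0.7, seed=config.stage_seed(f"bulk:{stage}"), stage=stage,
        )
        path = out / f"expr_{stage}.tsv"
        write_expression_tsv(m, path)
        manifest["digests"][path.name] = file_digest(path)
        de = stage_de(m, stage, alpha=alpha, fpkm_threshold=config["fpkm_not_expressed"])
        _, flags = filter_not_expressed(m, config["fpkm_not_expressed"])
        stage_results[stage] = de
        presence[stage] = flags.stage_presence[stage]
        manifest["stages"][stage] = {
            "kind": "bulk",
            "n_samples": m.shape[1],
            "n_genes": m.shape[0],
            "n_biased_called": int((de["bias"].isin(["XX", "XY"])).sum()),
            "alpha": alpha,
        }

    for stage, alpha in cell_stages.items():
        cells, truth = simulate_cells(
            stage=stage, n_cells=120, female_fraction=0.5, dropout=0.2,
            seed=config.stage_seed(f"cells:{stage}"),
        )
        calls = sex_cells(cells)
        calls_path = out / f"sex_calls_{stage}.tsv"
        calls.write_tsv(calls_path)
        manifest["digests"][calls_path.name] = file_digest(calls_path)
        de = stage_de(cells, stage, sex_source=calls, alpha=alpha,
                      fpkm_threshold=config["fpkm_not_expressed"])
        _, flags = filter_not_expressed(cells, config["fpkm_not_expressed"])
        stage_results[stage] = de
        presence[stage] = flags.stage_presence[stage]
        counts = calls.counts()
        manifest["stages"][stage] = {
            "kind": "single_cell",
            "n_cells": cells.shape[1],
            "calls": counts,
            "n_biased_called": int((de["bias"].isin(["XX", "XY"])).sum()),
            "alpha": alpha,
        }

    table = build_bias_table(stage_results, presence=presence)
    bias_path = out / "bias_table.tsv"
    write_bias_table_tsv(table, bias_path)
    manifest["digests"][bias_path.name] = file_digest(bias_path)
    classes = classify_table(table)
    cls_path = out / "trajectory_classes.tsv"
    classes.to_csv(cls_path, sep="\t", index=False)
    manifest["digests"][cls_path.name] = file_digest(cls_path)
    manifest["trajectory_groups"] = classes["group"].value_counts().to_dict()

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
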