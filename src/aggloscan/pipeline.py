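"""End-to-end orchestration: simulate → quantify → assay, with a manifest.

A run is described by a YAML/dict config naming an ordered list of stages
with per-stage parameter blocks and a single global seed. Every output file
is listed in a manifest with a SHA-256 checksum; identical config + seed
reproduces identical checksums (all randomness is derived from the global
seed via fixed per-operation child seeds).

Supported stages
----------------
simulate_dissolution  per-cell dissolution records -> cells.csv
dissolution_assay     quantile bins + agglomerate/aggregate call
simulate_field        two-channel field -> green/red/mask TIFF + truth.csv
quantify              cell stats + puncta calls from the field stage
simulate_coloc        co-localization pair field
coloc_assay           per-cell IoU scores + strain summary
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aggloscan import assays, image_quant, synthetic
from aggloscan.io import load_tiff, save_tiff_u16
from aggloscan.utils import child_seed

log = logging.getLogger("aggloscan.pipeline")

KNOWN_STAGES = (
    "simulate_dissolution",
    "dissolution_assay",
    "simulate_field",
    "quantify",
    "simulate_coloc",
    "coloc_assay",
)


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_params(block: dict, seed: int, op: str) -> synthetic.SimulationParams:
    block = dict(block or {})
    for key in ("field_shape", "ratio_distribution", "cell_axes_px", "focus_peak_fold"):
        if key in block:
            block[key] = tuple(block[key])
    block.setdefault("seed", child_seed(seed, op))
    return synthetic.SimulationParams(**block)


def validate_config(config: dict) -> list[dict]:
    stages = config.get("stages")
    if not stages:
        raise ConfigError("config must list at least one stage")
    norm = []
    for entry in stages:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry.get("name")
        if name not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {name!r}; known stages: {', '.join(KNOWN_STAGES)}")
        norm.append(entry)
    return norm


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    stages = validate_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": seed,
        "stages": [],
        "outputs": {},
        "config_echo": config,
    }

    def record(path: Path):
        manifest["outputs"][path.name] = _sha256(path)

    state: dict = {}
    for entry in stages:
        name = entry["name"]
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            if name == "simulate_dissolution":
                params = _sim_params(entry.get("params"), seed, name)
                cells = synthetic.simulate_dissolution_population(params)
                path = out / "cells.csv"
                cells.to_csv(path, index=False)
                record(path)
                state["cells"] = cells

            elif name == "dissolution_assay":
                cells = state.get("cells")
                if cells is None:
                    cells = pd.read_csv(out / "cells.csv")
                bins = assays.ratio_bins(cells, n_bins=int(entry.get("n_bins", 10)))
                call = assays.dissolution_call(bins)
                bins.to_csv(out / "bins.csv", index=False)
                (out / "dissolution_call.json").write_text(
                    json.dumps(dataclasses.asdict(call), indent=2, sort_keys=True)
                )
                record(out / "bins.csv")
                record(out / "dissolution_call.json")
                state["dissolution_call"] = call

            elif name == "simulate_field":
                params = _sim_params(entry.get("params"), seed, name)
                green, red, labels, truth = synthetic.simulate_field(params)
                for arr, fname in ((green, "green.tif"), (red, "red.tif"), (labels, "mask.tif")):
                    save_tiff_u16(out / fname, arr)
                    record(out / fname)
                truth.to_csv(out / "field_truth.csv", index=False)
                record(out / "field_truth.csv")
                state["field"] = (green, red, labels)

            elif name == "quantify":
                if "field" in state:
                    green, red, labels = state["field"]
                else:
                    green = load_tiff(out / "green.tif").astype(float)
                    red = load_tiff(out / "red.tif").astype(float)
                    labels = load_tiff(out / "mask.tif")
                qp = image_quant.QuantParams(**(entry.get("params") or {}))
                background = image_quant.estimate_background(green, labels)
                cells = image_quant.cell_stats(green, red, labels, qp)
                foci = image_quant.detect_puncta(green, labels, background, qp)
                cells.to_csv(out / "cell_stats.csv", index=False)
                foci.drop(columns=["pixels"]).to_csv(out / "foci_calls.csv", index=False)
                record(out / "cell_stats.csv")
                record(out / "foci_calls.csv")
                state["cell_stats"] = cells

            elif name == "simulate_coloc":
                params = _sim_params(entry.get("params"), seed, name)
                shared = float(entry.get("shared_fraction", 1.0))
                green, red, labels, truth = synthetic.simulate_coloc_pair(params, shared)
                for arr, fname in ((green, "coloc_green.tif"), (red, "coloc_red.tif"), (labels, "coloc_mask.tif")):
                    save_tiff_u16(out / fname, arr)
                    record(out / fname)
                truth.to_csv(out / "coloc_truth.csv", index=False)
                record(out / "coloc_truth.csv")
                state["coloc_field"] = (green, red, labels)

            elif name == "coloc_assay":
                green, red, labels = state["coloc_field"]
                qp = image_quant.QuantParams(**(entry.get("params") or {}))
                cells = image_quant.cell_stats(green, red, labels, qp)
                rows = []
                for _, rec in cells.iterrows():
                    mask = labels == rec["cell_id"]
                    score = assays.coloc_score(green, red, mask, qp.coloc_top_fraction)
                    rows.append(dict(cell_id=int(rec["cell_id"]), score=np.nan if score is None else score,
                                     has_foci=bool(rec["has_foci"])))
                scores = pd.DataFrame(rows)
                summary = assays.strain_pair_summary(scores, qp)
                scores.to_csv(out / "coloc_scores.csv", index=False)
                (out / "coloc_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
                record(out / "coloc_scores.csv")
                record(out / "coloc_summary.json")

        except Exception as exc:  # noqa: BLE001 - abort with stage name + partial manifest
            manifest["failed_stage"] = name
            _write_manifest(out, manifest)
            raise StageError(name, manifest, exc) from exc

        manifest["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
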