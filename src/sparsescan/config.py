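"""Experiment configuration, seed derivation and the end-to-end pipeline.

A single YAML (or dict) configuration drives phantom generation, the
beam model, the scan, the strategy and optional in-painting. One
master seed determines every stochastic choice; per-module seeds are
derived from it with a fixed counter scheme
(``SeedSequence(master, spawn_key=(k,))`` with k = 0 phantom, 1 beam,
2 scan, 3 strategy, 4 training), so adding a consumer does not perturb
earlier streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import easymask_io, inpaint
from .engine import ScanConfig, SavingsReport, run_scan, summarize_savings
from .phantom import make_phantom, simulate_beam
from .strategies import StrategySpec, make_strategy

__all__ = ["ExperimentConfig", "derive_seed", "load_config", "run_experiment"]

log = logging.getLogger("sparsescan")

_MODULE_KEYS = {"phantom": 0, "beam": 1, "scan": 2, "strategy": 3, "train": 4}


def derive_seed(master_seed: int, module: str) -> int:
    """Per-module seed from the master seed (documented counter scheme)."""
    k = _MODULE_KEYS[module]
    ss = np.random.SeedSequence(master_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


_DEFAULTS: dict[str, dict[str, Any]] = {
    "phantom": {"kind": "leaf", "rows": 64, "cols": 64, "pixel_size": 1.0, "elements": None},
    "beam": {
        "duration": 3600.0, "decay_time": 36000.0, "topup_period": 1200.0,
        "position_amp": 0.0, "blade_gains": [1.0, 1.0, 1.0, 1.0],
        "motor_drift_rate": 0.0, "nominal_flux": 20000.0,
    },
    "scan": {
        "step": None, "origin": [0.0, 0.0], "t_stxm": 0.005, "t_xrf": 1.0,
        "t_fast": 0.1, "t_move": 0.0, "scan_order": "row_major",
        "stxm_everywhere": True, "noise_sigma": 0.0,
    },
    "strategy": {
        "basis": "absorption", "threshold": 0.0, "normalizer": "identity",
        "window_auto": True, "window_length": None, "spare_fraction": 0.0,
        "roi_element": None, "adjust_threshold": False,
        "mask": None, "mask_file": None,
    },
    "inpaint": {"enabled": False, "method": "harmonic", "element": None},
}

_REQUIRED = {"scan": ["step", "t_xrf"], "strategy": ["threshold"]}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Resolved (post-default) experiment configuration."""

    master_seed: int
    phantom: dict = field(default_factory=dict)
    beam: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    strategy: dict = field(default_factory=dict)
    inpaint: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "phantom": self.phantom, "beam": self.beam, "scan": self.scan,
            "strategy": self.strategy, "inpaint": self.inpaint,
        }


def _merge_section(name: str, user: dict) -> dict:
    out = dict(_DEFAULTS[name])
    for key, val in (user or {}).items():
        if key not in out:
            raise ConfigError(f"unknown configuration key {name}.{key}")
        out[key] = val
    for key in _REQUIRED.get(name, []):
        if out.get(key) is None:
            raise ConfigError(f"missing required configuration key {name}.{key}")
    return out


def load_config(source, master_seed: int | None = None) -> ExperimentConfig:
    """Load and validate a config from a YAML path, stream, or dict."""
    if isinstance(source, dict):
        raw = source
    else:
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
    raw = raw or {}
    seed = master_seed if master_seed is not None else raw.get("master_seed")
    if seed is None:
        raise ConfigError("missing required configuration key master_seed")
    for section in raw:
        if section not in ("master_seed", *_DEFAULTS):
            raise ConfigError(f"unknown configuration section {section}")
    return ExperimentConfig(
        master_seed=int(seed),
        phantom=_merge_section("phantom", raw.get("phantom", {})),
        beam=_merge_section("beam", raw.get("beam", {})),
        scan=_merge_section("scan", raw.get("scan", {})),
        strategy=_merge_section("strategy", raw.get("strategy", {})),
        inpaint=_merge_section("inpaint", raw.get("inpaint", {})),
    )


def _build_scan_config(cfg: ExperimentConfig, rows: int, cols: int, elements) -> ScanConfig:
    s = cfg.scan
    return ScanConfig(
        rows=rows, cols=cols, step=float(s["step"]),
        origin=tuple(float(v) for v in s["origin"]),
        t_stxm=float(s["t_stxm"]), t_xrf=float(s["t_xrf"]),
        t_fast=float(s["t_fast"]), t_move=float(s["t_move"]),
        scan_order=s["scan_order"], elements=tuple(elements),
        stxm_everywhere=bool(s["stxm_everywhere"]),
        noise_sigma=float(s["noise_sigma"]),
    )


def _resolve_mask(st: dict):
    if st.get("mask") is not None:
        return np.asarray(st["mask"], bool)
    if st.get("mask_file"):
        return easymask_io.mask_from_image(st["mask_file"]).grid
    return None


def run_experiment(cfg: ExperimentConfig, out_h5=None) -> tuple:
    """Execute phantom -> beam -> scan -> savings (-> in-paint).

    Returns ``(record, savings_report, inpainted_or_None)``; if
    ``out_h5`` is given the record is archived there with the resolved
    configuration echoed into the file.
    """
    ph = cfg.phantom
    sample = make_phantom(
        ph["kind"], int(ph["rows"]), int(ph["cols"]), float(ph["pixel_size"]),
        elements=ph["elements"], seed=derive_seed(cfg.master_seed, "phantom"),
    )
    b = cfg.beam
    beam = simulate_beam(
        duration=float(b["duration"]), decay_time=float(b["decay_time"]),
        topup_period=float(b["topup_period"]), position_amp=float(b["position_amp"]),
        blade_gains=[float(g) for g in b["blade_gains"]],
        motor_drift_rate=float(b["motor_drift_rate"]),
        seed=derive_seed(cfg.master_seed, "beam"),
        nominal_flux=float(b["nominal_flux"]),
    )
    scan_cfg = _build_scan_config(cfg, sample.shape[0], sample.shape[1], sample.element_labels())
    st = cfg.strategy
    window_length = None if st["window_auto"] else st["window_length"]
    spec = StrategySpec(
        basis=st["basis"], threshold=float(st["threshold"]),
        normalizer=st["normalizer"], window_length=window_length,
        spare_fraction=float(st["spare_fraction"]), roi_element=st["roi_element"],
        t_fast=scan_cfg.t_fast, t_long=scan_cfg.t_xrf,
        adjust_threshold=bool(st["adjust_threshold"]),
        mask=_resolve_mask(st),
    )
    strategy = make_strategy(spec)
    log.info("scanning %dx%d phantom %r with strategy %r",
             scan_cfg.rows, scan_cfg.cols, ph["kind"], st["basis"])
    record = run_scan(sample, beam, scan_cfg, strategy, seed=derive_seed(cfg.master_seed, "scan"))
    for p in range(0, scan_cfg.n_pixels, 1000):
        log.debug("pixel %d/%d, simulated t=%.1f s", p, scan_cfg.n_pixels, record.timestamps[p])
    report = summarize_savings(record)
    log.info("coverage %.1f%%, time saving %.1f%%",
             report.coverage_percent, report.time_saving_percent)

    filled = None
    ip = cfg.inpaint
    if ip["enabled"]:
        element = ip["element"] or sample.element_labels()[0]
        smap = inpaint.sparse_map_from_record(record, element)
        filled = inpaint.inpaint_map(smap, method=ip["method"])

    if out_h5 is not None:
        easymask_io.write_h5(record, out_h5)
        import h5py

        with h5py.File(out_h5, "a") as f:
            f.attrs["resolved_config"] = yaml.safe_dump(cfg.resolved())
    return record, report, filled
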