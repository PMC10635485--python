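"""Mask handling, scan-path CSV files and HDF5 scan archives.

A scan mask is a boolean grid marking where the slow modality should be
acquired. Masks may be drawn at a coarser resolution than the final
scan and upscaled, converted to motor-position scan paths (CSV), and
summarized with coverage statistics. Scan records and ground-truth
samples are archived to HDF5 with per-pixel diagnostics.

CSV scan-path dialect (normative for this package)::

    index,x_um,y_um,stxm,xrf,t_stxm_s,t_xrf_s

with a 0-based strictly increasing index, coordinates in micrometres
with 3 decimals, 0/1 flags, and dwells in seconds with 6 decimals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import h5py
import imageio.v3 as iio
import numpy as np

from .engine import XRF_SENTINEL, ScanConfig, ScanRecord, predict_scan_time
from .phantom import GroundTruthSample
from .strategies import draw_spare_points

__all__ = [
    "ScanMask",
    "ScanPathRow",
    "ScanPathError",
    "SchemaError",
    "upscale_mask",
    "coverage_stats",
    "mask_to_scan_path",
    "mask_from_image",
    "write_csv",
    "read_csv",
    "write_h5",
    "read_h5",
]

CSV_HEADER = ["index", "x_um", "y_um", "stxm", "xrf", "t_stxm_s", "t_xrf_s"]


class ScanPathError(ValueError):
    """A scan-path CSV file violated the dialect."""


class SchemaError(KeyError):
    """An HDF5 archive is missing a required group or dataset."""


@dataclass
class ScanMask:
    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def coverage_fraction(self) -> float:
        return float(np.count_nonzero(self.grid)) / self.grid.size


@dataclass
class ScanPathRow:
    index: int
    x: float
    y: float
    stxm_flag: int
    xrf_flag: int
    t_stxm: float
    t_xrf: float


def upscale_mask(coarse: ScanMask, target_rows: int, target_cols: int) -> ScanMask:
    """Nearest-neighbour upscale: each fine pixel takes the value of the
    coarse pixel containing its centre. Integer scale factors preserve
    the coverage fraction exactly; downscaling is refused."""
    rows, cols = coarse.shape
    if target_rows < rows or target_cols < cols:
        raise ValueError(
            f"downscaling not supported: target {(target_rows, target_cols)} "
            f"smaller than mask {(rows, cols)}"
        )
    ri = ((np.arange(target_rows) + 0.5) * rows / target_rows).astype(int)
    ci = ((np.arange(target_cols) + 0.5) * cols / target_cols).astype(int)
    grid = coarse.grid[np.ix_(ri, ci)]
    return ScanMask(grid, provenance=f"upscaled from {rows}x{cols}")


def coverage_stats(mask: ScanMask, config: ScanConfig | None = None) -> dict:
    """Coverage percentage and pixel counts; with a config, also the
    predicted scan durations and time saving for this mask."""
    if mask.grid.size == 0:
        raise ValueError("mask must not be empty")
    n_true = int(np.count_nonzero(mask.grid))
    out = {
        "pixels_total": int(mask.grid.size),
        "pixels_true": n_true,
        "coverage_percent": 100.0 * n_true / mask.grid.size,
    }
    if config is not None:
        f = n_true / mask.grid.size
        full = predict_scan_time(config, 1.0, "stxm_triggered")
        cs = predict_scan_time(config, f, "stxm_triggered")
        out["time_full_s"] = full
        out["time_cs_s"] = cs
        out["time_saving_percent"] = 100.0 * (1.0 - cs / full)
    return out


def mask_from_image(source) -> ScanMask:
    """Boolean mask from a grayscale raster (file path or array),
    thresholded at 50% of the intensity range."""
    img = iio.imread(source) if isinstance(source, (str, bytes)) else np.asarray(source)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    thr = lo + 0.5 * (hi - lo) if hi > lo else 0.5
    return ScanMask(img > thr, provenance="raster import")


def mask_to_scan_path(
    mask: ScanMask,
    config: ScanConfig,
    spare_fraction: float = 0.0,
    seed: int = 0,
) -> list[ScanPathRow]:
    """One row per pixel in scan order, with motor positions computed
    from the scan origin and step (pixel (i, j) -> origin + (j*step, i*step))."""
    if mask.shape != (config.rows, config.cols):
        raise ValueError(
            f"mask shape {mask.shape} does not match scan shape "
            f"{(config.rows, config.cols)}"
        )
    effective = mask.grid | draw_spare_points(mask.grid, spare_fraction, seed)
    rows = []
    for idx, (i, j) in enumerate(config.pixel_order()):
        xrf = int(effective[i, j])
        stxm = 1 if config.stxm_everywhere else xrf
        rows.append(
            ScanPathRow(
                index=idx,
                x=config.origin[0] + j * config.step,
                y=config.origin[1] + i * config.step,
                stxm_flag=stxm,
                xrf_flag=xrf,
                t_stxm=config.t_stxm if stxm else 0.0,
                t_xrf=config.t_xrf if xrf else 0.0,
            )
        )
    return rows


def write_csv(rows: list[ScanPathRow], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for r in rows:
            w.writerow(
                [r.index, f"{r.x:.3f}", f"{r.y:.3f}", r.stxm_flag, r.xrf_flag,
                 f"{r.t_stxm:.6f}", f"{r.t_xrf:.6f}"]
            )


def read_csv(path) -> list[ScanPathRow]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScanPathError("empty scan-path file") from None
        if header != CSV_HEADER:
            raise ScanPathError(f"malformed header {header!r}, expected {CSV_HEADER!r}")
        rows: list[ScanPathRow] = []
        prev = -1
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != 7:
                raise ScanPathError(f"line {lineno}: expected 7 fields, got {len(rec)}")
            try:
                idx = int(rec[0])
                x, y = float(rec[1]), float(rec[2])
                stxm, xrf = int(rec[3]), int(rec[4])
                t_stxm, t_xrf = float(rec[5]), float(rec[6])
            except ValueError as e:
                raise ScanPathError(f"line {lineno}: {e}") from None
            if idx <= prev:
                raise ScanPathError(f"line {lineno}: non-monotone index {idx}")
            prev = idx
            if stxm not in (0, 1) or xrf not in (0, 1):
                raise ScanPathError(f"line {lineno}: flags must be 0 or 1")
            if t_stxm < 0 or t_xrf < 0:
                raise ScanPathError(f"line {lineno}: negative dwell")
            rows.append(ScanPathRow(idx, x, y, stxm, xrf, t_stxm, t_xrf))
    if not rows:
        raise ScanPathError("scan-path file contains no rows")
    return rows


# ----------------------------------------------------------------------
# HDF5 archives
# ----------------------------------------------------------------------

def _write_config_attrs(grp, config: ScanConfig) -> None:
    grp.attrs["rows"] = config.rows
    grp.attrs["cols"] = config.cols
    grp.attrs["step"] = config.step
    grp.attrs["origin_x"] = config.origin[0]
    grp.attrs["origin_y"] = config.origin[1]
    grp.attrs["t_stxm"] = config.t_stxm
    grp.attrs["t_xrf"] = config.t_xrf
    grp.attrs["t_fast"] = config.t_fast
    grp.attrs["t_move"] = config.t_move
    grp.attrs["scan_order"] = config.scan_order
    grp.attrs["elements"] = ",".join(config.elements)
    grp.attrs["stxm_everywhere"] = config.stxm_everywhere
    grp.attrs["noise_sigma"] = config.noise_sigma


def _read_config_attrs(grp) -> ScanConfig:
    a = grp.attrs
    els = str(a["elements"])
    return ScanConfig(
        rows=int(a["rows"]), cols=int(a["cols"]), step=float(a["step"]),
        origin=(float(a["origin_x"]), float(a["origin_y"])),
        t_stxm=float(a["t_stxm"]), t_xrf=float(a["t_xrf"]),
        t_fast=float(a["t_fast"]), t_move=float(a["t_move"]),
        scan_order=str(a["scan_order"]),
        elements=tuple(els.split(",")) if els else (),
        stxm_everywhere=bool(a["stxm_everywhere"]),
        noise_sigma=float(a["noise_sigma"]),
    )


def write_h5(obj, path) -> None:
    """Archive a ScanRecord or GroundTruthSample to HDF5."""
    if isinstance(obj, ScanRecord):
        _write_record(obj, path)
    elif isinstance(obj, GroundTruthSample):
        _write_sample(obj, path)
    else:
        raise TypeError(f"cannot archive object of type {type(obj).__name__}")


def _write_record(rec: ScanRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "scan_record"
        g = f.create_group("stxm")
        g.create_dataset("absorption", data=rec.stxm)
        g.create_dataset("dpc_x", data=rec.dpc_x)
        g.create_dataset("dpc_y", data=rec.dpc_y)
        g.create_dataset("acquired_mask", data=rec.acquired_stxm_mask)
        gx = f.create_group("xrf")
        for el, grid in rec.xrf.items():
            ge = gx.create_group(el)
            ge.create_dataset("counts", data=grid)
            if el in rec.xrf_fast:
                ge.create_dataset("fast_counts", data=rec.xrf_fast[el])
        gx.create_dataset("acquired_mask", data=rec.acquired_xrf_mask)
        gd = f.create_group("diagnostics")
        gd.create_dataset("ring_current", data=rec.ring_current_log)
        gd.create_dataset("bpm", data=rec.bpm_log.T)  # 4 x P
        gd.create_dataset("timestamps", data=rec.timestamps)
        gd.create_dataset("order_index", data=rec.order_index)
        gde = f.create_group("decisions")
        gde.create_dataset("value_compared", data=rec.value_compared)
        gde.create_dataset("threshold_in_force", data=rec.threshold_in_force)
        gdw = f.create_group("dwell")
        gdw.create_dataset("stxm", data=rec.dwell_stxm)
        gdw.create_dataset("fast", data=rec.dwell_fast)
        gdw.create_dataset("long", data=rec.dwell_long)
        gs = f.create_group("scan")
        _write_config_attrs(gs, rec.config)
        gs.attrs["strategy"] = rec.strategy_name
        gs.attrs["threshold"] = rec.threshold
        gs.attrs["normalizer"] = rec.normalizer_method
        gs.attrs["seed"] = rec.seed
        gs.attrs["basis"] = rec.basis
        gs.attrs["elapsed_total"] = rec.elapsed_total
        gs.attrs["reference_current"] = rec.reference_current
        gs.attrs["nominal_flux"] = rec.nominal_flux


def _write_sample(sample: GroundTruthSample, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "ground_truth"
        g = f.create_group("sample")
        g.create_dataset("thickness", data=sample.thickness)
        g.create_dataset("transmission", data=sample.transmission)
        g.create_dataset("dpc_x", data=sample.dpc_x)
        g.create_dataset("dpc_y", data=sample.dpc_y)
        g.create_dataset("support_mask", data=sample.support_mask)
        gr = g.create_group("xrf_rate")
        for el, grid in sample.xrf_rate.items():
            gr.create_dataset(el, data=grid)
        g.attrs["pixel_size"] = sample.pixel_size
        g.attrs["mu"] = sample.mu
        g.attrs["phantom_kind"] = sample.kind


def _require(f, key):
    if key not in f:
        raise SchemaError(f"missing group or dataset {key!r}")
    return f[key]


def read_h5(path):
    """Read back a scan record or ground-truth archive."""
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind")
        if kind == "ground_truth":
            g = _require(f, "sample")
            rates = {el: g["xrf_rate"][el][()] for el in _require(g, "xrf_rate")}
            return GroundTruthSample(
                thickness=g["thickness"][()],
                transmission=g["transmission"][()],
                dpc_x=g["dpc_x"][()],
                dpc_y=g["dpc_y"][()],
                xrf_rate=rates,
                support_mask=g["support_mask"][()].astype(bool),
                pixel_size=float(g.attrs["pixel_size"]),
                mu=float(g.attrs["mu"]),
                kind=str(g.attrs["phantom_kind"]),
            )
        if kind != "scan_record":
            raise SchemaError(f"unrecognized archive kind {kind!r}")
        gs = _require(f, "scan")
        config = _read_config_attrs(gs)
        gst = _require(f, "stxm")
        gx = _require(f, "xrf")
        gd = _require(f, "diagnostics")
        gde = _require(f, "decisions")
        gdw = _require(f, "dwell")
        xrf, xrf_fast = {}, {}
        for el in gx:
            if el == "acquired_mask":
                continue
            xrf[el] = gx[el]["counts"][()]
            if "fast_counts" in gx[el]:
                xrf_fast[el] = gx[el]["fast_counts"][()]
        return ScanRecord(
            config=config,
            stxm=_require(gst, "absorption")[()],
            dpc_x=gst["dpc_x"][()],
            dpc_y=gst["dpc_y"][()],
            xrf=xrf,
            xrf_fast=xrf_fast,
            acquired_xrf_mask=_require(gx, "acquired_mask")[()].astype(bool),
            acquired_stxm_mask=gst["acquired_mask"][()].astype(bool),
            dwell_stxm=gdw["stxm"][()],
            dwell_fast=gdw["fast"][()],
            dwell_long=gdw["long"][()],
            value_compared=gde["value_compared"][()],
            threshold_in_force=gde["threshold_in_force"][()],
            basis=str(gs.attrs["basis"]),
            ring_current_log=_require(gd, "ring_current")[()],
            bpm_log=gd["bpm"][()].T,
            timestamps=gd["timestamps"][()],
            order_index=gd["order_index"][()],
            elapsed_total=float(gs.attrs["elapsed_total"]),
            strategy_name=str(gs.attrs["strategy"]),
            seed=int(gs.attrs["seed"]),
            normalizer_method=str(gs.attrs["normalizer"]),
            threshold=float(gs.attrs["threshold"]),
            reference_current=float(gs.attrs["reference_current"]),
            nominal_flux=float(gs.attrs["nominal_flux"]),
        )
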