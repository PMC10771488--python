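"""Readers and writers with strict validation.

On-disk layouts:

* **Stack, TIFF**: one page per wavelength channel (page order = ascending
  wavelength) plus a JSON sidecar ``<stem>.json`` with the axis centers,
  bandwidth, excitation wavelength, optional pixel size and free-form meta.
* **Stack, HDF5**: ``/intensities`` (rows x cols x channels),
  ``/axis/centers``, root attributes ``excitation_nm`` and ``bandwidth_nm``
  (plus optional ``pixel_size_um``, ``meta`` as a JSON string).
* **Spectra CSV**: header ``wavelength_nm,<name1>,<name2>,...``; one row per
  channel.  Columns are max-normalized on read (with a warning if a rescale
  was needed); negative entries are rejected.
* **ROIs**: JSON list of ``{"label": ..., "vertices": [[row, col], ...]}``.
* **Abundance maps**: one 32-bit float TIFF per endmember plus
  ``residual.tif``, and an 8-bit PNG preview per map (per-map linear min-max
  scaling — stated in the filename suffix — with missing pixels transparent).

Negative counts on read are rejected rather than clipped: they flag an
upstream dark-correction problem that silent clipping would hide.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import (
    NONNEGATIVE,
    AbundanceMaps,
    ElementarySpectrum,
    EndmemberMatrix,
    PolygonROI,
    SpectralAxis,
    SpectralStack,
)
from .errors import AxisError, FormatError

__all__ = [
    "read_stack",
    "write_stack",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_rois",
    "write_rois",
    "write_abundance_maps",
    "RunConfig",
    "load_config",
    "save_config",
]

_PREVIEW_SUFFIX = "_preview_minmax.png"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: SpectralStack, path) -> Path:
    """Write a stack as multi-page TIFF + JSON sidecar, or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("intensities", data=stack.intensities)
            f.create_dataset("axis/centers", data=stack.axis.centers)
            f.attrs["excitation_nm"] = stack.excitation_nm
            f.attrs["bandwidth_nm"] = stack.axis.bandwidth_nm
            if stack.pixel_size_um is not None:
                f.attrs["pixel_size_um"] = stack.pixel_size_um
            f.attrs["meta"] = json.dumps(stack.meta)
        return path
    # TIFF pages are (channel, rows, cols), ascending wavelength
    tifffile.imwrite(path, np.moveaxis(stack.intensities, 2, 0))
    sidecar = {
        "axis_centers_nm": stack.axis.centers.tolist(),
        "bandwidth_nm": stack.axis.bandwidth_nm,
        "excitation_nm": stack.excitation_nm,
        "pixel_size_um": stack.pixel_size_um,
        "meta": stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> SpectralStack:
    """Read a stack written by :func:`write_stack` (TIFF+sidecar or HDF5)."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "intensities" not in f or "axis/centers" not in f:
                raise FormatError("missing /intensities or /axis/centers", path=path)
            if "excitation_nm" not in f.attrs or "bandwidth_nm" not in f.attrs:
                raise FormatError(
                    "missing excitation_nm / bandwidth_nm attributes", path=path
                )
            arr = np.asarray(f["intensities"], dtype=float)
            centers = np.asarray(f["axis/centers"], dtype=float)
            excitation = float(f.attrs["excitation_nm"])
            bandwidth = float(f.attrs["bandwidth_nm"])
            pixel_size = (
                float(f.attrs["pixel_size_um"]) if "pixel_size_um" in f.attrs else None
            )
            meta = json.loads(f.attrs.get("meta", "{}"))
        return _build_stack(arr, centers, bandwidth, excitation, pixel_size, meta, path)

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError("missing JSON sidecar", path=sidecar)
    try:
        side = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}", path=sidecar)
    for key in ("axis_centers_nm", "bandwidth_nm", "excitation_nm"):
        if key not in side:
            raise FormatError("missing required sidecar key", path=sidecar, field=key)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    arr = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
    return _build_stack(
        arr,
        np.asarray(side["axis_centers_nm"], dtype=float),
        float(side["bandwidth_nm"]),
        float(side["excitation_nm"]),
        side.get("pixel_size_um"),
        side.get("meta", {}),
        path,
    )


def _build_stack(arr, centers, bandwidth, excitation, pixel_size, meta, path):
    if arr.shape[2] != centers.size:
        raise FormatError(
            f"{arr.shape[2]} channel pages but {centers.size} axis entries",
            path=path,
            field="axis_centers_nm",
        )
    if np.any(arr < 0):
        raise FormatError(
            "negative counts on read (dark-correction issue upstream?)", path=path
        )
    try:
        axis = SpectralAxis(centers=centers, bandwidth_nm=bandwidth)
        return SpectralStack(
            intensities=arr,
            axis=axis,
            excitation_nm=excitation,
            pixel_size_um=None if pixel_size is None else float(pixel_size),
            meta=dict(meta),
        )
    except (AxisError, ValueError) as exc:
        raise FormatError(str(exc), path=path)


# ---------------------------------------------------------------------------
# spectra CSV


def write_spectra_csv(endmembers: EndmemberMatrix, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"wavelength_nm": endmembers.axis.centers})
    for s in endmembers.spectra:
        df[s.name] = s.values
    df.to_csv(path, index=False)
    return path


def read_spectra_csv(path, axis: SpectralAxis) -> EndmemberMatrix:
    """Read endmember spectra; wavelengths must match ``axis`` within 0.01 nm."""
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    df = pd.read_csv(path)
    if df.columns.size < 2 or df.columns[0] != "wavelength_nm":
        raise FormatError(
            'header must start with "wavelength_nm" and name >= 1 spectrum',
            path=path,
            field="header",
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if wl.size != axis.n_channels or np.any(np.abs(wl - axis.centers) > 0.01):
        raise AxisError(
            f"{path}: wavelength grid does not match the target axis within 0.01 nm"
        )
    spectra = []
    for name in df.columns[1:]:
        values = df[name].to_numpy(dtype=float)
        if np.any(values < 0):
            raise FormatError("negative spectrum value", path=path, field=name)
        peak = values.max()
        if peak > 0 and abs(peak - 1.0) > 1e-9:
            warnings.warn(
                f"{path}: column {name!r} max was {peak:g}; rescaled to 1",
                stacklevel=2,
            )
        spectra.append(ElementarySpectrum(name, values, axis, normalize=True))
    return EndmemberMatrix(spectra)


# ---------------------------------------------------------------------------
# ROIs


def write_rois(rois: Sequence[PolygonROI], path) -> Path:
    path = Path(path)
    payload = [{"label": r.label, "vertices": [list(v) for v in r.vertices]} for r in rois]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_rois(path) -> list[PolygonROI]:
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}", path=path)
    if not isinstance(payload, list):
        raise FormatError("expected a JSON list of ROIs", path=path)
    rois = []
    for i, entry in enumerate(payload):
        verts = entry.get("vertices", [])
        if len(verts) < 3:
            raise FormatError(
                f"ROI #{i} has {len(verts)} vertices; need >= 3",
                path=path,
                field="vertices",
            )
        try:
            rois.append(PolygonROI(verts, label=entry.get("label", f"roi_{i}")))
        except ValueError as exc:
            raise FormatError(f"ROI #{i}: {exc}", path=path, field="vertices")
    return rois


# ---------------------------------------------------------------------------
# abundance maps


def write_abundance_maps(maps: AbundanceMaps, directory) -> list[Path]:
    """Write one float32 TIFF per endmember + residual, plus PNG previews.

    Preview scaling is per map (linear min-max over finite pixels, stated in
    the filename suffix); missing pixels are transparent in the preview.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    items = list(maps.maps.items()) + [("residual", maps.residual)]
    for name, arr in items:
        tif = directory / f"{name}.tif"
        tifffile.imwrite(tif, arr.astype(np.float32))
        written.append(tif)
        finite = np.isfinite(arr)
        lo = float(arr[finite].min()) if finite.any() else 0.0
        hi = float(arr[finite].max()) if finite.any() else 0.0
        scale = (hi - lo) or 1.0
        gray = np.zeros(arr.shape, dtype=np.uint8)
        gray[finite] = np.round(255 * (arr[finite] - lo) / scale).astype(np.uint8)
        alpha = np.where(finite, 255, 0).astype(np.uint8)
        rgba = np.stack([gray, gray, gray, alpha], axis=-1)
        png = directory / f"{name}{_PREVIEW_SUFFIX}"
        Image.fromarray(rgba, mode="RGBA").save(png)
        written.append(png)
    return written


# ---------------------------------------------------------------------------
# run configuration


class RunConfig(BaseModel):
    """Validated run configuration (YAML); unknown keys are rejected.

    A resolved copy (including the seed) is written next to every command's
    outputs for reproducibility.
    """

    model_config = ConfigDict(extra="forbid")

    constraint: str = NONNEGATIVE
    spectra_files: list[str] = Field(default_factory=list)
    shg_name: str = "SHG"
    shg_excitations: list[float] = Field(default_factory=lambda: [920.0])
    peak_tol_nm: float = 10.0
    width_tol_frac: float = 0.25
    max_gaussians: int = 3
    improvement_tol: float = 0.05
    scenario: str | None = None
    shape: tuple[int, int] = (64, 64)
    exposure_scale: float = 1e4
    read_noise_sd: float = 3.0
    noise_enabled: bool = True
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("constraint")
    @classmethod
    def _constraint_known(cls, v):
        if v not in ("nonnegative", "unconstrained"):
            raise ValueError(f"constraint must be nonnegative|unconstrained, got {v!r}")
        return v

    @field_validator("peak_tol_nm", "exposure_scale")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("width_tol_frac", "improvement_tol")
    @classmethod
    def _unit_interval(cls, v, info):
        if not (0 < v < 1):
            raise ValueError(f"{info.field_name} must be in (0, 1)")
        return v

    @field_validator("max_gaussians")
    @classmethod
    def _at_least_one(cls, v):
        if v < 1:
            raise ValueError("max_gaussians must be >= 1")
        return v

    @field_validator("read_noise_sd")
    @classmethod
    def _nonnegative(cls, v):
        if v < 0:
            raise ValueError("read_noise_sd must be >= 0")
        return v


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a YAML mapping", path=path)
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise FormatError(f"invalid configuration: {exc}", path=path)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
    return path
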