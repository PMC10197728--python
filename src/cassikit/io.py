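"""Readers and writers for on-disk artifacts.

Spectral datacubes travel as multi-page 32-bit float TIFF (one page per band)
with a JSON sidecar carrying the wavelength grid, or as a single HDF5 file
with the same metadata in attributes; both round-trip losslessly. Masks are
8-bit PNG/TIFF images (0 opaque, 255 transparent) binarized at 128 on load.
Measurements are 32-bit float TIFF plus a JSON sidecar recording the per-band
shifts, a hash of the mask, and the noise sigma/seed, so a simulation is
reproducible from its artifacts alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .admm import IterationDiagnostics
from .errors import FormatError, MetadataError
from .sensing import Measurement
from .optics import CodedMask, DispersionModel, SpectralDataCube

__all__ = [
    "write_cube",
    "read_cube",
    "write_mask",
    "read_mask",
    "write_measurement",
    "read_measurement",
    "dispersion_to_json",
    "dispersion_from_json",
    "load_config",
    "write_diagnostics_csv",
    "mask_sha256",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_cube(cube: SpectralDataCube, path) -> Path:
    """Write a datacube (TIFF + sidecar, or HDF5 by extension)."""
    path = Path(path)
    values = cube.values.astype(np.float32)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("cube", data=values)
            ds.attrs["band_centers_nm"] = cube.band_centers_nm
            ds.attrs["band_edges_nm"] = cube.band_edges_nm
    else:
        tifffile.imwrite(path, values, photometric="minisblack")
        _sidecar(path).write_text(
            json.dumps(
                {
                    "n_bands": cube.n_bands,
                    "band_centers_nm": cube.band_centers_nm.tolist(),
                    "band_edges_nm": cube.band_edges_nm.tolist(),
                },
                indent=2,
            )
        )
    return path


def read_cube(path) -> SpectralDataCube:
    """Read a datacube written by :func:`write_cube`."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "cube" not in f:
                raise FormatError(f"{path}: no 'cube' dataset")
            ds = f["cube"]
            if "band_centers_nm" not in ds.attrs:
                raise MetadataError(f"{path}: missing wavelength attributes")
            return SpectralDataCube(
                np.asarray(ds, dtype=float),
                np.asarray(ds.attrs["band_centers_nm"]),
                np.asarray(ds.attrs["band_edges_nm"]),
            )
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim == 2:
        values = values[None, :, :]
    if values.shape[0] != meta["n_bands"]:
        raise FormatError(
            f"{path}: {values.shape[0]} TIFF pages but sidecar says L={meta['n_bands']}"
        )
    return SpectralDataCube(
        values, np.asarray(meta["band_centers_nm"]), np.asarray(meta["band_edges_nm"])
    )


def write_mask(mask: CodedMask, path) -> Path:
    """Write a mask as 8-bit image: 0 opaque, 255 transparent."""
    path = Path(path)
    img = (mask.values * 255).astype(np.uint8)
    iio.imwrite(path, img)
    return path


def read_mask(path, feature_px: int = 2) -> CodedMask:
    """Load a grayscale mask image, binarizing at threshold 128."""
    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse any color channels
        img = img[..., :3].mean(axis=-1)
    return CodedMask(values=(img >= 128).astype(float), feature_px=feature_px)


def mask_sha256(mask: CodedMask) -> str:
    return hashlib.sha256(mask.values.astype(np.uint8).tobytes()).hexdigest()


def write_measurement(
    y: Measurement, path, *, shifts, mask: CodedMask | None = None
) -> Path:
    """Write a measurement as float32 TIFF + JSON sidecar (shifts, hash, noise)."""
    path = Path(path)
    tifffile.imwrite(path, y.values.astype(np.float32), photometric="minisblack")
    meta = {
        "shifts": [int(s) for s in shifts],
        "noise_sigma": float(y.noise_sigma),
        "seed": y.seed,
        "mask_sha256": mask_sha256(mask) if mask is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_measurement(path) -> tuple[Measurement, dict]:
    """Read a measurement and its sidecar metadata."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    values = np.asarray(tifffile.imread(path), dtype=float)
    y = Measurement(values, noise_sigma=meta.get("noise_sigma", 0.0), seed=meta.get("seed"))
    return y, meta


def dispersion_to_json(model: DispersionModel, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {"segments": [list(s) for s in model.segments], "reference_nm": model.reference_nm},
            indent=2,
        )
    )
    return path


def dispersion_from_json(path) -> DispersionModel:
    data = json.loads(Path(path).read_text())
    if "segments" not in data:
        raise FormatError(f"{path}: dispersion JSON needs a 'segments' key")
    return DispersionModel(
        segments=tuple(tuple(s) for s in data["segments"]),
        reference_nm=data.get("reference_nm", 445.0),
    )


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


def write_diagnostics_csv(diags: IterationDiagnostics, path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=["iter", "data_residual", "split_residual"])
        writer.writeheader()
        writer.writerows(diags.rows())
    return path
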