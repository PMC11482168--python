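"""File formats and run configuration.

Interferogram stacks travel as multi-page TIFF (frames only, with a YAML
config sidecar) or HDF5 (dataset ``frames`` with the optical metadata as
attributes).  Complex field stacks use HDF5 (dataset ``field``).  Images
and wavefront maps are 32-bit float TIFF; coefficients are CSV; metrics
and provenance are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .core import ComplexFieldStack, InterferogramStack, OpticalConfig, Plane
from .doppler import DopplerBand
from .shack_hartmann import ReferenceMode, SubapertureGrid
from .wavefront import ZernikeCoefficients
from .zernike import mode_count

_CONFIG_FIELDS = [f.name for f in dataclasses.fields(OpticalConfig)]


# ---------------------------------------------------------------- configs

def config_to_yaml(config: OpticalConfig, path) -> None:
    data = {name: getattr(config, name) for name in _CONFIG_FIELDS}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path) -> OpticalConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "n_lateral" in data:
        data["n_lateral"] = int(data["n_lateral"])
    return OpticalConfig(**data)


# ----------------------------------------------------------------- stacks

def write_stack_tiff(path, stack: InterferogramStack) -> None:
    """Frames as multi-page float32 TIFF; config in a ``.yaml`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    config_to_yaml(stack.config, path.with_suffix(path.suffix + ".yaml"))


def read_stack_tiff(path, config: OpticalConfig | None = None
                    ) -> InterferogramStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    if config is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        config = config_from_yaml(sidecar) if sidecar.exists() \
            else OpticalConfig(n_lateral=frames.shape[-1])
    return InterferogramStack(frames, config)


def write_stack_hdf5(path, stack: InterferogramStack) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=stack.frames.astype(np.float32))
        for name in _CONFIG_FIELDS:
            ds.attrs[name] = getattr(stack.config, name)


def read_stack_hdf5(path) -> InterferogramStack:
    with h5py.File(path, "r") as f:
        ds = f["frames"]
        frames = np.asarray(ds, dtype=np.float64)
        kwargs = {name: ds.attrs[name] for name in _CONFIG_FIELDS
                  if name in ds.attrs}
        if "n_lateral" in kwargs:
            kwargs["n_lateral"] = int(kwargs["n_lateral"])
    return InterferogramStack(frames, OpticalConfig(**kwargs))


def write_field_hdf5(path, stack: ComplexFieldStack) -> None:
    """Complex field stack with plane tag and optical metadata."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("field", data=stack.field.astype(np.complex64))
        ds.attrs["plane"] = stack.plane.value
        ds.attrs["z"] = stack.z
        for name in _CONFIG_FIELDS:
            ds.attrs[name] = getattr(stack.config, name)


def read_field_hdf5(path) -> ComplexFieldStack:
    with h5py.File(path, "r") as f:
        ds = f["field"]
        field = np.asarray(ds, dtype=np.complex128)
        plane = Plane(ds.attrs.get("plane", "image"))
        z = float(ds.attrs.get("z", 0.0))
        kwargs = {name: ds.attrs[name] for name in _CONFIG_FIELDS
                  if name in ds.attrs}
        if "n_lateral" in kwargs:
            kwargs["n_lateral"] = int(kwargs["n_lateral"])
    return ComplexFieldStack(field, plane, z, OpticalConfig(**kwargs))


# ----------------------------------------------------------------- images

def write_image_tiff(path, image) -> None:
    """32-bit float TIFF (no quantisation in the compute path)."""
    data = np.asarray(getattr(image, "power", image), dtype=np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


# ----------------------------------------------- coefficients and reports

def write_coefficients_csv(path, coefficients: ZernikeCoefficients) -> None:
    lines = ["n,m,value_um"]
    for (n, m), c in zip(coefficients.mode_set.modes, coefficients.c):
        lines.append(f"{n},{m},{float(c)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients_csv(path):
    """Return (modes, values) parsed from a coefficients CSV."""
    rows = Path(path).read_text().strip().splitlines()[1:]
    modes, values = [], []
    for row in rows:
        n, m, c = row.split(",")
        modes.append((int(n), int(m)))
        values.append(float(c))
    return modes, np.asarray(values)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True)
                          + "\n")


def provenance_record(run_config: "RunConfig", extra: dict | None = None
                      ) -> dict:
    """Machine-readable record sufficient to replay a deterministic run."""
    from . import __version__

    record = {
        "holodop_version": __version__,
        "numpy_version": np.__version__,
        "python_version": sys.version.split()[0],
        "config": dataclasses.asdict(run_config),
    }
    if extra:
        record.update(extra)
    return record


# ------------------------------------------------------------- RunConfig

@dataclass
class RunConfig:
    """Complete configuration of a rendering / correction run.

    Defaults mirror the clinical-scale configuration: 33 kHz frames,
    3-16.5 kHz Doppler band, one 512-frame short-time window, 7x7
    subaperture grid, Zernike radial orders 2-3.
    """

    wavelength: float = 852e-9
    pixel_pitch: float = 28e-6
    n_lateral: int = 768
    eye_length: float = 25e-3
    lens_focal: float = 100e-3
    frame_rate: float = 33e3
    z: float = 0.35
    f_low: float = 3e3
    f_high: float = 16.5e3
    window: int | None = None
    overlap: int = 0
    n_reject: int = 30
    n_side: int = 7
    n_lo: int = 2
    n_hi: int = 3
    reference_mode: str = "resized_full"
    regularization: str = "zernike"
    crop_margin: float = 0.25
    peak_threshold: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.optical_config()  # field-level validation
        DopplerBand(self.f_low, self.f_high).validate_for(self.frame_rate)
        ReferenceMode(self.reference_mode)
        if self.regularization not in ("zernike", "gradient"):
            raise ValueError("regularization must be 'zernike' or "
                             "'gradient'")
        if not 0.0 <= self.crop_margin < 0.45:
            raise ValueError("crop_margin must be in [0, 0.45)")
        if not 0.0 <= self.peak_threshold <= 1.0:
            raise ValueError("peak_threshold must be in [0, 1]")
        grid = SubapertureGrid(n_side=self.n_side, aperture_px=1)
        n_rows = 2 * int(grid.inside_circle.sum())
        p = mode_count(self.n_lo, self.n_hi)
        if n_rows < p:
            raise ValueError(f"{self.n_side}x{self.n_side} grid provides "
                             f"{n_rows} shift components for {p} modes")

    def optical_config(self) -> OpticalConfig:
        return OpticalConfig(self.wavelength, self.pixel_pitch,
                             self.n_lateral, self.eye_length,
                             self.lens_focal, self.frame_rate)

    def doppler_band(self) -> DopplerBand:
        return DopplerBand(self.f_low, self.f_high)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown run-config fields: "
                             f"{sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
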