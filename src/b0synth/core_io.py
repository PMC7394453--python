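"""Volume and sidecar-file I/O for the distortion-correction pipeline.

Conventions used throughout the package:

* the world frame is RAS (right-anterior-superior);
* grid indices are 0-based and voxel centers sit at integer indices;
* all volumes are converted to ``float32`` on load so that training and
  field estimation share one numeric type.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Volume3D",
    "PhaseEncodingSpec",
    "AcqParamsTable",
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "write_acqparams",
    "read_acqparams",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("b0synth")


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel size (mm) and a grid-to-world affine (RAS)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s < 8 for s in self.data.shape):
            raise ValueError(f"all dims must be >= 8, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same geometry but different data."""
        return Volume3D(data, self.voxel_size, self.affine.copy())

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size, self.affine.copy())


@dataclass(frozen=True)
class PhaseEncodingSpec:
    """Phase-encoding axis, blip polarity and total readout time.

    ``readout_time`` is the total EPI readout in seconds; a value of 0
    encodes an acquisition free of susceptibility distortion (the
    infinite-bandwidth limit used to tell the field estimator that a
    reference volume is undistorted).
    """

    axis: int
    polarity: int
    readout_time: float

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError(f"PE axis must be 0, 1 or 2, got {self.axis}")
        if self.polarity not in (1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")
        if self.readout_time < 0:
            raise ValueError("readout_time must be >= 0")

    def flipped(self) -> "PhaseEncodingSpec":
        return PhaseEncodingSpec(self.axis, -self.polarity, self.readout_time)


@dataclass
class AcqParamsTable:
    """A topup-style acquisition-parameters table.

    Each row is a signed unit phase-encode vector (exactly one nonzero
    component, +1 or -1) followed by the total readout time in seconds.
    """

    rows: list[tuple[tuple[int, int, int], float]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("acqparams table needs at least one row")
        for vec, t in self.rows:
            nz = [v for v in vec if v != 0]
            if len(nz) != 1 or nz[0] not in (1, -1):
                raise ValueError(f"PE vector must have one +/-1 entry, got {vec}")
            if t < 0:
                raise ValueError("readout times must be >= 0")

    def to_specs(self) -> list[PhaseEncodingSpec]:
        specs = []
        for vec, t in self.rows:
            axis = int(np.nonzero(vec)[0][0])
            specs.append(PhaseEncodingSpec(axis, int(vec[axis]), t))
        return specs


def read_volume(path: str | Path) -> Volume3D:
    """Load a 3D NIfTI-1 volume (plain or gzipped).

    Intensities are the on-disk values after the format's scl slope and
    intercept are applied, cast to float32. Raises a descriptive error for
    missing files, non-3D images and non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata(dtype=np.float32))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def _format_float(x: float) -> str:
    """Compact fixed text for acqparams numbers ('0', '0.05', '-1')."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def write_acqparams(
    specs: Sequence[PhaseEncodingSpec], path: str | Path | None = None
) -> AcqParamsTable:
    """Serialize phase-encoding specs as a topup acquisition-parameters table.

    One text row per spec: three signed PE-vector components then the
    readout time in seconds, whitespace-separated, with the polarity placed
    in the column of the PE axis. All specs must share one axis. The table
    is returned and, if ``path`` is given, also written as plain text.
    """
    if not specs:
        raise ValueError("need at least one phase-encoding spec")
    axes = {s.axis for s in specs}
    if len(axes) > 1:
        raise ValueError(f"all specs must share one PE axis, got axes {sorted(axes)}")
    rows = []
    for s in specs:
        vec = [0, 0, 0]
        vec[s.axis] = s.polarity
        rows.append((tuple(vec), float(s.readout_time)))
    table = AcqParamsTable(rows)
    if path is not None:
        lines = [
            " ".join([str(v) for v in vec] + [_format_float(t)]) for vec, t in rows
        ]
        Path(path).write_text("\n".join(lines) + "\n")
    return table


def read_acqparams(path: str | Path) -> AcqParamsTable:
    """Parse a topup-style acquisition-parameters text file."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"acqparams rows need 4 columns, got: {line!r}")
        vec = tuple(int(float(p)) for p in parts[:3])
        rows.append((vec, float(parts[3])))
    return AcqParamsTable(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, dict[str, tuple[float, float]]] = {
    # section -> key -> (lo, hi) inclusive numeric range
    "phantom": {
        "grid": (16, 512),
        "voxel_size_mm": (0.1, 10.0),
        "field_amplitude_hz": (0.0, 500.0),
        "field_smoothness_vox": (1.0, 64.0),
        "n_hotspots": (0, 16),
        "noise_sd": (0.0, 1e4),
    },
    "normalization": {
        "t1_low": (0.0, 0.0),
        "t1_high": (1.0, 1e4),
        "b0_percentile": (50.0, 100.0),
    },
    "network": {
        "levels": (2, 6),
        "base_channels": (4, 256),
        "leaky_slope": (0.0, 1.0),
    },
    "training": {
        "epochs": (1, 10000),
        "learning_rate": (1e-8, 1.0),
        "weight_decay": (0.0, 1.0),
        "folds": (2, 50),
        "batch_size": (1, 64),
    },
    "field_estimation": {
        "smoothness_lambda": (0.0, 1e6),
        "max_iterations": (1, 1000),
        "tolerance": (1e-12, 1.0),
    },
    "seed": {},
}

_DEFAULT_CONFIG = {
    "phantom": {
        "grid": 48,
        "voxel_size_mm": 2.5,
        "field_amplitude_hz": 50.0,
        "field_smoothness_vox": 6.0,
        "n_hotspots": 2,
        "noise_sd": 10.0,
    },
    "normalization": {"t1_low": 0.0, "t1_high": 150.0, "b0_percentile": 99.0},
    "network": {"levels": 3, "base_channels": 16, "leaky_slope": 0.01},
    "training": {
        "epochs": 100,
        "learning_rate": 1e-4,
        "weight_decay": 1e-5,
        "folds": 5,
        "batch_size": 1,
    },
    "field_estimation": {
        "smoothness_lambda": 0.02,
        "max_iterations": 25,
        "tolerance": 1e-7,
    },
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (phantom, normalization, network,
    training, field estimation, seed)."""

    values: dict = field(default_factory=lambda: _deep_copy(_DEFAULT_CONFIG))

    def __getitem__(self, key: str):
        return self.values[key]


def _deep_copy(d):
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config, merged over the documented defaults.

    Unknown sections or keys are rejected; every numeric value is checked
    against its documented range.
    """
    values = _deep_copy(_DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("config root must be a mapping")
        for section, content in user.items():
            if section not in _CONFIG_SCHEMA:
                raise ValueError(f"unknown config section: {section!r}")
            if section == "seed":
                values["seed"] = int(content)
                continue
            if not isinstance(content, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, val in content.items():
                if key not in _CONFIG_SCHEMA[section]:
                    raise ValueError(f"unknown config key: {section}.{key}")
                values[section][key] = val
    for section, keys in _CONFIG_SCHEMA.items():
        if section == "seed":
            if not isinstance(values["seed"], int):
                raise ValueError("seed must be an integer")
            continue
        for key, (lo, hi) in keys.items():
            val = values[section][key]
            if not isinstance(val, (int, float)) or not (lo <= val <= hi):
                raise ValueError(
                    f"config {section}.{key}={val!r} outside [{lo}, {hi}]"
                )
    return PipelineConfig(values)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Structured logging to stderr plus an optional per-run logfile."""
    log.setLevel(level)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    log.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(str(logfile))
        fh.setFormatter(fmt)
        log.addHandler(fh)
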