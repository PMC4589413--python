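"""NIfTI and table I/O plus pipeline configuration."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import SeriesVolume, VolumeGrid
from .synthetic import CALLOSAL_COLUMNS

__all__ = [
    "DimensionError",
    "read_volume",
    "write_volume",
    "read_callosal_table",
    "write_callosal_table",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class DimensionError(ValueError):
    """Raised when a volume file does not have the expected dimensionality."""


def _affine(voxel_size: float, spatial_shape) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = -(np.asarray(spatial_shape) - 1) / 2.0 * voxel_size
    return aff


def write_volume(obj, path) -> None:
    """Write a :class:`VolumeGrid` or :class:`SeriesVolume` as NIfTI-1.

    The affine centres the grid so x = 0 lies on the midsagittal mirror
    plane; 4D volumes store the repetition interval in the time zoom.
    """
    data = np.asarray(obj.data, dtype=np.float64)
    img = nib.Nifti1Image(data, _affine(obj.voxel_size, obj.spatial_shape))
    v = float(obj.voxel_size)
    if isinstance(obj, SeriesVolume):
        img.header.set_zooms((v, v, v, float(obj.tr)))
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_zooms((v, v, v))
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path, kind: str | None = None):
    """Read a NIfTI file as a :class:`VolumeGrid` (3D) or :class:`SeriesVolume` (4D).

    ``kind`` may be ``'volume'`` or ``'series'`` to enforce dimensionality;
    a mismatch raises :class:`DimensionError`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()
    voxel = float(zooms[0])
    if data.ndim == 3:
        if kind == "series":
            raise DimensionError(f"expected a 4D series, got 3D volume: {path}")
        return VolumeGrid(data, voxel)
    if data.ndim == 4:
        if kind == "volume":
            raise DimensionError(f"expected a 3D volume, got 4D series: {path}")
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return SeriesVolume(data, voxel, tr)
    raise DimensionError(f"unsupported dimensionality {data.ndim} in {path}")


def write_callosal_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=CALLOSAL_COLUMNS)


def read_callosal_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CALLOSAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"callosal table is missing columns: {missing}")
    return table


_TUPLE_FIELDS = {"grid_shape"}


@dataclass
class PipelineConfig:
    """End-to-end configuration; numeric defaults follow the reference analysis."""

    # stage toggles
    run_simulate: bool = True
    run_symmetrize: bool = True
    run_vmhc: bool = True
    run_group: bool = True
    run_morpho: bool = True
    # simulation
    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: float = 2.0
    n_timepoints: int = 120
    tr_s: float = 2.0
    ar_coefficient: float = 0.3
    smoothing_fwhm_mm: float = 4.0
    baseline_rho: float = 0.2
    effect_delta_rho: float = 0.3
    effect_box: list = field(default_factory=lambda: [[1, 5], [6, 10], [6, 10]])
    n_subjects_per_group: int = 6
    # preprocessing
    n_discard: int = 4
    detrend_knot_spacing: int = 60
    temporal_fwhm_s: float = 4.0
    # symmetrization
    polynomial_degree: int = 5
    n_restarts: int = 5
    symmetrize_maxiter: int | None = None
    # symmetry mapping / group stats
    n_pairs: int = 1000
    alpha: float = 0.01
    voxel_z: float = 2.32
    cluster_p: float = 0.001
    n_null: int = 10000
    acf_runs: int = 10
    mask_p: float = 0.0005
    connectivity: int = 18
    null_tail: str = "image"
    # morphometry simulation
    cc_n_per_group: int = 18
    cc_brain_r: float = 0.46
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.effect_box = [list(map(int, pair)) for pair in self.effect_box]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return PipelineConfig.from_dict(d)
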