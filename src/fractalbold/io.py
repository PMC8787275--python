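"""File I/O: NIfTI-1 volumes and atlases, motion TSVs, series CSVs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import LabelAtlas, UniformTimeSeries, Volume4D, VoxelMap

__all__ = [
    "write_volume", "read_volume",
    "write_atlas", "read_atlas",
    "write_map", "read_map",
    "read_motion_tsv", "write_motion_tsv",
    "read_series_csv", "write_series_csv",
    "MOTION_COLUMNS",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_volume(volume: Volume4D, path: Union[str, Path]) -> None:
    """4-D float32 NIfTI-1 with the TR stored in pixdim[4]."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(tuple(volume.voxel_size) + (volume.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(path: Union[str, Path]) -> Volume4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4-D volume")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data, voxel_size=tuple(float(z) for z in zooms[:3]),
                    tr=tr, affine=np.asarray(img.affine))


def write_atlas(atlas: LabelAtlas, path: Union[str, Path],
                affine: Optional[np.ndarray] = None) -> None:
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), aff), str(path))


def read_atlas(path: Union[str, Path], legend: Optional[dict] = None) -> LabelAtlas:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    return LabelAtlas(np.rint(labels).astype(np.int16), legend or {})


def write_map(vmap: VoxelMap, path: Union[str, Path],
              affine: Optional[np.ndarray] = None) -> None:
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vmap.data.astype(np.float32), aff), str(path))


def read_map(path: Union[str, Path], kind: str = "hurst") -> VoxelMap:
    img = nib.load(str(path))
    return VoxelMap(np.asanyarray(img.dataobj).astype(float), kind=kind)


def read_motion_tsv(path: Union[str, Path], degrees: bool = False) -> pd.DataFrame:
    """Six-column motion table (translations mm, rotations rad).

    A header row is optional; ``degrees=True`` converts rotation columns
    from degrees to radians on read.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = first.iloc[0].astype(str).str.contains("[a-zA-Z]").any()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(f"{path} must have exactly six columns")
    df.columns = MOTION_COLUMNS
    df = df.astype(float)
    if degrees:
        df[MOTION_COLUMNS[3:]] = np.deg2rad(df[MOTION_COLUMNS[3:]])
    return df


def write_motion_tsv(params: pd.DataFrame, path: Union[str, Path]) -> None:
    params.to_csv(path, sep="\t", index=False, columns=MOTION_COLUMNS)


def read_series_csv(path: Union[str, Path],
                    sampling_interval: Optional[float] = None) -> UniformTimeSeries:
    """1-D series from CSV: either a single value column, or (time, value)
    columns from which the sampling interval is inferred."""
    df = pd.read_csv(path)
    if df.shape[1] == 1:
        if sampling_interval is None:
            raise ValueError("sampling_interval required for value-only CSV")
        return UniformTimeSeries(df.iloc[:, 0].to_numpy(float), sampling_interval)
    t = df.iloc[:, 0].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    return UniformTimeSeries(df.iloc[:, 1].to_numpy(float),
                             sampling_interval if sampling_interval else dt)


def write_series_csv(series: UniformTimeSeries, path: Union[str, Path],
                     value_name: str = "value") -> None:
    t = np.arange(len(series)) * series.sampling_interval
    pd.DataFrame({"time": t, value_name: series.values}).to_csv(path, index=False)
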