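"""File I/O: NIfTI series and maps, TrackVis/VTK pathlines, configs, manifests.

The on-disk contract: 4D NIfTI for image series (one 3D volume per frame,
uniform isotropic voxels required), 3D NIfTI for masks and derived maps,
TrackVis ``.trk`` and legacy-ASCII VTK polylines for pathlines with their
per-point speeds, CSV for tabular summaries, YAML/JSON for configuration,
and a JSON run manifest with checksums so every artifact is reproducible
from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import ImageGrid, ScalarField
from .lagrangian import PathlineSet
from .preprocess import DensitySeries

__all__ = [
    "grid_from_nifti",
    "read_series",
    "write_series",
    "read_mask",
    "write_scalar_field",
    "write_velocity_series",
    "write_trk",
    "write_vtk_polylines",
    "load_config",
    "file_checksum",
]


def grid_from_nifti(img: nib.Nifti1Image) -> ImageGrid:
    """Build the computational grid from a NIfTI header (uniform dx required)."""
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(
            f"anisotropic voxels {tuple(float(z) for z in zooms)}; the transport grid "
            "assumes a uniform edge length — resample the input first"
        )
    dims = img.shape[:3]
    return ImageGrid(dims=tuple(int(d) for d in dims), voxel_size=float(zooms[0]),
                     affine=np.asarray(img.affine, dtype=float))


def read_series(
    path, times=None, baseline_count: int = 1, units: str = "raw"
) -> DensitySeries:
    """Read a 4D NIfTI (or list of 3D volumes) as a density series.

    Frame times come from ``times`` (minutes) or, failing that, the header
    TR; all frames must share one grid and be finite.
    """
    if isinstance(path, (list, tuple)):
        imgs = [nib.load(str(p)) for p in path]
        grid = grid_from_nifti(imgs[0])
        data = []
        for p, img in zip(path, imgs):
            if img.shape[:3] != grid.dims or not np.allclose(img.affine, grid.affine, atol=1e-4):
                raise ValueError(f"frame {p} is not on the same grid as the first frame")
            data.append(np.asarray(img.dataobj, dtype=float).reshape(grid.dims))
        stack = np.stack(data)
    else:
        img = nib.load(str(path))
        if img.ndim != 4:
            raise ValueError(f"expected a 4D series, got shape {img.shape}")
        grid = grid_from_nifti(img)
        stack = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    n_bad = int((~np.isfinite(stack)).sum())
    if n_bad:
        raise ValueError(f"series contains {n_bad} non-finite voxels")
    n = len(stack)
    if times is None:
        tr = 1.0
        if not isinstance(path, (list, tuple)):
            zooms = nib.load(str(path)).header.get_zooms()
            if len(zooms) > 3 and zooms[3] > 0:
                tr = float(zooms[3])
        times = np.arange(n) * tr
    frames = [ScalarField(grid, fr) for fr in stack]
    return DensitySeries(frames=frames, times=np.asarray(times, float),
                         baseline_count=baseline_count, units=units)


def write_series(series: DensitySeries, path) -> Path:
    data = np.moveaxis(series.as_array(), 0, -1)
    img = nib.Nifti1Image(data.astype(np.float64), series.grid.affine)
    img.header.set_zooms((*[series.grid.voxel_size] * 3, float(np.median(np.diff(series.times)) if series.n_frames > 1 else 1.0)))
    nib.save(img, str(path))
    return Path(path)


def read_mask(path, grid: ImageGrid) -> np.ndarray:
    img = nib.load(str(path))
    if img.shape[:3] != grid.dims:
        raise ValueError(f"mask {path} shape {img.shape[:3]} does not match grid {grid.dims}")
    return np.asarray(img.dataobj) > 0


def write_scalar_field(field: ScalarField, path) -> Path:
    img = nib.Nifti1Image(field.values.astype(np.float64), field.grid.affine)
    nib.save(img, str(path))
    return Path(path)


def write_velocity_series(velocities, path) -> Path:
    """Stack per-step vector fields as a 5D (x, y, z, step, component) NIfTI."""
    arr = np.stack([v.components for v in velocities])  # (T, 3, m1, m2, m3)
    data = np.transpose(arr, (2, 3, 4, 0, 1)).astype(np.float64)
    img = nib.Nifti1Image(data, velocities[0].grid.affine)
    nib.save(img, str(path))
    return Path(path)


def write_trk(pset: PathlineSet, path) -> Path:
    """TrackVis export; points are world (RAS) mm, speeds as per-point scalars."""
    from nibabel import streamlines as nibs

    tractogram = nibs.Tractogram(
        streamlines=[pl.points.astype(np.float32) for pl in pset.pathlines],
        data_per_point={"speed": [pl.speeds[:, None].astype(np.float32) for pl in pset.pathlines]},
        affine_to_rasmm=np.eye(4),
    )
    header = {
        nibs.trk.Field.VOXEL_TO_RASMM: pset.grid.affine.astype(np.float32),
        nibs.trk.Field.VOXEL_SIZES: tuple([pset.grid.voxel_size] * 3),
        nibs.trk.Field.DIMENSIONS: pset.grid.dims,
    }
    nibs.save(nibs.trk.TrkFile(tractogram, header), str(path))
    return Path(path)


def write_vtk_polylines(pset: PathlineSet, path) -> Path:
    """Legacy-ASCII VTK polydata with per-point speed scalars."""
    lines = [
        "# vtk DataFile Version 3.0",
        "pathlines with per-point speed",
        "ASCII",
        "DATASET POLYDATA",
    ]
    n_pts = sum(len(pl.points) for pl in pset.pathlines)
    lines.append(f"POINTS {n_pts} float")
    for pl in pset.pathlines:
        for p in pl.points:
            lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    n_lines = len(pset.pathlines)
    size = sum(len(pl.points) + 1 for pl in pset.pathlines)
    lines.append(f"LINES {n_lines} {size}")
    offset = 0
    for pl in pset.pathlines:
        k = len(pl.points)
        lines.append(" ".join([str(k)] + [str(offset + i) for i in range(k)]))
        offset += k
    lines += [f"POINT_DATA {n_pts}", "SCALARS speed float 1", "LOOKUP_TABLE default"]
    for pl in pset.pathlines:
        lines += [f"{s:.6g}" for s in pl.speeds]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def load_config(path) -> dict:
    """YAML or JSON configuration file -> dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
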