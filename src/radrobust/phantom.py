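"""Miniature PET phantom fixture: blob volumes, resampling, NIfTI I/O.

A tiny stand-in for a whole-body FDG-PET acquisition: a 3-D SUV-valued
volume containing one or more spherical high-uptake blobs on a (optionally
noisy) background, plus a boolean tumour mask covering the blobs. Together
with the discretisation and first-order features in :mod:`.synthetic` it
lets the full pipeline be exercised end-to-end — image in, feature table
out — without any download. It is synthetic and deliberately minimal: no
point-spread function, no reconstruction artefacts, and only
nearest-neighbour and linear resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Blob",
    "PhantomSpec",
    "generate_phantom",
    "resample_volume",
    "write_nifti",
    "phantom_feature_table",
]


@dataclass(frozen=True)
class Blob:
    """Sphere of elevated uptake: centre (mm, physical space), radius (mm),
    intensity (SUV)."""

    centre: tuple[float, float, float]
    radius: float
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    blobs: tuple[Blob, ...] = ()
    background_sd: float = 0.0
    background_mean: float = 0.5
    seed: int = 0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SUV volume + boolean tumour mask from a spec.

    Voxel (i, j, k) has physical centre ((i+0.5)*dx, (j+0.5)*dy,
    (k+0.5)*dz); a voxel belongs to a blob when its centre lies within the
    blob's radius. Intensities are clipped at zero.
    """
    if not spec.blobs:
        raise ValueError("phantom needs at least one blob")
    shape = tuple(int(s) for s in spec.shape)
    extent = np.asarray(shape) * np.asarray(spec.voxel_size)
    for b in spec.blobs:
        c = np.asarray(b.centre)
        if (c - b.radius < 0).any() or (c + b.radius > extent).any():
            raise ValueError(f"blob at {b.centre} extends outside the volume")
    rng = np.random.default_rng(spec.seed)
    vol = np.full(shape, spec.background_mean, dtype=float)
    if spec.background_sd > 0:
        vol += rng.normal(0.0, spec.background_sd, shape)
    centres = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spec.voxel_size)
    ]
    xx, yy, zz = np.meshgrid(*centres, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for b in spec.blobs:
        inside = (
            (xx - b.centre[0]) ** 2
            + (yy - b.centre[1]) ** 2
            + (zz - b.centre[2]) ** 2
        ) <= b.radius**2
        vol[inside] = b.intensity + (
            rng.normal(0.0, spec.background_sd, int(inside.sum()))
            if spec.background_sd > 0
            else 0.0
        )
        mask |= inside
    if not mask.any():
        raise ValueError("tumour mask is empty; enlarge a blob")
    return np.clip(vol, 0.0, None), mask


def _to_sitk(volume: np.ndarray, voxel_size: tuple[float, float, float]):
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume, dtype=float))
    # numpy (i, j, k) -> sitk (z, y, x): reverse the spacing triple
    img.SetSpacing(tuple(float(s) for s in voxel_size[::-1]))
    return img


def resample_volume(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    target: float,
    method: str = "linear",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Centre-aligned resampling onto an isotropic ``target``-mm grid.

    ``method`` is ``linear`` or ``nearest_neighbour``; nearest-neighbour
    output intensities are a subset of the input intensities.
    """
    if target <= 0:
        raise ValueError("target voxel size must be positive")
    interp = {
        "linear": sitk.sitkLinear,
        "nearest_neighbour": sitk.sitkNearestNeighbor,
    }.get(method)
    if interp is None:
        raise ValueError(f"unsupported interpolator {method!r}")
    img = _to_sitk(volume, voxel_size)
    in_size = np.asarray(img.GetSize(), dtype=float)
    in_spacing = np.asarray(img.GetSpacing(), dtype=float)
    out_size = np.maximum(
        1, np.round(in_size * in_spacing / target)
    ).astype(int)
    # align the physical centres of the input and output grids; the sitk
    # origin is the centre of the first voxel
    in_centre = (in_size - 1) * in_spacing / 2.0
    out_origin = in_centre - (out_size - 1) * target / 2.0
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing((float(target),) * 3)
    resampler.SetSize([int(s) for s in out_size])
    resampler.SetOutputOrigin(tuple(float(o) for o in out_origin))
    resampler.SetInterpolator(interp)
    resampler.SetDefaultPixelValue(0.0)
    out = resampler.Execute(img)
    return sitk.GetArrayFromImage(out), (float(target),) * 3


def write_nifti(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    path: str | Path,
) -> None:
    """Write a volume (or boolean mask) as NIfTI."""
    arr = volume.astype(np.uint8) if volume.dtype == bool else volume
    sitk.WriteImage(_to_sitk(arr, voxel_size), str(path))


def phantom_feature_table(
    volume: np.ndarray,
    mask: np.ndarray,
    subject_id: str,
    grid,
):
    """First-order entropy/uniformity of the masked phantom over one grid.

    Returns long-format rows for the two fixture features across the
    grid's parameter values (bin widths, bin numbers, or voxel sizes with
    the grid's interpolator), mirroring what an external extractor would
    produce from the phantom.
    """
    import pandas as pd

    from .grids import Algorithm, Scheme
    from .synthetic import (
        fbn_discretise,
        fbw_discretise,
        first_order_entropy,
        first_order_uniformity,
    )

    rows = []
    for value in grid.values:
        if grid.algorithm is Algorithm.FBW:
            idx = fbw_discretise(volume[mask], value)
        elif grid.algorithm is Algorithm.FBN:
            idx = fbn_discretise(volume[mask], int(value))
        else:
            method = (
                "nearest_neighbour"
                if grid.algorithm is Algorithm.NEAREST_NEIGHBOUR
                else "linear"
            )
            vol_r, _ = resample_volume(volume, (2.0, 2.0, 2.0), value, method)
            mask_r, _ = resample_volume(
                mask.astype(float), (2.0, 2.0, 2.0), value, "nearest_neighbour"
            )
            sel = mask_r > 0.5
            if not sel.any():
                continue
            idx = fbn_discretise(vol_r[sel], 64)  # 64-bin convention
        for name, fn in (
            ("firstorder_Entropy", first_order_entropy),
            ("firstorder_Uniformity", first_order_uniformity),
        ):
            rows.append(
                {
                    "subject_id": subject_id,
                    "feature_name": name,
                    "scheme": grid.scheme.value,
                    "algorithm": grid.algorithm.value,
                    "parameter_value": value,
                    "value": fn(idx),
                }
            )
    return pd.DataFrame(rows)
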