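"""Sphere-based ROI time-series extraction from 4-D NIfTI volumes.

Convenience entry point for users whose data are still volumetric: averages
the BOLD signal over all voxels whose centers fall within a sphere of given
radius around each parcel coordinate (MNI mm, RAS+). Everything downstream
consumes the resulting (T, R) matrix.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .parcellation import ParcelTable
from .synthetic import SubjectTimeSeries

__all__ = ["extract_roi_timeseries"]


def extract_roi_timeseries(
    nifti_volume,
    parcel_table: ParcelTable,
    radius_mm: float = 5.0,
    subject_id: str = "sub-000",
) -> SubjectTimeSeries:
    """Mean signal in a sphere of ``radius_mm`` around each parcel coordinate.

    ``nifti_volume`` is a path or a loaded ``nibabel`` image, 4-D (x, y, z, t),
    with an affine mapping voxel indices to the same mm space as the parcel
    coordinates. A sphere containing no voxel centers raises, naming the
    region.
    """
    img = nib.load(str(nifti_volume)) if not isinstance(nifti_volume, nib.Nifti1Image) else nifti_volume
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    nx, ny, nz, n_t = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    voxels = np.column_stack((ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)))
    centers_mm = (voxels @ img.affine.T)[:, :3]
    flat = data.reshape(-1, n_t)

    series = np.empty((n_t, parcel_table.n_regions))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    for col, (rid, center) in enumerate(zip(parcel_table.region_ids, parcel_table.coords)):
        mask = np.sum((centers_mm - center) ** 2, axis=1) <= radius_mm**2
        if not mask.any():
            raise ValueError(
                f"region {rid}: sphere of radius {radius_mm} mm at {center.tolist()} "
                "contains no voxel centers (outside field of view?)"
            )
        series[:, col] = flat[mask].mean(axis=0)
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=series,
        region_ids=np.asarray(parcel_table.region_ids),
        tr_seconds=tr,
    )
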