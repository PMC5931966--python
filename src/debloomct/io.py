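"""Volume I/O: NIfTI read/write (canonical format) and DICOM series read."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .volume import ImageVolume


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz), spacing in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an ImageVolume.

    Raises
    ------
    ValueError
        If the file carries no usable spacing metadata.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        return read_dicom_series(path)
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: missing or invalid voxel spacing {zooms}; "
            "set pixdim in the NIfTI header before loading"
        )
    voxels = np.asanyarray(img.dataobj).astype(np.float64)
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(voxels, tuple(float(z) for z in zooms), origin)


def apply_rescale(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Stored DICOM pixel values to HU: ``stored * slope + intercept``."""
    return np.asarray(stored, dtype=np.float64) * float(slope) + float(intercept)


def read_dicom_series(directory) -> ImageVolume:
    """Read a single-series DICOM directory (HU via rescale slope/intercept).

    Requires the optional ``pydicom`` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "reading DICOM requires the optional 'pydicom' package "
            "(pip install pydicom); alternatively convert the series to NIfTI"
        ) from exc

    directory = os.fspath(directory)
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{directory}: no readable DICOM slices found")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(apply_rescale(ds.pixel_array, slope, intercept))
    vox = np.stack(planes, axis=-1)  # (row, col, slice)

    ds0 = slices[0]
    if not hasattr(ds0, "PixelSpacing"):
        raise ValueError(f"{directory}: DICOM series lacks PixelSpacing metadata")
    dy, dx = (float(v) for v in ds0.PixelSpacing)
    if len(slices) > 1:
        dz = abs(z_of(slices[1]) - z_of(slices[0])) or float(
            getattr(ds0, "SliceThickness", 1.0)
        )
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    origin = (0.0, 0.0, 0.0)
    if hasattr(ds0, "ImagePositionPatient"):
        origin = tuple(float(v) for v in ds0.ImagePositionPatient)
    return ImageVolume(vox, (dx, dy, dz), origin)
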