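"""Lumen, stenosis, calcium-volume and SNR measurements on HU volumes.

Lumen segmentation follows the full-width-at-half-maximum caliper
convention: a voxel belongs to the lumen when its HU exceeds the midpoint
between an in-image lumen reference and an in-image background reference,
and stays below the calcium threshold.  Because both references are read
from the image itself, the measurements are insensitive to small global HU
offsets and to the display window (the printed 1500/300 window is kept only
for rendering).

Diameter stenosis is measured along the line through the vessel center and
the calcium centroid (the diameter through the plaque), matching clinical
caliper practice for eccentric plaques; plaque-free lesions fall back to
the area-equivalent diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

#: Display window (width, level) used for rendered QC images.
DEFAULT_WINDOW = (1500.0, 300.0)
#: HU threshold separating calcium from contrast-enhanced lumen.  Chosen
#: above the contrast range (<= 365 HU) by more than 5 sigma of the noisiest
#: kernel, yet below the post-blur peak of even sub-millimetre plaques so
#: small calcifications stay detectable after PSF blur.
DEFAULT_CALCIUM_THRESHOLD = 450.0


class MeasurementError(RuntimeError):
    """Raised when a measurement cannot be made (e.g. no lumen found)."""


@dataclass
class SNRMeasurement:
    ct_vessel: float  # mean HU in the plaque-free lumen ROI
    sd_periphery: float  # SD of HU in the background ROI (image noise)
    snr: float | None  # ct_vessel / sd_periphery; None when undefined
    noise: float  # alias of sd_periphery

    @property
    def undefined(self) -> bool:
        return self.snr is None


@dataclass
class PlaqueQuant:
    """Per-plaque quantification of one image volume."""

    calcium_volume: float  # mm^3
    diameter_stenosis_pct: float
    area_stenosis_pct: float


@dataclass
class StenosisRecord:
    """Reference vs measured stenosis for one plaque under one kernel."""

    vessel_id: str
    plaque_id: str
    kernel: str
    true_stenosis_pct: float
    measured_pct_original: float | None = None
    measured_pct_debloomed: float | None = None


def calcium_volume(image: ImageVolume, threshold: float = DEFAULT_CALCIUM_THRESHOLD) -> float:
    """Volume (mm^3) of voxels at or above the calcium threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return float(np.count_nonzero(image.voxels >= threshold) * image.voxel_volume)


def snr(image: ImageVolume, vessel_roi: np.ndarray, periphery_roi: np.ndarray) -> SNRMeasurement:
    """Signal-to-noise ratio: mean vessel HU over periphery HU standard deviation."""
    vessel_roi = np.asarray(vessel_roi, dtype=bool)
    periphery_roi = np.asarray(periphery_roi, dtype=bool)
    if vessel_roi.shape != image.shape or periphery_roi.shape != image.shape:
        raise ValueError("ROI masks must match the image shape")
    if not vessel_roi.any() or not periphery_roi.any():
        raise ValueError("ROIs must be non-empty")
    if np.any(vessel_roi & periphery_roi):
        raise ValueError("vessel and periphery ROIs must be disjoint")
    ct_vessel = float(image.voxels[vessel_roi].mean())
    sd = float(image.voxels[periphery_roi].std(ddof=1))
    ratio = ct_vessel / sd if sd > 0 else None
    return SNRMeasurement(ct_vessel=ct_vessel, sd_periphery=sd, snr=ratio, noise=sd)


# -- stenosis -----------------------------------------------------------


def _as_slice(sl) -> slice:
    if isinstance(sl, slice):
        return sl
    lo, hi = sl
    return slice(int(lo), int(hi))


def _lumen_mask_2d(plane: np.ndarray, half_max: float, calcium_threshold: float) -> np.ndarray:
    return (plane >= half_max) & (plane < calcium_threshold)


def _max_run_length(flags: np.ndarray, step: float) -> float:
    """Length of the longest contiguous True run, in mm."""
    if not flags.any():
        return 0.0
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return float((stops - starts).max() * step)


def _stenosis_measurements(
    image: ImageVolume,
    axis: int,
    reference_slices,
    lesion_slices,
    calcium_threshold: float,
    center: tuple[float, float] | None,
    profile_step_mm: float = 0.02,
):
    """Shared machinery for diameter and area stenosis.

    Returns ``(diameter_pct, area_pct)``.  ``center`` is the in-plane voxel
    coordinate of the vessel axis; by default the grid center (phantoms are
    generated centered).
    """
    vox = np.moveaxis(image.voxels, axis, 2)
    sp = list(image.spacing)
    dz = sp.pop(axis)
    dx, dy = sp  # in-plane spacings in array order after the move
    nx, ny, nz = vox.shape
    ref_sl = _as_slice(reference_slices)
    les_sl = _as_slice(lesion_slices)
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = center
    icx, icy = int(round(cx)), int(round(cy))

    ref = vox[:, :, ref_sl]
    if ref.shape[2] == 0 or vox[:, :, les_sl].shape[2] == 0:
        raise MeasurementError("empty reference or lesion slice range")

    # in-image references: lumen HU at the vessel center, background HU at
    # the volume border (5-voxel frame)
    hu_lumen = float(ref[icx - 1 : icx + 2, icy - 1 : icy + 2, :].mean())
    frame = np.ones((nx, ny), dtype=bool)
    frame[5:-5, 5:-5] = False
    hu_background = float(ref[frame, :].mean())
    if hu_lumen <= hu_background:
        raise MeasurementError(
            f"no lumen detected at reference center (lumen {hu_lumen:.0f} HU "
            f"<= background {hu_background:.0f} HU)"
        )
    half_max = 0.5 * (hu_lumen + hu_background)

    pixel_area = dx * dy

    def lumen_area(plane: np.ndarray) -> float:
        return float(
            np.count_nonzero(_lumen_mask_2d(plane, half_max, calcium_threshold)) * pixel_area
        )

    ref_areas = [lumen_area(ref[:, :, k]) for k in range(ref.shape[2])]
    ref_area = float(np.mean(ref_areas))
    if ref_area <= 0:
        raise MeasurementError("no lumen detected in reference slices")
    ref_diameter = 2.0 * np.sqrt(ref_area / np.pi)

    lesion = vox[:, :, les_sl]

    # caliper direction: from the vessel center toward the calcium centroid
    calcium = lesion >= calcium_threshold
    direction = None
    if calcium.any():
        idx = np.nonzero(calcium)
        ux = (idx[0].mean() - cx) * dx
        uy = (idx[1].mean() - cy) * dy
        norm = np.hypot(ux, uy)
        if norm > 1e-6:
            direction = (ux / norm, uy / norm)

    half_range = ref_diameter / 2.0 * 1.5 + 1.0  # mm, covers the full lumen
    t = np.arange(-half_range, half_range + profile_step_mm, profile_step_mm)

    min_diam = np.inf
    min_area = np.inf
    for k in range(lesion.shape[2]):
        plane = lesion[:, :, k]
        min_area = min(min_area, lumen_area(plane))
        if direction is not None:
            coords = np.stack(
                [cx + t * direction[0] / dx, cy + t * direction[1] / dy]
            )
            vals = ndimage.map_coordinates(plane, coords, order=1, mode="nearest")
            flags = (vals >= half_max) & (vals < calcium_threshold)
            min_diam = min(min_diam, _max_run_length(flags, profile_step_mm))
        else:
            area = lumen_area(plane)
            min_diam = min(min_diam, 2.0 * np.sqrt(area / np.pi))

    diameter_pct = float(np.clip((1.0 - min_diam / ref_diameter) * 100.0, 0.0, 100.0))
    area_pct = float(np.clip((1.0 - min_area / ref_area) * 100.0, 0.0, 100.0))
    return diameter_pct, area_pct


def measure_diameter_stenosis(
    image: ImageVolume,
    axis: int = 2,
    reference_slices=(0, 1),
    lesion_slices=(0, 1),
    window: tuple[float, float] = DEFAULT_WINDOW,
    calcium_threshold: float = DEFAULT_CALCIUM_THRESHOLD,
    center: tuple[float, float] | None = None,
) -> float:
    """Maximal diameter stenosis (%) across the lesion slices.

    ``reference_slices`` must contain plaque-free lumen; the reference
    diameter is the area-equivalent diameter averaged over them.  The
    minimal free-lumen diameter in the lesion is the longest contiguous
    lumen run along the caliper line through the plaque, minimised over
    lesion slices.  ``window`` is accepted for interface parity with the
    reading workstation; segmentation itself is window-independent.
    """
    del window
    d, _ = _stenosis_measurements(
        image, axis, reference_slices, lesion_slices, calcium_threshold, center
    )
    return d


def measure_area_stenosis(
    image: ImageVolume,
    axis: int = 2,
    reference_slices=(0, 1),
    lesion_slices=(0, 1),
    window: tuple[float, float] = DEFAULT_WINDOW,
    calcium_threshold: float = DEFAULT_CALCIUM_THRESHOLD,
    center: tuple[float, float] | None = None,
) -> float:
    """Maximal area stenosis (%): minimal lesion lumen area vs reference."""
    del window
    _, a = _stenosis_measurements(
        image, axis, reference_slices, lesion_slices, calcium_threshold, center
    )
    return a
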