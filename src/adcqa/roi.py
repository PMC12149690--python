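"""Circular vial ROIs, organ masks, and ROI statistics on ADC maps.

Pixel membership for circular ROIs uses the pixel-center-inside-circle test
in the grid's centered physical frame (0-based voxel indices, coordinates at
pixel centers).  Statistics pool the valid voxels of all ROI slices; the
pooled mean is therefore the pixel-count-weighted mean of the per-slice
means, which are also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .fitting import AdcMap
from .grid import Grid
from .phantom import PhantomLayout

__all__ = [
    "CircularRoi",
    "MaskRoi",
    "RoiSet",
    "RoiMeasurement",
    "place_vial_rois",
    "extract_roi_stats",
    "organ_mask_stats",
]


@dataclass(frozen=True)
class CircularRoi:
    label: str
    slices: tuple[int, ...]
    center_xy: tuple[float, float]  # mm, in-plane
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")
        if not self.slices:
            raise ValueError("ROI must cover at least one slice")


@dataclass(frozen=True)
class MaskRoi:
    label: str
    mask: np.ndarray  # 3-D boolean

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask ROI must be a 3-D boolean volume")
        object.__setattr__(self, "mask", m)


Roi = Union[CircularRoi, MaskRoi]


@dataclass(frozen=True)
class RoiSet:
    rois: tuple[Roi, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, label: str) -> Roi:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass(frozen=True)
class RoiMeasurement:
    label: str
    mean_adc: float  # µm²/ms; NaN when not contained / no valid voxels
    sd_adc: float  # pooled voxel SD (ddof=1; 0 for a single voxel)
    n_pixels: int  # valid voxels pooled over slices
    per_slice_means: list[float]
    contained: bool


def place_vial_rois(
    layout: PhantomLayout,
    grid: Grid,
    diameter_mm: float = 10.0,
    n_slices: int = 3,
    centers_override: Mapping[int, tuple[float, float]] | None = None,
) -> RoiSet:
    """One circular ROI per vial, on the central ``n_slices`` slices.

    ROIs are centered at each vial's nominal center (or an override for
    offset phantoms).  A ROI whose circle extends outside the image grid is
    an error naming the vial.
    """
    slices = tuple(grid.central_slices(n_slices))
    half_y = grid.shape[1] * grid.voxel_size[1] / 2.0
    half_x = grid.shape[2] * grid.voxel_size[2] / 2.0
    rois = []
    for v in layout.vials:
        cx, cy = (centers_override or {}).get(v.vial_id, v.center_xy)
        r = diameter_mm / 2.0
        if abs(cx) + r > half_x or abs(cy) + r > half_y:
            raise ValueError(f"ROI for vial {v.vial_id} extends outside the image grid")
        rois.append(
            CircularRoi(
                label=f"vial_{v.vial_id}",
                slices=slices,
                center_xy=(cx, cy),
                diameter_mm=diameter_mm,
            )
        )
    return RoiSet(rois=tuple(rois))


def _roi_mask(roi: Roi, grid: Grid) -> np.ndarray:
    if isinstance(roi, MaskRoi):
        if roi.mask.shape != grid.shape:
            raise ValueError("mask ROI grid does not match the map grid")
        return roi.mask
    disk = grid.disk_mask(roi.center_xy, roi.diameter_mm)
    mask = np.zeros(grid.shape, dtype=bool)
    for k in roi.slices:
        if not 0 <= k < grid.n_slices:
            raise ValueError(f"ROI slice {k} outside the image grid")
        mask[k] = disk
    return mask


def _stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def extract_roi_stats(adc_map: AdcMap, roi: Roi) -> RoiMeasurement:
    """Pooled mean/SD (and per-slice means) of valid ADC voxels in a ROI.

    Invalid voxels (masked by the fit) are excluded; a ROI with no valid
    voxel at all yields ``contained=False`` with NaN statistics rather than
    an exception, so sweeps over many ROIs degrade gracefully.
    """
    grid = adc_map.grid
    mask = _roi_mask(roi, grid) & adc_map.valid_mask
    vol = adc_map.in_um2_per_ms()
    slice_ids = (
        roi.slices if isinstance(roi, CircularRoi) else tuple(np.flatnonzero(mask.any(axis=(1, 2))))
    )
    per_slice = []
    for k in slice_ids:
        vals = vol[k][mask[k]]
        per_slice.append(float(np.mean(vals)) if vals.size else math.nan)
    pooled = vol[mask]
    if pooled.size == 0:
        return RoiMeasurement(
            label=roi.label,
            mean_adc=math.nan,
            sd_adc=math.nan,
            n_pixels=0,
            per_slice_means=per_slice,
            contained=False,
        )
    mean, sd = _stats(pooled)
    return RoiMeasurement(
        label=roi.label,
        mean_adc=mean,
        sd_adc=sd,
        n_pixels=int(pooled.size),
        per_slice_means=per_slice,
        contained=True,
    )


def organ_mask_stats(
    adc_map: AdcMap,
    mask: np.ndarray,
    label: str,
    *,
    truncated: bool = False,
) -> RoiMeasurement:
    """ROI statistics for an organ mask, enforcing the containment rule.

    An organ counts as *contained* only if its mask was not clipped by the
    acquisition field of view: the source's ``truncated`` sentinel is false
    and the mask touches neither the first nor the last slice.  Non-contained
    organs keep their statistics for inspection but are excluded from
    downstream aggregation by their ``contained=False`` flag.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != adc_map.adc.shape:
        raise ValueError("organ mask grid does not match the map grid")
    if not m.any():
        raise ValueError(f"organ mask {label!r} is empty")
    contained = not truncated and not m[0].any() and not m[-1].any()
    meas = extract_roi_stats(adc_map, MaskRoi(label=label, mask=m))
    return RoiMeasurement(
        label=meas.label,
        mean_adc=meas.mean_adc,
        sd_adc=meas.sd_adc,
        n_pixels=meas.n_pixels,
        per_slice_means=meas.per_slice_means,
        contained=bool(contained and meas.contained),
    )
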