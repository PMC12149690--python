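"""Per-voxel mono-exponential ADC fitting and ADC-map comparison.

The signal model is ``S(b) = S0 * exp(-b * ADC)``.  The offline map is the
ordinary least-squares line through ``ln S`` versus ``b`` at every voxel
(uniform weights by default; a signal²-weighted variant, which approximates
maximum likelihood for Gaussian noise on S, is available behind a flag).
For exactly two b-values the fit reduces to the closed-form log-ratio
``ADC = ln(S1/S2) / (b2 - b1)``.

Units: all public ADC values are µm²/ms (= 1e-3 mm²/s); the fit itself runs
in mm²/s against b in s/mm² and the 1e3 factor is applied exactly once here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import Grid
from .simulate import DwiSeries

__all__ = [
    "AdcMap",
    "MapComparison",
    "apply_rescale",
    "invert_rescale",
    "two_point_adc",
    "fit_adc_map",
    "compare_adc_maps",
]

MM2_PER_S_TO_UM2_PER_MS = 1e3
_UNIT_TO_UM2MS = {"um2/ms": 1.0, "um2/s": 1e-3}


@dataclass
class AdcMap:
    """A fitted ADC volume with its validity mask and fit provenance."""

    adc: np.ndarray  # 3-D, µm²/ms unless ``units`` says otherwise
    valid_mask: np.ndarray  # 3-D boolean: fit succeeded, signal above floor
    b_values_used: np.ndarray  # s/mm²
    fit_method: str = "loglinear_lsq"  # or "two_point"
    units: str = "um2/ms"
    voxel_size: tuple[float, float, float] = (5.0, 0.859375, 0.859375)
    signal_floor: float = 0.0
    weighting: str = "uniform"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.adc.shape != self.valid_mask.shape or self.adc.ndim != 3:
            raise ValueError("adc and valid_mask must be matching 3-D volumes")
        if self.units not in _UNIT_TO_UM2MS:
            raise ValueError(f"unknown ADC units {self.units!r}")
        if not np.isfinite(self.adc[self.valid_mask]).all():
            raise ValueError("non-finite ADC inside the valid mask")

    @property
    def grid(self) -> Grid:
        return Grid(shape=self.adc.shape, voxel_size=self.voxel_size)

    def in_um2_per_ms(self) -> np.ndarray:
        """ADC volume converted to the package's canonical µm²/ms."""
        return self.adc * _UNIT_TO_UM2MS[self.units]

    @property
    def negative_mask(self) -> np.ndarray:
        """Valid voxels whose fitted ADC is negative (noise; kept, flagged)."""
        return self.valid_mask & (self.adc < 0)

    def clamped(self, lo: float = 0.0) -> np.ndarray:
        """Report-time convenience: ADC with negatives clamped to ``lo``."""
        out = self.in_um2_per_ms().copy()
        out[self.negative_mask] = lo
        return out


def apply_rescale(stored, slope: float, intercept: float):
    """Decode stored values to physical signal: ``stored * slope + intercept``."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return np.asarray(stored, dtype=float) * slope + intercept


def invert_rescale(physical, slope: float, intercept: float):
    """Encode physical signal back to stored values (writer-side inverse)."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return (np.asarray(physical, dtype=float) - intercept) / slope


def two_point_adc(s1: float, s2: float, b1: float, b2: float) -> float:
    """Closed-form two-b-value ADC, µm²/ms: ``ln(s1/s2) / (b2 - b1)``.

    ``s1`` is the signal at the lower b-value ``b1``.  Raises on non-positive
    signal (in map context such voxels are masked instead).
    """
    if b1 == b2:
        raise ValueError("b-values must differ")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("two_point_adc needs positive signals")
    return math.log(s1 / s2) / (b2 - b1) * MM2_PER_S_TO_UM2_PER_MS


def _select_b_subset(series: DwiSeries, b_subset: Sequence[float] | None) -> np.ndarray:
    if b_subset is None:
        return np.arange(series.b_values.size)
    idx = []
    for b in b_subset:
        hits = np.flatnonzero(np.isclose(series.b_values, b))
        if hits.size == 0:
            raise ValueError(f"b={b} not present in series (has {series.b_values})")
        idx.append(hits[0])
    return np.asarray(sorted(set(idx)))


def fit_adc_map(
    series: DwiSeries,
    b_subset: Sequence[float] | None = None,
    method: str = "loglinear_lsq",
    *,
    weighting: str = "uniform",
    floor: float | None = None,
) -> AdcMap:
    """Fit an ADC map from a b-value series.

    Parameters
    ----------
    b_subset
        b-values to fit over, e.g. ``(150, 500)`` for the anatomy-specific
        sequences whose maps deliberately drop b = 0 to dodge the
        pseudo-diffusion (IVIM) contamination; default uses all b-values.
    method
        ``"loglinear_lsq"`` (any number of b-values) or ``"two_point"``
        (requires exactly two after subsetting; identical result there).
    weighting
        ``"uniform"`` (default) or ``"signal2"`` — weights ∝ S² on the
        log-domain residuals.
    floor
        Signal validity floor in physical units; voxels with any fitted
        signal ≤ floor are masked invalid.  Default: 1e-6 × series maximum.
    """
    if method not in ("loglinear_lsq", "two_point"):
        raise ValueError(f"unknown fit method {method!r}")
    if weighting not in ("uniform", "signal2"):
        raise ValueError(f"unknown weighting {weighting!r}")
    idx = _select_b_subset(series, b_subset)
    b = series.b_values[idx]
    if np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values to fit ADC")
    if method == "two_point" and b.size != 2:
        raise ValueError("two_point method needs exactly 2 b-values")

    physical = series.physical_signal()[idx]
    if floor is None:
        floor = 1e-6 * float(np.max(physical)) if np.max(physical) > 0 else 0.0
    valid = (physical > floor).all(axis=0)

    # logs are only consumed where valid (all signals > floor > 0); plug
    # ones elsewhere so the vectorized arithmetic stays warning-free
    ln_s = np.log(np.where(physical > 0, physical, 1.0))
    bb = b[:, None, None, None]
    if weighting == "uniform":
        b_mean = b.mean()
        ln_mean = ln_s.mean(axis=0)
        sxx = np.sum((b - b_mean) ** 2)
        sxy = np.sum((bb - b_mean) * (ln_s - ln_mean[None]), axis=0)
        slope = sxy / sxx
    else:
        w = np.where(valid[None], physical**2, 1.0)
        wsum = w.sum(axis=0)
        b_mean = (w * bb).sum(axis=0) / wsum
        ln_mean = (w * ln_s).sum(axis=0) / wsum
        sxx = (w * (bb - b_mean[None]) ** 2).sum(axis=0)
        sxy = (w * (bb - b_mean[None]) * (ln_s - ln_mean[None])).sum(axis=0)
        slope = sxy / sxx
    adc = -slope * MM2_PER_S_TO_UM2_PER_MS  # mm²/s -> µm²/ms
    adc[~valid] = np.nan

    return AdcMap(
        adc=adc,
        valid_mask=valid,
        b_values_used=b,
        fit_method=method if method == "two_point" else "loglinear_lsq",
        voxel_size=series.voxel_size,
        signal_floor=float(floor),
        weighting=weighting,
        provenance=series.provenance,
    )


@dataclass
class MapComparison:
    """Inline-vs-offline style ROI comparison of two ADC maps."""

    percent_diff: float  # 100 * (mean_a - mean_b) / mean_b
    mean_a: float
    mean_b: float
    per_slice_means_a: list[float]
    per_slice_means_b: list[float]


def compare_adc_maps(map_a: AdcMap, map_b: AdcMap, roi) -> MapComparison:
    """Percent difference of ROI-mean ADC between two maps on the same grid.

    Units are harmonized (µm²/s maps are converted to µm²/ms) before
    comparing, and per-slice ROI means are reported alongside the pooled
    difference.  ``roi`` is any ROI accepted by
    :func:`adcqa.roi.extract_roi_stats`.
    """
    from .roi import extract_roi_stats  # circular-import avoidance

    if map_a.adc.shape != map_b.adc.shape or map_a.voxel_size != map_b.voxel_size:
        raise ValueError("ADC maps are on different grids")
    harmonized = []
    for m in (map_a, map_b):
        harmonized.append(
            AdcMap(
                adc=m.in_um2_per_ms(),
                valid_mask=m.valid_mask,
                b_values_used=m.b_values_used,
                fit_method=m.fit_method,
                units="um2/ms",
                voxel_size=m.voxel_size,
                signal_floor=m.signal_floor,
                weighting=m.weighting,
                provenance=m.provenance,
            )
        )
    stat_a = extract_roi_stats(harmonized[0], roi)
    stat_b = extract_roi_stats(harmonized[1], roi)
    if stat_b.mean_adc == 0:
        raise ValueError("reference map ROI mean is zero")
    return MapComparison(
        percent_diff=100.0 * (stat_a.mean_adc - stat_b.mean_adc) / stat_b.mean_adc,
        mean_a=stat_a.mean_adc,
        mean_b=stat_b.mean_adc,
        per_slice_means_a=stat_a.per_slice_means,
        per_slice_means_b=stat_b.per_slice_means,
    )
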