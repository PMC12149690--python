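"""Synthetic diffusion-weighted series: phantom and toy in vivo volumes.

The generator emulates the statistical structure the downstream QA analysis
assumes, and nothing more: every voxel inside a vial (or organ) decays
mono-exponentially, ``S(b) = S0 * exp(-b * ADC)``; magnitude noise is Rician
(equal-variance Gaussian noise on real and imaginary channels, then the
magnitude), calibrated so that mean/SD at b = 0 in a uniform region equals the
requested SNR; scanner-to-scanner and day-to-day differences enter as small
multiplicative offsets on the generating ADC.  There is no k-space, EPI
distortion, eddy-current or motion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .grid import Grid
from .phantom import PhantomLayout

__all__ = [
    "SimulationConfig",
    "DwiSeries",
    "OrganSpec",
    "OrganSimulation",
    "simulate_phantom_series",
    "simulate_study",
    "simulate_organ_volume",
]

NOISE_MODELS = ("none", "gaussian", "rician")

#: default b-values of the standardized 1.5 T phantom EPI sequence, s/mm²
QIBA_B_VALUES = (0.0, 500.0, 900.0, 2000.0)
#: acquisition b-values of the anatomy-specific (Consortium) sequences, s/mm²
CONSORTIUM_B_VALUES = (0.0, 150.0, 500.0)
#: b-value subset the Consortium recommends for ADC map generation
CONSORTIUM_B_SUBSET = (150.0, 500.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic acquisition.

    Defaults mirror the standardized phantom EPI protocol: b-values
    0/500/900/2000 s/mm², 256×256 in-plane matrix over a 220 mm field of view
    (0.859 mm pixels) and 5 mm slice spacing (4 mm slices + 1 mm gap).  Only
    the 9 central slices covering the 40 mm vial slab are generated; the
    outer slices of the clinical 25-slice stack hold background only.
    Noise is off by default; ``noise_model="rician"`` with ``snr_b0=75``
    (the middle of the measured 71–79 b = 0 SNR range) is the realistic
    setting used by the calibrated acceptance simulations.
    """

    b_values: tuple[float, ...] = QIBA_B_VALUES
    s0: float = 1000.0
    snr_b0: float = 75.0
    noise_model: str = "none"
    scanner_bias_percent: Mapping[str, float] = field(default_factory=dict)
    session_drift_percent: float = 0.0
    matrix: tuple[int, int, int] = (9, 256, 256)
    voxel_size: tuple[float, float, float] = (5.0, 0.859375, 0.859375)
    seed: int = 0
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    background_fraction: float = 1e-3  # air signal as a fraction of s0
    shading_percent: float = 0.0  # optional parabolic coil-shading term, NON-physical

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr_b0 <= 0:
            raise ValueError("snr_b0 must be positive when noise is on")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or np.unique(b).size < 2:
            raise ValueError("need at least 2 distinct b-values")
        if (b < 0).any():
            raise ValueError("b-values must be non-negative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.rescale_slope == 0:
            raise ValueError("rescale_slope must be nonzero")

    @property
    def grid(self) -> Grid:
        return Grid(shape=self.matrix, voxel_size=self.voxel_size)


@dataclass
class DwiSeries:
    """A 4-D stack of diffusion-weighted volumes with acquisition metadata.

    ``signal`` holds *stored* values; the physical signal is
    ``stored * rescale_slope + rescale_intercept``.
    """

    signal: np.ndarray  # (n_b, n_slices, n_rows, n_cols), stored values
    b_values: np.ndarray  # s/mm², one per volume
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    voxel_size: tuple[float, float, float] = (5.0, 0.859375, 0.859375)
    scanner_id: str = "A"
    day: int = 1
    repetition: int = 1
    sequence_name: str = "qiba_epi"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (b, slice, row, col)")
        if self.signal.shape[0] != self.b_values.size:
            raise ValueError(
                f"{self.signal.shape[0]} volumes but {self.b_values.size} b-values"
            )

    @property
    def grid(self) -> Grid:
        return Grid(shape=self.signal.shape[1:], voxel_size=self.voxel_size)

    def physical_signal(self) -> np.ndarray:
        """Decode stored values to physical signal (rescale applied once)."""
        return self.signal * self.rescale_slope + self.rescale_intercept

    @property
    def provenance(self) -> dict:
        return {
            "scanner_id": self.scanner_id,
            "day": int(self.day),
            "repetition": int(self.repetition),
            "sequence_name": self.sequence_name,
        }


def _rasterize_adc(
    layout: PhantomLayout,
    grid: Grid,
    adc_per_vial: Mapping[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """(adc volume µm²/ms, object mask) for the vial slab on ``grid``."""
    ym, xm = grid.inplane_mesh()
    half_y = grid.shape[1] * grid.voxel_size[1] / 2.0
    half_x = grid.shape[2] * grid.voxel_size[2] / 2.0
    adc_plane = np.zeros(grid.shape[1:], dtype=float)
    obj_plane = np.zeros(grid.shape[1:], dtype=bool)
    for v in layout.vials:
        cx, cy = v.center_xy
        if abs(cx) + v.radius > half_x or abs(cy) + v.radius > half_y:
            raise ValueError(
                f"vial {v.vial_id} footprint extends outside the simulated matrix"
            )
        m = (xm - cx) ** 2 + (ym - cy) ** 2 <= v.radius**2
        adc_plane[m] = adc_per_vial[v.vial_id]
        obj_plane |= m
    z = grid.axis_coords(0)
    in_slab = np.abs(z) <= layout.slab_thickness / 2.0
    adc = np.where(in_slab[:, None, None], adc_plane[None], 0.0)
    obj = in_slab[:, None, None] & obj_plane[None]
    return adc, obj


def _synthesize(
    adc_um2ms: np.ndarray,
    obj_mask: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Noisy stored-value stack from a generating-ADC volume."""
    b = np.asarray(config.b_values, dtype=float)
    # ADC is public in µm²/ms == 1e-3 mm²/s; the exponent needs mm²/s
    decay = np.exp(-b[:, None, None, None] * adc_um2ms[None] * 1e-3)
    signal = np.where(obj_mask[None], config.s0 * decay, config.s0 * config.background_fraction)
    if config.shading_percent:
        grid = config.grid
        ym, xm = grid.inplane_mesh()
        r2 = (xm**2 + ym**2) / max(xm.max(), ym.max()) ** 2
        signal = signal * (1.0 + config.shading_percent / 100.0 * (1.0 - r2))[None, None]
    if config.noise_model != "none":
        sigma = config.s0 / config.snr_b0
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if config.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:  # rician: magnitude of (S + n_re) + i n_im
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.hypot(re, im)
    # encode physical -> stored
    return (signal - config.rescale_intercept) / config.rescale_slope


def simulate_phantom_series(
    layout: PhantomLayout,
    config: SimulationConfig,
    adc_overrides: Mapping[int, float] | None = None,
    *,
    adc_scale: float = 1.0,
    scanner_id: str = "A",
    day: int = 1,
    repetition: int = 1,
    sequence_name: str = "qiba_epi",
    rng: np.random.Generator | None = None,
) -> DwiSeries:
    """One synthetic phantom acquisition.

    Each voxel inside vial ``v`` decays at that vial's reference ADC (or the
    override), scaled by ``adc_scale`` (used by :func:`simulate_study` to
    inject per-scanner bias and per-day drift); background sits at a small
    positive constant; noise and stored-value encoding are applied last.
    Deterministic for a fixed ``(config, seed)``.
    """
    adc_per_vial = {v.vial_id: v.reference_adc for v in layout.vials}
    if adc_overrides:
        unknown = set(adc_overrides) - set(adc_per_vial)
        if unknown:
            raise KeyError(f"adc_overrides for unknown vials: {sorted(unknown)}")
        adc_per_vial.update(adc_overrides)
    adc_per_vial = {k: v * adc_scale for k, v in adc_per_vial.items()}
    adc, obj = _rasterize_adc(layout, config.grid, adc_per_vial)
    stored = _synthesize(adc, obj, config, rng)
    return DwiSeries(
        signal=stored,
        b_values=np.asarray(config.b_values, dtype=float),
        rescale_slope=config.rescale_slope,
        rescale_intercept=config.rescale_intercept,
        voxel_size=config.voxel_size,
        scanner_id=scanner_id,
        day=day,
        repetition=repetition,
        sequence_name=sequence_name,
    )


def simulate_study(
    layout: PhantomLayout,
    config: SimulationConfig,
    scanners: Sequence[str],
    days: int = 2,
    repetitions: int = 4,
    *,
    sequence_name: str = "qiba_epi",
) -> list[DwiSeries]:
    """A full multi-scanner phantom study: one series per (scanner, day, rep).

    Per-scanner bias (``config.scanner_bias_percent``) and per-day drift
    (``config.session_drift_percent``, compounded from day 1) multiply the
    generating ADC before signal synthesis.  Noise streams are derived
    deterministically from ``(config.seed, scanner index, day, repetition)``,
    so repetitions differ while the whole study is reproducible.
    """
    if not scanners:
        raise ValueError("need at least one scanner")
    if days < 1 or repetitions < 1:
        raise ValueError("days and repetitions must be >= 1")
    series = []
    for s_idx, scanner in enumerate(scanners):
        bias = config.scanner_bias_percent.get(scanner, 0.0)
        for day in range(1, days + 1):
            drift = (1.0 + config.session_drift_percent / 100.0) ** (day - 1)
            scale = (1.0 + bias / 100.0) * drift
            for rep in range(1, repetitions + 1):
                ss = np.random.SeedSequence(
                    entropy=int(config.seed), spawn_key=(s_idx, day, rep)
                )
                series.append(
                    simulate_phantom_series(
                        layout,
                        config,
                        adc_scale=scale,
                        scanner_id=str(scanner),
                        day=day,
                        repetition=rep,
                        sequence_name=sequence_name,
                        rng=np.random.default_rng(ss),
                    )
                )
    return series


# ---------------------------------------------------------------------------
# toy in vivo volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal stand-in organ.

    ``center_mm`` and ``semi_axes_mm`` are (z, y, x) in the grid's physical
    frame.  ADC magnitudes of real organs span roughly 0.6–2.2 µm²/ms.
    """

    label: str
    adc: float  # µm²/ms
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass
class OrganSimulation:
    series: DwiSeries
    masks: dict[str, np.ndarray]  # label -> 3-D boolean, series grid
    truncated: dict[str, bool]  # label -> clipped by the field of view


def simulate_organ_volume(
    organ_specs: Sequence[OrganSpec],
    config: SimulationConfig,
    *,
    scanner_id: str = "A",
    day: int = 1,
    repetition: int = 1,
    sequence_name: str = "consortium",
    rng: np.random.Generator | None = None,
) -> OrganSimulation:
    """Synthetic multi-organ DWI volume plus aligned binary masks.

    Organs whose analytic extent crosses the grid boundary are clipped and
    flagged ``truncated`` — the sentinel the containment rule consumes.
    Overlapping organ masks are an error.
    """
    grid = config.grid
    z = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    x = grid.axis_coords(2)[None, None, :]
    half = [grid.shape[a] * grid.voxel_size[a] / 2.0 for a in range(3)]

    adc = np.zeros(grid.shape, dtype=float)
    occupied = np.zeros(grid.shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    truncated: dict[str, bool] = {}
    labels = [o.label for o in organ_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("organ labels must be unique")
    for o in organ_specs:
        cz, cy, cx = o.center_mm
        az, ay, ax = o.semi_axes_mm
        if min(az, ay, ax) <= 0:
            raise ValueError(f"organ {o.label!r} has non-positive semi-axes")
        m = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
        if not m.any():
            raise ValueError(f"organ {o.label!r} lies entirely outside the grid")
        if (m & occupied).any():
            raise ValueError(f"organ {o.label!r} overlaps another organ")
        clipped = (
            abs(cz) + az > half[0] or abs(cy) + ay > half[1] or abs(cx) + ax > half[2]
        )
        masks[o.label] = m
        truncated[o.label] = bool(clipped)
        occupied |= m
        adc[m] = o.adc

    stored = _synthesize(adc, occupied, config, rng)
    series = DwiSeries(
        signal=stored,
        b_values=np.asarray(config.b_values, dtype=float),
        rescale_slope=config.rescale_slope,
        rescale_intercept=config.rescale_intercept,
        voxel_size=config.voxel_size,
        scanner_id=scanner_id,
        day=day,
        repetition=repetition,
        sequence_name=sequence_name,
    )
    return OrganSimulation(series=series, masks=masks, truncated=truncated)
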