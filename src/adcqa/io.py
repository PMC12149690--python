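"""Readers and writers for the formats the pipeline touches.

The canonical interchange dialect is NIfTI: one 4-D image per series (stored
values, one volume per b-value) with two plain-text sidecars — ``<stem>.bval``
(space-separated b-values, FSL convention) and ``<stem>.json`` (rescale
slope/intercept and provenance labels).  Rescale parameters live in the
sidecar only and are applied exactly once, by
:meth:`adcqa.simulate.DwiSeries.physical_signal`; the NIfTI ``scl_`` fields
are left neutral so no library applies them a second time.

DICOM reading requires the optional ``pydicom`` dependency and supports only
single-frame series with the standard diffusion b-value and rescale tags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import AdcMap
from .simulate import DwiSeries

__all__ = [
    "read_flat_config",
    "write_flat_config",
    "write_dwi",
    "read_dwi",
    "read_dwi_dicom",
    "write_adc_map",
    "read_adc_map",
    "read_mask",
    "ManifestEntry",
    "write_manifest",
    "read_manifest",
    "conformance_frame",
    "write_provenance",
]


# ---------------------------------------------------------------------------
# flat key-value config
# ---------------------------------------------------------------------------


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment; blanks ignored."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        key = key.strip()
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = val.strip()
    return out


def write_flat_config(kv: dict, path: str | Path) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in kv.items()))


# ---------------------------------------------------------------------------
# DWI series (NIfTI dialect)
# ---------------------------------------------------------------------------


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = voxel_size
    return np.diag([dx, dy, dz, 1.0])


def write_dwi(series: DwiSeries, stem: str | Path) -> Path:
    """Write a series as ``<stem>.nii.gz`` + ``.bval`` + ``.json`` sidecars."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    # array (b, z, y, x) -> NIfTI (x, y, z, b)
    data = np.ascontiguousarray(series.signal.transpose(3, 2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.voxel_size))
    img.header.set_zooms((*img.header.get_zooms()[:3], 1.0))
    nii_path = stem.with_suffix(".nii.gz")
    nib.save(img, nii_path)
    stem.with_suffix(".bval").write_text(
        " ".join(f"{b:g}" for b in series.b_values) + "\n"
    )
    meta = {
        "rescale_slope": series.rescale_slope,
        "rescale_intercept": series.rescale_intercept,
        "voxel_size_mm": list(series.voxel_size),
        **series.provenance,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return nii_path


def read_dwi(path: str | Path) -> DwiSeries:
    """Read a NIfTI series written by :func:`write_dwi` (or compatible).

    Requires the ``.bval`` sidecar (count must match the volume count) and
    the ``.json`` sidecar's rescale parameters; volumes are reordered by
    ascending b-value.
    """
    path = Path(path)
    stem = path
    while stem.suffix in (".nii", ".gz"):
        stem = stem.with_suffix("")
    bval_path = stem.with_suffix(".bval")
    meta_path = stem.with_suffix(".json")
    if not bval_path.exists():
        raise FileNotFoundError(f"missing b-value sidecar {bval_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    img = nib.load(path)
    raw = np.asanyarray(img.dataobj)  # stored values; scl_ fields deliberately unused
    if raw.ndim == 3:
        raw = raw[..., None]
    if raw.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got shape {raw.shape}")
    b_values = np.array([float(x) for x in bval_path.read_text().split()])
    if b_values.size != raw.shape[3]:
        raise ValueError(
            f"{path}: {raw.shape[3]} volumes but {b_values.size} b-values in sidecar"
        )
    meta = json.loads(meta_path.read_text())
    for key in ("rescale_slope", "rescale_intercept"):
        if key not in meta:
            raise KeyError(f"{meta_path}: missing rescale parameter {key!r}")
    signal = raw.transpose(3, 2, 1, 0).astype(float)  # -> (b, z, y, x)
    order = np.argsort(b_values, kind="stable")
    zooms = img.header.get_zooms()[:3]
    voxel_size = tuple(
        meta.get("voxel_size_mm", (zooms[2], zooms[1], zooms[0]))
    )
    return DwiSeries(
        signal=signal[order],
        b_values=b_values[order],
        rescale_slope=float(meta["rescale_slope"]),
        rescale_intercept=float(meta["rescale_intercept"]),
        voxel_size=(float(voxel_size[0]), float(voxel_size[1]), float(voxel_size[2])),
        scanner_id=str(meta.get("scanner_id", "unknown")),
        day=int(meta.get("day", 1)),
        repetition=int(meta.get("repetition", 1)),
        sequence_name=str(meta.get("sequence_name", "unknown")),
    )


def read_dwi_dicom(directory: str | Path) -> DwiSeries:
    """Read a single-frame DICOM series directory (optional ``pydicom``).

    Looks at the standard diffusion b-value tag (0018,9087) and rescale
    slope/intercept (0028,1053)/(0028,1052).  Vendor multiframe dialects are
    out of scope.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM reading requires the optional 'pydicom' dependency; "
            "install it or convert the series to the NIfTI + sidecar dialect"
        ) from exc

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    frames = []
    for f in files:
        ds = pydicom.dcmread(f)
        if "DiffusionBValue" not in ds:
            raise KeyError(f"{f}: missing diffusion b-value tag (0018,9087)")
        frames.append(
            (
                float(ds.DiffusionBValue),
                int(ds.get("InstanceNumber", 0)),
                ds.pixel_array.astype(float),
                float(ds.get("RescaleSlope", 1.0)),
                float(ds.get("RescaleIntercept", 0.0)),
                ds,
            )
        )
    shapes = {fr[2].shape for fr in frames}
    if len(shapes) != 1:
        raise ValueError(f"{directory}: inconsistent frame geometry {shapes}")
    slopes = {fr[3] for fr in frames}
    intercepts = {fr[4] for fr in frames}
    if len(slopes) != 1 or len(intercepts) != 1:
        raise ValueError(f"{directory}: rescale parameters differ between frames")
    b_values = sorted({fr[0] for fr in frames})
    volumes = []
    for b in b_values:
        frs = sorted((fr for fr in frames if fr[0] == b), key=lambda fr: fr[1])
        volumes.append(np.stack([fr[2] for fr in frs]))
    ds0 = frames[0][5]
    spacing = [float(x) for x in ds0.get("PixelSpacing", [1.0, 1.0])]
    dz = float(ds0.get("SpacingBetweenSlices", ds0.get("SliceThickness", 1.0)))
    return DwiSeries(
        signal=np.stack(volumes),
        b_values=np.array(b_values),
        rescale_slope=slopes.pop(),
        rescale_intercept=intercepts.pop(),
        voxel_size=(dz, spacing[0], spacing[1]),
        scanner_id=str(ds0.get("StationName", "unknown")),
        sequence_name=str(ds0.get("SeriesDescription", "unknown")),
    )


# ---------------------------------------------------------------------------
# ADC maps
# ---------------------------------------------------------------------------


def write_adc_map(adc_map: AdcMap, stem: str | Path) -> Path:
    """Write an ADC map as float32 NIfTI (µm²/ms) + JSON provenance sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    vol = adc_map.in_um2_per_ms().copy()
    vol[~adc_map.valid_mask] = np.nan
    data = np.ascontiguousarray(vol.transpose(2, 1, 0)).astype(np.float32)
    nii_path = stem.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(data, _affine(adc_map.voxel_size)), nii_path)
    meta = {
        "units": "um2/ms",
        "b_values_used": [float(b) for b in adc_map.b_values_used],
        "fit_method": adc_map.fit_method,
        "weighting": adc_map.weighting,
        "signal_floor": adc_map.signal_floor,
        "voxel_size_mm": list(adc_map.voxel_size),
        "provenance": adc_map.provenance,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return nii_path


def read_adc_map(path: str | Path) -> AdcMap:
    path = Path(path)
    stem = path
    while stem.suffix in (".nii", ".gz"):
        stem = stem.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    img = nib.load(path)
    vol = np.asanyarray(img.dataobj).astype(float).transpose(2, 1, 0)
    valid = np.isfinite(vol)
    return AdcMap(
        adc=vol,
        valid_mask=valid,
        b_values_used=np.array(meta["b_values_used"], dtype=float),
        fit_method=meta.get("fit_method", "loglinear_lsq"),
        units=meta.get("units", "um2/ms"),
        voxel_size=tuple(meta["voxel_size_mm"]),
        signal_floor=float(meta.get("signal_floor", 0.0)),
        weighting=meta.get("weighting", "uniform"),
        provenance=meta.get("provenance", {}),
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary organ mask from a NIfTI volume -> (z, y, x) boolean."""
    img = nib.load(path)
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {vol.shape}")
    return vol.transpose(2, 1, 0) > 0


# ---------------------------------------------------------------------------
# manifests and reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    scanner_id: str
    sequence_name: str
    day: int
    repetition: int
    path: str


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    pd.DataFrame([asdict(e) for e in entries]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Load a series manifest, checking key uniqueness and path existence."""
    df = pd.read_csv(path)
    required = {"scanner_id", "sequence_name", "day", "repetition", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    keys = list(zip(df.scanner_id, df.sequence_name, df.day, df.repetition))
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (scanner, sequence, day, repetition) keys")
    base = Path(path).parent
    entries = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"{path}: listed series {p} does not exist")
        entries.append(
            ManifestEntry(
                scanner_id=str(row.scanner_id),
                sequence_name=str(row.sequence_name),
                day=int(row.day),
                repetition=int(row.repetition),
                path=str(p),
            )
        )
    return entries


def conformance_frame(results) -> pd.DataFrame:
    """Tidy table of battery results; N/A values stay as empty cells."""
    rows = []
    for r in results:
        rows.append(
            {
                "test": r.test_id,
                "metric": r.metric_name,
                "value": np.nan if r.value is None else r.value,
                "tolerance": r.tolerance,
                "passed": "N/A" if r.passed is None else bool(r.passed),
                "note": r.note,
                **{f"input_{k}": str(v) for k, v in sorted(r.inputs_summary.items())},
            }
        )
    return pd.DataFrame(rows)


def write_provenance(path: str | Path, **info) -> None:
    """Record the analysis switches in force alongside every report."""
    from . import __version__

    payload = {"adcqa_version": __version__, **info}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
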