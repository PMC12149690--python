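"""The 13-vial isotropic diffusion phantom (CaliberMRI / NIST design).

The phantom is a sphere holding a central water vial (vial 1) surrounded by an
inner and an outer ring of six vials each, filled with aqueous
polyvinylpyrrolidone (PVP) at increasing mass fractions.  At 0 °C (ice-water
bath) each fill has a NIST-characterized reference ADC, which is what makes
the phantom usable for absolute bias testing: water at 1.109 µm²/ms down to
50 % PVP at 0.110 µm²/ms.

Reference values are serial-number specific; the packaged layout carries the
published per-concentration values and can be overridden from a flat
key-value file for a particular physical phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "VialSpec",
    "PhantomLayout",
    "builtin_layout",
    "reference_adc",
    "load_layout",
    "save_layout",
]

RINGS = ("center", "inner", "outer")

#: vial id -> (ring, PVP mass %, reference ADC µm²/ms at 0 °C)
#: Concentrations follow the manufacturer's fill scheme (informational; the
#: analysis only uses the reference ADC values).
_VIAL_TABLE = {
    1: ("center", 0.0, 1.109),
    2: ("inner", 0.0, 1.109),
    3: ("outer", 0.0, 1.109),
    4: ("inner", 10.0, 0.817),
    5: ("outer", 10.0, 0.817),
    6: ("inner", 20.0, 0.579),
    7: ("outer", 20.0, 0.579),
    8: ("inner", 30.0, 0.380),
    9: ("outer", 30.0, 0.380),
    10: ("inner", 40.0, 0.220),
    11: ("outer", 40.0, 0.220),
    12: ("inner", 50.0, 0.110),
    13: ("outer", 50.0, 0.110),
}

# Nominal geometry (mm).  Not printed in the phantom's public data sheet at
# this granularity; only relative geometry matters for simulation and ROI
# placement.  Ring ordering runs clockwise from 12 o'clock, with each outer
# vial radially aligned with the inner vial holding the same fill.
_VIAL_RADIUS_MM = 15.0
_INNER_RING_MM = 40.0
_OUTER_RING_MM = 70.0
_PHANTOM_RADIUS_MM = 97.0
_SLAB_THICKNESS_MM = 40.0
#: clockwise from 12 o'clock (+y), degrees
_RING_ANGLES_DEG = (90.0, 30.0, -30.0, -90.0, -150.0, 150.0)


@dataclass(frozen=True)
class VialSpec:
    vial_id: int
    ring: str
    pvp_percent: float
    reference_adc: float  # µm²/ms at 0 °C
    center_xy: tuple[float, float]  # mm from phantom axis
    radius: float  # mm

    def __post_init__(self) -> None:
        if self.ring not in RINGS:
            raise ValueError(f"unknown ring {self.ring!r}")
        if self.pvp_percent < 0:
            raise ValueError("pvp_percent must be >= 0")
        if self.reference_adc <= 0:
            raise ValueError("reference_adc must be positive")
        if self.radius <= 0:
            raise ValueError("vial radius must be positive")


@dataclass(frozen=True)
class PhantomLayout:
    vials: tuple[VialSpec, ...]
    phantom_radius: float = _PHANTOM_RADIUS_MM
    slab_thickness: float = _SLAB_THICKNESS_MM
    temperature_c: float = 0.0
    serial: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        ids = [v.vial_id for v in self.vials]
        if len(set(ids)) != len(ids):
            raise ValueError("vial ids must be unique")
        if sum(v.ring == "center" for v in self.vials) != 1:
            raise ValueError("exactly one vial must be the center vial")
        for a in self.vials:
            for b in self.vials:
                if a.vial_id >= b.vial_id:
                    continue
                d = math.dist(a.center_xy, b.center_xy)
                if d < a.radius + b.radius - 1e-9:
                    raise ValueError(
                        f"vials {a.vial_id} and {b.vial_id} overlap in-plane"
                    )

    def vial(self, vial_id: int) -> VialSpec:
        for v in self.vials:
            if v.vial_id == vial_id:
                return v
        raise KeyError(f"phantom layout has no vial {vial_id}")

    @property
    def vial_ids(self) -> list[int]:
        return [v.vial_id for v in self.vials]

    def with_reference_adcs(self, overrides: dict[int, float]) -> "PhantomLayout":
        """Copy of the layout with some vials' reference ADC replaced."""
        unknown = set(overrides) - set(self.vial_ids)
        if unknown:
            raise KeyError(f"unknown vial ids in overrides: {sorted(unknown)}")
        vials = tuple(
            replace(v, reference_adc=overrides.get(v.vial_id, v.reference_adc))
            for v in self.vials
        )
        return replace(self, vials=vials)


def builtin_layout() -> PhantomLayout:
    """The packaged 13-vial layout with NIST reference ADCs at 0 °C."""
    vials = []
    inner_seen = outer_seen = 0
    for vial_id, (ring, pvp, adc) in _VIAL_TABLE.items():
        if ring == "center":
            xy = (0.0, 0.0)
            rr = 0.0
        elif ring == "inner":
            ang = math.radians(_RING_ANGLES_DEG[inner_seen])
            rr = _INNER_RING_MM
            inner_seen += 1
            xy = (rr * math.cos(ang), rr * math.sin(ang))
        else:
            ang = math.radians(_RING_ANGLES_DEG[outer_seen])
            rr = _OUTER_RING_MM
            outer_seen += 1
            xy = (rr * math.cos(ang), rr * math.sin(ang))
        vials.append(
            VialSpec(
                vial_id=vial_id,
                ring=ring,
                pvp_percent=pvp,
                reference_adc=adc,
                center_xy=xy,
                radius=_VIAL_RADIUS_MM,
            )
        )
    return PhantomLayout(vials=tuple(vials))


def reference_adc(layout: PhantomLayout, vial_id: int) -> float:
    """Reference ADC (µm²/ms) of one vial; raises KeyError for unknown ids."""
    return layout.vial(vial_id).reference_adc


# ---------------------------------------------------------------------------
# flat key-value serialization (user-overridable layout files)
# ---------------------------------------------------------------------------

_LAYOUT_KEYS = ("serial", "phantom_radius_mm", "slab_thickness_mm", "temperature_c")


def save_layout(layout: PhantomLayout, path: str | Path) -> None:
    lines = [
        f"serial = {layout.serial}",
        f"phantom_radius_mm = {layout.phantom_radius!r}",
        f"slab_thickness_mm = {layout.slab_thickness!r}",
        f"temperature_c = {layout.temperature_c!r}",
    ]
    for v in sorted(layout.vials, key=lambda v: v.vial_id):
        p = f"vial.{v.vial_id}"
        lines += [
            f"{p}.ring = {v.ring}",
            f"{p}.pvp_percent = {v.pvp_percent!r}",
            f"{p}.reference_adc = {v.reference_adc!r}",
            f"{p}.x_mm = {v.center_xy[0]!r}",
            f"{p}.y_mm = {v.center_xy[1]!r}",
            f"{p}.radius_mm = {v.radius!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_layout(path: str | Path) -> PhantomLayout:
    from .io import read_flat_config  # local import: io depends on phantom types

    kv = read_flat_config(path)
    unknown = [
        k for k in kv if not (k in _LAYOUT_KEYS or k.startswith("vial."))
    ]
    if unknown:
        raise ValueError(f"unknown layout keys: {sorted(unknown)}")
    per_vial: dict[int, dict[str, str]] = {}
    for k, val in kv.items():
        if not k.startswith("vial."):
            continue
        _, vid, fieldname = k.split(".", 2)
        per_vial.setdefault(int(vid), {})[fieldname] = val
    vials = tuple(
        VialSpec(
            vial_id=vid,
            ring=f["ring"],
            pvp_percent=float(f["pvp_percent"]),
            reference_adc=float(f["reference_adc"]),
            center_xy=(float(f["x_mm"]), float(f["y_mm"])),
            radius=float(f["radius_mm"]),
        )
        for vid, f in sorted(per_vial.items())
    )
    return PhantomLayout(
        vials=vials,
        phantom_radius=float(kv.get("phantom_radius_mm", _PHANTOM_RADIUS_MM)),
        slab_thickness=float(kv.get("slab_thickness_mm", _SLAB_THICKNESS_MM)),
        temperature_c=float(kv.get("temperature_c", 0.0)),
        serial=kv.get("serial", "SYNTHETIC"),
    )
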