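"""QIBA Diffusion Profile conformance statistics and multi-scanner summaries.

The profile's phantom battery (tests A–G) checks, for the central water vial
of the diffusion phantom (unless noted):

==== ====================================== ============================
test metric                                 tolerance
==== ====================================== ============================
A    |bias| vs. reference ADC, day-1 rep 1  ≤ 3.600 %
B    short-term repeatability, 4 same-day   RC_ST ≤ 0.015 µm²/ms,
     repetitions                            CV_ST ≤ 0.5 %
C    between-session repeatability, first   RC_BS ≤ 0.065 µm²/ms,
     measurements of 2 consecutive days     CV_BS ≤ 2.2 %
D    linearity of measured vs. reference    R² > 0.9,
     ADC over all 13 vials                  0.95 ≤ slope ≤ 1.05
E    precision: within-ROI spatial CV of a  CV_P < 2 %
     single repetition
F    SNR of the b = 0 image in the vial ROI ≥ 50
G    b-value dependence: worst two-point    max Dep_b < 2 %
     ADC vs. the all-b fit
==== ====================================== ============================

Repeatability statistics follow the biomarker convention RC = 2.77 × wSD,
where wSD is the sample SD (n−1 denominator) of the repeated measurements and
2.77 = 1.96·√2 bounds 95 % of test–retest differences.  Coefficients of
variation are 100 × sample SD / mean throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fitting import fit_adc_map
from .phantom import PhantomLayout
from .roi import RoiMeasurement, extract_roi_stats, place_vial_rois
from .simulate import DwiSeries

__all__ = [
    "RC_FACTOR",
    "percent_bias",
    "cv_percent",
    "repeatability",
    "RepeatabilityResult",
    "linearity",
    "LinearityResult",
    "precision_cv",
    "snr_b0",
    "b_value_dependence",
    "BValueDependence",
    "Tolerance",
    "ConformanceResult",
    "QIBA_TOLERANCES",
    "PhantomSessionMeasurement",
    "measure_phantom_series",
    "run_qiba_battery",
    "StudySummary",
    "multi_study_summary",
    "grand_row",
    "OrganMeasurement",
    "OrganSummary",
    "organ_level_summary",
]

#: 95 % repeatability-coefficient factor, 1.96 * sqrt(2)
RC_FACTOR = 2.77

#: battery vial-ROI diameter, mm — emulates the automated whole-vial analysis
#: ROIs (≈2/3 of the 30 mm vial diameter); the 10 mm default of
#: ``place_vial_rois`` is the *manual* comparison-ROI convention.
BATTERY_ROI_DIAMETER_MM = 20.0


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def percent_bias(measured: float, reference: float) -> float:
    """Signed percent deviation of a measurement from its reference."""
    if reference <= 0:
        raise ValueError("reference ADC must be positive")
    return 100.0 * (measured - reference) / reference


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, %: 100 × sample SD (ddof=1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cv_percent needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("cv_percent undefined for zero mean")
    return 100.0 * v.std(ddof=1) / mean


class RepeatabilityResult(NamedTuple):
    wsd: float  # within-subject SD, same units as the inputs
    rc: float  # repeatability coefficient, 2.77 × wSD
    cv: float  # %, 100 × wSD / mean


def repeatability(values: Sequence[float]) -> RepeatabilityResult:
    """Repeatability statistics of repeated measurements of one quantity.

    Applies both to same-day repetitions (short-term) and to the first
    measurements of consecutive days (between-session); with n = 2 the sample
    SD reduces to |x1 − x2|/√2.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("repeatability needs at least 2 repetitions")
    wsd = float(v.std(ddof=1))
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("repeatability CV undefined for zero mean")
    return RepeatabilityResult(wsd=wsd, rc=RC_FACTOR * wsd, cv=100.0 * wsd / mean)


class LinearityResult(NamedTuple):
    r_squared: float
    slope: float
    intercept: float


def linearity(measured: Sequence[float], reference: Sequence[float]) -> LinearityResult:
    """OLS line of measured on reference ADC over the phantom vials."""
    y = np.asarray(measured, dtype=float)
    x = np.asarray(reference, dtype=float)
    if x.size != y.size:
        raise ValueError("measured and reference lengths differ")
    if np.unique(x).size < 3:
        raise ValueError("linearity needs >= 3 distinct reference values")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate reference spread")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return LinearityResult(r_squared=r2, slope=slope, intercept=intercept)


def precision_cv(adc_map, roi) -> float:
    """Within-ROI spatial CV (%) of voxel ADC values, single repetition.

    This is the spatial reading of the profile's precision metric — the only
    one consistent with computing it from the first repetition alone.
    """
    meas = extract_roi_stats(adc_map, roi)
    if meas.n_pixels < 2:
        raise ValueError("precision_cv needs >= 2 valid voxels")
    if meas.mean_adc == 0:
        raise ValueError("precision_cv undefined for zero ROI mean")
    return 100.0 * meas.sd_adc / meas.mean_adc


def snr_b0(series: DwiSeries, roi) -> float:
    """SNR (mean/SD) of the decoded b = 0 signal over a ROI, one repetition.

    Noiseless data have zero SD; the degenerate case is reported as +inf
    rather than an error so that conformance reporting can flag it.
    """
    hits = np.flatnonzero(series.b_values == 0)
    if hits.size == 0:
        raise ValueError("series has no b = 0 volume")
    from .roi import _roi_mask

    mask = _roi_mask(roi, series.grid)
    vals = series.physical_signal()[hits[0]][mask]
    if vals.size < 2:
        raise ValueError("SNR ROI has fewer than 2 voxels")
    sd = float(vals.std(ddof=1))
    mean = float(vals.mean())
    if sd == 0:
        return math.inf
    return mean / sd


class BValueDependence(NamedTuple):
    max_dep_percent: float
    worst_pair: tuple[float, float]
    per_pair: dict[tuple[float, float], float]  # pair -> Dep_b %
    per_pair_adc: dict[tuple[float, float], float]  # pair -> ROI-mean ADC µm²/ms
    max_pairwise_spread_percent: float  # secondary reading: pair vs pair


def b_value_dependence(series: DwiSeries, roi, **fit_kwargs) -> BValueDependence:
    """Worst-case ADC discrepancy among b-value pairs (Dep_b, %).

    For every pair (b_i, b_j) the ROI-mean two-point ADC is compared with the
    ROI mean of the all-b fit: ``Dep_b = 100 |ADC_pair − ADC_all| / ADC_all``.
    The maximum pairwise-vs-pairwise spread is reported secondarily.
    """
    b = np.unique(series.b_values)
    if b.size < 3:
        raise ValueError("b-value dependence needs >= 3 distinct b-values")
    all_fit = fit_adc_map(series, **fit_kwargs)
    ref = extract_roi_stats(all_fit, roi).mean_adc
    if not math.isfinite(ref) or ref == 0:
        raise ValueError("all-b reference ADC is degenerate in the ROI")
    per_pair = {}
    pair_means = {}
    for b1, b2 in itertools.combinations(sorted(b), 2):
        m = fit_adc_map(series, b_subset=(b1, b2), method="two_point", **fit_kwargs)
        mean = extract_roi_stats(m, roi).mean_adc
        pair_means[(b1, b2)] = mean
        per_pair[(b1, b2)] = 100.0 * abs(mean - ref) / ref
    worst = max(per_pair, key=per_pair.get)
    means = np.array(list(pair_means.values()))
    spread = 100.0 * (means.max() - means.min()) / ref
    return BValueDependence(
        max_dep_percent=per_pair[worst],
        worst_pair=worst,
        per_pair=per_pair,
        per_pair_adc=pair_means,
        max_pairwise_spread_percent=float(spread),
    )


# ---------------------------------------------------------------------------
# conformance battery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tolerance:
    """A one- or two-sided bound with its direction."""

    kind: str  # 'le' | 'lt' | 'ge' | 'gt' | 'abs_le' | 'range'
    bound: float | tuple[float, float]

    def check(self, value: float) -> bool:
        # inclusive bounds tolerate machine-precision boundary hits (the
        # stated tolerances carry 3-4 significant figures); strict bounds stay
        # strict
        def close(a: float, b: float) -> bool:
            return math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12)

        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        if self.kind == "le":
            return value <= self.bound or close(value, self.bound)
        if self.kind == "lt":
            return value < self.bound
        if self.kind == "ge":
            return value >= self.bound or close(value, self.bound)
        if self.kind == "gt":
            return value > self.bound
        if self.kind == "abs_le":
            return abs(value) <= self.bound or close(abs(value), self.bound)
        if self.kind == "range":
            lo, hi = self.bound
            return (lo <= value or close(value, lo)) and (value <= hi or close(value, hi))
        raise ValueError(f"unknown tolerance kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "range":
            return f"{self.bound[0]} <= value <= {self.bound[1]}"
        return {
            "le": f"<= {self.bound}",
            "lt": f"< {self.bound}",
            "ge": f">= {self.bound}",
            "gt": f"> {self.bound}",
            "abs_le": f"|value| <= {self.bound}",
        }[self.kind]


#: Diffusion Profile tolerances, keyed (test, metric)
QIBA_TOLERANCES: dict[tuple[str, str], Tolerance] = {
    ("A", "bias_percent"): Tolerance("abs_le", 3.600),
    ("B", "rc_st"): Tolerance("le", 0.015),
    ("B", "cv_st_percent"): Tolerance("le", 0.5),
    ("C", "rc_bs"): Tolerance("le", 0.065),
    ("C", "cv_bs_percent"): Tolerance("le", 2.2),
    ("D", "r_squared"): Tolerance("gt", 0.9),
    ("D", "slope"): Tolerance("range", (0.95, 1.05)),
    ("E", "cv_p_percent"): Tolerance("lt", 2.0),
    ("F", "snr_b0"): Tolerance("ge", 50.0),
    ("G", "max_dep_b_percent"): Tolerance("lt", 2.0),
}


@dataclass(frozen=True)
class ConformanceResult:
    test_id: str  # 'A'..'G'
    metric_name: str
    value: float | None  # None => not assessable (reported N/A)
    tolerance: str
    passed: bool | None  # None when value is None
    inputs_summary: dict = field(default_factory=dict)
    note: str = ""

    @property
    def not_assessable(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class PhantomSessionMeasurement:
    """Per-series phantom measurements consumed by the battery."""

    scanner_id: str
    day: int
    repetition: int
    vial_stats: Mapping[int, RoiMeasurement]  # vial id -> ROI statistics
    snr_b0: float | None = None
    depb: BValueDependence | None = None


def measure_phantom_series(
    series: DwiSeries,
    layout: PhantomLayout,
    *,
    b_subset: Sequence[float] | None = None,
    roi_diameter_mm: float = BATTERY_ROI_DIAMETER_MM,
    n_slices: int = 3,
    compute_snr: bool = True,
    compute_depb: bool = True,
    **fit_kwargs,
) -> PhantomSessionMeasurement:
    """Fit one series and extract the per-vial ROI statistics the battery needs.

    ``compute_depb=False`` skips the b-value-dependence sweep (one extra map
    fit per b-pair) for bulk simulations that only need tests A–C; the
    battery then reports test G as N/A for that session.
    """
    adc_map = fit_adc_map(series, b_subset=b_subset, **fit_kwargs)
    rois = place_vial_rois(layout, adc_map.grid, diameter_mm=roi_diameter_mm, n_slices=n_slices)
    vial_stats = {
        v.vial_id: extract_roi_stats(adc_map, rois[f"vial_{v.vial_id}"])
        for v in layout.vials
    }
    vial1_roi = rois["vial_1"]
    snr = (
        snr_b0(series, vial1_roi)
        if compute_snr and (series.b_values == 0).any()
        else None
    )
    b_used = series.b_values if b_subset is None else np.asarray(b_subset, float)
    depb = (
        b_value_dependence(series, vial1_roi, **fit_kwargs)
        if compute_depb and np.unique(b_used).size >= 3
        else None
    )
    return PhantomSessionMeasurement(
        scanner_id=series.scanner_id,
        day=series.day,
        repetition=series.repetition,
        vial_stats=vial_stats,
        snr_b0=snr,
        depb=depb,
    )


def _result(
    test: str,
    metric: str,
    value: float | None,
    inputs: dict,
    note: str = "",
) -> ConformanceResult:
    tol = QIBA_TOLERANCES[(test, metric)]
    return ConformanceResult(
        test_id=test,
        metric_name=metric,
        value=value,
        tolerance=tol.describe(),
        passed=None if value is None else tol.check(value),
        inputs_summary=inputs,
        note=note,
    )


def run_qiba_battery(
    measurements: Sequence[PhantomSessionMeasurement],
    layout: PhantomLayout,
    *,
    vial_id: int = 1,
    bias_basis: str = "rep1",
) -> list[ConformanceResult]:
    """Evaluate the Diffusion Profile tests A–G for one scanner.

    ``measurements`` holds one entry per (day, repetition) of one scanner's
    phantom sessions; day 1 must carry the four same-day repetitions.  A
    missing day 2 does not fail: test C is reported as N/A (value ``None``),
    matching how a lost second session is tabulated.  ``bias_basis`` selects
    whether test A uses the first repetition (default) or the mean of the
    four repetitions.
    """
    if bias_basis not in ("rep1", "mean4"):
        raise ValueError(f"unknown bias_basis {bias_basis!r}")
    by_day: dict[int, dict[int, PhantomSessionMeasurement]] = {}
    for m in measurements:
        by_day.setdefault(m.day, {})[m.repetition] = m
    if 1 not in by_day:
        raise ValueError("battery requires day-1 measurements")
    day1 = by_day[1]
    if 1 not in day1:
        raise ValueError("tests A/D/E/F/G require day-1 repetition 1")
    reps = sorted(day1)
    if len(reps) < 2:
        raise ValueError("test B requires repeated day-1 measurements")
    scanner = measurements[0].scanner_id
    ref = layout.vial(vial_id).reference_adc

    def vmean(m: PhantomSessionMeasurement, vid: int = vial_id) -> float:
        return m.vial_stats[vid].mean_adc

    results: list[ConformanceResult] = []
    base = {"scanner": scanner, "vial": vial_id}

    # A — accuracy
    if bias_basis == "rep1":
        measured = vmean(day1[1])
        a_inputs = {**base, "day": 1, "repetition": 1}
    else:
        measured = float(np.mean([vmean(day1[r]) for r in reps]))
        a_inputs = {**base, "day": 1, "repetitions": reps}
    results.append(_result("A", "bias_percent", percent_bias(measured, ref), a_inputs))

    # B — short-term repeatability over the same-day repetitions
    rep_means = [vmean(day1[r]) for r in reps]
    st = repeatability(rep_means)
    b_inputs = {**base, "day": 1, "repetitions": reps}
    results.append(_result("B", "rc_st", st.rc, b_inputs))
    results.append(_result("B", "cv_st_percent", st.cv, b_inputs))

    # C — between-session repeatability over day firsts
    c_inputs = {**base, "days": sorted(by_day)}
    if 2 in by_day and 1 in by_day[2]:
        bs = repeatability([vmean(day1[1]), vmean(by_day[2][1])])
        results.append(_result("C", "rc_bs", bs.rc, c_inputs))
        results.append(_result("C", "cv_bs_percent", bs.cv, c_inputs))
    else:
        note = "day-2 session absent; reported N/A"
        results.append(_result("C", "rc_bs", None, c_inputs, note))
        results.append(_result("C", "cv_bs_percent", None, c_inputs, note))

    # D — linearity across all vials, repetition 1
    first = day1[1]
    vials = sorted(first.vial_stats)
    lin = linearity(
        [first.vial_stats[v].mean_adc for v in vials],
        [layout.vial(v).reference_adc for v in vials],
    )
    d_inputs = {"scanner": scanner, "day": 1, "repetition": 1, "vials": vials}
    results.append(_result("D", "r_squared", lin.r_squared, d_inputs))
    results.append(_result("D", "slope", lin.slope, d_inputs))

    # E — precision (spatial CV of repetition 1)
    stat1 = first.vial_stats[vial_id]
    cv_p = (
        100.0 * stat1.sd_adc / stat1.mean_adc
        if stat1.n_pixels >= 2 and stat1.mean_adc != 0
        else None
    )
    results.append(_result("E", "cv_p_percent", cv_p, {**base, "day": 1, "repetition": 1}))

    # F — SNR at b = 0
    f_note = ""
    snr = first.snr_b0
    if snr is not None and math.isinf(snr):
        f_note = "zero noise SD: SNR degenerate (infinite)"
    results.append(
        _result("F", "snr_b0", snr, {**base, "day": 1, "repetition": 1}, f_note)
    )

    # G — b-value dependence
    if first.depb is None:
        results.append(
            _result(
                "G",
                "max_dep_b_percent",
                None,
                {**base, "day": 1, "repetition": 1},
                "fewer than 3 b-values; reported N/A",
            )
        )
    else:
        results.append(
            _result(
                "G",
                "max_dep_b_percent",
                first.depb.max_dep_percent,
                {**base, "day": 1, "repetition": 1, "worst_pair": first.depb.worst_pair},
            )
        )
    return results


# ---------------------------------------------------------------------------
# multi-scanner aggregation
# ---------------------------------------------------------------------------


def grand_row(bias_percent: Sequence[float], cv_percent_values: Sequence[float]) -> tuple[float, float]:
    """Unweighted over-vials means of per-vial bias and CV (the 'Av All' row)."""
    b = np.asarray(bias_percent, dtype=float)
    c = np.asarray(cv_percent_values, dtype=float)
    if b.size == 0 or c.size == 0:
        raise ValueError("grand_row needs non-empty columns")
    return float(b.mean()), float(c.mean())


@dataclass
class StudySummary:
    """Multi-scanner phantom aggregation.

    ``per_scanner``: one row per (scanner, vial) with the day-1 intra-scanner
    mean ADC (over repetitions), its SD, bias, and between-day CV_BS where a
    day 2 exists.  ``per_vial``: inter-scanner mean bias and CV per vial.
    ``grand_bias``/``grand_cv``: unweighted means over vials.
    """

    per_scanner: pd.DataFrame
    per_vial: pd.DataFrame
    grand_bias: float
    grand_cv: float

    def vial_table(self) -> pd.DataFrame:
        """Wide per-vial table (reference, bias, CV) plus the grand row."""
        t = self.per_vial.copy()
        grand = pd.DataFrame(
            [
                {
                    "vial_id": "all",
                    "reference_adc": np.nan,
                    "inter_scanner_bias_percent": self.grand_bias,
                    "inter_scanner_cv_percent": self.grand_cv,
                }
            ]
        )
        return pd.concat([t, grand], ignore_index=True)


def multi_study_summary(
    per_scanner_measurements: Mapping[str, Sequence[PhantomSessionMeasurement]],
    layout: PhantomLayout,
) -> StudySummary:
    """Inter-scanner reproducibility (CV) and average bias per phantom vial.

    Per scanner and vial the day-1 repetitions are averaged into an
    intra-scanner mean ADC and average bias; per vial the inter-scanner mean
    bias is the unweighted mean of the per-scanner biases and the
    inter-scanner CV is the CV of the per-scanner day-1 mean ADCs; the grand
    row averages both columns over vials.
    """
    scanners = sorted(per_scanner_measurements)
    if len(scanners) < 2:
        raise ValueError("multi_study_summary needs >= 2 scanners")
    vial_sets = []
    day1_means: dict[str, dict[int, float]] = {}
    rows = []
    for sc in scanners:
        meas = [m for m in per_scanner_measurements[sc] if m.day == 1]
        if not meas:
            raise ValueError(f"scanner {sc!r} has no day-1 measurements")
        vials = sorted(meas[0].vial_stats)
        vial_sets.append(tuple(vials))
        day2 = [m for m in per_scanner_measurements[sc] if m.day == 2]
        day1_means[sc] = {}
        for v in vials:
            ref = layout.vial(v).reference_adc
            rep_means = [m.vial_stats[v].mean_adc for m in sorted(meas, key=lambda m: m.repetition)]
            mean_adc = float(np.mean(rep_means))
            day1_means[sc][v] = mean_adc
            biases = [percent_bias(x, ref) for x in rep_means]
            cv_bs = np.nan
            if day2:
                d1_first = min(meas, key=lambda m: m.repetition).vial_stats[v].mean_adc
                d2_first = min(day2, key=lambda m: m.repetition).vial_stats[v].mean_adc
                cv_bs = repeatability([d1_first, d2_first]).cv
            rows.append(
                {
                    "scanner": sc,
                    "vial_id": v,
                    "mean_adc": mean_adc,
                    "sd_adc": float(np.std(rep_means, ddof=1)) if len(rep_means) > 1 else 0.0,
                    "bias_percent": float(np.mean(biases)),
                    "cv_bs_percent": cv_bs,
                }
            )
    if len(set(vial_sets)) != 1:
        raise ValueError("scanners report mismatched vial sets")
    vials = list(vial_sets[0])

    per_vial_rows = []
    for v in vials:
        ref = layout.vial(v).reference_adc
        means = [day1_means[sc][v] for sc in scanners]
        biases = [percent_bias(m, ref) for m in means]
        per_vial_rows.append(
            {
                "vial_id": v,
                "reference_adc": ref,
                "inter_scanner_bias_percent": float(np.mean(biases)),
                "inter_scanner_cv_percent": cv_percent(means),
            }
        )
    per_vial = pd.DataFrame(per_vial_rows)
    g_bias, g_cv = grand_row(
        per_vial["inter_scanner_bias_percent"], per_vial["inter_scanner_cv_percent"]
    )
    return StudySummary(
        per_scanner=pd.DataFrame(rows),
        per_vial=per_vial,
        grand_bias=g_bias,
        grand_cv=g_cv,
    )


# ---------------------------------------------------------------------------
# organ-level (in vivo) aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganMeasurement:
    scanner_id: str
    day: int
    organ: str
    measurement: RoiMeasurement


@dataclass
class OrganSummary:
    """Per-organ intra-scanner repeatability and inter-scanner reproducibility.

    ``intra``: one row per (organ, scanner) with the day means, the over-days
    mean ADC and the between-session CV_BS (NaN when only one contained day
    exists — organs clipped by the field of view on one day are reported from
    the other day alone).  ``inter``: day-1 mean/SD/CV across scanners.
    """

    intra: pd.DataFrame
    inter: pd.DataFrame


def organ_level_summary(measurements: Sequence[OrganMeasurement]) -> OrganSummary:
    contained = [m for m in measurements if m.measurement.contained]
    organs = sorted({m.organ for m in contained})
    scanners = sorted({m.scanner_id for m in measurements})
    intra_rows = []
    for organ in organs:
        for sc in scanners:
            day_means = {
                m.day: m.measurement.mean_adc
                for m in contained
                if m.organ == organ and m.scanner_id == sc
            }
            if not day_means:
                continue
            cv_bs = (
                repeatability([day_means[1], day_means[2]]).cv
                if 1 in day_means and 2 in day_means
                else np.nan
            )
            intra_rows.append(
                {
                    "organ": organ,
                    "scanner": sc,
                    "day1_adc": day_means.get(1, np.nan),
                    "day2_adc": day_means.get(2, np.nan),
                    "mean_adc": float(np.mean(list(day_means.values()))),
                    "cv_bs_percent": cv_bs,
                }
            )
    inter_rows = []
    for organ in organs:
        d1 = [
            m.measurement.mean_adc
            for m in contained
            if m.organ == organ and m.day == 1
        ]
        if len(d1) < 2:
            inter_rows.append(
                {
                    "organ": organ,
                    "n_scanners": len(d1),
                    "mean_adc": d1[0] if d1 else np.nan,
                    "sd_adc": np.nan,
                    "cv_percent": np.nan,
                }
            )
            continue
        inter_rows.append(
            {
                "organ": organ,
                "n_scanners": len(d1),
                "mean_adc": float(np.mean(d1)),
                "sd_adc": float(np.std(d1, ddof=1)),
                "cv_percent": cv_percent(d1),
            }
        )
    return OrganSummary(intra=pd.DataFrame(intra_rows), inter=pd.DataFrame(inter_rows))
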