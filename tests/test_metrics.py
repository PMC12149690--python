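"""Conformance statistics: formula oracles, battery behavior, aggregation."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adcqa import (
    DwiSeries,
    OrganMeasurement,
    RC_FACTOR,
    SimulationConfig,
    b_value_dependence,
    cv_percent,
    grand_row,
    linearity,
    measure_phantom_series,
    multi_study_summary,
    organ_level_summary,
    percent_bias,
    precision_cv,
    repeatability,
    run_qiba_battery,
    simulate_study,
    snr_b0,
    two_point_adc,
    place_vial_rois,
)
from adcqa.roi import MaskRoi, RoiMeasurement
from tests.conftest import SMALL_MATRIX, SMALL_VOXEL

values_list = st.lists(st.floats(0.5, 2.0), min_size=2, max_size=10)


class TestScalarFormulas:
    def test_percent_bias(self):
        assert percent_bias(1.109, 1.109) == 0.0
        assert percent_bias(1.209, 1.109) == pytest.approx(100 * 0.1 / 1.109)
        assert percent_bias(1.209, 1.109) == pytest.approx(9.02, abs=5e-3)
        with pytest.raises(ValueError):
            percent_bias(1.0, 0.0)

    def test_cv_percent_examples(self):
        assert cv_percent([1.11, 1.11, 1.11]) == 0.0
        assert cv_percent([1.0, 1.1]) == pytest.approx(6.734, abs=5e-4)
        with pytest.raises(ValueError):
            cv_percent([1.0])
        with pytest.raises(ValueError):
            cv_percent([1.0, -1.0])

    @given(values=values_list)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cv_matches_stdlib_recomputation(self, values):
        assert cv_percent(values) == pytest.approx(
            100 * statistics.stdev(values) / statistics.mean(values), rel=1e-12
        )

    def test_repeatability_identities(self):
        assert repeatability([1.1, 1.1, 1.1, 1.1]) == (0.0, 0.0, 0.0)
        # frozen pair: wSD 0.00433 at mean 1.109 -> RC ~0.0120, CV ~0.39 %
        spread = np.array([-1.5, -0.5, 0.5, 1.5])
        vals = 1.109 + 0.00433 * spread / spread.std(ddof=1)
        res = repeatability(vals)
        assert res.wsd == pytest.approx(0.00433, rel=1e-9)
        assert res.rc == pytest.approx(0.0120, abs=5e-5)
        assert res.cv == pytest.approx(0.39, abs=5e-3)
        # two-value (between-session) case reduces to |x1-x2|/sqrt(2)
        res2 = repeatability([1.0, 1.2])
        assert res2.wsd == pytest.approx(0.2 / math.sqrt(2), rel=1e-12)

    @given(values=values_list)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rc_cv_consistency(self, values):
        res = repeatability(values)
        assert res.rc == pytest.approx(
            RC_FACTOR * (res.cv / 100) * statistics.mean(values), rel=1e-9, abs=1e-12
        )

    def test_linearity_exact_cases(self):
        ref = [1.109, 0.817, 0.579, 0.380, 0.220, 0.110]
        perfect = linearity(ref, ref)
        assert perfect.r_squared == pytest.approx(1.0)
        assert perfect.slope == pytest.approx(1.0)
        scaled = linearity([1.02 * r for r in ref], ref)
        assert scaled.slope == pytest.approx(1.02, rel=1e-12)
        assert scaled.r_squared == pytest.approx(1.0)
        with pytest.raises(ValueError):
            linearity([1.0, 1.1], [0.5, 0.6])

    def test_linearity_matches_polyfit(self, rng):
        ref = np.array([1.109, 1.109, 0.817, 0.579, 0.380, 0.220, 0.110])
        for _ in range(10):
            meas = ref * (1 + rng.normal(0, 0.02, ref.size))
            ours = linearity(meas, ref)
            slope, intercept = np.polyfit(ref, meas, 1)
            assert ours.slope == pytest.approx(slope, rel=1e-10)
            assert ours.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-12)
            ss_res = np.sum((meas - (intercept + slope * ref)) ** 2)
            ss_tot = np.sum((meas - meas.mean()) ** 2)
            assert ours.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)


class TestRoiBasedMetrics:
    def test_precision_cv_direct_arithmetic(self, rng, noiseless_map):
        from adcqa import AdcMap

        vals = rng.normal(1.1, 0.05, (1, 4, 4))
        adc_map = AdcMap(
            adc=vals, valid_mask=np.ones(vals.shape, bool),
            b_values_used=np.array([0.0, 500.0]), voxel_size=(5.0, 1, 1),
        )
        roi = MaskRoi("r", np.ones(vals.shape, bool))
        assert precision_cv(adc_map, roi) == pytest.approx(
            100 * vals.std(ddof=1) / vals.mean(), rel=1e-12
        )

    def test_snr_constructed_region(self, rng):
        z = rng.normal(size=100)
        z = (z - z.mean()) / z.std(ddof=1)
        vals = 800 + 10 * z
        signal = np.stack(
            [vals.reshape(1, 10, 10), np.full((1, 10, 10), 500.0)]
        )
        series = DwiSeries(signal=signal, b_values=np.array([0.0, 500.0]))
        roi = MaskRoi("r", np.ones((1, 10, 10), bool))
        assert snr_b0(series, roi) == pytest.approx(80.0, rel=1e-12)

    def test_snr_requires_b0(self):
        series = DwiSeries(
            signal=np.ones((2, 1, 4, 4)), b_values=np.array([150.0, 500.0])
        )
        with pytest.raises(ValueError, match="b = 0"):
            snr_b0(series, MaskRoi("r", np.ones((1, 4, 4), bool)))

    def test_snr_degenerate_noiseless_is_inf(self, layout, noiseless_series):
        roi = place_vial_rois(layout, noiseless_series.grid)["vial_1"]
        assert math.isinf(snr_b0(noiseless_series, roi))

    def test_depb_zero_for_model_consistent_data(self, layout, noiseless_series):
        roi = place_vial_rois(layout, noiseless_series.grid)["vial_1"]
        dep = b_value_dependence(noiseless_series, roi)
        assert dep.max_dep_percent == pytest.approx(0.0, abs=1e-9)
        assert dep.max_pairwise_spread_percent == pytest.approx(0.0, abs=1e-9)
        # pairwise values agree with the scalar closed form on uniform signal
        phys = noiseless_series.physical_signal()
        roi_mask = noiseless_series.grid.disk_mask(roi.center_xy, roi.diameter_mm)
        s = {b: phys[i, 2][roi_mask].mean() for i, b in enumerate(noiseless_series.b_values)}
        for (b1, b2), dep_val in dep.per_pair.items():
            assert dep_val == pytest.approx(0.0, abs=1e-9)
            assert two_point_adc(s[b1], s[b2], b1, b2) == pytest.approx(1.109, rel=1e-9)

    def test_depb_noise_floor_implicates_highest_b(self, layout, noiseless_series):
        corrupted = DwiSeries(
            signal=noiseless_series.signal.copy(),
            b_values=noiseless_series.b_values.copy(),
            voxel_size=noiseless_series.voxel_size,
        )
        corrupted.signal[-1] += 30.0  # additive floor on the b=2000 volume
        roi = place_vial_rois(layout, corrupted.grid)["vial_1"]
        dep = b_value_dependence(corrupted, roi)
        assert dep.max_dep_percent > 2.0
        assert dep.max_pairwise_spread_percent > dep.max_dep_percent
        # the pair estimate farthest from the generating ADC involves b=2000
        # (the floor drags the all-b reference too, so Dep_b vs. that
        # reference can implicate a clean pair; the raw pair ADCs cannot)
        worst_vs_truth = max(dep.per_pair_adc, key=lambda p: abs(dep.per_pair_adc[p] - 1.109))
        assert 2000.0 in worst_vs_truth


@pytest.fixture(scope="module")
def noiseless_study(layout):
    cfg = SimulationConfig(matrix=SMALL_MATRIX, voxel_size=SMALL_VOXEL)
    series = simulate_study(layout, cfg, ["A"], days=2, repetitions=4)
    return [measure_phantom_series(s, layout) for s in series]


class TestBattery:
    def test_noiseless_study_all_pass_with_degenerate_snr(self, layout, noiseless_study):
        results = run_qiba_battery(noiseless_study, layout)
        assert {r.test_id for r in results} == set("ABCDEFG")
        assert all(r.passed for r in results)
        f = next(r for r in results if r.test_id == "F")
        assert math.isinf(f.value) and "degenerate" in f.note

    def test_battery_deterministic(self, layout, noiseless_study):
        a = run_qiba_battery(noiseless_study, layout)
        b = run_qiba_battery(noiseless_study, layout)
        assert a == b

    def test_injected_bias_fails_exactly_test_a(self, layout):
        cfg = SimulationConfig(
            matrix=SMALL_MATRIX, voxel_size=SMALL_VOXEL,
            scanner_bias_percent={"A": 5.0},
        )
        series = simulate_study(layout, cfg, ["A"], days=2, repetitions=4)
        meas = [measure_phantom_series(s, layout) for s in series]
        results = run_qiba_battery(meas, layout)
        failed = {r.test_id for r in results if r.passed is False}
        assert failed == {"A"}
        bias = next(r for r in results if r.test_id == "A").value
        assert bias == pytest.approx(5.0, abs=1e-6)

    def test_missing_day2_reports_na_for_test_c(self, layout):
        cfg = SimulationConfig(matrix=SMALL_MATRIX, voxel_size=SMALL_VOXEL)
        series = simulate_study(layout, cfg, ["A"], days=1, repetitions=4)
        meas = [measure_phantom_series(s, layout) for s in series]
        results = run_qiba_battery(meas, layout)
        c = [r for r in results if r.test_id == "C"]
        assert all(r.value is None and r.passed is None for r in c)
        assert all("N/A" in r.note for r in c)
        others = [r for r in results if r.test_id != "C"]
        assert all(r.passed for r in others)

    def test_missing_repetitions_raise(self, layout, noiseless_study):
        only_rep2 = [m for m in noiseless_study if m.repetition == 2]
        with pytest.raises(ValueError, match="repetition 1"):
            run_qiba_battery(only_rep2, layout)
        rep1_only = [m for m in noiseless_study if m.repetition == 1 and m.day == 1]
        with pytest.raises(ValueError, match="test B"):
            run_qiba_battery(rep1_only, layout)

    def test_mean4_bias_basis(self, layout, noiseless_study):
        rep1 = run_qiba_battery(noiseless_study, layout, bias_basis="rep1")
        mean4 = run_qiba_battery(noiseless_study, layout, bias_basis="mean4")
        a1 = next(r for r in rep1 if r.test_id == "A").value
        a4 = next(r for r in mean4 if r.test_id == "A").value
        assert a1 == pytest.approx(a4, abs=1e-9)  # noiseless: identical reps


def _meas(mean, label="vial", n=100):
    return RoiMeasurement(
        label=label, mean_adc=mean, sd_adc=0.01, n_pixels=n,
        per_slice_means=[mean], contained=True,
    )


def _session(scanner, day, rep, vial_means):
    from adcqa import PhantomSessionMeasurement

    return PhantomSessionMeasurement(
        scanner_id=scanner, day=day, repetition=rep,
        vial_stats={v: _meas(m) for v, m in vial_means.items()},
    )


class TestMultiStudy:
    def test_two_scanner_toy_matches_spreadsheet(self, layout):
        x = {
            1: [1.12, 1.10],  # scanner X, vial 1, reps 1-2
            4: [0.80, 0.82],
        }
        y = {1: [1.09, 1.11], 4: [0.84, 0.80]}
        per_scanner = {
            "X": [_session("X", 1, r + 1, {v: x[v][r] for v in x}) for r in range(2)],
            "Y": [_session("Y", 1, r + 1, {v: y[v][r] for v in y}) for r in range(2)],
        }
        summary = multi_study_summary(per_scanner, layout)
        refs = {1: 1.109, 4: 0.817}
        for v in (1, 4):
            mx, my = np.mean(x[v]), np.mean(y[v])
            exp_bias = np.mean(
                [100 * (mx - refs[v]) / refs[v], 100 * (my - refs[v]) / refs[v]]
            )
            exp_cv = 100 * np.std([mx, my], ddof=1) / np.mean([mx, my])
            row = summary.per_vial[summary.per_vial.vial_id == v].iloc[0]
            assert row.inter_scanner_bias_percent == pytest.approx(exp_bias, rel=1e-12)
            assert row.inter_scanner_cv_percent == pytest.approx(exp_cv, rel=1e-12)
        assert summary.grand_bias == pytest.approx(
            summary.per_vial.inter_scanner_bias_percent.mean(), rel=1e-12
        )

    def test_identical_scanners_zero_cv(self, layout):
        vials = {1: 1.109, 4: 0.817}
        per_scanner = {
            s: [_session(s, 1, 1, vials), _session(s, 1, 2, vials)] for s in "ABC"
        }
        summary = multi_study_summary(per_scanner, layout)
        np.testing.assert_allclose(summary.per_vial.inter_scanner_cv_percent, 0, atol=1e-9)
        assert summary.grand_cv == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_vial_sets_raise(self, layout):
        per_scanner = {
            "A": [_session("A", 1, 1, {1: 1.1})],
            "B": [_session("B", 1, 1, {1: 1.1, 4: 0.8})],
        }
        with pytest.raises(ValueError, match="mismatch"):
            multi_study_summary(per_scanner, layout)

    def test_grand_row_arithmetic(self):
        bias, cv = grand_row([1.0, 2.0, 3.0], [0.5, 1.5])
        assert bias == 2.0 and cv == 1.0


class TestOrganSummary:
    def _om(self, scanner, day, organ, mean, contained=True):
        m = RoiMeasurement(organ, mean, 0.05, 50, [mean], contained)
        return OrganMeasurement(scanner_id=scanner, day=day, organ=organ, measurement=m)

    def test_identical_day_pair_zero_cv(self):
        meas = [self._om("A", 1, "brain", 0.83), self._om("A", 2, "brain", 0.83),
                self._om("B", 1, "brain", 0.85)]
        out = organ_level_summary(meas)
        row = out.intra[(out.intra.organ == "brain") & (out.intra.scanner == "A")].iloc[0]
        assert row.cv_bs_percent == 0.0

    def test_day1_only_gives_na_cvbs_but_inter_cv(self):
        meas = [
            self._om("A", 1, "rectum", 1.07),
            self._om("A", 2, "rectum", 1.10),
            self._om("B", 1, "rectum", 1.45),
            self._om("B", 2, "rectum", 1.50, contained=False),  # clipped on day 2
            self._om("C", 1, "rectum", 1.70),
        ]
        out = organ_level_summary(meas)
        row_b = out.intra[(out.intra.scanner == "B")].iloc[0]
        assert np.isnan(row_b.cv_bs_percent)
        assert row_b.mean_adc == pytest.approx(1.45)  # day-1 only
        inter = out.inter.iloc[0]
        d1 = [1.07, 1.45, 1.70]
        assert inter.cv_percent == pytest.approx(100 * np.std(d1, ddof=1) / np.mean(d1))

    def test_three_scanner_known_offsets_closed_form(self):
        meas = [self._om(s, 1, "kidney", v) for s, v in zip("ABC", (1.0, 1.1, 1.2))]
        out = organ_level_summary(meas)
        inter = out.inter.iloc[0]
        assert inter.mean_adc == pytest.approx(1.1)
        assert inter.cv_percent == pytest.approx(100 * np.std([1.0, 1.1, 1.2], ddof=1) / 1.1)

    def test_non_contained_excluded_everywhere(self):
        meas = [
            self._om("A", 1, "liver", 1.5, contained=False),
            self._om("B", 1, "liver", 1.6),
        ]
        out = organ_level_summary(meas)
        assert out.inter.iloc[0].n_scanners == 1
        assert np.isnan(out.inter.iloc[0].cv_percent)
        assert (out.intra.scanner == "A").sum() == 0
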