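"""Channel extraction, peak integration, S/N and RT alignment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eicoquant.errors import InsufficientDataError
from eicoquant.method_library import RtTable, Transition
from eicoquant.mzml_io import Run, Scan
from eicoquant.signal_extraction import (
    Chromatogram,
    align_by_internal_standards,
    detect_peak,
    estimate_snr,
    extract_channel,
)

T115 = Transition("x", "x", 319.2275, 115.0388, -22, -31, window_da=0.05)


def _scan(rt, prec, peaks):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return Scan(rt, prec, mz, inten)


def _gauss_chrom(
    n=601, apex=5.0, sigma=0.05, height=1000.0, span=0.5, baseline=0.0, noise=None, ref="x"
):
    t = np.linspace(apex - span, apex + span, n)
    y = height * np.exp(-0.5 * ((t - apex) / sigma) ** 2) + baseline
    if noise is not None:
        y = np.clip(y + noise, 0, None)
    return Chromatogram(ref, t, y)


class TestExtractChannel:
    def test_in_window_centroid_passes_through(self):
        run = [_scan(1.0, 319.2275, [(115.0390, 1000.0)])]
        c = extract_channel(run, T115)
        assert c.intensities.tolist() == [1000.0]

    def test_out_of_window_centroid_excluded(self):
        run = [_scan(1.0, 319.2275, [(115.0900, 1000.0)])]
        c = extract_channel(run, T115)
        assert c.intensities.tolist() == [0.0]

    def test_in_window_centroids_summed(self):
        run = [_scan(1.0, 319.2275, [(115.0380, 400.0), (115.0400, 600.0)])]
        c = extract_channel(run, T115)
        assert c.intensities.tolist() == [1000.0]

    def test_non_matching_precursor_contributes_no_point(self):
        run = [
            _scan(1.0, 319.2275, [(115.0390, 10.0)]),
            _scan(1.1, 351.2168, [(115.0390, 99.0)]),
        ]
        c = extract_channel(run, T115, precursor_tol_da=0.7)
        assert len(c) == 1

    def test_no_matching_scan_gives_empty_chromatogram(self):
        c = extract_channel([_scan(1.0, 500.0, [(115.0390, 1.0)])], T115)
        assert len(c) == 0

    def test_equals_brute_force_double_loop(self, rng):
        for _ in range(30):
            scans = []
            for i in range(rng.integers(1, 15)):
                n = int(rng.integers(0, 20))
                scans.append(
                    Scan(
                        rt_min=float(i) + float(rng.uniform(0, 0.5)),
                        precursor_mz=float(rng.choice([319.2275, 319.9, 351.2, 500.0])),
                        mz=rng.uniform(50, 700, n),
                        intensity=rng.uniform(0, 1e4, n),
                    )
                )
            got = extract_channel(scans, T115, precursor_tol_da=0.7)
            lo, hi = 115.0388 - 0.025, 115.0388 + 0.025
            exp_t, exp_v = [], []
            for s in sorted(scans, key=lambda s: s.rt_min):
                if abs(s.precursor_mz - 319.2275) <= 0.7:
                    exp_t.append(s.rt_min)
                    exp_v.append(
                        sum(v for m, v in zip(s.mz, s.intensity) if lo <= m <= hi)
                    )
            assert np.allclose(got.times, exp_t)
            assert np.allclose(got.intensities, exp_v)


class TestChromatogramInvariants:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            Chromatogram("x", np.array([2.0, 1.0]), np.array([0.0, 0.0]))

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            Chromatogram("x", np.array([1.0, 2.0]), np.array([1.0, -1.0]))


class TestDetectPeak:
    def test_noiseless_gaussian_area_matches_closed_form(self):
        h, sigma = 1000.0, 0.05
        c = _gauss_chrom(height=h, sigma=sigma)
        p = detect_peak(c, 5.0, 0.5)
        assert p.found
        assert p.left_rt_min < p.apex_rt_min < p.right_rt_min
        analytic = h * sigma * math.sqrt(2 * math.pi)
        assert p.area == pytest.approx(analytic, rel=0.01)

    def test_all_zero_trace_not_found(self):
        t = np.linspace(4.5, 5.5, 101)
        p = detect_peak(Chromatogram("x", t, np.zeros_like(t)), 5.0, 0.5)
        assert not p.found and p.area == 0.0

    def test_isomer_apex_assigned_by_retention_time_not_height(self):
        # taller 6-trans peak at 10.09 must not steal the 10.54 assignment
        t = np.linspace(9.5, 11.1, 1601)
        y = 5000.0 * np.exp(-0.5 * ((t - 10.09) / 0.05) ** 2)
        y += 1000.0 * np.exp(-0.5 * ((t - 10.54) / 0.05) ** 2)
        c = Chromatogram("LTB4", t, y)
        p = detect_peak(c, expected_rt_min=10.54, rt_tolerance_min=0.5)
        assert p.apex_rt_min == pytest.approx(10.54, abs=0.005)
        assert p.area == pytest.approx(1000.0 * 0.05 * math.sqrt(2 * math.pi), rel=0.02)
        # and the earlier isomer from its own expected RT
        p2 = detect_peak(c, expected_rt_min=10.09, rt_tolerance_min=0.5)
        assert p2.apex_rt_min == pytest.approx(10.09, abs=0.005)

    def test_empty_and_out_of_window_not_found(self):
        assert not detect_peak(Chromatogram("x", np.array([]), np.array([])), 5.0).found
        c = _gauss_chrom()
        assert not detect_peak(c, 20.0, 0.5).found

    @given(shift=st.floats(-3, 3), scale=st.floats(0.1, 100))
    def test_area_shift_invariant_and_intensity_linear(self, shift, scale):
        c = _gauss_chrom()
        base = detect_peak(c, 5.0, 0.5)
        shifted = Chromatogram("x", c.times + shift, c.intensities)
        p_shift = detect_peak(shifted, 5.0 + shift, 0.5)
        assert p_shift.area == pytest.approx(base.area, rel=1e-9)
        scaled = Chromatogram("x", c.times, c.intensities * scale)
        p_scale = detect_peak(scaled, 5.0, 0.5)
        assert p_scale.area == pytest.approx(base.area * scale, rel=1e-6)


class TestEstimateSnr:
    def test_noiseless_peak_has_infinite_snr(self):
        t = np.linspace(4.5, 5.5, 601)
        y = 1000.0 * np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2) + 50.0
        y[np.abs(t - 5.0) > 0.3] = 50.0  # exactly flat baseline outside the peak
        c = Chromatogram("x", t, y)
        p = detect_peak(c, 5.0, 0.5)
        assert estimate_snr(c, p) == math.inf

    def test_snr_estimates_known_noise_within_25_percent(self, rng):
        h, sd = 2000.0, 20.0
        noise = rng.normal(0, sd, 501)
        c = _gauss_chrom(n=501, height=h, baseline=10 * sd, noise=noise)
        p = detect_peak(c, 5.0, 0.5)
        assert p.found
        snr = estimate_snr(c, p)
        assert snr == pytest.approx(h / sd, rel=0.25)

    def test_not_found_peak_is_a_contract_violation(self):
        c = _gauss_chrom()
        from eicoquant.signal_extraction import PeakResult

        with pytest.raises(ValueError):
            estimate_snr(c, PeakResult.not_found())

    def test_too_few_out_of_peak_points_raises(self):
        from eicoquant.signal_extraction import PeakResult

        c = _gauss_chrom(n=21, span=0.1)  # integration bounds span the trace
        p = PeakResult(found=True, apex_rt_min=5.0, left_rt_min=c.times[1],
                       right_rt_min=c.times[-2], area=1.0, height=1.0, snr=0.0)
        with pytest.raises(InsufficientDataError):
            estimate_snr(c, p)


def _is_library():
    ids = ["A-d4", "B-d4", "C-d4"]
    rts = {"A-d4": 3.0, "B-d4": 6.0, "C-d4": 9.0}
    lib = [
        Transition(i, i, 300.0 + 10 * k, 150.0 + 10 * k, -20, -30, is_internal_standard=True)
        for k, i in enumerate(ids)
    ]
    return lib, RtTable("5.8", rts)


def _runs_with_offsets(offsets):
    lib, rt = _is_library()
    scans = []
    for t, off in zip(lib, offsets):
        apex = rt.rt_for(t.analyte_id) + off
        for x in np.linspace(apex - 0.4, apex + 0.4, 81):
            inten = 1000.0 * math.exp(-0.5 * ((x - apex) / 0.05) ** 2)
            scans.append(
                Scan(x, t.precursor_mz, np.array([t.product_mz]), np.array([inten]))
            )
    scans.sort(key=lambda s: s.rt_min)
    return Run("align", scans), lib, rt


class TestAlignment:
    def test_constant_shift_recovered(self):
        run, lib, rt = _runs_with_offsets([0.10, 0.10, 0.10])
        res = align_by_internal_standards(run, lib, rt)
        assert res.ok and res.n_is_used == 3
        assert res.offset_min == pytest.approx(0.10, abs=0.015)

    def test_median_robust_to_one_outlier(self):
        run, lib, rt = _runs_with_offsets([0.10, 0.10, 0.30])
        res = align_by_internal_standards(run, lib, rt)
        assert res.offset_min == pytest.approx(0.10, abs=0.015)

    def test_blank_run_flags_alignment_failure(self):
        lib, rt = _is_library()
        res = align_by_internal_standards(Run("blank", []), lib, rt)
        assert not res.ok and res.offset_min == 0.0
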