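"""Spot detection and 3D Gaussian fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsquant.detect import (
    CandidatePeak,
    Spot,
    SpotFilter,
    bandpass_filter,
    detect_candidates,
    detect_spots,
    filter_spots,
    fit_spot,
)
from tsquant.geometry import ImageStack

from conftest import SXY, SZ, amp_to_integral, render_spots


class TestBandpass:
    def test_flat_stack_gives_zero_response(self):
        st_ = ImageStack(np.full((7, 32, 32), 50.0))
        f = bandpass_filter(st_, SXY, SZ)
        # constant output, negligible relative to the input scale
        assert np.ptp(f) < 1e-9
        assert np.abs(f).max() < 1e-3 * 50.0

    def test_response_maximum_at_spot_voxel(self):
        st_ = render_spots((9, 32, 32), [(4.0, 15.7, 12.3)], [1500.0])
        f = bandpass_filter(st_, SXY, SZ)
        z, y, x = np.unravel_index(np.argmax(f), f.shape)
        assert (z, y, x) == (4, 16, 12)

    def test_two_equal_spots_give_equal_maxima(self):
        st_ = render_spots((9, 48, 48), [(4.0, 12.0, 12.0), (4.0, 36.0, 36.0)], [1500.0, 1500.0])
        f = bandpass_filter(st_, SXY, SZ)
        assert f[4, 12, 12] == pytest.approx(f[4, 36, 36], rel=1e-6)


class TestDetectCandidates:
    def test_constant_stack_yields_nothing(self):
        f = bandpass_filter(ImageStack(np.full((7, 32, 32), 5.0)), SXY, SZ)
        assert detect_candidates(f) == []

    def test_single_spot_first_candidate_is_brightest_voxel(self):
        st_ = render_spots((9, 32, 32), [(4.0, 16.0, 12.0)], [1500.0])
        f = bandpass_filter(st_, SXY, SZ)
        cands = detect_candidates(f)
        assert cands[0].z == 4 and cands[0].y == 16 and cands[0].x == 12

    def test_ten_noisy_spots_detected_exactly(self):
        """10 spots at peak SNR >= 10 yield exactly 10 candidates, each
        within one voxel of a true center."""
        rng = np.random.default_rng(0)
        centers = [(5.0, 16.0 + 24 * (i // 4), 16.0 + 24 * (i % 4)) for i in range(10)]
        st_ = render_spots((11, 96, 96), centers, [amp_to_integral(100.0)] * 10)
        noisy = ImageStack(rng.poisson(st_.data).astype(float))
        f = bandpass_filter(noisy, SXY, SZ)
        cands = detect_candidates(f)
        assert len(cands) == 10
        truth = np.array(centers)
        for c in cands:
            d = np.abs(truth - np.array([c.z, c.y, c.x])).max(axis=1)
            assert d.min() <= 1.0


class TestFitSpot:
    def test_noiseless_round_trip(self):
        """Subvoxel center recovered to 0.05 voxel; A and B to 1%."""
        center = (5.0, 15.7, 12.3)
        st_ = render_spots((11, 32, 32), [center], [amp_to_integral(100.0)], background=10.0)
        spot = fit_spot(st_, CandidatePeak(5, 16, 12, 0.0))
        assert spot.ok
        assert abs(spot.z0 - 5.0) < 0.05
        assert abs(spot.y0 - 15.7) < 0.05
        assert abs(spot.x0 - 12.3) < 0.05
        assert spot.amplitude == pytest.approx(100.0, rel=0.01)
        assert spot.background == pytest.approx(10.0, rel=0.01)

    def test_integrated_intensity_closed_form(self):
        st_ = render_spots((11, 32, 32), [(5.0, 16.0, 16.0)], [amp_to_integral(80.0)])
        spot = fit_spot(st_, CandidatePeak(5, 16, 16, 0.0))
        expected = spot.amplitude * (2 * np.pi) ** 1.5 * spot.sigma_xy**2 * spot.sigma_z
        assert spot.integrated_intensity == pytest.approx(expected, rel=1e-9)
        assert spot.integrated_intensity == pytest.approx(amp_to_integral(80.0), rel=0.01)

    def test_flat_window_fails(self):
        st_ = ImageStack(np.full((11, 32, 32), 7.0))
        spot = fit_spot(st_, CandidatePeak(5, 16, 16, 0.0))
        assert not spot.ok

    def test_constant_offset_absorbed_by_background(self):
        center = (5.0, 16.0, 16.0)
        st1 = render_spots((11, 32, 32), [center], [amp_to_integral(90.0)], background=10.0)
        st2 = ImageStack(st1.data + 500.0)
        s1 = fit_spot(st1, CandidatePeak(5, 16, 16, 0.0))
        s2 = fit_spot(st2, CandidatePeak(5, 16, 16, 0.0))
        assert s1.ok and s2.ok
        assert s2.integrated_intensity == pytest.approx(s1.integrated_intensity, rel=1e-3)
        assert s2.background == pytest.approx(s1.background + 500.0, rel=1e-3)

    def test_translation_equivariance(self):
        i = amp_to_integral(100.0)
        sa = fit_spot(render_spots((11, 48, 48), [(5.0, 20.3, 20.6)], [i]),
                      CandidatePeak(5, 20, 21, 0.0))
        sb = fit_spot(render_spots((11, 48, 48), [(5.0, 29.3, 27.6)], [i]),
                      CandidatePeak(5, 29, 28, 0.0))
        assert sa.ok and sb.ok
        assert sb.y0 - sa.y0 == pytest.approx(9.0, abs=1e-3)
        assert sb.x0 - sa.x0 == pytest.approx(7.0, abs=1e-3)
        assert sb.integrated_intensity == pytest.approx(sa.integrated_intensity, rel=1e-3)

    def test_peak_outside_stack_is_an_error(self):
        st_ = ImageStack(np.zeros((5, 16, 16)))
        with pytest.raises(ValueError):
            fit_spot(st_, CandidatePeak(10, 0, 0, 0.0))


def _mk_spot(amplitude, sigma_xy, sigma_z, ok=True):
    return Spot(5.0, 5.0, 5.0, amplitude, 0.0, sigma_xy, sigma_z, 0.0, ok)


class TestFilterSpots:
    def test_empty_input(self):
        assert filter_spots([], SpotFilter()) == []

    def test_wide_spot_removed(self):
        bounds = SpotFilter(max_sigma_xy=1.5)
        assert filter_spots([_mk_spot(10, 3.0, 1.0)], bounds) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 200.0),
                st.floats(0.05, 5.0),
                st.floats(0.05, 6.0),
                st.booleans(),
            ),
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_predicate(self, raw):
        """filter_spots equals an exhaustive per-spot bound evaluation."""
        spots = [_mk_spot(a, sxy, sz, ok) for a, sxy, sz, ok in raw]
        bounds = SpotFilter(min_amplitude=1.0, max_amplitude=150.0,
                            min_sigma_xy=0.3, max_sigma_xy=3.0,
                            min_sigma_z=0.3, max_sigma_z=4.0)
        expected = [
            s for s in spots
            if s.ok and 1.0 < s.amplitude <= 150.0
            and 0.3 <= s.sigma_xy <= 3.0 and 0.3 <= s.sigma_z <= 4.0
        ]
        assert filter_spots(spots, bounds) == expected


class TestDetectSpots:
    def test_noiseless_recall_one_fp_zero(self):
        """Every well-separated spot found, nothing else, at defaults."""
        centers = [(5.0, 16.0 + 20 * (i // 4), 16.0 + 20 * (i % 4)) for i in range(8)]
        st_ = render_spots((11, 96, 96), centers, [amp_to_integral(100.0)] * 8)
        spots = detect_spots(st_, SXY, SZ)
        assert len(spots) == 8
        truth = np.array(centers)
        for s in spots:
            d = np.sqrt(((truth - [s.z0, s.y0, s.x0]) ** 2).sum(axis=1))
            assert d.min() < 0.2
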