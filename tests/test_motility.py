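"""Motility formulas: hand values, algebraic identities, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import casatrack as ct
from casatrack import motility

from conftest import zigzag_track

ZZ_X = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
ZZ_Y = np.array([0.0, 1.0, 0.0, 1.0, 0.0])


class TestVclVsl:
    def test_single_segment_3_4_5(self):
        assert ct.vcl([0.0, 3.0], [0.0, 4.0], 1.0) == pytest.approx(5.0)
        assert ct.vsl([0.0, 3.0], [0.0, 4.0], 1.0) == pytest.approx(5.0)

    def test_zigzag_hand_summation(self):
        # 4 segments of sqrt(2) μm over 4 * 0.1 s.
        assert ct.vcl(ZZ_X, ZZ_Y, 0.1) == pytest.approx(4 * np.sqrt(2) / 0.4)
        assert ct.vsl(ZZ_X, ZZ_Y, 0.1) == pytest.approx(10.0)

    def test_stationary_track(self):
        x = np.zeros(10)
        assert ct.vcl(x, x, 0.1) == 0.0
        assert ct.vsl(x, x, 0.1) == 0.0

    def test_closed_loop_vsl_zero(self):
        theta = np.linspace(0, 2 * np.pi, 21)
        assert ct.vsl(np.cos(theta), np.sin(theta), 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_length(self):
        with pytest.raises(ct.InsufficientLengthError):
            ct.vcl([1.0], [1.0], 0.1)
        with pytest.raises(ct.InsufficientLengthError):
            ct.vsl([], [], 0.1)


class TestSmoothPath:
    def test_constant_path_unchanged(self):
        x = np.full(9, 3.5)
        xs, ys = ct.smooth_path(x, x)
        assert np.allclose(xs, 3.5) and np.allclose(ys, 3.5)

    def test_linear_path_unchanged(self):
        # Centred means of an arithmetic sequence reproduce it at every
        # point (the shrinking windows stay centred at the ends).
        x = np.arange(10, dtype=float)
        xs, _ = ct.smooth_path(x, x)
        assert np.allclose(xs, x)

    def test_impulse_interior_value(self):
        x = np.array([0.0, 0.0, 5.0, 0.0, 0.0])
        xs, _ = ct.smooth_path(x, np.zeros(5))
        assert xs[2] == pytest.approx(1.0)  # (0+0+5+0+0)/5

    def test_output_length_preserved(self):
        for n in (1, 2, 3, 6, 11):
            xs, _ = ct.smooth_path(np.arange(n, dtype=float), np.zeros(n))
            assert len(xs) == n


class TestVap:
    def test_straight_swimmer_all_equal(self):
        x = np.arange(10, dtype=float) * 2.0
        y = np.arange(10, dtype=float)
        dt = 0.1
        assert ct.vap(x, y, dt) == pytest.approx(ct.vcl(x, y, dt))
        assert ct.vap(x, y, dt) == pytest.approx(ct.vsl(x, y, dt))

    def test_sinusoidal_wobble_ordering(self):
        t = np.arange(51) * 0.01
        x = 30.0 * t
        y = 2.0 * np.sin(2 * np.pi * 5 * t)
        v_sl, v_ap, v_cl = ct.vsl(x, y, 0.01), ct.vap(x, y, 0.01), ct.vcl(x, y, 0.01)
        assert v_sl < v_ap < v_cl  # smoothing attenuates the wobble

    def test_stationary_is_zero(self):
        x = np.zeros(10)
        assert ct.vap(x, x, 0.1) == 0.0

    def test_minimum_length_enforced(self):
        with pytest.raises(ct.InsufficientLengthError):
            ct.vap(np.arange(6, dtype=float), np.zeros(6), 0.1)
        # configurable minimum
        assert ct.vap(np.arange(6, dtype=float), np.zeros(6), 0.1, min_frames=2) > 0


class TestMotilityRecord:
    def test_straight_swimmer_unit_ratios(self):
        rec = ct.motility_record(np.arange(10, dtype=float), np.zeros(10), 0.1)
        assert rec.LIN == pytest.approx(1.0)
        assert rec.STR == pytest.approx(1.0)
        assert rec.WOB == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        rec = ct.motility_record(ZZ_X, ZZ_Y, 0.1, min_frames_vap=2)
        assert rec.LIN == pytest.approx(rec.VSL / rec.VCL)
        assert rec.STR == pytest.approx(rec.VSL / rec.VAP)
        assert rec.WOB == pytest.approx(rec.VAP / rec.VCL)

    def test_stationary_ratios_undefined(self):
        rec = ct.motility_record(np.zeros(10), np.zeros(10), 0.1)
        assert rec.VCL == 0.0 and rec.VSL == 0.0
        assert rec.LIN is None and rec.STR is None and rec.WOB is None

    def test_short_track_has_no_vap(self):
        rec = ct.motility_record([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], 0.1)
        assert rec.VAP is None and rec.STR is None and rec.WOB is None
        assert rec.VCL > 0


class TestSummarize:
    def test_single_record(self):
        rec = ct.motility_record(np.arange(10, dtype=float), np.zeros(10), 0.1)
        summary = ct.summarize_population([rec])
        assert summary.loc["VCL", "mean"] == pytest.approx(rec.VCL)
        assert summary.loc["VCL", "sd"] == 0.0
        assert summary.loc["VCL", "n"] == 1

    def test_two_records_hand_values(self):
        recs = [
            ct.motility_record(np.arange(10, dtype=float) * 2.0, np.zeros(10), 0.1),
            ct.motility_record(np.arange(10, dtype=float) * 3.0, np.zeros(10), 0.1),
        ]
        summary = ct.summarize_population(recs)
        assert summary.loc["VCL", "mean"] == pytest.approx(25.0)
        assert summary.loc["VCL", "sd"] == pytest.approx(np.sqrt(50.0) / 1.0, rel=1e-12)

    def test_identical_records_zero_sd(self):
        rec = ct.motility_record(np.arange(10, dtype=float), np.zeros(10), 0.1)
        summary = ct.summarize_population([rec, rec, rec])
        assert summary.loc["VSL", "sd"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ct.InvalidInputError):
            ct.summarize_population([])

    def test_percent_formatting(self):
        rec = ct.motility_record(ZZ_X, ZZ_Y, 0.1, min_frames_vap=2)
        pct = ct.summarize_population([rec], as_percent=True)
        assert pct.loc["LIN", "mean"] == pytest.approx(100 * rec.LIN)


def _random_track(rng, m):
    steps = rng.normal(0, 1.0, (m - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pos[:, 0], pos[:, 1]


class TestProperties:
    @given(
        seed=st.integers(0, 10_000),
        m=st.integers(7, 60),
        scale=st.floats(0.1, 100.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_scale_equivariance(self, seed, m, scale):
        rng = np.random.default_rng(seed)
        x, y = _random_track(rng, m)
        a = ct.motility_record(x, y, 0.05)
        b = ct.motility_record(x * scale, y * scale, 0.05)
        assert b.VCL == pytest.approx(scale * a.VCL, rel=1e-9)
        assert b.VSL == pytest.approx(scale * a.VSL, rel=1e-9)
        assert b.VAP == pytest.approx(scale * a.VAP, rel=1e-9)
        if a.LIN is not None:
            assert b.LIN == pytest.approx(a.LIN, rel=1e-9)

    @given(seed=st.integers(0, 10_000), m=st.integers(7, 80))
    @settings(deadline=None, max_examples=80)
    def test_ratio_identity_and_ordering(self, seed, m):
        rng = np.random.default_rng(seed)
        x, y = _random_track(rng, m)
        rec = ct.motility_record(x, y, 0.02)
        # VSL <= VAP: the smoothed path connects the raw endpoints.
        # VAP <= VCL: averaging contracts total variation.
        assert rec.VSL <= rec.VAP + 1e-9
        assert rec.VAP <= rec.VCL + 1e-9
        if rec.LIN is not None and rec.STR is not None and rec.WOB is not None:
            assert abs(rec.LIN - rec.STR * rec.WOB) < 1e-12

    @given(seed=st.integers(0, 10_000), m=st.integers(7, 60))
    @settings(deadline=None, max_examples=60)
    def test_agrees_with_bruteforce_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        x, y = _random_track(rng, m)
        track = ct.GroundTruthTrack(track_id=0, times=np.arange(m) * 0.02, x=x, y=y)
        oracle = ct.ground_truth_motility(track)
        fast = ct.motility_record(x, y, 0.02)
        assert fast.VCL == pytest.approx(oracle.VCL, rel=1e-9)
        assert fast.VSL == pytest.approx(oracle.VSL, rel=1e-9)
        assert fast.VAP == pytest.approx(oracle.VAP, rel=1e-9)


def test_subsampled_vcl_never_larger():
    """Dropping frames can only shorten the measured path (triangle inequality)."""
    rng = np.random.default_rng(5)
    t = np.arange(101) * 0.01
    x = 30 * t + rng.normal(0, 0.2, 101)
    y = 2 * np.sin(2 * np.pi * 5 * t) + rng.normal(0, 0.2, 101)
    full = ct.vcl(x, y, 0.01)
    for stride in (2, 5, 10):
        sub = ct.vcl(x[::stride], y[::stride], 0.01 * stride)
        assert sub <= full + 1e-12


def test_records_from_dataframe_skips_gappy_tracks(caplog):
    import logging
    import pandas as pd

    df = pd.DataFrame(
        {
            "track_id": [0] * 5 + [1] * 5,
            "frame": [0, 1, 2, 3, 4, 0, 1, 2, 4, 5],  # track 1 has a gap
            "x_um": np.arange(10, dtype=float),
            "y_um": np.zeros(10),
        }
    )
    with caplog.at_level(logging.WARNING):
        recs = motility.records_from_dataframe(df, fps=30.0)
    assert [r.track_id for r in recs] == [0]
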