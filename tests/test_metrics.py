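"""Marker-profile amplitude metrics and relative-change ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circamp as ca
from circamp.metrics import profile_metrics, relative_change, synthetic_profile


def triangle(base: float, height: float, step: float = 0.25) -> ca.MarkerProfile:
    t = np.arange(0.0, base + step / 2, step)
    half = base / 2.0
    v = np.where(t < half, height * t / half, height * (base - t) / half)
    return ca.MarkerProfile(t, np.clip(v, 0.0, None))


def test_triangle_profile_analytic_metrics():
    m = profile_metrics(triangle(8.0, 10.0), threshold=0.0)
    assert m.auc == pytest.approx(40.0)
    assert m.peak == pytest.approx(10.0)
    assert m.width == pytest.approx(8.0)
    assert m.range == pytest.approx(10.0)
    assert not m.below_threshold


def test_triangle_width_with_interpolated_crossings():
    m = profile_metrics(triangle(8.0, 10.0), threshold=5.0)
    assert m.width == pytest.approx(4.0)  # crossings at t = 2 and t = 6


def test_flat_zero_profile_flags_warning():
    prof = ca.MarkerProfile(np.arange(5.0), np.zeros(5))
    with pytest.warns(UserWarning, match="never exceeds"):
        m = profile_metrics(prof, threshold=0.0)
    assert m.auc == m.peak == m.width == m.range == 0.0
    assert m.below_threshold


def test_relative_change_identity_and_worked_ratios():
    before = profile_metrics(triangle(6.0, 10.0), threshold=0.0)
    same = relative_change(before, before)
    assert all(r == 1.0 for r in same.ratios.values())
    assert all(f == "unchanged" for f in same.flags.values())

    after = profile_metrics(triangle(4.0, 6.0), threshold=0.0)
    rc = relative_change(before, after)
    assert rc.ratios["auc_ratio"] == pytest.approx(0.40)
    assert rc.flags["auc_ratio"] == "suppression"
    assert rc.ratios["width_ratio"] == pytest.approx(2.0 / 3.0)
    assert rc.flags["width_ratio"] == "suppression"


def test_relative_change_zero_baseline_is_undefined_not_fatal():
    with pytest.warns(UserWarning):
        zero = profile_metrics(ca.MarkerProfile(np.arange(4.0), np.zeros(4)), 0.0)
    some = profile_metrics(triangle(4.0, 5.0), threshold=0.0)
    rc = relative_change(zero, some)
    assert all(math.isnan(r) for r in rc.ratios.values())
    assert all(f == "undefined" for f in rc.flags.values())


def test_synthetic_profile_peaks_at_peak_time():
    prof = synthetic_profile(peak_time=2.0, peak_value=60.0, rise=1.5, fall=2.5)
    assert prof.times[np.argmax(prof.values)] == pytest.approx(2.0, abs=0.1)
    assert prof.values.max() == pytest.approx(60.0, rel=1e-6)


def test_synthetic_profile_auc_linear_in_peak():
    a = synthetic_profile(0.0, 30.0, 2.0, 2.0, sample_every=0.05)
    b = synthetic_profile(0.0, 60.0, 2.0, 2.0, sample_every=0.05)
    ma, mb = profile_metrics(a, 0.0), profile_metrics(b, 0.0)
    assert mb.auc == pytest.approx(2.0 * ma.auc, rel=1e-9)


def test_synthetic_profile_noise_reproducible():
    a = synthetic_profile(0.0, 60.0, 2.0, 3.0, noise_sd=5.0, seed=9)
    b = synthetic_profile(0.0, 60.0, 2.0, 3.0, noise_sd=5.0, seed=9)
    assert np.array_equal(a.values, b.values)


def test_metrics_recover_generator_closed_forms():
    """Half-Gaussian-limb generator: AUC and threshold width have closed
    forms that profile_metrics recovers within 1%."""
    peak, rise, fall, thr = 60.0, 1.5, 2.5, 3.0
    prof = synthetic_profile(0.0, peak, rise, fall, sample_every=0.01)
    m = profile_metrics(prof, threshold=thr)
    auc_exact = peak * math.sqrt(math.pi / 2.0) * (rise + fall)
    width_exact = (rise + fall) * math.sqrt(2.0 * math.log(peak / thr))
    assert m.auc == pytest.approx(auc_exact, rel=0.01)
    assert m.width == pytest.approx(width_exact, rel=0.01)
    assert m.peak == pytest.approx(peak, rel=0.01)


def test_auc_converges_second_order():
    """Trapezoidal AUC error against the analytic integral over the
    sampled span shrinks ~4x when sampling density doubles."""
    peak, rise, fall = 50.0, 1.0, 2.0

    def err(step):
        prof = synthetic_profile(0.0, peak, rise, fall, sample_every=step)
        a, b = prof.times[0], prof.times[-1]
        exact = peak * math.sqrt(math.pi / 2.0) * (
            rise * math.erf(-a / (rise * math.sqrt(2.0)))
            + fall * math.erf(b / (fall * math.sqrt(2.0)))
        )
        return abs(profile_metrics(prof, 0.0).auc - exact)

    e1, e2 = err(0.4), err(0.2)
    assert 3.0 <= e1 / e2 <= 6.5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50.0, allow_nan=False))
def test_ratios_are_scale_consistent(scale):
    """Multiplying both profiles (and the threshold, in concentration
    units) by a constant leaves every ratio unchanged."""
    b = synthetic_profile(0.0, 60.0, 2.0, 3.0, sample_every=0.05)
    a = synthetic_profile(0.0, 40.0, 1.5, 2.0, sample_every=0.05)
    base = relative_change(profile_metrics(b, 3.0), profile_metrics(a, 3.0))
    sb = ca.MarkerProfile(b.times, b.values * scale)
    sa = ca.MarkerProfile(a.times, a.values * scale)
    scaled = relative_change(
        profile_metrics(sb, 3.0 * scale), profile_metrics(sa, 3.0 * scale)
    )
    for key in base.ratios:
        assert scaled.ratios[key] == pytest.approx(base.ratios[key], rel=1e-9)


def test_profile_csv_round_trip(tmp_path):
    prof = synthetic_profile(3.0, 45.0, 1.0, 2.0, noise_sd=2.0, seed=4)
    path = tmp_path / "profile.csv"
    prof.to_csv(path)
    back = ca.MarkerProfile.from_csv(path)
    assert np.allclose(back.times, prof.times)
    assert np.allclose(back.values, prof.values)


def test_profile_validation():
    with pytest.raises(ValueError):
        ca.MarkerProfile(np.array([0.0, 1.0]), np.array([1.0, 2.0]))  # too short
    with pytest.raises(ValueError):
        ca.MarkerProfile(np.array([0.0, 2.0, 1.0]), np.array([1.0, 2.0, 1.0]))
    with pytest.raises(ValueError):
        ca.MarkerProfile(np.array([0.0, 1.0, 2.0]), np.array([1.0, -2.0, 1.0]))
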