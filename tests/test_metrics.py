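"""Threshold estimation, peak picking and IOF extraction."""
import dataclasses

import numpy as np
import pytest

import abrscreen as abr
from abrscreen.metrics import (
    NoResponseError,
    compute_iofs,
    default_search_windows,
    detect_peaks,
    estimate_threshold,
)
from abrscreen.waveform import LevelSeries, clean_trace, generate_level_series


def test_noise_free_threshold_recovery_exhaustive(noise_free_model):
    """On noise-free input the estimate equals the generator's threshold for
    every grid value 0-95."""
    for true in range(0, 100, 5):
        series = generate_level_series(abr.CLICK, true, noise_free_model, 0, 95, seed=1)
        est = estimate_threshold(series)
        assert est.threshold_db == true and not est.ceiling


def test_all_noise_series_returns_ceiling():
    series = generate_level_series(abr.CLICK, 200.0, level_min=0, level_max=95, seed=2)
    est = estimate_threshold(series)
    assert est.threshold_db == 95 and est.ceiling


def test_threshold_recovery_under_calibrated_noise():
    """At noise sd = 1/4 of the near-threshold wave-1 amplitude, recovery is
    within one 5-dB step in >= 95 of 100 seeded replicates."""
    w1 = abr.DEFAULT_WAVE_MODEL.waves[0]
    noise = w1.amplitude_uv(5.0) / 4.0
    model = dataclasses.replace(abr.DEFAULT_WAVE_MODEL, noise_sd_uv=noise)
    ok = 0
    for rep in range(100):
        series = generate_level_series(abr.CLICK, 40.0, model, 0, 95, seed=500 + rep)
        if abs(estimate_threshold(series).threshold_db - 40.0) <= 5.0:
            ok += 1
    assert ok >= 95


def test_estimator_input_validation(noise_free_model):
    series = generate_level_series(abr.CLICK, 40.0, noise_free_model, 40, 40 + 5, seed=0)
    one_level = LevelSeries(
        series.stimulus, series.levels_db[:1], series.traces_uv[:1],
        series.sample_rate_hz, series.window_ms,
    )
    with pytest.raises(ValueError, match="2 levels"):
        estimate_threshold(one_level)
    uneven = LevelSeries(
        "click", np.array([0.0, 5.0, 20.0]),
        np.zeros((3, noise_free_model.n_samples)),
        noise_free_model.sample_rate_hz, noise_free_model.window_ms,
    )
    with pytest.raises(ValueError, match="non-uniform"):
        estimate_threshold(uneven)


def test_quality_gate_marks_contaminated_level(noise_free_model):
    """A level with gross myogenic-style noise is marked, not dropped."""
    series = generate_level_series(abr.CLICK, 40.0, abr.DEFAULT_WAVE_MODEL, 0, 85, seed=3)
    rng = np.random.default_rng(0)
    series.traces_uv[4] += rng.normal(0, 2.0, series.traces_uv.shape[1])
    est = estimate_threshold(series)
    assert series.levels_db[4] in est.contaminated_levels


def test_peak_latencies_exact_over_sl_sweep(noise_free_model):
    m = noise_free_model
    wins = default_search_windows(m)
    dt = 1e3 / m.sample_rate_hz
    for sl in range(0, 65, 5):
        ps = detect_peaks(clean_trace(float(sl), m), m.times_ms(), wins)
        expected_p = np.array([w.latency_ms(sl) for w in m.waves])
        expected_n = expected_p + np.array([m.trough_offset_sigmas * w.width_ms for w in m.waves])
        assert np.all(np.abs(ps.p_latency_ms - expected_p) <= dt + 1e-9)
        assert np.all(np.abs(ps.n_latency_ms - expected_n) <= dt + 1e-9)


def test_peak_translation_symmetry(noise_free_model):
    """Shifting the trace by +0.3 ms shifts every latency by +0.3 ms and
    leaves amplitudes unchanged."""
    m = noise_free_model
    wins = default_search_windows(m)
    t = m.times_ms()
    base = clean_trace(20.0, m)
    shift = int(round(0.3 * 1e-3 * m.sample_rate_hz))
    shifted = np.concatenate([np.zeros(shift), base[:-shift]])
    shifted_windows = tuple((lo + 0.3, hi + 0.3) for lo, hi in wins)
    a = detect_peaks(base, t, wins)
    b = detect_peaks(shifted, t, shifted_windows)
    assert np.allclose(b.p_latency_ms - a.p_latency_ms, 0.3, atol=1e-9)
    assert np.allclose(b.n_latency_ms - a.n_latency_ms, 0.3, atol=1e-9)
    assert np.allclose(a.p_amplitude_uv, b.p_amplitude_uv)
    assert np.allclose(a.n_amplitude_uv, b.n_amplitude_uv)


def test_flat_trace_raises_no_response(noise_free_model):
    m = noise_free_model
    with pytest.raises(NoResponseError):
        detect_peaks(np.zeros(m.n_samples), m.times_ms(), default_search_windows(m))


def test_peak_ordering_invariant_on_noisy_traces():
    """P1<N1<...<P4<N4 holds for every emitted PeakSet under recording noise."""
    m = abr.DEFAULT_WAVE_MODEL
    wins = default_search_windows(m)
    for rep in range(50):
        tr = abr.synth_trace(abr.CLICK, 70.0, 30.0, m, seed=rep)
        ps = detect_peaks(tr, m.times_ms(), wins)
        order = np.empty(8)
        order[0::2] = ps.p_latency_ms
        order[1::2] = ps.n_latency_ms
        assert np.all(np.diff(order) > 0)


def _peaks_by_level(model, threshold, levels):
    wins = default_search_windows(model)
    return {
        float(lvl): detect_peaks(clean_trace(lvl - threshold, model), model.times_ms(), wins)
        for lvl in levels
    }


def test_iof_sl_grid_and_count(noise_free_model):
    peaks = _peaks_by_level(noise_free_model, 45.0, range(45, 100, 5))
    curves = compute_iofs(peaks, 45.0)
    assert len(curves) == 10
    assert all(np.array_equal(c.sl_db, np.arange(5.0, 55.0, 5.0)) for c in curves)
    assert not any(c.parameter == "amp_P2N2" for c in curves)


def test_iof_amplitude_linear_in_sl(noise_free_model):
    """The noise-free generator has a linear amplitude law, so the wave-1
    amplitude IOF must be linear in SL with the generator's P+N gain."""
    peaks = _peaks_by_level(noise_free_model, 20.0, range(25, 85, 5))
    by_name = {c.parameter: c for c in compute_iofs(peaks, 20.0)}
    c = by_name["amp_P1N1"]
    slope, _ = np.polyfit(c.sl_db, c.values, 1)
    r2 = np.corrcoef(c.sl_db, c.values)[0, 1] ** 2
    assert r2 > 0.999
    assert abs(slope - 2 * noise_free_model.waves[0].amplitude_gain_uv_per_db) < 0.002


def test_iof_interval_identity(noise_free_model):
    peaks = _peaks_by_level(noise_free_model, 30.0, range(35, 95, 5))
    by_name = {c.parameter: c for c in compute_iofs(peaks, 30.0)}
    assert np.allclose(
        by_name["interval_P1P3"].values,
        by_name["lat_P3"].values - by_name["lat_P1"].values,
    )


def test_iof_empty_suprathreshold_rejected(noise_free_model):
    peaks = _peaks_by_level(noise_free_model, 30.0, [35.0])
    with pytest.raises(ValueError):
        compute_iofs(peaks, 95.0)
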