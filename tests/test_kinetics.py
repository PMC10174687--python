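import numpy as np
import pytest

from azmap import (
    amplitude_spectrum,
    average_trace,
    decompose_decay,
    minmax_normalize,
)
from azmap.errors import (
    DegenerateNormalizationError,
    EmptyInputError,
    InsufficientDataError,
)
from azmap.model import FluorescenceTrace


def _trace(values, det=10, frame_ms=50.0, base=None):
    return FluorescenceTrace(
        event_id="e", frame_ms=frame_ms, values=np.asarray(values, float),
        detection_index=det, baseline_frames=min(det, 5) if base is None else base,
    )


def _model_trace(a=10.0, tau=60.0, c=5.0, m=-0.002, n_post=19, frame_ms=50.0):
    t = np.arange(n_post + 1) * frame_ms
    post = a * np.exp(-t / tau) + c + m * t
    return _trace(np.concatenate([np.zeros(10), post]), det=10, frame_ms=frame_ms)


def test_pure_linear_decay_has_no_ultrafast_component():
    t = np.arange(20) * 50.0
    tr = _trace(np.concatenate([np.zeros(10), 5.0 - 0.002 * t]))
    dec = decompose_decay(tr)
    assert dec.fast_intercept == pytest.approx(5.0)
    assert dec.fast_slope == pytest.approx(-0.002)
    assert dec.uf_amplitude == pytest.approx(0.0, abs=1e-6)
    assert not dec.fit_ok


def test_noiseless_two_component_trace_is_recovered():
    # 10*exp(-t/60 ms) + (5 - 0.002*t), 50 ms sampling over 950 ms; the
    # linear tail still contains a trace of the exponential, so 15%
    dec = decompose_decay(_model_trace())
    assert dec.fit_ok
    assert dec.uf_amplitude == pytest.approx(10.0, rel=0.15)
    assert dec.uf_tau_ms == pytest.approx(60.0, rel=0.15)
    assert dec.fast_intercept == pytest.approx(5.0, rel=0.15)
    assert dec.fast_slope == pytest.approx(-0.002, rel=0.15)
    assert 0 < dec.uf_fraction < 1
    assert dec.uf_fraction == pytest.approx(
        dec.uf_amplitude / (dec.uf_amplitude + dec.fast_intercept)
    )


def test_too_few_post_detection_samples_is_an_error():
    tr = _model_trace(n_post=6)
    with pytest.raises(InsufficientDataError):
        decompose_decay(tr)


def test_average_of_identical_traces_is_the_trace_with_zero_sem():
    tr = _model_trace()
    mean, sem, n, det = average_trace([tr, tr, tr])
    np.testing.assert_allclose(mean, tr.values)
    np.testing.assert_allclose(sem, 0.0, atol=1e-12)
    assert n == 3 and det == 10


def test_average_trace_closed_form():
    a = _trace([0.0, 2.0], det=0)
    b = _trace([2.0, 0.0], det=0)
    mean, sem, n, _ = average_trace([a, b])
    np.testing.assert_allclose(mean, [1.0, 1.0])
    # sd of {0,2} is sqrt(2); SEM = sd/sqrt(2) = 1
    np.testing.assert_allclose(sem, [1.0, 1.0])


def test_single_trace_has_zero_sem_by_convention():
    tr = _model_trace()
    mean, sem, n, _ = average_trace([tr])
    np.testing.assert_allclose(mean, tr.values)
    assert (sem == 0).all() and n == 1


def test_average_trace_rejects_empty_collection():
    with pytest.raises(EmptyInputError):
        average_trace([])


def test_minmax_normalization():
    np.testing.assert_allclose(minmax_normalize([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])
    with pytest.raises(DegenerateNormalizationError):
        minmax_normalize([5.0, 5.0, 5.0])
    rng = np.random.default_rng(1)
    out = minmax_normalize(rng.normal(size=40))
    assert out.min() == 0.0 and out.max() == 1.0


def test_spectrum_of_constant_signal_is_pure_dc():
    tr = _trace(np.concatenate([np.zeros(10), np.full(19, 3.0)]))
    freqs, amp = amplitude_spectrum(tr, window_ms=900.0)
    assert freqs[0] == 0.0
    assert amp[0] == pytest.approx(3.0)
    np.testing.assert_allclose(amp[1:], 0.0, atol=1e-12)
    assert len(freqs) == 18 // 2 + 1
    assert freqs[-1] == pytest.approx(10.0)  # Nyquist at 50 ms sampling


def test_spectrum_of_bin_frequency_cosine_is_a_single_line():
    n = 18
    k = 4
    t = np.arange(n)
    x = np.cos(2 * np.pi * k * t / n)
    tr = _trace(np.concatenate([np.zeros(10), x]))
    _, amp = amplitude_spectrum(tr, window_ms=900.0)
    assert amp[k] == pytest.approx(1.0)
    others = np.delete(amp, k)
    np.testing.assert_allclose(others, 0.0, atol=1e-12)


def test_two_sided_spectrum_is_parseval_consistent():
    rng = np.random.default_rng(6)
    x = rng.normal(size=18)
    tr = _trace(np.concatenate([np.zeros(10), x]))
    amplitude_spectrum(tr, window_ms=900.0)  # smoke: shapes valid
    two_sided = np.abs(np.fft.fft(x)) / len(x)
    energy_freq = np.sum(two_sided**2) * len(x)
    energy_time = np.sum(x**2)
    assert energy_freq == pytest.approx(energy_time, rel=1e-9)


def test_window_longer_than_trace_is_an_error():
    tr = _trace(np.concatenate([np.zeros(10), np.ones(10)]))
    with pytest.raises(InsufficientDataError):
        amplitude_spectrum(tr, window_ms=900.0)


def test_odd_sample_window_is_truncated_by_one():
    # 900 ms at 60 ms/frame = 15 samples -> truncated to 14
    tr = _trace(np.concatenate([np.zeros(10), np.ones(20)]), frame_ms=60.0)
    freqs, amp = amplitude_spectrum(tr, window_ms=900.0)
    assert len(freqs) == 14 // 2 + 1
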