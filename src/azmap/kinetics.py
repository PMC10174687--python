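"""Two-component decay decomposition, trace averaging, and spectra.

After fusion, the fluorescence of a single vesicle decays with two
kinetically distinct components attributed to ultrafast (~60 ms,
calcium-insensitive) and fast (~1 s, calcium-sensitive) endocytosis.
Rather than an ill-conditioned double-exponential fit, the decay is
dissected in two robust stages:

1. a straight line is fitted to the tail of the trace, starting five
   frames after detection; its value extrapolated back to the detection
   time (intercept) and its slope parametrize the *fast* component;
2. the extrapolated line is subtracted from the whole post-detection
   segment and the residual is fitted with a single exponential
   ``A * exp(-t / tau)``, giving the amplitude and time constant of the
   *ultrafast* component.

The relative weights of the two components at the moment of detection are
``A / (A + intercept)`` and its complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateNormalizationError,
    EmptyInputError,
    InsufficientDataError,
)
from .model import FluorescenceTrace

#: First tail sample of the linear fit, in frames after detection.
LINEAR_START_OFFSET = 5


@dataclass
class DecayDecomposition:
    """Ultrafast (exponential) + fast (linear) components of one decay."""

    uf_amplitude: float | None
    uf_tau_ms: float | None
    fast_intercept: float
    fast_slope: float
    fit_ok: bool
    residual_rms: float | None

    @property
    def uf_fraction(self) -> float | None:
        """Ultrafast share of the signal at detection, in [0, 1] when both
        components are non-negative."""
        if not self.fit_ok or self.uf_amplitude is None:
            return None
        total = self.uf_amplitude + self.fast_intercept
        return self.uf_amplitude / total if total > 0 else None


def decompose_decay(
    trace: FluorescenceTrace,
    end_index: int | None = None,
    linear_start: int = LINEAR_START_OFFSET,
) -> DecayDecomposition:
    """Decompose one trace's post-detection decay (see module docstring).

    Parameters
    ----------
    trace
        The event trace; ``t = 0`` at the detection sample.
    end_index
        Last sample of the fit window (inclusive); defaults to the last
        sample of the trace (callers normally truncate traces at the frame
        preceding the next stimulus).
    linear_start
        Offset, in frames after detection, of the first sample of the
        linear tail fit.

    Raises
    ------
    InsufficientDataError
        If fewer than 7 post-detection samples are available.
    """
    det = trace.detection_index
    if end_index is None:
        end_index = len(trace.values) - 1
    if end_index >= len(trace.values):
        raise InsufficientDataError("end_index beyond the trace")
    n_post = end_index - det
    if n_post < 7:
        raise InsufficientDataError(
            f"need >= 7 post-detection samples, have {n_post}"
        )
    t = (np.arange(det, end_index + 1) - det) * trace.frame_ms
    y = trace.values[det : end_index + 1]

    # stage 1: linear tail -> fast component
    tail = slice(linear_start, None)
    slope, intercept = np.polyfit(t[tail], y[tail], 1)
    # stage 2: exponential on the line-subtracted residual -> ultrafast
    resid = y - (intercept + slope * t)
    a0 = max(float(resid[0]), 1e-12)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            resid,
            p0=(a0, trace.frame_ms),
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        a_fit, tau_fit = float(popt[0]), float(popt[1])
        # amplitude pinned at the zero bound => no resolvable ultrafast
        # component; report A = 0 with an undefined time constant
        fit_ok = a_fit > 1e-9
        if not fit_ok:
            a_fit, tau_fit = 0.0, None
    except RuntimeError:
        a_fit = tau_fit = None
        fit_ok = False
    if fit_ok:
        model = a_fit * np.exp(-t / tau_fit)
        rms = float(np.sqrt(np.mean((resid - model) ** 2)))
    else:
        rms = None
    return DecayDecomposition(
        uf_amplitude=a_fit,
        uf_tau_ms=tau_fit,
        fast_intercept=float(intercept),
        fast_slope=float(slope),
        fit_ok=fit_ok,
        residual_rms=rms,
    )


def average_trace(
    traces: list[FluorescenceTrace],
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Pointwise mean and SEM of traces aligned at their detection sample.

    The overlap window spans the smallest pre-detection and post-detection
    extents over the collection.  Returns ``(mean, sem, n, detection_index)``
    where *detection_index* locates the alignment point within the returned
    arrays.  SEM is zero for a single trace (by convention).
    """
    if not traces:
        raise EmptyInputError("average_trace needs at least one trace")
    pre = min(t.detection_index for t in traces)
    post = min(t.n_post for t in traces)
    stack = np.stack(
        [
            t.values[t.detection_index - pre : t.detection_index + post + 1]
            for t in traces
        ]
    )
    mean = stack.mean(axis=0)
    n = len(traces)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    )
    return mean, sem, n, pre


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map a trace to [0, 1] via (x - min) / (max - min)."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateNormalizationError("constant trace cannot be normalized")
    return (values - lo) / (hi - lo)


def amplitude_spectrum(
    trace: FluorescenceTrace, window_ms: float = 900.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of the post-detection signal.

    The first ``window_ms`` of the signal starting at the detection sample
    are transformed (an odd sample count is truncated by one sample so the
    length is even).  Interior bins of the two-sided spectrum are doubled;
    the frequency axis runs from 0 to the Nyquist frequency with
    resolution 1/window.
    """
    n = int(round(window_ms / trace.frame_ms))
    if n % 2 == 1:
        n -= 1
    if n < 2:
        raise InsufficientDataError("window too short for a spectrum")
    avail = len(trace.values) - trace.detection_index
    if avail < n:
        raise InsufficientDataError(
            f"window needs {n} post-detection samples, have {avail}"
        )
    x = trace.values[trace.detection_index : trace.detection_index + n]
    two_sided = np.abs(np.fft.fft(x)) / n
    single = two_sided[: n // 2 + 1].copy()
    single[1:-1] *= 2
    freqs = np.arange(n // 2 + 1) / (n * trace.frame_ms / 1000.0)
    return freqs, single
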