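"""Event amplitudes and multivesicular-release (MVR) detection.

The amplitude of an event is its fluorescence at the detection frame minus
the baseline, defined as the mean of the five frames preceding detection.
Amplitudes of one bouton, pooled over release classes, are expected to be
normally distributed around the quantal (single-vesicle) mean; MVR events
break that normality.  Detection therefore runs an iterative
Anderson-Darling loop: while normality is rejected, the single largest
amplitude is removed and the test repeated.  The mean of the surviving
(normal) subset is the bouton's quantal mean; every event's amplitude is
divided by it, and events whose normalized amplitude exceeds 2 are called
MVR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PreconditionError
from .model import Dataset, FluorescenceTrace

#: Smallest sample the Anderson-Darling loop will test; below this the
#: test is uninformative and boutons are skipped (no MVR calls).
MIN_MVR_SAMPLE = 8


def event_amplitude(trace: FluorescenceTrace, baseline_frames: int | None = None) -> float:
    """Baseline-subtracted signal at the detection frame.

    ``amplitude = values[detection] - mean(values[detection-b : detection])``
    with *b* pre-detection baseline frames (the trace's own count by
    default).
    """
    b = trace.baseline_frames if baseline_frames is None else baseline_frames
    if trace.detection_index < b:
        raise InsufficientDataError(
            f"need {b} pre-detection frames, have {trace.detection_index}"
        )
    i = trace.detection_index
    return float(trace.values[i] - trace.values[i - b : i].mean())


def attach_amplitudes(dataset: Dataset) -> Dataset:
    """Compute amplitudes for all events with traces and store them in the
    ``amplitude`` column (NaN for trace-less events)."""
    amps = {
        eid: event_amplitude(tr, dataset.config.baseline_frames)
        for eid, tr in dataset.traces.items()
    }
    dataset.events = dataset.events.assign(
        amplitude=dataset.events["event_id"].map(amps)
    )
    return dataset


def _ad_normal(x: np.ndarray, alpha: float) -> bool:
    """Anderson-Darling normality decision at level *alpha*."""
    try:
        res = stats.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue >= alpha)
    except TypeError:  # scipy < 1.17: fixed critical-value table
        res = stats.anderson(x, dist="norm")
        sig = np.asarray(res.significance_level, dtype=float)
        idx = int(np.argmin(np.abs(sig - alpha * 100)))
        return bool(res.statistic < res.critical_values[idx])


def detect_mvr(
    amplitudes: pd.Series | np.ndarray,
    alpha: float = 0.05,
    threshold: float = 2.0,
    min_n: int = MIN_MVR_SAMPLE,
) -> tuple[pd.DataFrame, float | None, str]:
    """Iterative normality-based MVR detection for one bouton.

    Parameters
    ----------
    amplitudes
        One bouton's event amplitudes, indexed by event id if a Series.
    alpha
        Anderson-Darling significance level.
    threshold
        Normalized-amplitude MVR threshold.
    min_n
        Minimum sample size; smaller boutons are skipped and a shrinking
        subset that never passes normality is flagged unresolvable.

    Returns
    -------
    (table, quantal_mean, status)
        *table* has columns ``norm_amplitude, mvr_flag`` for every event
        (flags None when skipped/unresolvable); *status* is one of
        ``ok, skipped, unresolvable``.
    """
    s = pd.Series(np.asarray(amplitudes, dtype=float)) if not isinstance(
        amplitudes, pd.Series
    ) else amplitudes.astype(float)
    n = len(s)
    out = pd.DataFrame(index=s.index)
    if n < min_n:
        out["norm_amplitude"] = np.nan
        out["mvr_flag"] = None
        return out, None, "skipped"
    # survivors are an ascending-sorted prefix: drop the largest, one per
    # iteration, until the Anderson-Darling test accepts normality
    order = np.argsort(s.to_numpy(), kind="stable")
    sorted_vals = s.to_numpy()[order]
    k = n
    while k >= min_n and not _ad_normal(sorted_vals[:k], alpha):
        k -= 1
    if k < min_n:
        out["norm_amplitude"] = np.nan
        out["mvr_flag"] = None
        return out, None, "unresolvable"
    quantal_mean = float(sorted_vals[:k].mean())
    out["norm_amplitude"] = s / quantal_mean
    out["mvr_flag"] = out["norm_amplitude"] > threshold
    return out, quantal_mean, "ok"


def detect_mvr_all(dataset: Dataset) -> pd.DataFrame:
    """Run MVR detection per bouton over all events with amplitudes.

    Amplitudes of all release classes of a bouton are pooled.  Returns a
    per-event table ``event_id, bouton_id, norm_amplitude, mvr_flag`` and
    writes ``norm_amplitude`` / ``mvr_flag`` back onto the event table.
    A per-bouton ``quantal_mean`` / ``mvr_status`` table is attached as
    ``.attrs['boutons']`` of the returned frame.
    """
    ev = dataset.events
    if "amplitude" not in ev.columns:
        raise PreconditionError("attach_amplitudes must run before detect_mvr_all")
    cfg = dataset.config
    pieces = []
    brows = []
    for bouton_id, sub in ev.groupby("bouton_id", sort=False):
        with_amp = sub[sub["amplitude"].notna()]
        table, qmean, status = detect_mvr(
            with_amp.set_index("event_id")["amplitude"],
            alpha=cfg.ad_alpha,
            threshold=cfg.mvr_threshold,
        )
        table = table.reset_index().rename(columns={"index": "event_id"})
        table["bouton_id"] = bouton_id
        pieces.append(table)
        brows.append((bouton_id, qmean, status, len(with_amp)))
    result = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["event_id", "norm_amplitude", "mvr_flag", "bouton_id"])
    )
    merged = ev.drop(columns=["norm_amplitude", "mvr_flag"], errors="ignore").merge(
        result[["event_id", "norm_amplitude", "mvr_flag"]], on="event_id", how="left"
    )
    dataset.events = merged
    result.attrs["boutons"] = pd.DataFrame(
        brows, columns=["bouton_id", "quantal_mean", "mvr_status", "n_amplitudes"]
    )
    return result
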