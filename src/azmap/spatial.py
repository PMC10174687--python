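"""Distance-resolved population and per-bouton analyses.

Events are grouped in concentric rings around the AZ center (100 nm wide
by default, half-open ``[k*w, (k+1)*w)``) and the per-ring mean amplitude
and decay parameters are examined as a function of distance.  The same
question is asked per bouton: amplitudes are binned against distance,
fitted with a line, and the fraction of boutons with a positive slope is
compared with the 50% chance level.  The sampling question — does the
in-AZ share of asynchronous events saturate as more synchronous events are
detected? — is answered by a saturating-exponential fit of that share
against the per-bouton synchronous event count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    UndefinedStatisticError,
)


def ring_profile(
    table: pd.DataFrame,
    ring_width_nm: float = 100.0,
    distance_col: str = "d_center_nm",
    value_cols: tuple[str, ...] = ("amplitude",),
) -> pd.DataFrame:
    """Per-ring event counts and mean values.

    Parameters
    ----------
    table
        Per-event rows carrying *distance_col* plus the columns to
        average.  Use ``distance_col="d_norm"`` for normalized-distance
        binning (with *ring_width_nm* then a normalized width).
    ring_width_nm
        Ring width; ring ``k`` collects events with distance in
        ``[k*w, (k+1)*w)``.

    Returns a frame with ``ring, d_mid, n`` plus ``mean_<col>`` and
    ``sem_<col>`` for each value column (empty if no event has a defined
    distance).
    """
    t = table[table[distance_col].notna()]
    if len(t) == 0:
        return pd.DataFrame(columns=["ring", "d_mid", "n"])
    ring = np.floor(t[distance_col].to_numpy() / ring_width_nm).astype(int)
    out_rows = []
    for k in sorted(set(ring)):
        sub = t[ring == k]
        row = {
            "ring": k,
            "d_mid": (k + 0.5) * ring_width_nm,
            "n": len(sub),
        }
        for col in value_cols:
            if col in sub.columns:
                vals = sub[col].dropna()
                row[f"mean_{col}"] = vals.mean() if len(vals) else np.nan
                row[f"sem_{col}"] = (
                    vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def amplitude_distance_correlation(
    ring_means: pd.DataFrame,
    value_col: str = "mean_amplitude",
) -> tuple[float, float]:
    """Pearson correlation between ring midpoints and ring mean amplitudes.

    Requires at least 3 occupied rings; a zero-variance amplitude profile
    has no defined correlation.
    """
    t = ring_means[ring_means[value_col].notna()]
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 occupied rings for a correlation")
    y = t[value_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("constant ring means: correlation undefined")
    r, p = stats.pearsonr(t["d_mid"].to_numpy(dtype=float), y)
    return float(r), float(p)


def correlation_across_widths(
    table: pd.DataFrame,
    widths_nm: list[float],
    distance_col: str = "d_center_nm",
) -> pd.DataFrame:
    """Pearson r / p for several ring widths (a bin-robustness check)."""
    rows = []
    for w in widths_nm:
        prof = ring_profile(table, w, distance_col=distance_col)
        try:
            r, p = amplitude_distance_correlation(prof)
        except (InsufficientDataError, UndefinedStatisticError):
            r = p = np.nan
        rows.append({"width": w, "r": r, "p": p, "n_rings": len(prof)})
    return pd.DataFrame(rows)


def freedman_diaconis_width(distances: np.ndarray) -> float:
    """Automatic ring width by the Freedman-Diaconis rule."""
    distances = np.asarray(distances, dtype=float)
    iqr = np.subtract(*np.percentile(distances, [75, 25]))
    if iqr == 0:
        raise UndefinedStatisticError("zero IQR: Freedman-Diaconis undefined")
    return float(2 * iqr / len(distances) ** (1 / 3))


def per_bouton_slope_fraction(
    table: pd.DataFrame,
    bin_nm: float = 80.0,
    top_n: int = 100,
    r2_min: float = 0.1,
    distance_col: str = "d_center_nm",
) -> tuple[float, pd.DataFrame]:
    """Fraction of boutons whose amplitude increases with distance.

    For the *top_n* boutons with the most events (amplitude and distance
    both defined), amplitudes are binned against distance (*bin_nm* bins,
    bin-mean amplitude vs bin midpoint) and fitted with a line.  Boutons
    with fewer than 3 occupied bins, or a fit with R^2 below *r2_min*
    (not robustly representing either slope sign), are excluded.  Returns
    the fraction of surviving boutons with a positive slope, plus the
    per-bouton table (``bouton_id, n_events, n_bins, slope, r2, eligible``).
    """
    t = table[table["amplitude"].notna() & table[distance_col].notna()]
    counts = t.groupby("bouton_id").size().sort_values(ascending=False)
    chosen = set(counts.head(top_n).index)
    rows = []
    for bouton_id, sub in t[t["bouton_id"].isin(chosen)].groupby("bouton_id"):
        d = sub[distance_col].to_numpy(dtype=float)
        a = sub["amplitude"].to_numpy(dtype=float)
        bins = np.floor(d / bin_nm).astype(int)
        uniq = np.unique(bins)
        if len(uniq) < 3:
            rows.append((bouton_id, len(sub), len(uniq), np.nan, np.nan, False))
            continue
        mids = (uniq + 0.5) * bin_nm
        means = np.array([a[bins == k].mean() for k in uniq])
        slope, intercept = np.polyfit(mids, means, 1)
        pred = intercept + slope * mids
        ss_res = np.sum((means - pred) ** 2)
        ss_tot = np.sum((means - means.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        rows.append((bouton_id, len(sub), len(uniq), slope, r2, r2 >= r2_min))
    per_bouton = pd.DataFrame(
        rows, columns=["bouton_id", "n_events", "n_bins", "slope", "r2", "eligible"]
    )
    eligible = per_bouton[per_bouton["eligible"]]
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"only {len(eligible)} eligible boutons (need >= 3)"
        )
    fraction = float((eligible["slope"] > 0).mean())
    return fraction, per_bouton


def in_az_asymptote(
    per_bouton: pd.DataFrame,
    n_col: str = "n_sync",
    frac_col: str = "frac_in_az",
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Saturating-exponential fit of the in-AZ asynchronous share.

    Fits ``p(n) = P * (1 - exp(-n / tau))`` to the per-``n_sync`` mean of
    the in-AZ fraction.  Returns ``(P, tau, means)``; on non-convergence
    the parameters are None and the raw means are still returned.
    """
    t = per_bouton[[n_col, frac_col]].dropna()
    means = (
        t.groupby(n_col)[frac_col].mean().reset_index().rename(
            columns={n_col: "n_sync", frac_col: "mean_frac"}
        )
    )
    if len(means) < 5:
        raise InsufficientDataError("need >= 5 distinct synchronous counts")
    n = means["n_sync"].to_numpy(dtype=float)
    p = means["mean_frac"].to_numpy(dtype=float)
    try:
        popt, _ = curve_fit(
            lambda nn, plateau, tau: plateau * (1 - np.exp(-nn / tau)),
            n,
            p,
            p0=(0.8, 5.0),
            bounds=([0.0, 1e-9], [1.5, np.inf]),
            maxfev=10000,
        )
        return float(popt[0]), float(popt[1]), means
    except RuntimeError:
        return None, None, means


def compare_distributions(
    sample_a,
    sample_b,
    test: str = "ks",
) -> tuple[float, float]:
    """Two-sample comparison: ``ks`` (Kolmogorov-Smirnov, two-sided),
    ``t`` (two-sample two-tailed t-test) or ``kruskal`` (Kruskal-Wallis).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("both samples must be non-empty")
    if test == "ks":
        res = stats.ks_2samp(a, b)
    elif test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "kruskal":
        res = stats.kruskal(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def fraction_pct(numerator: int | float, denominator: int | float, digits: int = 1) -> float:
    """A fraction expressed as a percentage, rounded for reporting.

    Headline percentages are always derived from an explicit
    numerator/denominator pair so they remain auditable.
    """
    if denominator == 0:
        raise ZeroDivisionError("fraction with zero denominator")
    return round(100.0 * numerator / denominator, digits)
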