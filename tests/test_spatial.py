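import numpy as np
import pandas as pd
import pytest

from azmap import (
    amplitude_distance_correlation,
    compare_distributions,
    fraction_pct,
    in_az_asymptote,
    per_bouton_slope_fraction,
    ring_profile,
)
from azmap.errors import (
    EmptyInputError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from azmap.spatial import correlation_across_widths, freedman_diaconis_width


def _events(d, amp, bouton="A"):
    return pd.DataFrame(
        {"bouton_id": bouton, "event_id": [f"e{i}" for i in range(len(d))],
         "d_center_nm": d, "amplitude": amp}
    )


def test_ring_binning_is_half_open():
    t = _events([50.0, 100.0, 150.0], [1.0, 1.0, 1.0])
    prof = ring_profile(t, 100.0)
    assert list(prof["ring"]) == [0, 1]
    assert list(prof["n"]) == [1, 2]  # the event at exactly 100 nm joins ring 1
    assert prof["n"].sum() == 3


def test_ring_means_reproduce_a_linear_gradient():
    rng = np.random.default_rng(10)
    d = rng.uniform(0, 500, 4000)
    amp = 1.0 + 0.004 * d + rng.normal(0, 0.1, len(d))
    prof = ring_profile(_events(d, amp), 100.0)
    for _, row in prof.iterrows():
        expected = 1.0 + 0.004 * row["d_mid"]
        assert row["mean_amplitude"] == pytest.approx(expected, abs=3 * row["sem_amplitude"] + 0.01)


def test_correlation_sign_and_degenerate_cases():
    lin = pd.DataFrame({"d_mid": [50, 150, 250, 350], "mean_amplitude": [1, 2, 3, 4.0]})
    r, p = amplitude_distance_correlation(lin)
    assert r == pytest.approx(1.0)
    anti = lin.assign(mean_amplitude=[4, 3, 2, 1.0])
    r, _ = amplitude_distance_correlation(anti)
    assert r == pytest.approx(-1.0)
    const = lin.assign(mean_amplitude=1.0)
    with pytest.raises(UndefinedStatisticError):
        amplitude_distance_correlation(const)
    with pytest.raises(InsufficientDataError):
        amplitude_distance_correlation(lin.iloc[:2])


def test_correlation_is_stable_across_bin_widths():
    rng = np.random.default_rng(11)
    d = rng.uniform(0, 400, 3000)
    amp = 1.0 + 0.003 * d + rng.normal(0, 0.05, len(d))
    out = correlation_across_widths(_events(d, amp), [50.0, 80.0, 100.0, 150.0])
    assert (out["r"] > 0.9).all()
    assert (out["p"] < 0.05).all()
    # the Freedman-Diaconis width is a usable alternative
    w = freedman_diaconis_width(d)
    out_fd = correlation_across_widths(_events(d, amp), [w])
    assert out_fd["r"].iloc[0] > 0.9


def _gradient_boutons(n_boutons, slope, noise, rng, events_per=30):
    frames = []
    for b in range(n_boutons):
        d = rng.uniform(0, 400, events_per)
        amp = 1.0 + slope * d + rng.normal(0, noise, events_per)
        frames.append(
            pd.DataFrame(
                {"bouton_id": f"b{b}", "event_id": [f"b{b}e{i}" for i in range(events_per)],
                 "d_center_nm": d, "amplitude": amp}
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_noiseless_gradient_gives_unit_slope_fraction():
    rng = np.random.default_rng(12)
    t = _gradient_boutons(20, slope=0.002, noise=0.0, rng=rng)
    frac, per_bouton = per_bouton_slope_fraction(t, top_n=20)
    assert frac == 1.0
    assert per_bouton["eligible"].all()


def test_flat_noisy_boutons_split_near_chance():
    rng = np.random.default_rng(13)
    t = _gradient_boutons(400, slope=0.0, noise=0.2, rng=rng)
    frac, per_bouton = per_bouton_slope_fraction(t, top_n=400)
    n = int(per_bouton["eligible"].sum())
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def test_bouton_with_two_bins_is_excluded():
    rng = np.random.default_rng(14)
    t = _gradient_boutons(5, slope=0.002, noise=0.0, rng=rng)
    narrow = pd.DataFrame(
        {"bouton_id": "narrow", "event_id": [f"n{i}" for i in range(40)],
         "d_center_nm": rng.uniform(0, 150, 40), "amplitude": rng.normal(1, 0.1, 40)}
    )
    t = pd.concat([t, narrow], ignore_index=True)
    _, per_bouton = per_bouton_slope_fraction(t, top_n=6)
    row = per_bouton.set_index("bouton_id").loc["narrow"]
    assert row["n_bins"] <= 2 and not row["eligible"]


def test_slope_fraction_invariances():
    rng = np.random.default_rng(15)
    t = _gradient_boutons(30, slope=0.002, noise=0.05, rng=rng)
    frac, _ = per_bouton_slope_fraction(t, top_n=30)
    scaled = t.assign(amplitude=t["amplitude"] * 7.5)
    frac_scaled, _ = per_bouton_slope_fraction(scaled, top_n=30)
    shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
    frac_shuffled, _ = per_bouton_slope_fraction(shuffled, top_n=30)
    assert frac == frac_scaled == frac_shuffled


def test_asymptote_parameter_recovery():
    rng = np.random.default_rng(16)
    n_sync = rng.integers(3, 40, 500)
    frac = 0.83 * (1 - np.exp(-n_sync / 6.0)) + rng.normal(0, 0.05, 500)
    t = pd.DataFrame({"n_sync": n_sync, "frac_in_az": np.clip(frac, 0, 1)})
    plateau, tau, means = in_az_asymptote(t)
    assert plateau == pytest.approx(0.83, abs=0.05)
    assert tau == pytest.approx(6.0, abs=2.0)


def test_constant_fraction_drives_tau_to_zero():
    t = pd.DataFrame({"n_sync": [5, 10, 15, 20, 25], "frac_in_az": [0.8] * 5})
    plateau, tau, _ = in_az_asymptote(t)
    assert plateau == pytest.approx(0.8, abs=0.01)
    assert tau < 1.0


def test_asymptote_needs_five_distinct_counts():
    t = pd.DataFrame({"n_sync": [5, 10], "frac_in_az": [0.5, 0.8]})
    with pytest.raises(InsufficientDataError):
        in_az_asymptote(t)


def test_two_sample_comparisons():
    x = np.arange(100.0)
    d, p = compare_distributions(x, x, "ks")
    assert d == 0.0 and p == 1.0
    d, _ = compare_distributions(x, x + 1000.0, "ks")
    assert d == 1.0
    with pytest.raises(EmptyInputError):
        compare_distributions([], x, "ks")
    for test in ("t", "kruskal"):
        stat, p = compare_distributions(x, x + 0.0, test)
        assert p > 0.9


def test_ks_p_values_are_calibrated_under_the_null():
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        a, b = rng.normal(size=(2, 60))
        _, p = compare_distributions(a, b, "ks")
        rejections += p < 0.05
    assert abs(rejections / n_rep - 0.05) < 0.04


def test_fraction_formatter():
    assert fraction_pct(1, 3) == 33.3
    with pytest.raises(ZeroDivisionError):
        fraction_pct(1, 0)
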