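import numpy as np
import pandas as pd
import pytest

from azmap import (
    assign_to_sites,
    cluster_all_sites,
    cluster_sites,
    label_events,
    nearest_sync_distances,
)
from .conftest import make_dataset
from .oracles import complete_linkage_bruteforce


def _events(xs, bouton="A"):
    return pd.DataFrame(
        {
            "bouton_id": bouton,
            "event_id": [f"e{i}" for i in range(len(xs))],
            "x_nm": xs,
            "y_nm": 0.0,
        }
    )


def _partition(sites):
    return sorted(frozenset(s.member_event_ids) for s in sites)


def test_fifty_nm_diameter_cut_on_line_examples():
    # {0, 10} merge (span 10), 100 stays apart
    sites = cluster_sites(_events([0.0, 10.0, 100.0]), diameter_nm=50.0)
    assert _partition(sites) == sorted([frozenset({"e0", "e1"}), frozenset({"e2"})])
    # 0-30-60: full span 60 > 50, so complete linkage keeps {0,30} | {60}
    sites = cluster_sites(_events([0.0, 30.0, 60.0]), diameter_nm=50.0)
    assert _partition(sites) == sorted([frozenset({"e0", "e1"}), frozenset({"e2"})])


def test_single_event_forms_unreused_site():
    sites = cluster_sites(_events([5.0]), diameter_nm=50.0)
    assert len(sites) == 1
    assert sites[0].n_events == 1 and not sites[0].reused


def test_clustering_matches_bruteforce_for_small_boutons():
    """scipy complete-linkage cut equals the first-principles agglomerative
    oracle for boutons of up to 8 events (reduced count; the 500-bouton
    version runs in the acceptance suite)."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        xy = rng.uniform(0, 200, size=(n, 2))
        ev = pd.DataFrame(
            {"bouton_id": "A", "event_id": [f"e{i}" for i in range(n)],
             "x_nm": xy[:, 0], "y_nm": xy[:, 1]}
        )
        sites = cluster_sites(ev, diameter_nm=50.0)
        expected = complete_linkage_bruteforce(xy, 50.0)
        got = sorted(
            sorted(int(e[1:]) for e in s.member_event_ids) for s in sites
        )
        assert got == sorted(sorted(c) for c in expected)


def test_site_bookkeeping_is_conserved():
    rng = np.random.default_rng(8)
    xy = rng.uniform(0, 300, size=(20, 2))
    ev = pd.DataFrame(
        {"bouton_id": "A", "event_id": [f"e{i}" for i in range(20)],
         "x_nm": xy[:, 0], "y_nm": xy[:, 1]}
    )
    sites = cluster_sites(ev, diameter_nm=50.0)
    assert len(sites) <= 20
    assert sum(s.n_events for s in sites) == 20
    # within-site span never exceeds the clustering diameter
    for s in sites:
        members = ev[ev["event_id"].isin(s.member_event_ids)][["x_nm", "y_nm"]].to_numpy()
        d = np.linalg.norm(members[:, None] - members[None, :], axis=2)
        assert d.max() <= 50.0 + 1e-9


def _site_table():
    return pd.DataFrame(
        {
            "site_id": ["A:s0", "A:s1"],
            "bouton_id": ["A", "A"],
            "x_nm": [0.0, 80.0],
            "y_nm": [0.0, 0.0],
            "n_events": [3, 2],
            "reused": [True, True],
        }
    )


def test_capture_radius_rule_and_tie_break():
    async_ev = pd.DataFrame(
        {
            "bouton_id": "A",
            "event_id": ["in20", "out30", "tie40"],
            "x_nm": [20.0, 30.0, 40.0],
            "y_nm": [0.0, 0.0, 0.0],
        }
    )
    out = assign_to_sites(async_ev, _site_table(), capture_nm=25.0).set_index("event_id")
    assert out.loc["in20", "in_cluster"] == True  # 20 nm <= 25 nm
    assert out.loc["out30", "in_cluster"] == False  # 30 nm > 25 nm
    # exactly equidistant between s0 and s1: lowest site id wins
    assert out.loc["tie40", "nearest_site_id"] == "A:s0"
    assert out.loc["tie40", "in_cluster"] == False


def test_in_cluster_fraction_monotone_in_capture_radius():
    rng = np.random.default_rng(9)
    async_ev = pd.DataFrame(
        {
            "bouton_id": "A",
            "event_id": [f"a{i}" for i in range(50)],
            "x_nm": rng.uniform(-50, 130, 50),
            "y_nm": rng.uniform(-50, 50, 50),
        }
    )
    fracs = [
        assign_to_sites(async_ev, _site_table(), capture_nm=c)["in_cluster"].mean()
        for c in (10, 25, 50, 100)
    ]
    assert all(a <= b for a, b in zip(fracs, fracs[1:]))


def test_bouton_without_sites_is_unassigned():
    async_ev = pd.DataFrame(
        {"bouton_id": "Z", "event_id": ["a0"], "x_nm": [0.0], "y_nm": [0.0]}
    )
    out = assign_to_sites(async_ev, _site_table(), capture_nm=25.0)
    assert out.loc[0, "nearest_site_id"] is None
    assert np.isnan(out.loc[0, "d_site_nm"])


def test_nearest_sync_distance_to_reused_sites():
    sync = pd.DataFrame(
        {"bouton_id": ["A", "A"], "event_id": ["s0", "s1"],
         "x_nm": [0.0, 200.0], "y_nm": [0.0, 0.0]}
    )
    async_ev = pd.DataFrame(
        {"bouton_id": ["A", "A", "B"], "event_id": ["a40", "a60", "bz"],
         "x_nm": [40.0, 140.0, 0.0], "y_nm": [0.0, 0.0, 0.0]}
    )
    out = nearest_sync_distances(async_ev, sync).set_index("event_id")
    assert out.loc["a40", "d_nn_nm"] == pytest.approx(40.0)   # counts at <= 50 nm
    assert out.loc["a60", "d_nn_nm"] == pytest.approx(60.0)   # does not count
    assert np.isnan(out.loc["bz", "d_nn_nm"])                 # no reused sites there
    frac = (out["d_nn_nm"].dropna() <= 50.0).mean()
    assert frac == pytest.approx(0.5)


def test_identical_positions_give_zero_nn_distance():
    sync = pd.DataFrame(
        {"bouton_id": ["A"], "event_id": ["s0"], "x_nm": [7.0], "y_nm": [7.0]}
    )
    async_ev = pd.DataFrame(
        {"bouton_id": ["A"], "event_id": ["a0"], "x_nm": [7.0], "y_nm": [7.0]}
    )
    out = nearest_sync_distances(async_ev, sync)
    assert out.loc[0, "d_nn_nm"] == 0.0


def test_cluster_all_sites_writes_site_ids_back():
    rows = [("A", 0, 0, 0, 1), ("A", 10, 0, 1, 1), ("A", 200, 0, 2, 1),
            ("A", 100, 0, 10, 2)]
    ds = label_events(make_dataset(rows))
    table = cluster_all_sites(ds)
    assert len(table) == 2
    assert table["n_events"].sum() == 3
    sync_sites = ds.events.loc[ds.events["release_class"] == "synchronous", "site_id"]
    assert sync_sites.notna().all()
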