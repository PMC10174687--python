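"""One-command orchestration of the full analysis battery.

Runs classification, bouton filters, AZ geometry, release sites, MVR
detection, decay decomposition, spatial and temporal statistics and the
spatial-randomization null model on a conforming dataset, and assembles a
machine-readable JSON summary.  Condition labels partition the report; no
cross-condition pooling is performed.  Every headline fraction is reported
with its numerator and denominator.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplitude import attach_amplitudes, detect_mvr_all
from .classify import filter_boutons, label_events
from .errors import (
    InsufficientDataError,
    PreconditionError,
    UndefinedStatisticError,
)
from .geometry import attach_location, build_az_map, radial_profile
from .kinetics import decompose_decay
from .model import ASYNCHRONOUS, ECTOPIC, IN_AZ, SYNCHRONOUS, Dataset
from .nullmodel import randomize_positions
from .sites import cluster_all_sites, site_utilization_summary
from .spatial import (
    compare_distributions,
    fraction_pct,
    per_bouton_slope_fraction,
    ring_profile,
    amplitude_distance_correlation,
)
from .temporal import sync_intervals

SCHEMA_VERSION = 1


def _frac(n: int, d: int) -> dict:
    out = {"numerator": int(n), "denominator": int(d)}
    if d > 0:
        out["pct"] = fraction_pct(n, d)
    return out


def decay_table(dataset: Dataset) -> pd.DataFrame:
    """Per-event decay decomposition for every classified event with a trace."""
    rows = []
    ev = dataset.events
    classified = ev[ev["release_class"].isin([SYNCHRONOUS, ASYNCHRONOUS])]
    for eid, rc in zip(classified["event_id"], classified["release_class"]):
        tr = dataset.traces.get(eid)
        if tr is None:
            continue
        try:
            dec = decompose_decay(tr)
        except InsufficientDataError:
            continue
        rows.append(
            (eid, rc, dec.uf_amplitude, dec.uf_tau_ms, dec.fast_intercept,
             dec.fast_slope, dec.uf_fraction, dec.fit_ok)
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "release_class", "uf_amplitude", "uf_tau_ms",
                 "fast_intercept", "fast_slope", "uf_fraction", "fit_ok"],
    )


def _decay_summary(decay: pd.DataFrame) -> dict:
    out = {}
    for rc, sub in decay.groupby("release_class"):
        ok = sub[sub["fit_ok"].astype(bool)]
        out[rc] = {
            "n": int(len(sub)),
            "n_fit_ok": int(len(ok)),
            "median_uf_tau_ms": float(ok["uf_tau_ms"].median()) if len(ok) else None,
            "mean_uf_amplitude": float(ok["uf_amplitude"].mean()) if len(ok) else None,
            "mean_fast_intercept": float(sub["fast_intercept"].mean()),
            "mean_fast_slope": float(sub["fast_slope"].mean()),
            "mean_uf_fraction": float(ok["uf_fraction"].dropna().mean())
            if len(ok) else None,
        }
    return out


def run_condition(dataset: Dataset, seed: int = 0, n_reps: int = 10) -> dict:
    """Run the analysis battery on one condition's dataset; returns the
    per-condition report (also stashes intermediate tables in
    ``report['_tables']``)."""
    report: dict = {}
    tables: dict = {}

    # 1. temporal classification + inclusion filters
    dataset = label_events(dataset)
    class_counts = dataset.events["release_class"].value_counts().to_dict()
    report["counts"] = {
        "n_events": int(dataset.n_events),
        "by_class": {k: int(v) for k, v in class_counts.items()},
    }
    filtered_all, audit_all = filter_boutons(dataset, "all")
    spatial_ds, audit_spatial = filter_boutons(dataset, "spatial")
    report["filters"] = {
        "n_boutons_input": int(len(audit_all)),
        "n_boutons_all": int(audit_all["kept"].sum()),
        "n_boutons_spatial": int(audit_spatial["kept"].sum()),
    }
    tables["audit_all"], tables["audit_spatial"] = audit_all, audit_spatial
    if audit_spatial["kept"].sum() == 0:
        report["note"] = "zero boutons pass the spatial filters"
        report["_tables"] = tables
        return report

    # 2. geometry: functional AZs + radial measures
    az_map = build_az_map(spatial_ds)
    radial = radial_profile(spatial_ds, az_map)
    spatial_ds = attach_location(spatial_ds, radial)
    tables["radial"] = radial
    async_radial = radial[radial["release_class"] == ASYNCHRONOUS]
    n_async = int(async_radial["location_class"].isin([IN_AZ, ECTOPIC]).sum())
    n_in = int((async_radial["location_class"] == IN_AZ).sum())
    n_ect = int((async_radial["location_class"] == ECTOPIC).sum())
    report["location"] = {
        "in_az": _frac(n_in, n_async),
        "ectopic": _frac(n_ect, n_async),
        "az_area_nm2_mean": float(
            np.mean([az.area_nm2 for az in az_map.values()])
        ) if az_map else None,
    }
    # distance-distribution comparisons (sync vs async; in-AZ async vs sync)
    sync_d = radial.loc[radial["release_class"] == SYNCHRONOUS, "d_center_nm"].dropna()
    async_d = async_radial["d_center_nm"].dropna()
    in_az_d = async_radial.loc[
        async_radial["location_class"] == IN_AZ, "d_center_nm"
    ].dropna()
    tests = {}
    if len(sync_d) and len(async_d):
        s, p = compare_distributions(sync_d, async_d, "ks")
        tests["sync_vs_async_d_center"] = {"ks_D": s, "p": p}
    if len(sync_d) and len(in_az_d):
        s, p = compare_distributions(sync_d, in_az_d, "ks")
        tests["sync_vs_inaz_async_d_center"] = {"ks_D": s, "p": p}

    # 3. release sites and their utilization
    sites = cluster_all_sites(spatial_ds)
    tables["sites"] = sites
    per_bouton_sites = sites.groupby("bouton_id").agg(
        n_sites=("site_id", "size"), n_reused=("reused", "sum")
    )
    report["sites"] = {
        "sites_per_az_mean": float(per_bouton_sites["n_sites"].mean()),
        "reused_sites_per_az_mean": float(per_bouton_sites["n_reused"].mean()),
        "utilization": site_utilization_summary(spatial_ds, sites),
    }

    # 4. amplitudes + MVR
    spatial_ds = attach_amplitudes(spatial_ds)
    mvr = detect_mvr_all(spatial_ds)
    tables["mvr"] = mvr
    ev = spatial_ds.events
    mvr_rates = {}
    for rc in (SYNCHRONOUS, ASYNCHRONOUS):
        sub = ev[(ev["release_class"] == rc) & ev["mvr_flag"].notna()]
        mvr_rates[rc] = _frac(int(sub["mvr_flag"].sum()), len(sub))
    report["mvr"] = mvr_rates

    # 5. decay decomposition
    decay = decay_table(spatial_ds)
    tables["decay"] = decay
    report["decay"] = _decay_summary(decay)

    # 6. spatial statistics: rings, correlations, per-bouton slopes
    evr = ev.merge(
        radial[["event_id", "d_border_nm"]], on="event_id", how="left"
    )
    spatial_report = {}
    for rc in (SYNCHRONOUS, ASYNCHRONOUS):
        sub = evr[(evr["release_class"] == rc) & evr["amplitude"].notna()]
        prof = ring_profile(sub, spatial_ds.config.ring_width_nm)
        tables[f"rings_{rc}"] = prof
        entry = {"n_rings": int(len(prof))}
        try:
            r, p = amplitude_distance_correlation(prof)
            entry["pearson_r"], entry["pearson_p"] = r, p
        except (InsufficientDataError, UndefinedStatisticError):
            entry["pearson_r"] = entry["pearson_p"] = None
        try:
            frac, per_bouton = per_bouton_slope_fraction(
                sub,
                bin_nm=spatial_ds.config.bouton_bin_nm,
                r2_min=spatial_ds.config.r2_exclusion,
            )
            entry["positive_slope_fraction"] = frac
            entry["n_eligible_boutons"] = int(per_bouton["eligible"].sum())
        except InsufficientDataError:
            entry["positive_slope_fraction"] = None
        spatial_report[rc] = entry
    report["amplitude_distance"] = spatial_report

    # 7. temporal statistics: flanking synchronous intervals
    intervals = sync_intervals(spatial_ds)
    intervals = intervals.merge(
        radial[["event_id", "location_class"]], on="event_id", how="left"
    )
    tables["intervals"] = intervals
    interval_report = {}
    for loc in (IN_AZ, ECTOPIC):
        sub = intervals[intervals["location_class"] == loc]
        interval_report[loc] = {
            "n": int(len(sub)),
            "median_dt_prev_ms": float(sub["dt_prev_ms"].median())
            if sub["dt_prev_ms"].notna().any() else None,
            "median_dt_next_ms": float(sub["dt_next_ms"].median())
            if sub["dt_next_ms"].notna().any() else None,
        }
    prev_in = intervals.loc[intervals["location_class"] == IN_AZ, "dt_prev_ms"].dropna()
    prev_ect = intervals.loc[intervals["location_class"] == ECTOPIC, "dt_prev_ms"].dropna()
    if len(prev_in) and len(prev_ect):
        s, p = compare_distributions(prev_in, prev_ect, "ks")
        tests["inaz_vs_ectopic_dt_prev"] = {"ks_D": s, "p": p}
    report["intervals"] = interval_report

    # 8. spatial-randomization null model
    try:
        sim = randomize_positions(spatial_ds, radial, az_map, n_reps=n_reps, seed=seed)
        tables["simulated"] = sim
        report["nullmodel"] = {
            "n_observed": int(len(async_radial["d_norm"].dropna())),
            "n_simulated": int(len(sim)),
            "n_reps": int(n_reps),
        }
        obs_norm = async_radial["d_norm"].dropna()
        if len(sim):
            s, p = compare_distributions(obs_norm, sim["d_norm"], "ks")
            tests["observed_vs_simulated_d_norm"] = {"ks_D": s, "p": p}
    except PreconditionError:
        report["nullmodel"] = None

    report["tests"] = tests
    report["_tables"] = tables
    return report


def run_pipeline(
    dataset: Dataset,
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_reps: int = 10,
) -> dict:
    """Run the full battery, partitioned by condition label.

    If *out_dir* is given, per-stage TSV tables and ``summary.json`` are
    written there.  The JSON summary is byte-identical across runs with
    the same inputs and seed.
    """
    conditions = sorted(dataset.boutons["condition"].unique())
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "azmap_version": __version__,
        "seed": int(seed),
        "config": dataset.config.to_dict(),
        "conditions": {},
    }
    all_tables: dict = {}
    for cond in conditions:
        ids = set(
            dataset.boutons.loc[dataset.boutons["condition"] == cond, "bouton_id"]
        )
        sub = dataset.copy()
        sub.events = sub.events[sub.events["bouton_id"].isin(ids)].reset_index(drop=True)
        sub.traces = {
            eid: tr for eid, tr in sub.traces.items()
            if eid in set(sub.events["event_id"])
        }
        sub.boutons = sub.boutons[sub.boutons["bouton_id"].isin(ids)].reset_index(drop=True)
        if len(sub.events) == 0:
            continue
        report = run_condition(sub, seed=seed, n_reps=n_reps)
        all_tables[cond] = report.pop("_tables", {})
        summary["conditions"][cond] = report

    cfg_text = json.dumps(dataset.config.to_dict(), sort_keys=True)
    summary["config_hash"] = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cond, tables in all_tables.items():
            for name, table in tables.items():
                table.to_csv(out_dir / f"{cond}_{name}.tsv", sep="\t", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
            + "\n"
        )
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
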