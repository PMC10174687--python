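"""Synthetic single-vesicle release datasets with full ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised and checked against a known answer
without any imaging data:

* per bouton, a random convex "true" AZ polygon (~250 nm across) with a
  handful of release sites scattered inside it;
* synchronous events at those sites (first post-stimulus frame), scattered
  by within-site jitter plus localization error;
* asynchronous events (second frame, respecting the no-first-frame-event
  veto) drawn as a two-population mixture: an in-AZ population biased
  toward the AZ center and an ectopic population beyond the functional
  AZ border, with ectopic events preferentially placed at stimuli far
  from any synchronous event;
* amplitudes from a univesicular Gaussian with a multivesicular (doubled)
  contamination, optionally with a linear amplitude-vs-distance gradient
  on synchronous events;
* traces with an instantaneous rise and a two-component decay
  (ultrafast exponential + linear fast component) plus Gaussian noise.

The asynchronous populations are placed relative to the *functional* AZ
(the hull of the bouton's emitted synchronous events), exactly as the
pipeline will reconstruct it, so configured population fractions are
recovered without geometric bias; the latent true polygon is kept in the
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .config import AcquisitionConfig
from .errors import ConfigError, GenerationError
from .geometry import ActiveZone, build_az, ray_border_distance
from .model import Dataset, FluorescenceTrace

#: Pre-detection frames included in every synthetic trace.
PRE_FRAMES = 10


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset generator.

    Geometry is in nm, rates are per stimulus, amplitudes in arbitrary
    units with a quantal mean of ``amp_mean``.
    """

    seed: int = 0
    n_boutons: int = 100
    az_radius_nm: float = 125.0          # mean AZ "radius" (~250 nm across)
    az_radius_sd_nm: float = 25.0
    n_vertices: tuple[int, int] = (6, 10)
    n_sites: tuple[int, int] = (6, 12)   # brackets ~9 sites per AZ
    site_jitter_nm: float = 15.0
    p_sync: float = 0.12
    async_rate: float = 0.06
    frac_ectopic: float = 0.27
    central_bias: float = 2.0            # 0 disables the central bias (null)
    ectopic_band_nm: float = 150.0
    ectopic_extra_interval: float = 2.0  # >1: ectopic events take the most
    # temporally isolated stimuli
    loc_error_nm: float = 27.0
    amp_mean: float = 1.0
    amp_cv: float = 0.2
    p_mvr: float = 0.05
    trace_tau_uf_ms: float = 60.0
    trace_uf_frac: float = 0.58
    # linear fast component relaxing on a ~800 ms timescale:
    # slope = -(1 - uf_frac) / 800 per ms
    trace_fast_slope: float = -0.42 / 800.0
    noise_sd: float = 0.1
    gradient_b: float = 0.0              # a.u. per nm, synchronous events only

    def __post_init__(self) -> None:
        for name in ("p_sync", "async_rate", "frac_ectopic", "p_mvr"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in (
            "az_radius_nm", "amp_mean", "trace_tau_uf_ms", "ectopic_band_nm"
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.central_bias < 0:
            raise ConfigError("central_bias must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, event by event."""

    events: pd.DataFrame          # event_id, true_class, true_site,
    # true_ectopic, true_mvr, true_amplitude
    az_true: dict = field(default_factory=dict)        # bouton -> vertices
    az_functional: dict = field(default_factory=dict)  # bouton -> ActiveZone
    trace_params: dict = field(default_factory=dict)   # model parameters


def generate_trace(
    amplitude: float,
    *,
    frame_ms: float = 50.0,
    n_post: int = 19,
    tau_uf_ms: float = 60.0,
    uf_frac: float = 0.58,
    fast_slope: float = -0.42 / 800.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    event_id: str = "e0",
) -> FluorescenceTrace:
    """One synthetic event trace.

    The noiseless model is ``amplitude * max(uf_frac * exp(-t/tau) +
    (1 - uf_frac) + fast_slope * t, 0)`` for t >= 0 (t = 0 at detection)
    and a flat zero baseline before detection; Gaussian noise of sd
    *noise_sd* is added to every sample.
    """
    if tau_uf_ms <= 0:
        raise ConfigError("tau_uf_ms must be strictly positive")
    if amplitude <= 0:
        raise ConfigError("amplitude must be strictly positive")
    t = np.arange(n_post + 1) * frame_ms
    decay = uf_frac * np.exp(-t / tau_uf_ms) + (1 - uf_frac) + fast_slope * t
    post = amplitude * np.clip(decay, 0.0, None)
    values = np.concatenate([np.zeros(PRE_FRAMES), post])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return FluorescenceTrace(
        event_id=event_id,
        frame_ms=frame_ms,
        values=values,
        detection_index=PRE_FRAMES,
        baseline_frames=5,
    )


def _random_polygon(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """A random convex polygon centered at the origin."""
    n_v = int(rng.integers(cfg.n_vertices[0], cfg.n_vertices[1] + 1))
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, size=n_v))
    radii = np.clip(
        rng.normal(cfg.az_radius_nm, cfg.az_radius_sd_nm, size=n_v), 40.0, None
    )
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    hull = Polygon(pts).convex_hull
    return np.asarray(hull.exterior.coords[:-1])


def _points_in_polygon(
    rng: np.random.Generator, poly: Polygon, n: int, max_tries: int = 200
) -> np.ndarray:
    """Uniform rejection sampling of *n* points inside *poly*."""
    minx, miny, maxx, maxy = poly.bounds
    out: list[np.ndarray] = []
    for _ in range(max_tries):
        m = max(4 * n, 16)
        xy = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
        out.extend(xy[inside])
        if len(out) >= n:
            return np.asarray(out[:n])
    raise GenerationError("could not place points inside the AZ polygon")


def generate_dataset(
    cfg: SyntheticConfig,
    acq: AcquisitionConfig | None = None,
    condition: str = "control",
) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic dataset plus its ground truth.

    The output is bitwise reproducible for a given ``cfg.seed``.
    """
    if acq is None:
        acq = AcquisitionConfig()
    rng = np.random.default_rng(cfg.seed)
    frames_per_stim = acq.frames_per_stimulus

    ev_rows = []
    gt_rows = []
    traces: dict[str, FluorescenceTrace] = {}
    az_true: dict = {}
    az_functional: dict = {}

    for ib in range(cfg.n_boutons):
        bouton_id = f"b{ib:04d}"
        poly_xy = _random_polygon(rng, cfg)
        # spread boutons on a coarse grid so the field looks plausible
        offset = np.array([(ib % 100) * 2000.0, (ib // 100) * 2000.0])
        poly_xy = poly_xy + offset
        poly = Polygon(poly_xy)
        az_true[bouton_id] = poly_xy

        n_sites = int(rng.integers(cfg.n_sites[0], cfg.n_sites[1] + 1))
        site_xy = _points_in_polygon(rng, poly, n_sites)

        # --- synchronous events -----------------------------------------
        sync_stims = np.flatnonzero(rng.random(acq.n_stimuli) < cfg.p_sync)
        scatter = np.hypot(cfg.site_jitter_nm, cfg.loc_error_nm)

        sync_positions = []
        sync_records = []
        for s in sync_stims:
            site = int(rng.integers(n_sites))
            pos = site_xy[site] + rng.normal(0.0, scatter, size=2)
            sync_positions.append(pos)
            sync_records.append((int(s), site, pos))

        az = None
        if len(sync_positions) >= 3:
            try:
                az = build_az(np.asarray(sync_positions), bouton_id=bouton_id)
            except Exception:
                az = None
        if az is not None:
            az_functional[bouton_id] = az

        # --- asynchronous events ----------------------------------------
        free = np.setdiff1d(np.arange(acq.n_stimuli), sync_stims)
        async_stims = free[rng.random(len(free)) < cfg.async_rate]
        n_async = len(async_stims)
        n_ect = int(rng.binomial(n_async, cfg.frac_ectopic)) if n_async else 0
        if n_async:
            if cfg.ectopic_extra_interval > 1 and len(sync_stims):
                # ectopic events occupy the stimuli most isolated from
                # synchronous activity, enlarging their flanking intervals
                gaps = np.min(
                    np.abs(async_stims[:, None] - sync_stims[None, :]), axis=1
                )
                order = np.argsort(-(gaps + rng.uniform(0, 0.5, n_async)))
            else:
                order = rng.permutation(n_async)
            ect_mask = np.zeros(n_async, dtype=bool)
            ect_mask[order[:n_ect]] = True
        else:
            ect_mask = np.zeros(0, dtype=bool)

        # --- emit rows ---------------------------------------------------
        counter = 0

        def emit(stim, offset_frames, pos, true_class, true_site, true_ect):
            nonlocal counter
            eid = f"{bouton_id}e{counter:03d}"
            counter += 1
            ev_rows.append(
                (bouton_id, eid, pos[0], pos[1], int(stim), int(offset_frames),
                 condition)
            )
            gt_rows.append((eid, bouton_id, true_class, true_site, true_ect))
            return eid

        for s, site, pos in sync_records:
            emit(s, 1, pos, "synchronous", site, False)

        ref_az = az  # asynchronous placement is relative to the functional AZ
        for s, is_ect in zip(async_stims, ect_mask):
            if ref_az is not None:
                center = ref_az.center_nm
                theta = rng.uniform(0.0, 2 * np.pi)
                direction = np.array([np.cos(theta), np.sin(theta)])
                border = float(
                    ray_border_distance(ref_az, direction[None, :])[0]
                )
                reach = border + acq.rim_nm
                if is_ect:
                    r = reach + rng.uniform(1.0, cfg.ectopic_band_nm)
                    pos = center + direction * r
                elif cfg.central_bias > 0:
                    d_norm = rng.beta(1.0, 1.0 + cfg.central_bias)
                    pos = center + direction * (d_norm * reach)
                else:
                    # null: positions bootstrapped from this bouton's own
                    # synchronous events, so in-AZ asynchronous events are
                    # spatially indistinguishable from synchronous ones
                    pos = np.array(
                        sync_positions[int(rng.integers(len(sync_positions)))]
                    )
            else:
                # too few synchronous events for a functional AZ; fall back
                # to the latent polygon (these boutons fail the filters)
                pos = _points_in_polygon(rng, poly, 1)[0]
            emit(s, 2, pos, "asynchronous", None, bool(is_ect))

    events = pd.DataFrame(
        ev_rows,
        columns=["bouton_id", "event_id", "x_nm", "y_nm", "stim_index",
                 "frame_offset", "condition"],
    )
    truth = pd.DataFrame(
        gt_rows,
        columns=["event_id", "bouton_id", "true_class", "true_site",
                 "true_ectopic"],
    )

    # --- amplitudes -----------------------------------------------------
    n_ev = len(events)
    is_mvr = rng.random(n_ev) < cfg.p_mvr
    draws = rng.normal(cfg.amp_mean, cfg.amp_cv * cfg.amp_mean, size=n_ev)
    draws = np.clip(draws, 0.05 * cfg.amp_mean, None)
    amp = np.where(is_mvr, 2.0 * draws, draws)
    if cfg.gradient_b != 0:
        sync_mask = (events["frame_offset"] == 1).to_numpy()
        d_center = np.zeros(n_ev)
        for bouton_id, sub in events.groupby("bouton_id", sort=False):
            az = az_functional.get(bouton_id)
            if az is None:
                continue
            idx = sub.index.to_numpy()
            xy = sub[["x_nm", "y_nm"]].to_numpy()
            d_center[idx] = np.linalg.norm(xy - az.center_nm, axis=1)
        amp = np.where(sync_mask, amp + cfg.gradient_b * d_center, amp)
    truth["true_mvr"] = is_mvr
    truth["true_amplitude"] = amp

    # --- traces ----------------------------------------------------------
    for eid, offset_frames, a in zip(
        events["event_id"], events["frame_offset"], amp
    ):
        n_post = frames_per_stim - int(offset_frames)
        traces[eid] = generate_trace(
            float(a),
            frame_ms=acq.frame_ms,
            n_post=n_post,
            tau_uf_ms=cfg.trace_tau_uf_ms,
            uf_frac=cfg.trace_uf_frac,
            fast_slope=cfg.trace_fast_slope,
            noise_sd=cfg.noise_sd,
            rng=rng,
            event_id=str(eid),
        )

    dataset = Dataset(config=acq, events=events, traces=traces)
    dataset.boutons["condition"] = condition
    gt = GroundTruth(
        events=truth,
        az_true=az_true,
        az_functional=az_functional,
        trace_params={
            "tau_uf_ms": cfg.trace_tau_uf_ms,
            "uf_frac": cfg.trace_uf_frac,
            "fast_slope": cfg.trace_fast_slope,
            "noise_sd": cfg.noise_sd,
            **dataclasses.asdict(cfg),
        },
    )
    return dataset, gt
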