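"""Spatial randomization null model for asynchronous event positions.

To test whether the observed spatial pattern of asynchronous events could
arise from placement that is random in angle while preserving the observed
radial occupancy, each observed asynchronous event is replaced by
``n_reps`` simulated events in its own bouton: the polar angle about the
AZ center is drawn uniformly on [0, 2pi), and the normalized radial
coordinate is resampled (with replacement) from the pooled empirical
multiset of asynchronous normalized distances.  The drawn normalized
radius is converted back to nanometers using that bouton's ray-border
distance along the drawn angle plus the rim, so simulated events respect
each AZ's size and shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .geometry import ray_border_distance
from .model import ASYNCHRONOUS, Dataset


def randomize_positions(
    dataset: Dataset,
    radial: pd.DataFrame,
    az_map: dict,
    n_reps: int = 10,
    seed: int = 0,
    radius_mode: str = "normalized",
) -> pd.DataFrame:
    """Simulate angle-uniform, radius-empirical asynchronous positions.

    Parameters
    ----------
    dataset, radial, az_map
        Labeled dataset, its radial-profile table and AZ map.
    n_reps
        Simulated events per observed asynchronous event.
    seed
        Seed of the dedicated random generator; identical seeds give
        identical output.
    radius_mode
        ``"normalized"`` (default): pool normalized radii across boutons
        and rescale per bouton and angle.  ``"raw"``: pool the raw
        distances in nm.  ``"per_bouton"``: pool normalized radii within
        each bouton only.

    Returns a frame with one row per simulated event: ``source_event_id,
    bouton_id, rep, x_nm, y_nm, theta, d_norm, d_center_nm``.
    """
    if radius_mode not in {"normalized", "raw", "per_bouton"}:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    obs = radial[
        (radial["release_class"] == ASYNCHRONOUS) & radial["d_norm"].notna()
    ]
    if len(obs) == 0:
        raise PreconditionError("no asynchronous events with radial measures")
    rng = np.random.default_rng(seed)
    rim = dataset.config.rim_nm
    pooled_norm = obs["d_norm"].to_numpy()
    pooled_raw = obs["d_center_nm"].to_numpy()

    rows = []
    for bouton_id, sub in obs.groupby("bouton_id", sort=False):
        az = az_map.get(bouton_id)
        if az is None:
            continue
        n_sim = len(sub) * n_reps
        theta = rng.uniform(0.0, 2 * np.pi, size=n_sim)
        if radius_mode == "per_bouton":
            pool = sub["d_norm"].to_numpy()
        elif radius_mode == "raw":
            pool = pooled_raw
        else:
            pool = pooled_norm
        draws = rng.choice(pool, size=n_sim, replace=True)
        directions = np.column_stack([np.cos(theta), np.sin(theta)])
        border = ray_border_distance(az, directions)
        if radius_mode == "raw":
            r = draws
            d_norm = r / (border + rim)
        else:
            d_norm = draws
            r = d_norm * (border + rim)
        xy = az.center_nm + directions * r[:, None]
        src = np.repeat(sub["event_id"].to_numpy(), n_reps)
        rep = np.tile(np.arange(n_reps), len(sub))
        for j in range(n_sim):
            rows.append(
                (src[j], bouton_id, int(rep[j]), xy[j, 0], xy[j, 1],
                 theta[j], d_norm[j], r[j])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "source_event_id", "bouton_id", "rep",
            "x_nm", "y_nm", "theta", "d_norm", "d_center_nm",
        ],
    )
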