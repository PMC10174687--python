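"""Temporal classification of release events and bouton-level inclusion filters.

An event detected in the first post-stimulus frame is synchronous.  An event
in the second frame is asynchronous only if no event was detected in the
first frame of the same stimulus at the same bouton (otherwise the persisting
fluorescence of a synchronous event could masquerade as asynchronous, and
the second-frame event is excluded).  Later frames are left unclassified
under the default 50 ms protocol but can be labeled through configurable
asynchronous windows (e.g. offsets 2-4 under the 25 ms near-TIRF protocol,
corresponding to the 25-50, 50-75 and 75-100 ms windows).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidOffsetError, PreconditionError
from .model import (
    ASYNCHRONOUS,
    EXCLUDED,
    SYNCHRONOUS,
    UNCLASSIFIED,
    Dataset,
)


def label_events(dataset: Dataset, async_offsets: Sequence[int] = (2,)) -> Dataset:
    """Label every event synchronous / asynchronous / excluded / unclassified.

    Parameters
    ----------
    dataset
        Events with ``stim_index`` and ``frame_offset`` populated.
    async_offsets
        Frame offsets treated as asynchronous windows.  Each window is
        labeled separately in the ``async_window`` column (0-based index
        into *async_offsets*); the no-preceding-first-frame-event veto
        applies to every window.

    Returns
    -------
    Dataset
        The same dataset with ``release_class`` (and ``async_window``)
        columns set.  Labeling is idempotent.
    """
    ev = dataset.events
    if (ev["frame_offset"] < 1).any():
        raise InvalidOffsetError("frame_offset must be >= 1")
    offsets = list(async_offsets)
    if any(o < 2 for o in offsets):
        raise InvalidOffsetError("asynchronous windows start at frame offset 2")

    offset = ev["frame_offset"].to_numpy()
    sync_mask = offset == 1
    # stimuli with a first-frame event, per bouton
    vetoed = set(
        zip(ev.loc[sync_mask, "bouton_id"], ev.loc[sync_mask, "stim_index"])
    )
    has_sync = np.array(
        [(b, s) in vetoed for b, s in zip(ev["bouton_id"], ev["stim_index"])]
    )

    release_class = np.full(len(ev), UNCLASSIFIED, dtype=object)
    async_window = np.full(len(ev), -1, dtype=int)
    release_class[sync_mask] = SYNCHRONOUS
    for w, off in enumerate(offsets):
        in_window = offset == off
        release_class[in_window & ~has_sync] = ASYNCHRONOUS
        async_window[in_window & ~has_sync] = w
        release_class[in_window & has_sync] = EXCLUDED

    out = ev.copy()
    out["release_class"] = release_class
    out["async_window"] = async_window
    dataset.events = out
    return dataset


def filter_boutons(dataset: Dataset, purpose: str = "all") -> tuple[Dataset, pd.DataFrame]:
    """Apply the per-bouton inclusion criteria.

    ``purpose="all"`` keeps boutons with at least ``min_sync_events``
    synchronous events (guards against active zones strongly tilted out of
    the imaging plane); ``purpose="spatial"`` additionally requires at
    least ``min_events_spatial`` classified (synchronous + asynchronous)
    events, ensuring adequate sampling of release sites.

    Returns the filtered dataset and a per-bouton audit table with columns
    ``bouton_id, n_sync, n_async, kept, reason``.
    """
    if purpose not in {"all", "spatial"}:
        raise ValueError(f"purpose must be 'all' or 'spatial', got {purpose!r}")
    ev = dataset.events
    if "release_class" not in ev.columns:
        raise PreconditionError("label_events must run before filter_boutons")
    cfg = dataset.config

    counts = (
        ev.groupby("bouton_id")["release_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[SYNCHRONOUS, ASYNCHRONOUS], fill_value=0)
    )
    audit = pd.DataFrame(
        {
            "bouton_id": counts.index,
            "n_sync": counts[SYNCHRONOUS].to_numpy(),
            "n_async": counts[ASYNCHRONOUS].to_numpy(),
        }
    ).reset_index(drop=True)
    n_classified = audit["n_sync"] + audit["n_async"]

    kept = audit["n_sync"] >= cfg.min_sync_events
    reason = np.where(kept, "", f"fewer than {cfg.min_sync_events} synchronous events")
    if purpose == "spatial":
        too_few = kept & (n_classified < cfg.min_events_spatial)
        reason = np.where(
            too_few,
            f"fewer than {cfg.min_events_spatial} classified events",
            reason,
        )
        kept = kept & ~too_few
    audit["kept"] = kept
    audit["reason"] = reason

    keep_ids = set(audit.loc[audit["kept"], "bouton_id"])
    filtered = dataset.copy()
    filtered.events = filtered.events[
        filtered.events["bouton_id"].isin(keep_ids)
    ].reset_index(drop=True)
    filtered.traces = {
        eid: tr
        for eid, tr in filtered.traces.items()
        if eid in set(filtered.events["event_id"])
    }
    filtered.boutons = filtered.boutons[
        filtered.boutons["bouton_id"].isin(keep_ids)
    ].reset_index(drop=True)
    return filtered, audit
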