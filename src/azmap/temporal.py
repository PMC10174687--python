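"""Inter-event intervals between asynchronous and flanking synchronous events.

For every asynchronous event, the elapsed time from the immediately
preceding synchronous event and to the immediately following synchronous
event of the same bouton are measured across the whole recording (the
interval distributions extend over multiple stimulus cycles).  A missing
flank (no earlier / later synchronous event) leaves the corresponding
interval undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .model import ASYNCHRONOUS, SYNCHRONOUS, Dataset


def sync_intervals(dataset: Dataset) -> pd.DataFrame:
    """Per-asynchronous-event intervals to the flanking synchronous events.

    Returns ``event_id, bouton_id, dt_prev_ms, dt_next_ms`` (NaN where the
    flank does not exist, including boutons with no synchronous events).
    Both intervals are strictly positive whenever defined: the
    classification veto guarantees no synchronous event shares a stimulus
    with an asynchronous one in the same bouton.
    """
    ev = dataset.events
    if "release_class" not in ev.columns:
        raise PreconditionError("label_events must run before sync_intervals")
    rows = []
    for bouton_id, sub in ev.groupby("bouton_id", sort=False):
        sync_t = np.sort(
            sub.loc[sub["release_class"] == SYNCHRONOUS, "time_ms"].to_numpy()
        )
        asyncs = sub[sub["release_class"] == ASYNCHRONOUS]
        for eid, t in zip(asyncs["event_id"], asyncs["time_ms"]):
            if len(sync_t) == 0:
                rows.append((eid, bouton_id, np.nan, np.nan))
                continue
            i = np.searchsorted(sync_t, t, side="left")
            dt_prev = t - sync_t[i - 1] if i > 0 else np.nan
            dt_next = sync_t[i] - t if i < len(sync_t) else np.nan
            rows.append((eid, bouton_id, dt_prev, dt_next))
    return pd.DataFrame(
        rows, columns=["event_id", "bouton_id", "dt_prev_ms", "dt_next_ms"]
    )
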