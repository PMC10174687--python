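"""Core containers: the event table, per-event traces, and the dataset.

Events live in a :class:`pandas.DataFrame` with a fixed column schema (one
row per localized fusion event); per-event fluorescence traces are kept as
:class:`FluorescenceTrace` objects in a mapping keyed by event id.  The
:class:`Dataset` bundles both with the acquisition configuration and a
bouton table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .errors import EmptyInputError, InvalidOffsetError, OrphanTraceError

# -- release_class labels ---------------------------------------------------
SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"
EXCLUDED = "excluded"
UNCLASSIFIED = "unclassified"
RELEASE_CLASSES = (SYNCHRONOUS, ASYNCHRONOUS, EXCLUDED, UNCLASSIFIED)

# -- location_class labels --------------------------------------------------
IN_AZ = "in_az"
ECTOPIC = "ectopic"
UNDEFINED = "undefined"
LOCATION_CLASSES = (IN_AZ, ECTOPIC, UNDEFINED)

#: Columns every event table must provide.
MANDATORY_COLUMNS = ("bouton_id", "x_nm", "y_nm", "stim_index", "frame_offset")

#: Full schema of a processed event table (optional columns may be absent
#: until the corresponding stage has run).
EVENT_COLUMNS = (
    "bouton_id", "event_id", "x_nm", "y_nm", "stim_index", "frame_offset",
    "time_ms", "amplitude", "norm_amplitude", "release_class",
    "location_class", "site_id", "mvr_flag", "condition",
)


def event_time_ms(stim_index, frame_offset, config: AcquisitionConfig):
    """Event time under the frame-start convention.

    An event detected in the k-th post-stimulus frame is assigned
    ``stim_index * stim_period + k * frame_ms``, the earliest time
    consistent with a frame-resolved detection.
    """
    return (
        np.asarray(stim_index, dtype=float) * config.stim_period_ms
        + np.asarray(frame_offset, dtype=float) * config.frame_ms
    )


@dataclass
class FluorescenceTrace:
    """One event's fluorescence time course on a regular frame grid.

    ``values[detection_index]`` is the sample in which the event was
    detected; ``baseline_frames`` pre-detection frames are available for
    baseline subtraction.
    """

    event_id: str
    frame_ms: float
    values: np.ndarray
    detection_index: int
    baseline_frames: int = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if self.detection_index < self.baseline_frames:
            raise ValueError(
                "detection_index must be >= baseline_frames "
                f"({self.detection_index} < {self.baseline_frames})"
            )
        if len(self.values) <= self.detection_index:
            raise ValueError("trace ends before its detection index")

    @property
    def n_post(self) -> int:
        """Number of samples after the detection sample."""
        return len(self.values) - self.detection_index - 1

    def times_ms(self, origin: str = "detection") -> np.ndarray:
        """Sample times in ms, with t=0 at detection (default) or at the
        first sample."""
        t = np.arange(len(self.values), dtype=float) * self.frame_ms
        if origin == "detection":
            t -= self.detection_index * self.frame_ms
        return t


@dataclass
class Dataset:
    """Event table + traces + bouton table under one acquisition config."""

    config: AcquisitionConfig
    events: pd.DataFrame
    traces: dict[str, FluorescenceTrace] = field(default_factory=dict)
    boutons: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.events) == 0:
            raise EmptyInputError("dataset contains no events")
        missing = [c for c in MANDATORY_COLUMNS if c not in self.events.columns]
        if missing:
            raise KeyError(f"event table missing columns: {missing}")
        if "event_id" not in self.events.columns:
            self.events = self.events.copy()
            self.events["event_id"] = [f"e{i}" for i in range(len(self.events))]
        if self.events["event_id"].duplicated().any():
            dup = self.events["event_id"][self.events["event_id"].duplicated()]
            raise ValueError(f"duplicate event ids: {sorted(set(dup))[:5]}")
        if (self.events["frame_offset"] < 1).any():
            raise InvalidOffsetError("frame_offset must be >= 1 for all events")
        if "time_ms" not in self.events.columns:
            self.events["time_ms"] = event_time_ms(
                self.events["stim_index"], self.events["frame_offset"], self.config
            )
        known = set(self.events["event_id"])
        orphans = [eid for eid in self.traces if eid not in known]
        if orphans:
            raise OrphanTraceError(f"traces without events: {orphans[:5]}")
        if self.boutons is None:
            ids = self.events["bouton_id"].drop_duplicates()
            self.boutons = pd.DataFrame(
                {"bouton_id": ids, "condition": "control"}
            ).reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_of(self, bouton_id, release_class: str | None = None) -> pd.DataFrame:
        """Events of one bouton, optionally restricted to one release class."""
        mask = self.events["bouton_id"] == bouton_id
        if release_class is not None:
            mask &= self.events["release_class"] == release_class
        return self.events[mask]

    def copy(self) -> "Dataset":
        return Dataset(
            config=self.config,
            events=self.events.copy(),
            traces=dict(self.traces),
            boutons=None if self.boutons is None else self.boutons.copy(),
        )
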