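"""Acquisition configuration: the fixed constants of the imaging protocol.

The defaults encode a 1 Hz field-stimulation protocol imaged at 50 ms/frame
for 120 s, with the geometric and statistical constants used throughout the
analysis (active-zone rim width, release-site clustering diameter, capture
radii, inclusion thresholds, multivesicular-release threshold, binning
widths).  An alternate 25 ms/frame near-TIRF protocol is obtained by setting
``frame_ms=25``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class AcquisitionConfig:
    """Protocol constants and analysis thresholds.

    Parameters
    ----------
    frame_ms
        Duration of one acquisition frame in ms (50 default; 25 for the
        near-TIRF protocol).
    stim_period_ms
        Inter-stimulus interval in ms (1000 = 1 Hz stimulation).
    n_stimuli
        Number of stimuli per recording (120 at 1 Hz over 120 s).
    rim_nm
        Rim added to the active-zone border, approximating the vesicle
        radius, before computing normalized radial distances.
    cluster_diameter_nm
        Complete-linkage cut height for release-site clustering.
    site_capture_radius_nm
        An asynchronous event within this distance of a release-site center
        is counted as occurring in that site.
    nn_overlap_radius_nm
        Radius for the nearest-neighbor overlap fraction between
        asynchronous and synchronous events.
    min_sync_events
        Minimum synchronous events per bouton for any analysis.
    min_events_spatial
        Minimum total classified events per bouton for spatial analyses.
    mvr_threshold
        Normalized-amplitude threshold above which an event is called
        multivesicular.
    ad_alpha
        Significance level of the Anderson-Darling normality test used in
        MVR detection.
    ring_width_nm
        Width of the concentric rings for distance-binned averages.
    bouton_bin_nm
        Bin width for the per-bouton amplitude-vs-distance fits.
    r2_exclusion
        Per-bouton linear fits with R^2 below this are excluded as noise.
    baseline_frames
        Number of pre-detection frames averaged as the baseline F0.
    spectrum_window_ms
        Length of the post-detection window used for the amplitude
        spectrum.
    """

    frame_ms: float = 50.0
    stim_period_ms: float = 1000.0
    n_stimuli: int = 120
    rim_nm: float = 25.0
    cluster_diameter_nm: float = 50.0
    site_capture_radius_nm: float = 25.0
    nn_overlap_radius_nm: float = 50.0
    min_sync_events: int = 5
    min_events_spatial: int = 10
    mvr_threshold: float = 2.0
    ad_alpha: float = 0.05
    ring_width_nm: float = 100.0
    bouton_bin_nm: float = 80.0
    r2_exclusion: float = 0.1
    baseline_frames: int = 5
    spectrum_window_ms: float = 900.0

    def __post_init__(self) -> None:
        positive = (
            "frame_ms", "stim_period_ms", "rim_nm", "cluster_diameter_nm",
            "site_capture_radius_nm", "nn_overlap_radius_nm", "mvr_threshold",
            "ring_width_nm", "bouton_bin_nm", "spectrum_window_ms",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n_stimuli < 1:
            raise ConfigError("n_stimuli must be >= 1")
        if self.baseline_frames < 1:
            raise ConfigError("baseline_frames must be >= 1")
        if not (0 < self.ad_alpha < 1):
            raise ConfigError("ad_alpha must lie in (0, 1)")
        ratio = self.stim_period_ms / self.frame_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("frame_ms must divide stim_period_ms")

    @property
    def frames_per_stimulus(self) -> int:
        return int(round(self.stim_period_ms / self.frame_ms))

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
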