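"""Shared setup for the analysis drivers.

All drivers analyze the same deterministic synthetic dataset (seed below),
regenerated through the library rather than passed around as large files;
each driver writes its tables under results/.
"""

from pathlib import Path

from azmap import (
    SyntheticConfig,
    attach_amplitudes,
    build_az_map,
    filter_boutons,
    generate_dataset,
    label_events,
    radial_profile,
)
from azmap.geometry import attach_location

SEED = 2026
N_BOUTONS = 300
RESULTS = Path(__file__).resolve().parent.parent / "results"


def dataset(**overrides):
    RESULTS.mkdir(exist_ok=True)
    return generate_dataset(
        SyntheticConfig(seed=SEED, n_boutons=N_BOUTONS, **overrides)
    )


def analyzed(**overrides):
    """Labeled, spatially filtered dataset with radial measures and
    amplitudes attached; returns (dataset, radial table, AZ map, truth)."""
    ds, gt = dataset(**overrides)
    ds = label_events(ds)
    sp, _ = filter_boutons(ds, "spatial")
    az_map = build_az_map(sp)
    radial = radial_profile(sp, az_map)
    sp = attach_location(sp, radial)
    sp = attach_amplitudes(sp)
    return sp, radial, az_map, gt
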