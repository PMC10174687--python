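# azmap

Nanoscale spatiotemporal analysis of single synaptic-vesicle release events.

Modern live-imaging experiments localize individual vesicle-fusion events at
presynaptic boutons with a precision of a few tens of nanometers, frame by
frame, during 1 Hz field stimulation. `azmap` is the analysis side of such an
experiment: given a table of localized release events (bouton, x/y position
in nm, stimulus index, detection-frame offset) and, optionally, each event's
fluorescence time course, it answers the questions a synapse physiologist
asks of these data:

* which events are **synchronous** (first post-stimulus frame) and which are
  **asynchronous** (second frame, with no first-frame event at the same
  bouton and stimulus);
* where does each event sit relative to the **functional active zone (AZ)**
  — the convex hull of the bouton's synchronous events — and is an
  asynchronous event inside the AZ or **ectopic**;
* do asynchronous events reuse the **release sites** defined by clustering
  synchronous events;
* which events are **multivesicular** (MVR);
* how does the post-fusion fluorescence decay decompose into **ultrafast**
  and **fast** endocytosis components, and does event amplitude depend on
  the distance to the AZ center;
* could the observed spatial pattern arise from random placement
  (**randomization null model**).

A synthetic-data generator with complete ground truth stands in for imaging
data, so the entire pipeline is testable end to end.

## The quantities at the core

**Normalized radial distance.** For an event at distance `d_c` from the AZ
center (the mean position of the bouton's synchronous events), with `d_b`
the distance from the center to the hull border along the same ray and `r`
a 25 nm rim (one vesicle radius, absorbing localization uncertainty of the
hull-defining events):

```
d_norm = d_c / (d_b + r);    d_norm <= 1  ->  in-AZ,   d_norm > 1  ->  ectopic
```

**Release sites.** Agglomerative clustering of a bouton's synchronous
events with complete linkage, cut at a 50 nm diameter, so no site spans
more than 50 nm. An asynchronous event within 25 nm of a site center is
counted as using that site; a site with ≥ 2 events is "reused".

**MVR detection.** Per bouton, event amplitudes (detection-frame signal
minus the mean of the 5 preceding frames) are tested for normality
(Anderson–Darling). While normality is rejected, the largest amplitude is
removed; the surviving subset's mean is the quantal mean `q`, and events
with amplitude `> 2 q` are flagged multivesicular.

**Decay decomposition.** For each trace (t = 0 at detection), a line fitted
to the tail from the 5th post-detection frame gives the *fast* component
(intercept `c`, slope `m`); a single exponential `A·exp(−t/τ)` fitted to
the line-subtracted residual gives the *ultrafast* component. The component
shares at detection are `A/(A+c)` and `c/(A+c)`.

**Null model.** Each asynchronous event is replaced by `n_reps` simulated
events with angle `θ ~ U[0, 2π)` about the AZ center and normalized radius
resampled from the pooled empirical `d_norm` multiset, mapped back to nm
through that bouton's border distance along `θ`.

## Worked example

```python
from azmap import (SyntheticConfig, generate_dataset, label_events,
                   filter_boutons, build_az_map, radial_profile, fraction_pct)

ds, truth = generate_dataset(SyntheticConfig(seed=2026, n_boutons=300))
ds = label_events(ds)                      # synchronous / asynchronous
ds, _ = filter_boutons(ds, "spatial")      # >=5 sync and >=10 events per bouton
radial = radial_profile(ds, build_az_map(ds))

a = radial[radial.release_class == "asynchronous"]
n_in = (a.location_class == "in_az").sum()
print(f"in-AZ: {fraction_pct(n_in, len(a))}%  ectopic: {fraction_pct(len(a)-n_in, len(a))}%")
```

prints

```
in-AZ: 75.2%  ectopic: 24.8%
```

i.e. roughly three quarters of asynchronous events fall inside the
functionally defined AZ and one quarter occurs ectopically, matching the
generator's configured two-population mixture. The numbered drivers under
`analysis/` run the full battery on the same dataset and narrate each step
(release-site utilization, MVR rates, decay components, distance-dependent
amplitude, interval analysis, null model), writing tables under `results/`.

The same analyses run from the shell:

```
azmap simulate --out-events e.csv --out-traces t.h5 --out-truth gt.csv --n-boutons 50
azmap run --events e.csv --traces t.h5 --out results/
```

`results/summary.json` then holds per-class counts, in-AZ/ectopic
fractions with numerators and denominators, site-utilization overlaps
under both definitions, MVR rates, decay summaries and the statistical
comparisons.

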