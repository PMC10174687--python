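# Methods

This note records what `azmap` computes, the assumptions behind each step,
the numerical choices that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model and timing

Events are planar points in nm in an arbitrary per-field frame; no pixel
units cross the API. An event detected in post-stimulus frame `k` is
assigned the frame-start time `t = stim_index · stim_period + k · frame_ms`
— the earliest time consistent with frame-resolved detection. The default
protocol is 50 ms/frame, 1 Hz stimulation, 120 stimuli; a 25 ms/frame
variant is configured through `AcquisitionConfig(frame_ms=25)`.

## Temporal classification

Frame 1 → synchronous; frame 2 → asynchronous, unless an event occurred in
frame 1 of the same stimulus at the same bouton, in which case the frame-2
event is excluded (a synchronous event's fluorescence can persist into the
next frame and masquerade as asynchronous). The veto is applied per
bouton-and-stimulus, not per release site. Frame ≥ 3 events are kept as
`unclassified` rather than dropped, so alternate window configurations
(e.g. offsets 2–4 at 25 ms/frame) can relabel them; every asynchronous
window is labeled separately. Multiple frame-2 events at one stimulus are
all kept. Bouton filters: ≥ 5 synchronous events for any analysis (guards
against active zones tilted out of the imaging plane), ≥ 10 classified
events for spatial analyses (release-site sampling).

## Active-zone geometry

The functional AZ is the convex hull of a bouton's synchronous events; the
AZ center is the **mean of all synchronous event positions**, not the
polygon centroid (the two coincide for symmetric event sets; the centroid
is available as an option). The hull guarantees the mean lies strictly
inside, so every center-to-event ray crosses the boundary exactly once;
the crossing is computed by exact ray–segment intersection against each
hull edge (validated in the tests against a 0.01 nm ray-marching search).

The 25 nm rim is applied as an additive offset to the ray-intersection
distance — a radial dilation along each ray — not as a Minkowski disk sum.
This keeps `d_norm = d_c/(d_b + rim)` a simple ratio; the two constructions
differ only near vertices, by less than `rim · (1 − cos(θ/2))` for vertex
angle θ. Ties at `d_norm` exactly 1 classify as in-AZ. An event exactly at
the center reports `d_norm = 0` (border distance by convention along +x).
Synchronous events always come out with `d_norm < 1`: they define the
hull, and the rim keeps the border ratio strictly below one.

## Release sites

Hierarchical clustering uses **complete linkage** cut at the 50 nm
clustering diameter, so "diameter" literally bounds the within-site span;
single/average linkage are accepted options for sensitivity checks. Merge
order ties are resolved deterministically (scipy's observation-order rule;
the worked 1-D examples pin the expected partitions, and random boutons
are checked against a first-principles agglomerative oracle). The 50 nm
value itself is a configuration constant; its inconsistency-coefficient
derivation belongs to earlier work and is not re-implemented. Asynchronous
events within 25 nm of a site center (one vesicle radius under a 50 nm
site) count as using the site; equidistant ties go to the lowest site id.
The nearest-neighbor variant measures distances to synchronous events of
reused sites only (≥ 2 events) and reports the ≤ 50 nm fraction.

The overall synchronous/asynchronous overlap is reported in two labeled
compositions — capture-fraction × in-AZ share and NN-fraction × in-AZ
share — because the two definitions bracket the quantity rather than
coincide.

## Amplitudes and multivesicular events

Amplitude = signal at the detection frame − mean of the 5 preceding
frames. MVR detection pools all of a bouton's event amplitudes and runs
the iterative Anderson–Darling loop: while normality is rejected at
`alpha` (default 0.05, conventional; the test statistic's p-value is
interpolated), remove the single largest amplitude. The surviving subset
is therefore always an ascending-sorted prefix; its mean is the quantal
mean, every event (including removed ones) is normalized by it, and
normalized amplitude > 2 flags MVR. Boutons with fewer than 8 amplitudes
are skipped (the test is uninformative below that), and a subset that
shrinks below 8 without ever passing is flagged unresolvable, with no
calls. Removed-then-renormalized events at or below 2 stay non-MVR.

A structural property of the threshold worth knowing: when true MVR
amplitudes are distributed around exactly twice the quantal mean, the
`> 2` rule sits at the center of that distribution, so roughly half of
such events fall under the threshold regardless of how well the quantal
mean is recovered. The acceptance suite measures this operating point on
a 2× mixture (sensitivity ≈ 0.5, specificity > 0.99); the rule is a
high-specificity detector, not a high-sensitivity one.

## Decay decomposition, averaging, spectra

Stage 1 fits an ordinary least-squares line to the tail starting at the
5th sample after detection ("fifth point after the detection" read
literally as `detection_index + 5`; the offset is configurable),
unweighted, out to the last frame before the next stimulus (19
post-detection frames at 50 ms / 1 Hz). Stage 2 subtracts the
extrapolated line from the whole post-detection segment — including the
detection sample — and fits `A·exp(−t/τ)` by bounded nonlinear least
squares with `A ≥ 0, τ > 0`, initialized at `A₀ =` residual at detection
and `τ₀ =` one frame. If the fit fails to converge, or `A` lands on the
zero bound (a purely linear decay), `fit_ok` is false; the zero-bound
case still reports `A = 0` with an undefined τ. At least 7 post-detection
samples are required. The component shares at detection are defined as
`A/(A + c)` and its complement — the only definition consistent with both
quantities being amplitudes at t = 0; this is an interpretation, flagged
as such.

Trace averaging aligns at the detection sample over the common overlap
window and reports the pointwise mean and SEM (`sd/√n`; zero for a single
trace by convention). Min-max normalization maps `(x − min)/(max − min)`
and rejects constant traces. The amplitude spectrum transforms the first
900 ms from detection (18 samples at 50 ms; an odd count is truncated by
one sample), doubles the interior bins of the two-sided spectrum, and
reports frequencies from 0 to Nyquist at 1/window resolution.

## Spatial and temporal statistics

Rings are half-open `[k·w, (k+1)·w)` with `w = 100` nm (a normalized-
distance variant uses `d_norm` bins), events weighted equally within a
ring. Pearson correlation between ring midpoints and ring mean amplitudes
requires ≥ 3 occupied rings; a list of widths (plus the Freedman–Diaconis
automatic width) exposes the bin-robustness of the result. Per-bouton
slope analysis takes the 100 boutons with the most events, bins amplitude
vs distance in 80 nm bins, fits a line to the bin means, excludes boutons
with < 3 occupied bins or `R² < 0.1` (the published "R² < ±0.1" exclusion
is read as an R² magnitude threshold, with survivors classified by slope
sign — R² is non-negative), and reports the positive-slope fraction
against the 50% chance level. The in-AZ-share saturation fits
`p(n) = P·(1 − exp(−n/τ))` to per-`n_sync` means.

Inter-event intervals are computed within a bouton across the whole
recording (the interval distributions span multiple stimulus cycles):
for each asynchronous event, the time from the last synchronous event
strictly before and to the first strictly after. The classification veto
makes a same-stimulus 50 ms interval impossible; the shortest preceding
interval is one stimulus period plus one frame.

No multiple-testing correction is applied anywhere; raw p-values are
reported.

## Randomization null model

The randomization draws, for each observed asynchronous event, `n_reps`
(default 10) simulated events in its bouton: angle uniform on `[0, 2π)`,
normalized radius resampled with replacement from the pooled empirical
`d_norm` multiset of asynchronous events, converted to nm via the
bouton's border distance along the drawn angle plus the rim. (The
published description assigns the uniform 0–2π numbers to the radial
coordinate — an evident slip; angle-uniform/radius-empirical is the only
self-consistent reading of the procedure.) Raw-radius and per-bouton
pooling variants are available behind flags. All draws come from one
seeded generator; identical seeds give identical output.

On synthetic data this null is *calibrated* against the asynchronous
events themselves — their generative process is angle-uniform with
i.i.d. radii, so observed and randomized distributions coincide up to
resampling noise — while the site-clustered synchronous pattern is
detected as non-random. Real recordings carry bouton-to-bouton
heterogeneity and angular structure that the generator does not emulate,
which is what the randomization is designed to expose there.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth. Defaults (chosen once, as the study conditions):

| parameter | default | meaning |
|---|---|---|
| `az_radius_nm` | 125 ± 25 | latent AZ polygon scale (~250 nm across) |
| `n_sites` | 6–12 | release sites per AZ (brackets ~9) |
| `site_jitter_nm` | 15 | within-site scatter sd |
| `loc_error_nm` | 27 | localization error sd (synchronous scatter) |
| `p_sync` | 0.12 | synchronous events per stimulus (~14 per 120 s) |
| `async_rate` | 0.06 | asynchronous events per sync-free stimulus |
| `frac_ectopic` | 0.27 | ectopic share of asynchronous events |
| `central_bias` | 2 | Beta(1, 1+β) normalized radius for in-AZ events |
| `ectopic_band_nm` | 150 | ectopic band beyond border + rim |
| `amp_mean`, `amp_cv` | 1.0, 0.2 | quantal amplitude model |
| `p_mvr` | 0.05 | MVR probability (amplitude doubled) |
| `trace_tau_uf_ms` | 60 | ultrafast decay constant |
| `trace_uf_frac` | 0.58 | ultrafast share of the decay at detection |
| `trace_fast_slope` | −0.42/800 per ms | fast component relaxing on ~800 ms |
| `noise_sd` | 0.1 | additive Gaussian trace noise (SNR 10 at unit amplitude) |

Design choices that were genuinely open:

* **Functional vs latent AZ.** Asynchronous events are placed relative to
  the *functional* hull of the bouton's emitted synchronous events —
  exactly the object the pipeline reconstructs — so configured population
  fractions are recovered without geometric bias. The latent polygon is
  kept in the ground truth.
* **Asynchronous positions are drawn directly as localized positions**
  (the radial mixture is taken to describe the observed, error-convolved
  distribution); explicit localization jitter is applied only to the
  synchronous site scatter, where it shapes the hull.
* **`central_bias = 0` (the spatial null)** bootstraps in-AZ asynchronous
  positions from the bouton's own synchronous events. Weaker nulls — a
  fresh draw from the site process, with or without conditioning on
  landing in-AZ, or a radial bootstrap with an independent angle — are
  all measurably "closer to center" at study scale, through truncation at
  the hull (synchronous events carry their own extremes into the hull,
  asynchronous draws cannot) or through the angle–radius correlation of
  hull-vertex events. Positional resampling is the only null under which
  the two distance distributions coincide exactly.
* **Ectopic temporal isolation**: the ectopic quota is assigned to the
  asynchronous stimuli most distant from any synchronous stimulus
  (rank-based thinning, active when `ectopic_extra_interval > 1`), which
  reproduces the longer flanking intervals of ectopic events while
  preserving the configured ectopic fraction exactly.
* **Trace model**: instantaneous rise to the event amplitude, then
  `amp · max(uf·exp(−t/τ) + (1−uf) + slope·t, 0)` plus Gaussian noise;
  the linear slope is set so the fast component relaxes on the ~800 ms
  timescale of fast endocytosis (hence −(1−uf)/800 per ms), and the
  clamp keeps the noiseless model non-negative once the line crosses
  zero late in the window.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: bouton-to-bouton heterogeneity of radial
occupancy and angular structure (real AZs are not angle-isotropic);
synapse displacement over the 120 s recording; within-frame fusion-time
variability and the detectability limit; photobleaching; reacidification
kinetics; any dependence of the in-AZ share on synchronous sampling (the
generator's share is constant in `n_sync`, so the saturation fit recovers
the plateau with a near-zero τ rather than a sampling time constant);
and correlations between amplitude and kinetics beyond the optional
distance gradient.

## Problem sizes and seeds

The test and reproduction runs use 300-bouton datasets (~6,000 events),
500 traces for decay-parameter recovery, 200 polygons × 50 rays for the
geometry oracle and 500 small boutons for the clustering oracle — sizes at
which every binomial interval used in the checks is a few percent wide.
All randomness flows through explicitly seeded generators; the
reproduction script derives its per-stage seeds from a single `--seed`.

## Known limitations

* The `> 2` MVR threshold is conservative by construction (see above);
  per-bouton rates on mixtures with doubled-amplitude MVR events run at
  roughly half the generating rate.
* The decay decomposition's linear stage absorbs residual exponential
  signal when τ approaches the frame period, biasing τ upward by a few
  percent at 50 ms sampling (median recovery stays well within ±30%).
* Fit windows end at the next stimulus, so synchronous and asynchronous
  traces differ by one sample in window length; at large n this produces
  a small detectable difference in fast-component intercepts even when
  the underlying model is identical.
* With fewer than three non-collinear synchronous events a bouton has no
  functional AZ; its events are flagged undefined and the bouton is
  excluded by the standard filters.
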