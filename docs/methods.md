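# Methods

This note documents the models, parameter choices and numerical
conventions behind `fogspeed`, and what the simulations can and cannot
say about real observers.

## Scene model

Frames are procedural stand-ins for a driving simulator's view of a
straight single-lane road: an asphalt strip (base brightness 96) between
grass shoulders (150) under a uniform grey sky, stored as a single
achromatic channel in [0, 255]. Every downstream formula first collapses
colour to the arithmetic mean of R, G and B, so the achromatic channel
is lossless with respect to all implemented maths. The sky brightness
defaults to 128, the fog colour, making sky pixels a fixed point of fog
blending.

Depth comes from back-projecting each below-horizon row through a
pinhole camera at eye height 0.8 m: a row `dr` pixels below the horizon
lies at ground distance `0.8·f_px/dr`, with focal length fixed at the
image height in pixels (vertical field of view ≈ 53°). Sky rows carry an
infinite-depth sentinel. The curved 230°×125° projection surface of a
real simulator is out of scope; angular quantities use an explicit
pixels-per-degree scale instead.

Texture is seeded value noise evaluated in world coordinates (so its
wavelength shrinks with distance, approximating perspective
foreshortening), with peak-to-mean amplitude proportional to
`texture_contrast`. The true texture statistics of the original scenes
are unknown; amplitude and scale are free parameters here, and only
order-level properties (nonzero contrast, monotone texture energy,
determinism) are relied upon.

## Contrast reduction and matching

All three visibility manipulations are per-pixel alpha blending with the
fog colour; fog uses `α = exp(−f·d)`, anti-fog `α = 1 − exp(−af·d)`,
uniform `α = 1 − opacity`. Densities 0.1 and 0.3 /m give meteorological
visibility ranges `ln(20)/f` of 30 m and 10 m. Anti-fog at `af = 0` is
the degenerate fully-obscured scene; the clear scene is its `af → ∞`
limit, which the matching solver treats as infeasible at finite density.

Brightness→luminance calibration is a quadratic `L = a2·b² + a1·b + a0`,
validated non-negative and monotone on [0, 255] at construction. Tests
default to the identity-like linear curve; a curved fixture exercises
the nonlinearity.

"RMS contrast" is implemented as the normalised form `σ_L/μ_L` with the
population standard deviation over all pixels of the frame (frames are
the full population of rendered pixels). A literal root-mean-square of
luminance would carry units of cd/m² and could not match the
dimensionless condition values this statistic is meant to summarise; the
definition is isolated in one function so an alternative convention is a
one-line swap. Matching solvers bisect the monotone parameter→contrast
maps (opacity decreasing, anti-fog density increasing on the bracket
[1e−6, 1e3] /m) to a contrast tolerance of 1e−6 with a 200-iteration
cap; both are deterministic. Whether the original conditions were
matched in luminance or brightness space is unknowable from the printed
values; luminance space is the default and the calibration argument
makes either available. Because the original simulator scenes are
unavailable, the exact printed contrast values (0.46/0.31/0.19/0.24) are
not reproduction targets; the matching *relations* between conditions
are.

## Psychometric model and adaptive procedure

The 2IFC response model is a cumulative Gaussian in natural-log speed
with fixed lapse (default 0.02, splitting equally between floor and
ceiling). The log abscissa makes the slope σ dimensionless and encodes
Weber-like speed discrimination. The adaptive procedure is a grid psi
method: posterior over a PSE×σ lattice (PSE log-spaced over 0.25–4×
the reference, 61 points; σ log-spaced 0.05–1.0, 21 points), candidate
stimuli log-spaced over the same speed range (41 points), uniform prior,
each trial's stimulus chosen to minimise the expected posterior entropy
under the posterior predictive, ties broken toward the lower speed.
Estimates are the posterior mean of log-PSE (exponentiated) and the
posterior mean of σ. No stopping rule beyond the fixed 80-trial count is
used. The selection step uses an algebraically expanded entropy
(avoiding per-candidate normalisation) with a guarded plain-log fast
path; a naive loop implementation is kept in the test suite as an exact
oracle.

The JND is reported as the posterior-mean σ in log-speed units, i.e. the
psychometric slope, not a speed difference in km/hr. Slope values around
0.2–0.6 log-units are the natural scale for this task; treating them as
km/hr differences against 40–90 km/hr stimuli would be implausible by
two orders of magnitude, so no km/hr JND is produced or targeted.

The offline MLE refit maximises the Bernoulli likelihood over (log PSE,
log σ) by bounded L-BFGS-B from a 5×4 grid of starts (σ bounds
0.01–2.0). Logs with fewer than two distinct speeds, a single response
type, or perfect separation (a threshold splitting responses exactly)
are flagged `boundary` rather than raised, since the likelihood is then
maximised on a flat region or at a bound.

## Observer model

Perception is multiplicative with log-normal noise:
`perceived = g_c·v·exp(ε)`, `ε ~ N(0, noise_sigma)`. Log-normal noise
keeps speeds positive and yields Weber-like discrimination; two
independent intervals give an implied psychometric slope of
`√2·noise_sigma` and PSE `reference·g_clear/g_c`. The production task
inverts the same mechanism, `produced = (target/g_c)·exp(ε′)`, ignoring
the transient memory-refresher dynamics of the real task (steady state
only).

Default parameters: `noise_sigma = 0.15` (implied slope ≈ 0.21, giving
discrimination thresholds in the range human observers show on this
task), `lapse = 0.02`, `production_noise_sigma = 0.10`, between-subject
gain jitter 0.05 log-units. Group gains are calibrated from the measured
group-mean PSEs as `g_c = PSE_clear/PSE_c` (fog 60.1/47.7 ≈ 1.26,
anti-fog 60.1/121.6 ≈ 0.49 in the three-condition study). Calibrating
by the PSE *ratio* rather than by absolute PSEs is forced by the model's
structure: a clear-vs-clear comparison always has its PSE at the
reference, so a global clear-condition bias (e.g. a measured clear PSE
of 65 against a 60 km/hr reference) is not representable and the
simulated PSEs preserve ratios to clear rather than absolute values.
For the same reason produced speeds are veridical at clear; the
simulated production magnitudes under anti-fog are therefore larger than
the measured ones, and only the direction structure (fog < clear <
anti-fog) is treated as a reproducible claim.

The mechanistic alternative derives gains from the rendered scene:
`g = (Ĉ_periph/Ĉ_central)^κ`, each region's contrast normalised by the
clear frame, with the central region an axis-aligned angular window
around the image centre. The underlying idea — perceived speed follows
the relative contrast of central vs peripheral visual field — is stated
only qualitatively in the literature this models; the power-law form and
κ are this package's constructs, exploratory by design, and calibrated
mode is the default for headline runs.

## Analysis

The perceived-speed statistic
`PSE_clear·(1 + ln(PSE_clear/PSE_reduced))` is applied per subject
before group averaging; the reverse order differs by a Jensen gap, which
is why evaluating the transform on group-mean PSEs only approximates
(within a few percent) group-mean perceived speeds.

The repeated-measures ANOVA is the classical one-way within-subject
decomposition with `F = MS_cond/MS_error`, generalized eta squared
`SS_cond/(SS_cond + SS_subject + SS_error)` (Olejnik–Algina form for a
fully within design), and Huynh–Feldt epsilon computed from the
double-centred condition covariance (capped at 1) applied to the
degrees of freedom of the reported p. The multi-speed designs are
analysed through this one-way path after averaging across target speeds
— the quantity the group figures report — with an uncorrected two-factor
extension available via statsmodels `AnovaRM`. Holm adjustment is
delegated to statsmodels and cross-checked against a hand step-down
implementation; p-values from simulated data are reported but are never
reproduction targets.

## Orchestration, seeding, problem sizes

Each experiment replication flows from one master seed through
`numpy.random.SeedSequence` spawning (per subject, condition and speed);
no global random state is touched, and a provenance record (config,
hash, version) accompanies written bundles, which are produced by
write-then-rename. Default study sizes follow the original designs: 12
or 10 subjects, five conditions × three speeds × 80 staircase trials
(discrimination) or five production trials per cell. The three-condition
study's fog density defaults to 0.2 /m — the original value is
unpublished and its matched global contrast (0.24) lies between the
moderate (0.31) and severe (0.19) conditions; this only affects rendered
scenes in mechanistic mode, as calibrated-gain simulations are
density-independent. The acceptance script uses 50 seeded pipeline
replications and 50 staircase replicates per PSE level, sizes chosen to
make the run comfortably reproducible on a laptop-class single CPU.

## What the simulations show — and what they do not

Passing tests demonstrate that the implemented machinery is
self-consistent and recovers what it generates: staircases recover
observer PSEs to a few percent, matched conditions share global
contrast to 1e−6, and the calibrated pipeline reproduces the direction
structure of the perceptual and behavioural effects essentially always.
They do not validate the observer model against humans: the gains are
calibrated *from* the measured PSEs, so group PSE levels are inputs, not
predictions; only the propagation from PSEs to perceived/produced speeds
and the statistical machinery are genuinely exercised. Known
limitations: no image-computable motion observer (gains are scalars, not
derived from optic flow), no chromatic or physically scattering fog, no
vehicle dynamics, no lapse estimation, and the mechanistic κ rule is an
untested functional form.
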