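# fogspeed

A simulation pipeline for studying how fog-like contrast reduction biases
perceived driving speed.

Real fog attenuates contrast *with distance*: nearby road surface stays
visible while the distance ahead dissolves into grey. Classic vision
experiments instead reduced contrast *uniformly* (like a dirty
windshield) and concluded that low contrast makes motion look slower —
an explanation often offered for speeding in fog. The two manipulations
turn out to have opposite perceptual effects: distance-dependent
reduction makes self-motion look **faster** (drivers slow down), uniform
reduction makes it look **slower** (drivers speed up), and a reversed
gradient ("anti-fog": near objects obscured, far ones clear) flips the
fog bias. `fogspeed` reimplements the computational core needed to
regenerate these effects from seeds alone: scene rendering with depth,
the three contrast-reduction models with contrast matching, a Bayesian
adaptive 2IFC procedure, generative observers, and the group-level
statistics.

## The models at the core

**Contrast reduction.** Each pixel is alpha-blended with a grey fog
colour `C_f = 128`: `C_r = C_o·α + C_f·(1−α)`, with

- fog: `α = exp(−f·d)` (density `f` per metre, `d` pixel depth);
  meteorological visibility range `MVR = ln(20)/f` (5% contrast);
- anti-fog: `α = 1 − exp(−af·d)`;
- uniform: `α = 1 − opacity`, independent of depth.

Brightness maps to luminance through a quadratic display calibration,
and global contrast is the normalised RMS contrast `σ_L/μ_L`. Bisection
solvers match the uniform opacity and anti-fog density to a fog
condition's global contrast, so conditions differ only in how contrast
is distributed over depth.

**Psychophysics.** The 2IFC response model is a cumulative Gaussian in
log speed, `P(test faster) = λ/2 + (1−λ)·Φ((ln v − ln PSE)/σ)`. A grid
psi method keeps a posterior over (PSE, σ), picks each test speed to
minimise expected posterior entropy, and reads out the PSE (posterior
log-mean) and JND (posterior mean slope, in log-speed units).

**Observers.** A synthetic observer perceives speed `v` under condition
`c` as `g_c·v·exp(ε)`. The same gain drives both tasks: the implied 2IFC
PSE is `reference/g_c`, and the produced speed when holding a remembered
target is `target/g_c`. Gains are calibrated from the measured group
PSEs (`g_c = PSE_clear/PSE_c`) or derived mechanistically from the
rendered scene's peripheral/central contrast ratio.

**Analysis.** PSEs convert to perceived speeds via
`Speed_perceived = PSE_clear + PSE_clear·ln(PSE_clear/PSE_reduced)`,
applied per subject before group averaging; group tables feed a one-way
repeated-measures ANOVA with Huynh–Feldt correction, generalized eta
squared, and Holm-adjusted pairwise post hocs.

## Worked example

`examples/03_fog_antifog_experiment.py` simulates the three-condition
fog/anti-fog studies with ten calibrated observers:

```
discrimination study (PSE/JND via adaptive staircases) ...
  group mean PSE   : clear   59.7  fog   48.1  anti-fog  117.5  km/hr
  perceived speed  : clear   59.7  fog   73.1  anti-fog   19.5  km/hr
  ANOVA: F(2.0,17.7) = 468.5, p = 4.9e-16, eta_G^2 = 0.95

production study (drive at a remembered 60 km/hr target) ...
  produced speed   : clear   60.2  fog   48.2  anti-fog  118.7  km/hr
```

A fog PSE of ~48 km/hr means the foggy scene only has to move at
48 km/hr to look as fast as a clear 60 km/hr scene — speed is
overestimated (perceived ~73 km/hr) — and the same observers drive
slower than the target under fog and faster under anti-fog: the double
dissociation between global contrast and its spatial distribution.

The other examples cover contrast matching (`01`), a single staircase
with MLE refit (`02`), and the mechanistic contrast-gradient gain rule
(`04`). A thin CLI mirrors the stages
(`fogspeed render-scene | apply | run-staircase | simulate | analyze | run`).

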