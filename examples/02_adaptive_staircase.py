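"""Run one Bayesian adaptive staircase against a biased synthetic observer.

The observer overestimates speed under fog by a gain of 1.26 (the value
implied by the measured group PSEs, 60.1/47.7), so the staircase should
converge on a PSE near 60/1.26 ~ 47.6 km/hr: the fog scene only needs to
move at ~48 km/hr to look as fast as a clear 60 km/hr reference.
"""

import numpy as np

from fogspeed.observer import ObserverParams, respond_2ifc
from fogspeed.psychophysics import fit_psychometric_mle, psi_estimate, run_staircase

observer = ObserverParams(gains={"fog": 60.1 / 47.7}, noise_sigma=0.15, lapse=0.02)
reference = 60.0  # km/hr, clear visibility

rng = np.random.default_rng(7)
state = run_staircase(
    lambda v, r: respond_2ifc(observer, reference, v, "fog", r),
    reference_speed=reference,
    n_trials=80,
    rng=rng,
    condition="fog",
)

pse, jnd = psi_estimate(state)
print(f"true PSE   = {reference / observer.gains['fog']:.1f} km/hr")
print(f"psi PSE    = {pse:.1f} km/hr   (posterior mean, 80 trials)")
print(f"psi JND    = {jnd:.3f} log-units (psychometric slope)")

refit = fit_psychometric_mle(state.trial_log, lapse=0.02)
print(f"MLE refit  = PSE {refit.pse:.1f} km/hr, sigma {refit.sigma:.3f}")
print(
    "\nA PSE below the 60 km/hr reference means fog makes the scene look"
    "\nfaster than it is (speed overestimation)."
)
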