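"""2IFC psychometric model, Bayesian adaptive (psi) staircase, and design builder.

The observer's comparative judgment ("which interval moved faster") is
modelled as a cumulative Gaussian in natural-log speed,

    P(test faster) = lapse/2 + (1 - lapse) * Phi((ln v - ln pse) / sigma),

so the slope ``sigma`` is dimensionless and discrimination is Weber-like.
The adaptive procedure is a grid psi method: it maintains a posterior over
a (pse, sigma) lattice, picks each test speed to minimise the expected
posterior entropy over the two possible responses, and applies Bayes'
rule after each response.  PSE is read out as the posterior mean of the
pse axis in the log domain (exponentiated); JND as the posterior mean of
sigma (log-units — the psychometric slope, not a speed difference).

An offline maximum-likelihood refit of staircase logs and a builder for
fully randomised interleaved designs round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, xlogy

__all__ = [
    "PsychometricModel",
    "PsiState",
    "TrialRecord",
    "ExperimentDesign",
    "default_grids",
    "psi_init",
    "psi_select_stimulus",
    "expected_entropies",
    "psi_update",
    "psi_estimate",
    "run_staircase",
    "fit_psychometric_mle",
    "build_design",
    "build_production_design",
]

DEFAULT_LAPSE = 0.02


@dataclass(frozen=True)
class PsychometricModel:
    """Cumulative-Gaussian-in-log-speed 2IFC response model.

    ``pse`` is the speed (km/hr) judged faster than the reference half the
    time (for zero lapse); ``sigma`` the slope in natural-log-speed units;
    ``lapse`` the rate of stimulus-independent random responses, which
    floors/ceils the function at lapse/2 and 1 - lapse/2.  ``boundary``
    flags a degenerate fit that hit a parameter bound.
    """

    pse: float
    sigma: float
    lapse: float = DEFAULT_LAPSE
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.pse <= 0 or self.sigma <= 0:
            raise ValueError("pse and sigma must be positive")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must be in [0, 1]")

    def prob_test_faster(self, v_test: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(v_test, dtype=float)
        p = self.lapse / 2.0 + (1.0 - self.lapse) * ndtr(
            (np.log(v) - np.log(self.pse)) / self.sigma
        )
        return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class TrialRecord:
    """One 2IFC trial: speeds shown, presentation order, and the response."""

    reference_speed: float
    test_speed: float
    condition: str
    order_ref_first: bool
    response_test_faster: bool
    trial_index: int

    def __post_init__(self) -> None:
        if self.reference_speed <= 0 or self.test_speed <= 0:
            raise ValueError("speeds must be positive")


@dataclass
class PsiState:
    """Posterior over the (pse, sigma) lattice plus the staircase's trial log.

    ``posterior`` has shape ``(len(pse_grid), len(sigma_grid))`` and sums
    to 1.  ``_lik[c, i, j]`` caches P(test faster | candidate c, pse i,
    sigma j) for the candidate stimuli.
    """

    pse_grid: np.ndarray
    sigma_grid: np.ndarray
    candidate_stimuli: np.ndarray
    posterior: np.ndarray
    lapse: float = DEFAULT_LAPSE
    trial_log: list[TrialRecord] = field(default_factory=list)
    _lik: np.ndarray = field(default=None, repr=False)

    def likelihood_for_speed(self, v_test: float) -> np.ndarray:
        """P(test faster | pse, sigma) over the grid for one test speed."""
        z = (np.log(v_test) - np.log(self.pse_grid)[:, None]) / self.sigma_grid[None, :]
        return self.lapse / 2.0 + (1.0 - self.lapse) * ndtr(z)


def default_grids(
    reference_speed: float,
    n_pse: int = 61,
    n_sigma: int = 21,
    n_candidates: int = 41,
    speed_span: float = 4.0,
    sigma_range: tuple[float, float] = (0.05, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-spaced default lattices spanning reference/span .. reference*span."""
    lo, hi = reference_speed / speed_span, reference_speed * speed_span
    pse_grid = np.geomspace(lo, hi, n_pse)
    sigma_grid = np.geomspace(sigma_range[0], sigma_range[1], n_sigma)
    candidates = np.geomspace(lo, hi, n_candidates)
    return pse_grid, sigma_grid, candidates


def psi_init(
    pse_grid: np.ndarray,
    sigma_grid: np.ndarray,
    candidate_stimuli: np.ndarray,
    prior: np.ndarray | None = None,
    lapse: float = DEFAULT_LAPSE,
) -> PsiState:
    """Initialise a psi staircase with a uniform (or supplied) prior.

    A supplied prior is normalised on entry; grids must be sorted,
    positive and non-empty.
    """
    pse_grid = np.asarray(pse_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    candidates = np.asarray(candidate_stimuli, dtype=float)
    for name, g in (("pse_grid", pse_grid), ("sigma_grid", sigma_grid),
                    ("candidate_stimuli", candidates)):
        if g.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if np.any(g <= 0):
            raise ValueError(f"{name} entries must be positive")
        if np.any(np.diff(g) < 0):
            raise ValueError(f"{name} must be sorted ascending")
    shape = (pse_grid.size, sigma_grid.size)
    if prior is None:
        posterior = np.full(shape, 1.0 / (shape[0] * shape[1]))
    else:
        posterior = np.asarray(prior, dtype=float).copy()
        if posterior.shape != shape:
            raise ValueError("prior shape must match (pse_grid, sigma_grid)")
        if np.any(posterior < 0) or posterior.sum() <= 0:
            raise ValueError("prior must be non-negative with positive mass")
        posterior /= posterior.sum()
    state = PsiState(
        pse_grid=pse_grid,
        sigma_grid=sigma_grid,
        candidate_stimuli=candidates,
        posterior=posterior,
        lapse=lapse,
    )
    # cache P(test faster | candidate, pse, sigma): (C, P, S)
    z = (
        np.log(candidates)[:, None, None] - np.log(pse_grid)[None, :, None]
    ) / sigma_grid[None, None, :]
    state._lik = lapse / 2.0 + (1.0 - lapse) * ndtr(z)
    return state


def psi_select_stimulus(state: PsiState) -> float:
    """Candidate test speed minimising expected posterior entropy.

    The expectation runs over the two possible responses under the
    posterior predictive.  Deterministic given the state; ties break
    toward the lower speed (argmin over the ascending candidate grid).
    """
    if state.candidate_stimuli.size == 0:
        raise ValueError("empty candidate set")
    return float(state.candidate_stimuli[int(np.argmin(expected_entropies(state)))])


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy (nats) for each candidate stimulus."""
    post = state.posterior.ravel()
    lik = state._lik.reshape(state._lik.shape[0], -1)  # (C, P*S)
    a = lik * post  # joint mass if response "test faster"
    b = post - a  # response "test slower"
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    # expected entropy = sa*H(a/sa) + sb*H(b/sb), expanded to avoid
    # normalising each candidate's posterior explicitly
    if post.min() > 0.0 and 0.0 < state.lapse:
        # all joint masses strictly positive: plain log is safe and fast
        ha = -(a * np.log(a)).sum(axis=1) + sa * np.log(sa)
        hb = -(b * np.log(b)).sum(axis=1) + sb * np.log(sb)
    else:
        ha = -xlogy(a, a).sum(axis=1) + xlogy(sa, sa)
        hb = -xlogy(b, b).sum(axis=1) + xlogy(sb, sb)
    return ha + hb


def psi_update(state: PsiState, trial: TrialRecord) -> PsiState:
    """Bayes-update the posterior with one observed trial (in place).

    The posterior is multiplied by the Bernoulli likelihood of the
    observed response at every grid point and renormalised; the trial is
    appended to the log.  Returns the same state for chaining.
    """
    idx = np.searchsorted(state.candidate_stimuli, trial.test_speed)
    if (
        state._lik is not None
        and idx < state.candidate_stimuli.size
        and np.isclose(state.candidate_stimuli[idx], trial.test_speed, rtol=1e-12, atol=0)
    ):
        p_faster = state._lik[idx]
    else:
        p_faster = state.likelihood_for_speed(trial.test_speed)
    lik = p_faster if trial.response_test_faster else 1.0 - p_faster
    post = state.posterior * lik
    total = post.sum()
    if total <= 0:
        raise ValueError("degenerate grid: observed response impossible everywhere")
    state.posterior = post / total
    state.trial_log.append(trial)
    return state


def psi_estimate(state: PsiState) -> tuple[float, float]:
    """(PSE, JND) from the posterior.

    PSE is the posterior mean of log-PSE, exponentiated; JND is the
    posterior mean slope sigma (dimensionless log-speed units).
    """
    import warnings

    if not state.trial_log:
        warnings.warn("psi_estimate called before any update; returning prior means")
    w_pse = state.posterior.sum(axis=1)
    w_sigma = state.posterior.sum(axis=0)
    pse = float(np.exp(np.dot(w_pse, np.log(state.pse_grid))))
    jnd = float(np.dot(w_sigma, state.sigma_grid))
    return pse, jnd


def run_staircase(
    respond,
    reference_speed: float,
    n_trials: int,
    rng: np.random.Generator,
    condition: str = "",
    lapse: float = DEFAULT_LAPSE,
    grids: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> PsiState:
    """Drive one adaptive staircase against a response callable.

    ``respond(test_speed, rng) -> bool`` reports whether the test interval
    was judged faster.  Presentation order is randomised per trial and
    logged; it does not enter the update (the model is order-symmetric).
    """
    if grids is None:
        grids = default_grids(reference_speed)
    state = psi_init(*grids, lapse=lapse)
    for t in range(n_trials):
        v_test = psi_select_stimulus(state)
        trial = TrialRecord(
            reference_speed=reference_speed,
            test_speed=v_test,
            condition=condition,
            order_ref_first=bool(rng.random() < 0.5),
            response_test_faster=bool(respond(v_test, rng)),
            trial_index=t,
        )
        psi_update(state, trial)
    return state


def _nll(params: np.ndarray, v: np.ndarray, y: np.ndarray, lapse: float) -> float:
    log_pse, log_sigma = params
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((np.log(v) - log_pse) / np.exp(log_sigma))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def fit_psychometric_mle(
    trials: list[TrialRecord],
    lapse: float = DEFAULT_LAPSE,
    sigma_bounds: tuple[float, float] = (0.01, 2.0),
) -> PsychometricModel:
    """Offline maximum-likelihood refit of a staircase log, lapse fixed.

    Bounded L-BFGS-B over (log pse, log sigma) from a coarse grid of
    starts.  Perfectly separated or otherwise unidentifiable logs (fewer
    than two distinct speeds, or only one response type) are fitted at the
    box boundary and flagged via ``boundary=True`` rather than raising.
    """
    if not trials:
        raise ValueError("no trials to fit")
    v = np.array([t.test_speed for t in trials], dtype=float)
    y = np.array([t.response_test_faster for t in trials], dtype=bool)
    identifiable = np.unique(v).size >= 2 and y.any() and (~y).any()
    # perfect separation: a threshold splits the responses exactly, so the
    # likelihood is maximised on a flat region as sigma -> 0
    separated = identifiable and float(v[~y].max()) < float(v[y].min())

    lo_pse, hi_pse = np.log(v.min() / 4.0), np.log(v.max() * 4.0)
    lo_s, hi_s = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    bounds = [(lo_pse, hi_pse), (lo_s, hi_s)]
    starts = [
        (lp, ls)
        for lp in np.linspace(lo_pse, hi_pse, 5)
        for ls in np.linspace(lo_s, hi_s, 4)
    ]
    best = None
    for x0 in starts:
        res = minimize(_nll, x0, args=(v, y, lapse), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    log_pse, log_sigma = best.x
    eps = 1e-6
    at_bound = (
        log_pse <= lo_pse + eps
        or log_pse >= hi_pse - eps
        or log_sigma <= lo_s + eps
        or log_sigma >= hi_s - eps
    )
    return PsychometricModel(
        pse=float(np.exp(log_pse)),
        sigma=float(np.exp(log_sigma)),
        lapse=lapse,
        boundary=bool(at_bound or separated or not identifiable),
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """A fully randomised interleaved 2IFC design.

    One independent staircase per (condition, target speed); the global
    trial sequence is a seeded permutation of all staircases' trials.
    """

    conditions: tuple[str, ...]
    target_speeds: tuple[float, ...]
    trials_per_condition: int
    interleave_seed: int

    @property
    def total_trials(self) -> int:
        return len(self.conditions) * len(self.target_speeds) * self.trials_per_condition


def build_design(
    conditions: list[str],
    target_speeds: list[float],
    trials_per_condition: int,
    seed: int,
) -> tuple[ExperimentDesign, list[tuple[str, float]]]:
    """Build a design plus its interleaved (condition, speed) trial sequence.

    Each staircase contributes exactly ``trials_per_condition`` entries;
    the sequence order is a permutation drawn from ``seed``.
    """
    if not conditions or not target_speeds or trials_per_condition <= 0:
        raise ValueError("all design counts must be positive")
    design = ExperimentDesign(
        conditions=tuple(conditions),
        target_speeds=tuple(float(s) for s in target_speeds),
        trials_per_condition=trials_per_condition,
        interleave_seed=seed,
    )
    sequence = [
        (c, float(s))
        for c in conditions
        for s in target_speeds
        for _ in range(trials_per_condition)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequence))
    return design, [sequence[i] for i in order]


def build_production_design(
    conditions: list[str],
    target_speeds: list[float],
    trials_per_condition: int,
    seed: int,
) -> list[tuple[str, float]]:
    """Randomised trial list for a speed-production session.

    ``trials_per_condition`` counts trials per (condition, target speed)
    cell, so 5 conditions x 1 speed x 5 trials gives the 25-trial session.
    """
    _, sequence = build_design(conditions, target_speeds, trials_per_condition, seed)
    return sequence
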