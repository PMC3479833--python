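"""End-to-end orchestration of the four simulated experiments.

Experiments 1 and 3 are 2IFC speed-discrimination studies (adaptive
staircases yielding per-subject PSE/JND per condition and target speed);
experiments 2 and 4 are speed-production studies (drivers hold a
remembered target speed under each visibility condition).  Experiments
1-2 use five visibility conditions (clear, moderate/severe fog,
moderate/severe uniform reduction) at three target speeds; experiments
3-4 use three conditions (clear, fog, anti-fog) at a single 60 km/hr
target.

Observer gains default to "calibrated" mode: group-level gains derived
from the measured group PSEs via ``g_c = PSE_clear / PSE_c``, with
seeded log-normal between-subject jitter.  All randomness flows from one
master seed through ``numpy`` SeedSequence spawning, so a bundle is
byte-reproducible from its provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    AnovaResult,
    aggregate_subject_means,
    pairwise_posthoc,
    perceived_speed_table,
    rm_anova_oneway,
)
from .observer import CLEAR, ObserverParams, calibrated_gains, produce_speed, respond_2ifc
from .psychophysics import build_design, psi_estimate, run_staircase

__all__ = [
    "RunConfig",
    "ExperimentBundle",
    "default_config",
    "make_observers",
    "run_experiment",
    "GROUP_PSES",
]

#: group-mean PSEs (km/hr) measured in the discrimination studies, used to
#: calibrate default observer gains (clear anchors each study's transform)
GROUP_PSES = {
    "exp1": {
        "clear": 65.0,
        "fog_moderate": 54.7,
        "fog_severe": 41.7,
        "uniform_moderate": 95.5,
        "uniform_severe": 95.2,
    },
    "exp3": {"clear": 60.1, "fog": 47.7, "antifog": 121.6},
}

#: visibility-condition parameter sets (per-metre densities / opacities)
CONDITION_PARAMS = {
    "exp1": {
        "clear": {"kind": "clear"},
        "fog_moderate": {"kind": "fog", "density": 0.1},
        "fog_severe": {"kind": "fog", "density": 0.3},
        "uniform_moderate": {"kind": "uniform", "opacity": 0.28},
        "uniform_severe": {"kind": "uniform", "opacity": 0.52},
    },
    "exp3": {
        "clear": {"kind": "clear"},
        "fog": {"kind": "fog", "density": 0.2},
        "antifog": {"kind": "antifog", "density": 0.2},
    },
}

_N_CONDITIONS = {1: 5, 2: 5, 3: 3, 4: 3}
_N_SPEEDS = {1: 3, 2: 3, 3: 1, 4: 1}
_DEFAULT_SUBJECTS = {1: 12, 2: 10, 3: 10, 4: 10}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to replicate one experiment from a seed."""

    experiment: int
    conditions: tuple[str, ...]
    target_speeds: tuple[float, ...]
    n_subjects: int
    trials_per_condition: int
    gains: dict[str, float]
    noise_sigma: float = 0.15
    production_noise_sigma: float = 0.10
    lapse: float = 0.02
    subject_gain_sd: float = 0.05
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3, 4):
            raise ValueError("experiment must be 1-4")
        if len(self.conditions) != _N_CONDITIONS[self.experiment]:
            raise ValueError(
                f"experiment {self.experiment} requires "
                f"{_N_CONDITIONS[self.experiment]} conditions, got {len(self.conditions)}"
            )
        if len(self.target_speeds) != _N_SPEEDS[self.experiment]:
            raise ValueError(
                f"experiment {self.experiment} requires "
                f"{_N_SPEEDS[self.experiment]} target speed(s)"
            )
        if CLEAR not in self.conditions:
            raise ValueError("a 'clear' condition is required as the reference")
        if self.n_subjects < 2 or self.trials_per_condition < 1:
            raise ValueError("need >= 2 subjects and >= 1 trial per condition")
        missing = [c for c in self.conditions if c not in self.gains and c != CLEAR]
        if missing:
            raise ValueError(f"gains missing for conditions: {missing}")

    @property
    def is_discrimination(self) -> bool:
        return self.experiment in (1, 3)


@dataclass
class ExperimentBundle:
    """Outputs of one experiment run."""

    config: RunConfig
    estimates: pd.DataFrame
    subject_table: pd.DataFrame
    anova: AnovaResult
    posthoc: pd.DataFrame
    summary: dict
    perceived: pd.DataFrame | None = None


def default_config(
    experiment: int,
    n_subjects: int | None = None,
    master_seed: int = 0,
    out_dir: str | None = None,
    trials_per_condition: int | None = None,
) -> RunConfig:
    """Study-condition defaults for each experiment.

    80 staircase trials per condition x speed for the discrimination
    experiments, 5 production trials per cell for the driving ones;
    12/10/10/10 subjects; gains calibrated from the group PSEs.
    """
    study = "exp1" if experiment in (1, 2) else "exp3"
    pses = GROUP_PSES[study]
    gains = calibrated_gains(pses[CLEAR], {c: p for c, p in pses.items() if c != CLEAR})
    if trials_per_condition is None:
        trials_per_condition = 80 if experiment in (1, 3) else 5
    return RunConfig(
        experiment=experiment,
        conditions=tuple(CONDITION_PARAMS[study]),
        target_speeds=(40.0, 60.0, 90.0) if experiment in (1, 2) else (60.0,),
        n_subjects=n_subjects or _DEFAULT_SUBJECTS[experiment],
        trials_per_condition=trials_per_condition,
        gains=gains,
        master_seed=master_seed,
        out_dir=out_dir,
    )


def make_observers(config: RunConfig) -> list[ObserverParams]:
    """Seeded observer population with log-normal between-subject gain jitter."""
    observers = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence((config.master_seed, 40_000 + s))
        )
        gains = {
            c: g * float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
            for c, g in config.gains.items()
        }
        gains[CLEAR] = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
        observers.append(
            ObserverParams(
                gains=gains,
                noise_sigma=config.noise_sigma,
                lapse=config.lapse,
                production_noise_sigma=config.production_noise_sigma,
                seed=s,
            )
        )
    return observers


def _run_discrimination(config: RunConfig, observers: list[ObserverParams]) -> pd.DataFrame:
    rows = []
    for s, obs in enumerate(observers):
        # one independent staircase per (condition, target speed)
        design, _sequence = build_design(
            list(config.conditions),
            list(config.target_speeds),
            config.trials_per_condition,
            seed=int(
                np.random.SeedSequence((config.master_seed, 50_000 + s)).generate_state(1)[0]
                % (2**31)
            ),
        )
        for ci, cond in enumerate(design.conditions):
            for vi, speed in enumerate(design.target_speeds):
                rng = np.random.default_rng(
                    np.random.SeedSequence((config.master_seed, s, ci, vi))
                )

                def respond(v_test: float, r: np.random.Generator, _c=cond) -> bool:
                    return respond_2ifc(obs, speed, v_test, _c, r)

                state = run_staircase(
                    respond,
                    reference_speed=speed,
                    n_trials=config.trials_per_condition,
                    rng=rng,
                    condition=cond,
                    lapse=config.lapse,
                )
                pse, jnd = psi_estimate(state)
                rows.append(
                    {
                        "subject": s,
                        "condition": cond,
                        "target_speed": speed,
                        "pse": pse,
                        "jnd": jnd,
                        "n_trials": config.trials_per_condition,
                    }
                )
    return pd.DataFrame(rows)


def _run_production(config: RunConfig, observers: list[ObserverParams]) -> pd.DataFrame:
    rows = []
    for s, obs in enumerate(observers):
        for ci, cond in enumerate(config.conditions):
            for vi, speed in enumerate(config.target_speeds):
                rng = np.random.default_rng(
                    np.random.SeedSequence((config.master_seed, s, ci, vi))
                )
                for t in range(config.trials_per_condition):
                    rows.append(
                        {
                            "subject": s,
                            "condition": cond,
                            "target_speed": speed,
                            "trial": t,
                            "produced_speed": produce_speed(obs, speed, cond, rng),
                        }
                    )
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> ExperimentBundle:
    """Run one experiment end to end; deterministic for a fixed master seed.

    Discrimination experiments produce per-staircase PSE/JND estimates,
    the per-subject perceived-speed table and its one-way RM-ANOVA;
    production experiments produce per-trial speeds, per-subject condition
    means and their ANOVA.  With ``out_dir`` set, per-subject CSVs plus a
    summary and provenance JSON are written atomically
    (write-then-rename).
    """
    observers = make_observers(config)
    perceived = None
    if config.is_discrimination:
        estimates = _run_discrimination(config, observers)
        pse_table = aggregate_subject_means(estimates, "pse")
        perceived = perceived_speed_table(pse_table, clear_label=CLEAR)
        subject_table = pse_table
        anova = rm_anova_oneway(perceived)
        posthoc = pairwise_posthoc(perceived)
        group = {
            "pse": pse_table.mean().to_dict(),
            "jnd": aggregate_subject_means(estimates, "jnd").mean().to_dict(),
            "perceived_speed": perceived.mean().to_dict(),
        }
    else:
        estimates = _run_production(config, observers)
        subject_table = aggregate_subject_means(estimates, "produced_speed")
        anova = rm_anova_oneway(subject_table)
        posthoc = pairwise_posthoc(subject_table)
        group = {"produced_speed": subject_table.mean().to_dict()}

    summary = {
        "experiment": config.experiment,
        "n_subjects": config.n_subjects,
        "conditions": list(config.conditions),
        "target_speeds": list(config.target_speeds),
        "group_means": group,
        "anova": dataclasses.asdict(anova),
        "posthoc": posthoc.to_dict(orient="records"),
        "master_seed": config.master_seed,
    }
    bundle = ExperimentBundle(
        config=config,
        estimates=estimates,
        subject_table=subject_table,
        anova=anova,
        posthoc=posthoc,
        summary=summary,
        perceived=perceived,
    )
    if config.out_dir is not None:
        _write_bundle(bundle)
    return bundle


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_bundle(bundle: ExperimentBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, df in bundle.estimates.groupby("subject"):
        tmp = out / f"subject_{s:02d}.csv.tmp"
        df.to_csv(tmp, index=False)
        os.replace(tmp, out / f"subject_{s:02d}.csv")
    _atomic_write_text(out / "summary.json", json.dumps(bundle.summary, indent=2, sort_keys=True))
    provenance = {
        "package": "fogspeed",
        "version": __version__,
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(bundle.config).items()
            }
        },
        "config_hash": hash_config(bundle.config),
    }
    _atomic_write_text(out / "provenance.json", json.dumps(provenance, indent=2, sort_keys=True))


def hash_config(config: RunConfig) -> str:
    """Stable hex digest of a config, for provenance records."""
    import hashlib

    payload = json.dumps(
        {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
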