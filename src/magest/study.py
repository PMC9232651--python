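"""Assembly of complete synthetic studies.

A study emulates the duration-reproduction design: each subject performs one
session whose stimuli follow a bounded random walk and one session with the
same values in scrambled order (the "randomized" condition), and responses
come from a simulated observer with subject-specific parameters drawn from
configured ranges.  Everything is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np

from .observer import ObserverParams
from .sequences import (
    TrialSequence,
    calibrate_step_sd,
    gen_random_walk_sequence,
    permute_sequence,
    simulate_observer,
)

__all__ = ["SyntheticStudyConfig", "make_synthetic_study"]

CONDITION_WALK = "random_walk"
CONDITION_RANDOMIZED = "randomized"


@dataclass
class SyntheticStudyConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the duration-reproduction design: 14 subjects, 400 trials
    per condition, stimuli between 400 and 1900 ms.  Per-subject variance
    ratios are drawn uniformly from the ranges observed across real subjects
    (v/r in [0.20, 4.12], q/r in [0, 0.66]); the response shift Δx is drawn
    from a narrow band around zero, and response noise is 0.1 log units.
    """

    n_subjects: int = 14
    n_trials: int = 400
    bounds: tuple[float, float] = (400.0, 1900.0)
    v_over_r_range: tuple[float, float] = (0.20, 4.12)
    q_over_r_range: tuple[float, float] = (0.0, 0.66)
    delta_x_range: tuple[float, float] = (-0.05, 0.05)
    model_kind: str = "two_state"
    response_noise_sd: float = 0.1
    d0: float = 1.0
    step_sd: float | None = None  # calibrated from bounds/n_trials when None
    seed: int = 0

    @classmethod
    def from_dict(cls, config: dict) -> "SyntheticStudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        cfg = dict(config)
        for key in ("bounds", "v_over_r_range", "q_over_r_range", "delta_x_range"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 2:
            raise ValueError("need at least 1 subject and 2 trials")
        for name in ("v_over_r_range", "q_over_r_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be nonnegative")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


def _draw_subject_params(cfg: SyntheticStudyConfig, rng: np.random.Generator) -> ObserverParams:
    v = rng.uniform(*cfg.v_over_r_range)
    q = rng.uniform(*cfg.q_over_r_range)
    dx = rng.uniform(*cfg.delta_x_range)
    if cfg.model_kind == "static":
        q = 0.0
    elif cfg.model_kind == "iterative":
        v = 0.0
    return ObserverParams(cfg.model_kind, v_over_r=v, q_over_r=q, delta_x=dx, d0=cfg.d0)


def make_synthetic_study(config: SyntheticStudyConfig | dict,
                         ) -> tuple[list[TrialSequence], dict]:
    """Generate a full synthetic cohort.

    Returns one :class:`TrialSequence` per subject × condition (walk first,
    then its permutation) and a manifest dictionary recording the seeds and
    the true observer parameters per subject.  Identical configs produce
    identical output.
    """
    if isinstance(config, dict):
        config = SyntheticStudyConfig.from_dict(config)
    config.validate()
    step_sd = config.step_sd
    if step_sd is None:
        step_sd = calibrate_step_sd(config.bounds, n=config.n_trials)

    trials: list[TrialSequence] = []
    manifest: dict = {
        "config": {**asdict(config), "step_sd": step_sd},
        "subjects": [],
    }
    param_rng = np.random.default_rng([config.seed, 10_001])
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        params = _draw_subject_params(config, param_rng)
        walk_seed = [config.seed, s, 0]
        perm_seed = [config.seed, s, 1]
        walk = gen_random_walk_sequence(config.n_trials, step_sd, config.bounds,
                                        walk_seed)
        randomized = permute_sequence(walk, perm_seed, source_id=f"{subject_id}:walk")
        for cond_idx, (cond, stim) in enumerate(
            [(CONDITION_WALK, walk), (CONDITION_RANDOMIZED, randomized)]
        ):
            resp_seed = [config.seed, s, 2 + cond_idx]
            seq = simulate_observer(stim, params, config.response_noise_sd,
                                    resp_seed, subject_id=subject_id, condition=cond)
            trials.append(seq)
        manifest["subjects"].append({
            "subject_id": subject_id,
            "truth": {
                "model_kind": params.model_kind,
                "v_over_r": params.v_over_r,
                "q_over_r": params.q_over_r,
                "delta_x": params.delta_x,
                "d0": params.d0,
            },
            "seeds": {"walk": walk_seed, "permutation": perm_seed},
        })
    return trials, manifest
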