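"""Synthetic observer: response data with the structure the analysis assumes.

The human data behind the original two-line search task are not deposited,
so this module generates stand-in responses with the features the
statistical pipeline relies on: right-skewed reaction times (shifted
lognormal), stable participant-level speed differences (a participant
random effect on the log scale), a condition-specific detection advantage
when the odd stimulus crosses a nonaccidental boundary, and accuracy near
ceiling that is higher for nonaccidental than metric targets.

Reaction time for one trial of participant p in condition c:

    RT = shift + exp( N( log(baseline_c - advantage_c * [NAP trial]) + u_p,
                         sigma_trial ) ),      u_p ~ N(0, sigma_participant)

With this form the population median of (RT | MP) - (RT | NAP) equals the
generating advantage, which is why the analysis summarizes cells by
per-participant medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import TrialRecord
from .geometry import CONDITION_NAMES, Triplet

__all__ = ["ObserverParams", "simulate_responses", "DEFAULT_BASELINES",
           "DEFAULT_ADVANTAGES"]

# per-condition lognormal-median baselines (ms, before the shift).  Chosen
# once to span the plausible 0.85-1.2 s range of a peripheral odd-one-out
# search, slower for the junction conditions.
DEFAULT_BASELINES = {
    "alignment": 600.0,
    "collinearity_between": 650.0,
    "generic_to_L": 800.0,
    "generic_to_T": 850.0,
    "generic_to_X": 800.0,
    "T_to_L": 900.0,
    "X_to_T": 900.0,
    "cotermination": 650.0,
    "expansion_constant": 950.0,
    "collinearity_within": 700.0,
    "curvature_edges": 750.0,
    "curvature_axis": 800.0,
    "curvature_control": 600.0,
}

# ms advantage for detecting a nonaccidental over a metric change.
# expansion_constant gets the smallest advantage (the near-null condition);
# the curvature-axis advantage clearly exceeds the single-line control's
# while curvature-edges matches it, so the 2x2 interaction contrasts have
# a qualitative pattern to detect.
DEFAULT_ADVANTAGES = {name: 60.0 for name in CONDITION_NAMES}
DEFAULT_ADVANTAGES.update(
    {
        "expansion_constant": 15.0,
        "curvature_edges": 80.0,
        "curvature_control": 80.0,
        "curvature_axis": 140.0,
    }
)


@dataclass(frozen=True)
class ObserverParams:
    n_participants: int = 10
    rt_shift: float = 250.0  # ms non-decision time
    participant_mean_sd: float = 0.1  # between-participant, log-ms
    trial_sd: float = 0.35  # within-participant lognormal scale, log-ms
    condition_baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    nap_advantage: dict = field(default_factory=lambda: dict(DEFAULT_ADVANTAGES))
    p_correct_metric: float = 0.90
    p_correct_nap: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for p in (self.p_correct_metric, self.p_correct_nap):
            if not 0.0 < p <= 1.0:
                raise ValueError("correctness probabilities must be in (0, 1]")


def null_params(**overrides) -> ObserverParams:
    """Observer with no nonaccidental advantage (Type-I calibration model)."""
    overrides.setdefault("nap_advantage", {n: 0.0 for n in CONDITION_NAMES})
    return ObserverParams(**overrides)


def simulate_responses(
    trials: list[TrialRecord],
    params: ObserverParams,
    stimulus_set: list[Triplet] | None = None,
    condition_by_triplet: dict | None = None,
) -> pd.DataFrame:
    """Simulate all participants responding to the full trial list.

    Every participant sees every trial.  Errors select a uniformly random
    wrong quadrant.  Fully reproducible from ``params.seed``.
    """
    if condition_by_triplet is None:
        if stimulus_set is None:
            raise ValueError("need stimulus_set or condition_by_triplet")
        condition_by_triplet = {t.triplet_id: t.condition for t in stimulus_set}
    rng = np.random.default_rng(params.seed)
    n_t = len(trials)
    cond = np.array([condition_by_triplet[t.triplet_id] for t in trials])
    variant = np.array([t.variant_changed for t in trials])
    is_nap = variant == "nonaccidental"
    baseline = np.array([params.condition_baseline[c] for c in cond])
    advantage = np.array([params.nap_advantage[c] for c in cond])
    scale = baseline - advantage * is_nap
    if (scale <= 0).any():
        raise ValueError("advantage exceeds baseline for some condition")
    target_q = np.array([t.target_quadrant for t in trials])
    p_correct = np.where(is_nap, params.p_correct_nap, params.p_correct_metric)

    frames = []
    for p in range(params.n_participants):
        u_p = rng.normal(0.0, params.participant_mean_sd)
        rt = params.rt_shift + np.exp(
            rng.normal(np.log(scale) + u_p, params.trial_sd)
        )
        correct = rng.random(n_t) < p_correct
        # errors land on one of the three wrong quadrants
        offs = rng.integers(1, 4, size=n_t)
        chosen = np.where(correct, target_q, (target_q - 1 + offs) % 4 + 1)
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "trial_id": [t.trial_id for t in trials],
                    "triplet_id": [t.triplet_id for t in trials],
                    "condition": cond,
                    "variant_changed": variant,
                    "role": [t.role for t in trials],
                    "target_quadrant": target_q,
                    "chosen_quadrant": chosen,
                    "correct": correct,
                    "rt": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
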