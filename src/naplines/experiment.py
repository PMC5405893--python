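"""Odd-one-out trial table and display layout.

Every trial shows four stimuli, one per display quadrant at 5 deg
eccentricity; three are identical (distractors) and one (the target)
differs.  The full factorial design crosses 78 triplets x 2 changed
variants (metric vs nonaccidental) x 2 target roles (the variant is the
odd one out, or the base is) x 4 target quadrants = 1,248 trials, each
combination occurring exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import Stimulus, Triplet, apply_jitter

__all__ = [
    "TrialRecord",
    "Placement",
    "DisplaySpec",
    "QUADRANT_ANGLES",
    "build_trial_table",
    "layout_trial",
    "trials_frame",
]

#: polar angle (deg) of each quadrant center, eccentricity is config
QUADRANT_ANGLES = {1: 45.0, 2: 135.0, 3: 225.0, 4: 315.0}


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    triplet_id: str
    variant_changed: str  # metric | nonaccidental
    role: str  # variant_is_target | base_is_target
    target_quadrant: int
    block: str  # condition name, or "interleaved"
    order_index: int


@dataclass(frozen=True)
class Placement:
    stimulus_id: str
    quadrant: int
    center: tuple[float, float]  # deg from fixation, jitter included
    jitter_offset: tuple[float, float]
    jitter_rotation: float
    stimulus: Stimulus  # jittered geometry, relative to its own center


@dataclass(frozen=True)
class DisplaySpec:
    trial_id: str
    placements: tuple[Placement, Placement, Placement, Placement]

    @property
    def target(self) -> Placement:
        for p in self.placements:
            if p.quadrant == self._target_quadrant:
                return p
        raise LookupError("no placement in the target quadrant")

    _target_quadrant: int = 0


def build_trial_table(
    stimulus_set: list[Triplet],
    mode: str = "interleaved",
    rng: np.random.Generator | None = None,
    allow_reduced: bool = False,
) -> list[TrialRecord]:
    """Enumerate the full factorial design and order it.

    ``interleaved`` shuffles all trials; ``blocked`` presents each
    condition in its own block (block order shuffled, trial order shuffled
    within block) as in the replication experiment.  Both modes contain
    the same trials as multisets.
    """
    if mode not in ("interleaved", "blocked"):
        raise ValueError(f"mode must be 'interleaved' or 'blocked', got {mode!r}")
    if len(stimulus_set) != 78 and not allow_reduced:
        raise ValueError(
            f"expected 78 triplets, got {len(stimulus_set)} "
            "(pass allow_reduced=True for a reduced design)"
        )
    rng = rng if rng is not None else np.random.default_rng()
    cells = [
        (t, variant, role, q)
        for t in stimulus_set
        for variant in ("metric", "nonaccidental")
        for role in ("variant_is_target", "base_is_target")
        for q in (1, 2, 3, 4)
    ]
    if mode == "interleaved":
        order = rng.permutation(len(cells))
        ordered = [(cells[i], "interleaved") for i in order]
    else:
        conditions = list(dict.fromkeys(t.condition for t in stimulus_set))
        ordered = []
        for cond in rng.permutation(conditions):
            block = [c for c in cells if c[0].condition == cond]
            for i in rng.permutation(len(block)):
                ordered.append((block[i], cond))
    records = []
    for idx, ((t, variant, role, q), block) in enumerate(ordered):
        records.append(
            TrialRecord(
                trial_id=f"trial-{idx:04d}",
                triplet_id=t.triplet_id,
                variant_changed=variant,
                role=role,
                target_quadrant=q,
                block=block,
                order_index=idx,
            )
        )
    return records


def layout_trial(
    trial: TrialRecord,
    stimulus_set: list[Triplet],
    rng: np.random.Generator,
    eccentricity: float = 5.0,
    jitter_pos: float = 0.25,
    jitter_rot: float = 5.0,
) -> DisplaySpec:
    """Resolve a trial into four jittered placements.

    If the variant is the target, the three distractors are copies of the
    base stimulus; if the base is the target, the distractors are three
    copies of the changed variant.  Each of the four stimuli receives
    independent position and orientation jitter.
    """
    by_id = {t.triplet_id: t for t in stimulus_set}
    try:
        triplet = by_id[trial.triplet_id]
    except KeyError:
        raise ValueError(f"trial references unknown triplet {trial.triplet_id!r}")
    variant_stim = getattr(triplet, trial.variant_changed)
    if trial.role == "variant_is_target":
        target, distractor = variant_stim, triplet.base
    else:
        target, distractor = triplet.base, variant_stim
    placements = []
    for q in (1, 2, 3, 4):
        stim = target if q == trial.target_quadrant else distractor
        jittered, (dx, dy), rot = apply_jitter(
            stim, rng, pos_bound=jitter_pos, rot_bound=jitter_rot,
            return_params=True,
        )
        # positional jitter displaces the whole placement; keep the stored
        # geometry relative to the placement center
        rotated_only = replace(
            jittered,
            segments=tuple(
                replace(seg, center=(seg.center[0] - dx, seg.center[1] - dy))
                for seg in jittered.segments
            ),
        )
        a = math.radians(QUADRANT_ANGLES[q])
        center = (
            eccentricity * math.cos(a) + dx,
            eccentricity * math.sin(a) + dy,
        )
        placements.append(
            Placement(
                stimulus_id=stim.stimulus_id,
                quadrant=q,
                center=center,
                jitter_offset=(float(dx), float(dy)),
                jitter_rotation=rot,
                stimulus=rotated_only,
            )
        )
    return DisplaySpec(
        trial_id=trial.trial_id,
        placements=tuple(placements),
        _target_quadrant=trial.target_quadrant,
    )


def trials_frame(trials: list[TrialRecord], stimulus_set: list[Triplet] | None = None
                 ) -> pd.DataFrame:
    df = pd.DataFrame([t.__dict__ for t in trials])
    if stimulus_set is not None:
        cond = {t.triplet_id: t.condition for t in stimulus_set}
        df["condition"] = df["triplet_id"].map(cond)
    return df
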