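"""Plain-text serialization: stimulus manifests (CSV) and configs (YAML)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .geometry import Segment, Stimulus, StimulusConfig, Triplet

__all__ = [
    "manifest_frame",
    "write_manifest",
    "read_manifest",
    "load_config",
    "save_config",
]

_MAX_SEGMENTS = 2


def manifest_frame(triplets: list[Triplet]) -> pd.DataFrame:
    """Flatten a stimulus set to one row per stimulus.

    Segment fields are flattened as seg{i}_{cx,cy,orientation,length,sagitta};
    single-segment stimuli leave the second slot empty.
    """
    rows = []
    for t in triplets:
        for s in t.stimuli:
            row = {
                "stimulus_id": s.stimulus_id,
                "triplet_id": t.triplet_id,
                "condition": s.condition,
                "variant": s.variant,
                "exemplar": s.exemplar,
                "mirror": s.mirror,
                "pose_deg": s.pose_deg,
                "param_value": s.param_value,
                "n_segments": len(s.segments),
            }
            for i in range(_MAX_SEGMENTS):
                if i < len(s.segments):
                    seg = s.segments[i]
                    row.update(
                        {
                            f"seg{i}_cx": seg.center[0],
                            f"seg{i}_cy": seg.center[1],
                            f"seg{i}_orientation": seg.orientation,
                            f"seg{i}_length": seg.length,
                            f"seg{i}_sagitta": seg.sagitta,
                        }
                    )
                else:
                    row.update({f"seg{i}_{k}": None for k in
                                ("cx", "cy", "orientation", "length", "sagitta")})
            rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(triplets: list[Triplet], path) -> None:
    manifest_frame(triplets).to_csv(path, index=False)


def _stimulus_from_row(row) -> Stimulus:
    segs = []
    for i in range(int(row["n_segments"])):
        segs.append(
            Segment(
                (float(row[f"seg{i}_cx"]), float(row[f"seg{i}_cy"])),
                float(row[f"seg{i}_orientation"]),
                float(row[f"seg{i}_length"]),
                float(row[f"seg{i}_sagitta"]),
            )
        )
    return Stimulus(
        stimulus_id=row["stimulus_id"],
        condition=row["condition"],
        variant=row["variant"],
        exemplar=int(row["exemplar"]),
        segments=tuple(segs),
        param_value=float(row["param_value"]),
        mirror=row["mirror"],
        pose_deg=float(row["pose_deg"]),
    )


def read_manifest(path) -> list[Triplet]:
    df = pd.read_csv(path)
    triplets = []
    for tid, g in df.groupby("triplet_id", sort=False):
        by_variant = {row["variant"]: _stimulus_from_row(row)
                      for _, row in g.iterrows()}
        if set(by_variant) != {"base", "metric", "nonaccidental"}:
            raise ValueError(f"triplet {tid!r} incomplete in manifest")
        triplets.append(
            Triplet(
                triplet_id=tid,
                condition=g["condition"].iloc[0],
                exemplar=int(g["exemplar"].iloc[0]),
                base=by_variant["base"],
                metric=by_variant["metric"],
                nonaccidental=by_variant["nonaccidental"],
            )
        )
    return triplets


def load_config(path) -> StimulusConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return StimulusConfig(**data)


def save_config(config: StimulusConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
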