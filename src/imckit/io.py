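"""Delimited-text input/output for trials, labels and tables.

Trial CSV dialect: one row per sample, columns
``subject_id, side, repetition, angle_deg, velocity_deg_s, torque_nm``;
an optional JSON sidecar records the generating specification.  Labels
are ``trial_id, pattern`` (plus ``injury_class`` in cohort manifests).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .synthetic import CohortTrial, CurveSpec, TorqueCurve

TRIAL_COLUMNS = ["subject_id", "side", "repetition", "angle_deg", "velocity_deg_s", "torque_nm"]


def trial_to_frame(
    repetitions: Sequence[TorqueCurve], subject_id: str = "", side: str = "R"
) -> pd.DataFrame:
    frames = []
    for rep in repetitions:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id or rep.subject_id,
                    "side": side or rep.side,
                    "repetition": rep.repetition_index,
                    "angle_deg": rep.angle,
                    "velocity_deg_s": rep.velocity,
                    "torque_nm": rep.torque,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trial_csv(
    repetitions: Sequence[TorqueCurve],
    path: str | Path,
    subject_id: str = "",
    side: str = "R",
    spec: CurveSpec | None = None,
) -> None:
    path = Path(path)
    trial_to_frame(repetitions, subject_id=subject_id, side=side).to_csv(path, index=False)
    if spec is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")


def read_trial_csv(path: str | Path) -> list[TorqueCurve]:
    """Read a trial CSV back into per-repetition traces (ordered by repetition)."""
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"trial CSV {path} lacks columns {missing}")
    reps = []
    for (subject, side, idx), group in frame.groupby(
        ["subject_id", "side", "repetition"], sort=True, dropna=False
    ):
        reps.append(
            TorqueCurve(
                angle=group["angle_deg"].to_numpy(),
                velocity=group["velocity_deg_s"].to_numpy(),
                torque=group["torque_nm"].to_numpy(),
                repetition_index=int(idx),
                subject_id=str(subject),
                side=str(side),
            )
        )
    reps.sort(key=lambda r: r.repetition_index)
    return reps


def write_cohort(trials: Sequence[CohortTrial], out_dir: str | Path) -> Path:
    """Write one trial CSV per cohort member plus a manifest CSV.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        csv_path = out_dir / f"{trial.trial_id}.csv"
        write_trial_csv(trial.repetitions, csv_path, subject_id=trial.trial_id, spec=trial.spec)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "injury_class": trial.injury_class,
                "injected_pattern": trial.injected_pattern,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_labels_csv(path: str | Path, column: str = "pattern") -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "trial_id" not in frame.columns or column not in frame.columns:
        raise ValidationError(f"labels CSV {path} needs columns trial_id,{column}")
    return frame
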