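"""CSV / JSON / YAML plumbing for cohorts, splits, models and reports.

The interchange format for cohorts is a wide CSV, one row per trial::

    trial_id,study,participant_id,condition_id,met_cost,
    grf_ver_001..grf_ver_100,grf_ap_001..grf_ap_100,
    hip_m_001..hip_m_100,knee_m_001..knee_m_100,ankle_m_001..ankle_m_100

UTF-8, '.' decimal separator, header mandatory.  Raw motion-capture
containers (C3D/MOT) are deliberately out of scope: the pipeline
consumes already stride-averaged, mass-normalized waveforms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .narx import NarxModel
from .pdp import PhaseSensitivity
from .preprocess import DatasetSplit
from .selection import SearchRecord
from .synthetic import CHANNELS, CohortDesign, GaitTrial

META_COLUMNS = ("trial_id", "study", "participant_id", "condition_id", "met_cost")


def _waveform_columns() -> list[str]:
    return [f"{ch}_{i:03d}" for ch in CHANNELS for i in range(1, 101)]


def write_cohort_csv(trials: Sequence[GaitTrial], path: str | Path) -> None:
    """Write a cohort to the wide one-row-per-trial CSV format."""
    rows = []
    for t in trials:
        row: dict = {
            "trial_id": t.trial_id,
            "study": t.study,
            "participant_id": t.participant_id,
            "condition_id": t.condition_id,
            "met_cost": repr(t.met_cost),
        }
        for ch in CHANNELS:
            wave = t.waveform(ch)
            for i in range(100):
                row[f"{ch}_{i + 1:03d}"] = repr(float(wave[i]))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + _waveform_columns())
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path: str | Path) -> list[GaitTrial]:
    """Read a wide cohort CSV, validating the full column schema."""
    df = pd.read_csv(path, encoding="utf-8")
    expected = list(META_COLUMNS) + _waveform_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV is missing column {missing[0]!r}")
    trials = []
    for _, row in df.iterrows():
        waves = {
            ch: np.array([float(row[f"{ch}_{i:03d}"]) for i in range(1, 101)])
            for ch in CHANNELS
        }
        trials.append(
            GaitTrial(
                trial_id=str(row["trial_id"]),
                study=str(row["study"]),
                participant_id=str(row["participant_id"]),
                condition_id=str(row["condition_id"]),
                met_cost=float(row["met_cost"]),
                **waves,
            )
        )
    return trials


def write_split_csv(split: DatasetSplit, path: str | Path) -> None:
    part = split.partition_of()
    df = pd.DataFrame(
        {"trial_id": list(part.keys()), "partition": list(part.values())}
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_split_csv(path: str | Path) -> DatasetSplit:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("trial_id", "partition"):
        if col not in df.columns:
            raise FormatError(f"split CSV is missing column {col!r}")
    groups: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    for _, row in df.iterrows():
        part = str(row["partition"])
        if part not in groups:
            raise FormatError(f"unknown partition label {part!r}")
        groups[part].append(str(row["trial_id"]))
    return DatasetSplit(
        train_ids=groups["train"],
        validation_ids=groups["validation"],
        test_ids=groups["test"],
    )


def write_design_yaml(design: CohortDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def read_design_yaml(path: str | Path) -> CohortDesign:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError("design YAML must contain a mapping")
    try:
        return CohortDesign.from_dict(d)
    except TypeError as exc:
        raise FormatError(f"bad design field: {exc}") from exc


def write_model_json(model: NarxModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model_json(path: str | Path) -> NarxModel:
    with open(path, encoding="utf-8") as fh:
        return NarxModel.from_dict(json.load(fh))


def write_records_csv(records: Sequence[SearchRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "hidden_size": r.hidden_size,
                "delays": r.delays,
                "repetition_seed": r.repetition_seed,
                "mse_train": r.mse_train,
                "mse_val": r.mse_val,
                "mse_test": r.mse_test,
                "r_train": r.r_train,
                "r_val": r.r_val,
                "r_test": r.r_test,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False, encoding="utf-8")


def write_sensitivity_csv(
    sensitivities: Sequence[PhaseSensitivity], path: str | Path
) -> None:
    """Plot-ready long CSV: channel,pct,rmse_mean,rmse_sd (100 rows/channel)."""
    rows = []
    for s in sensitivities:
        for i in range(100):
            rows.append(
                {
                    "channel": s.channel,
                    "pct": i + 1,
                    "rmse_mean": s.rmse_mean[i],
                    "rmse_sd": s.rmse_sd[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
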