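"""CSV/JSON readers and writers for the pipeline's on-disk formats.

Recordings: one CSV per bout with columns time_s, mcav_affected,
mcav_nonaffected, map_mmhg, petco2_mmhg, beat_onset (0/1 at the sample
nearest each onset).  Subjects and per-subject results are flat CSV tables;
ground truth and QC reports are JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import AcquisitionRecording, GroundTruth, SubjectProfile

__all__ = [
    "write_recording_csv", "read_recording_csv",
    "write_subjects_csv", "read_subjects_csv",
    "write_ground_truth_json", "read_ground_truth_json",
    "write_results_csv", "read_results_csv",
    "write_json",
]


def write_recording_csv(rec: AcquisitionRecording, path) -> None:
    t = rec.time
    onset_flag = np.zeros(len(t), dtype=int)
    idx = np.clip(np.round(rec.beat_onsets * rec.sample_rate).astype(int),
                  0, len(t) - 1)
    onset_flag[idx] = 1
    pd.DataFrame({
        "time_s": t,
        "mcav_affected": rec.mcav["stroke_affected"],
        "mcav_nonaffected": rec.mcav["non_affected"],
        "map_mmhg": rec.map_mmhg,
        "petco2_mmhg": rec.petco2_mmhg,
        "beat_onset": onset_flag,
    }).to_csv(path, index=False, float_format="%.4f")


def read_recording_csv(path, subject_id: str = "", bout_index: int = 0,
                       visit: str = "3mo") -> AcquisitionRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.median(np.diff(t))
    return AcquisitionRecording(
        subject_id=subject_id,
        sample_rate=1.0 / dt,
        duration=float(t[-1] + dt),
        mcav={"stroke_affected": df["mcav_affected"].to_numpy(),
              "non_affected": df["mcav_nonaffected"].to_numpy()},
        map_mmhg=df["map_mmhg"].to_numpy(),
        petco2_mmhg=df["petco2_mmhg"].to_numpy(),
        beat_onsets=t[df["beat_onset"].to_numpy() == 1],
        bout_index=bout_index,
        visit=visit,
    )


def write_subjects_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        row = {k: v for k, v in asdict(p).items() if k != "covariates"}
        row.update(p.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth_json(truths, path) -> None:
    payload = {t.subject_id: {"rest": t.rest, "cvr": t.cvr,
                              "artifact_log": t.artifact_log}
               for t in truths}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth_json(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {sid: GroundTruth(subject_id=sid, rest=d["rest"], cvr=d["cvr"],
                             artifact_log=[tuple(e) for e in d["artifact_log"]])
            for sid, d in raw.items()}


def write_results_csv(results, path) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
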