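"""End-to-end orchestration: simulate -> preprocess -> metrics -> stats.

A single config object surfaces every analysis constant (censoring
thresholds, discard fraction, analysis windows, HbA1c split, alpha) so
sensitivity analyses over the under-specified choices are one-line edits.
The run is deterministic given (config, seed): every random draw comes from
a substream keyed on the root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError
from .io import (write_ground_truth_json, write_json, write_recording_csv,
                 write_results_csv, write_subjects_csv)
from .metrics import cvr_from_series
from .preprocess import (apply_discard_rule, average_bouts, censor_cycles,
                         extract_cycles, resample_to_2hz, smooth_3s_9s)
from .simulate import (HEMISPHERES, SynthParams, inject_artifacts,
                       simulate_cohort, simulate_recording)
from .stats import summarize_table1

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    synth: SynthParams = field(default_factory=SynthParams)
    rate_max_hz: float = 5.0
    jump_max: float = 10.0
    discard_threshold: float = 0.15
    hba1c_split: float = 7.0
    alpha: float = 0.05
    rest_window: tuple = (0.0, 90.0)
    steady_state_window: tuple = (180.0, 270.0)
    visit: str = "3mo"
    write_recordings: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = SynthParams(**d.pop("synth", {}))
        for key in ("rest_window", "steady_state_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(synth=synth, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rest_window"] = list(self.rest_window)
        d["steady_state_window"] = list(self.steady_state_window)
        d["synth"]["steady_state_window"] = list(self.synth.steady_state_window)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    seed: int
    version: str
    subjects_in: int
    subjects_out: int
    subjects_excluded: int
    bouts_total: int
    bouts_discarded: int
    group_sizes: dict             # {"low": n, "high": n}
    key_tests: dict               # outcome -> {u, z, p_exact, p_asymptotic}
    table1: list                  # records of the group-summary table


def validate_config(config: PipelineConfig) -> list:
    """Return a list of 'field: rule' violation strings (empty when valid)."""
    v = []
    if config.rate_max_hz <= 0:
        v.append("rate_max_hz: must be positive")
    if config.jump_max <= 0:
        v.append("jump_max: must be positive")
    if not (0 <= config.discard_threshold <= 1):
        v.append("discard_threshold: must lie in [0, 1]")
    if config.hba1c_split <= 0:
        v.append("hba1c_split: must be positive")
    if not (0 < config.alpha < 1):
        v.append("alpha: must lie in (0, 1)")
    r0, r1 = config.rest_window
    s0, s1 = config.steady_state_window
    if not (r0 < r1 and s0 < s1):
        v.append("windows: bounds must increase")
    elif r1 > s0:
        v.append("windows: rest window overlaps steady-state window")
    if s1 > config.synth.duration:
        v.append("steady_state_window: exceeds recording duration")
    v.extend(f"synth.{msg}" for msg in config.synth.violations())
    return v


def _preprocess_bout(rec, hemi, config):
    cycles = extract_cycles(rec, hemi)
    mask = censor_cycles(cycles, config.rate_max_hz, config.jump_max)
    if apply_discard_rule(mask, config.discard_threshold):
        return None, mask
    series = resample_to_2hz(cycles, mask, rec.duration)
    return smooth_3s_9s(series), mask


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Run all stages on a simulated cohort; optionally write artifacts.

    Subjects whose every bout is discarded on either hemisphere are excluded
    (the bilateral outcome cannot be modeled), mirroring how unusable
    acquisitions drop out of small TCD studies.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    p = config.synth
    cohort = simulate_cohort(p)

    results = []
    qc = []
    excluded = []
    bouts_total = 0
    bouts_discarded = 0
    recordings_to_write = []

    for profile, truth in cohort:
        per_hemi = {h: [] for h in HEMISPHERES}
        for bout in range(p.n_bouts):
            try:
                rec = simulate_recording(profile, truth, p, bout)
                rec, art_log = inject_artifacts(rec, p)
            except Exception as e:  # pragma: no cover - stage tagging
                raise PipelineError(f"simulate: {profile.subject_id} bout {bout}: {e}") from e
            truth.artifact_log.extend((bout, t, kind) for t, kind in art_log)
            if config.write_recordings:
                recordings_to_write.append(rec)
            bouts_total += 1
            discarded_any = False
            for hemi in HEMISPHERES:
                try:
                    block, mask = _preprocess_bout(rec, hemi, config)
                except Exception as e:
                    raise PipelineError(f"preprocess: {profile.subject_id} bout {bout}: {e}") from e
                qc.append({
                    "subject_id": profile.subject_id, "bout": bout,
                    "hemisphere": hemi,
                    "censored_fraction": mask.censored_fraction,
                    "discarded": block is None,
                    "reasons": {r: mask.reasons.count(r)
                                for r in ("rr_implausible", "velocity_jump")},
                })
                if block is None:
                    discarded_any = True
                else:
                    per_hemi[hemi].append(block)
            if discarded_any:
                bouts_discarded += 1
        if any(len(per_hemi[h]) == 0 for h in HEMISPHERES):
            excluded.append(profile.subject_id)
            log.warning("subject %s unmodelable (all bouts discarded on one side)",
                        profile.subject_id)
            continue
        for hemi in HEMISPHERES:
            avg = average_bouts(per_hemi[hemi])
            try:
                results.append(cvr_from_series(
                    avg, profile.subject_id, hemi, config.visit,
                    config.rest_window, config.steady_state_window))
            except Exception as e:
                raise PipelineError(f"metrics: {profile.subject_id}/{hemi}: {e}") from e

    profiles = [pr for pr, _ in cohort if pr.subject_id not in excluded]
    subj_rows = []
    for pr in profiles:
        row = {"subject_id": pr.subject_id, "age": pr.age, "sex": pr.sex,
               "hba1c": pr.hba1c, "beta_blocker": pr.beta_blocker,
               "resting_hr": pr.resting_hr, "t2dm": pr.t2dm,
               "stroke_side": pr.stroke_side}
        row.update(pr.covariates)
        subj_rows.append(row)
    subjects_df = pd.DataFrame(subj_rows)
    results_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    key_tests = {}
    if len(results_df):
        try:
            table = summarize_table1(subjects_df, results_df,
                                     alpha=config.alpha, threshold=config.hba1c_split)
        except Exception as e:
            raise PipelineError(f"stats: {e}") from e
        for _, row in table.iterrows():
            if row.get("kind") == "continuous" and "CVR" in str(row["variable"]):
                key_tests[row["variable"]] = {
                    "u": row.get("u"), "z": row.get("z"), "p": row["p_value"]}
    else:
        log.warning("no modelable subjects; group statistics skipped")
        table = pd.DataFrame()

    if len(subjects_df):
        group_sizes = {
            "low": int((subjects_df["hba1c"] <= config.hba1c_split).sum()),
            "high": int((subjects_df["hba1c"] > config.hba1c_split).sum()),
        }
    else:
        group_sizes = {"low": 0, "high": 0}
    report = RunReport(
        config=config.to_dict(),
        config_hash=config.content_hash(),
        seed=p.seed,
        version=__version__,
        subjects_in=len(cohort),
        subjects_out=len(profiles),
        subjects_excluded=len(excluded),
        bouts_total=bouts_total,
        bouts_discarded=bouts_discarded,
        group_sizes=group_sizes,
        key_tests=key_tests,
        table1=json.loads(table.to_json(orient="records")),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_subjects_csv([pr for pr, _ in cohort], out / "subjects.csv")
        write_ground_truth_json([tr for _, tr in cohort], out / "ground_truth.json")
        write_results_csv(results, out / "results.csv")
        table.to_csv(out / "table1.csv", index=False)
        write_json(qc, out / "qc.json")
        write_json(dataclasses.asdict(report), out / "report.json")
        if config.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec in recordings_to_write:
                write_recording_csv(
                    rec, rec_dir / f"{rec.subject_id}_bout{rec.bout_index}.csv")
    return report
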