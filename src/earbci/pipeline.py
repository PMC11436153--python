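"""Configuration-driven end-to-end runs: simulate -> preprocess -> epoch ->
features -> classify -> report.

A run covers the grid scenario x electrode set x feature subset x
classifier for one or more synthetic subjects.  Scenarios:

* ``hand_rehab``   — hand movement, EMG-onset aligned, window (-2, 0) s
  (no post-onset information, for neurorehabilitation timing);
* ``hand_control`` — hand movement, EMG-onset aligned, window (-2, 1) s;
* ``tongue_control`` — tongue movement, cue aligned (no usable EMG),
  window (-2, 1) s.

Idle epochs are drawn once per scenario and shared across electrode sets
and classifiers; folds are planned once per scenario/electrode cell and
shared across feature subsets and classifiers, so each comparison varies
only the factor under study.  All stage seeds derive from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._seeding import derive_seed
from .classify import (
    ClassifierSpec,
    chance_level,
    combine_epochs,
    balance_idle,
    plan_folds,
    run_scenario,
)
from .epochs import (
    CONTROL_WINDOW,
    REHAB_WINDOW,
    EpochWindow,
    RejectionSpec,
    detect_onsets,
    extract_epochs,
    sample_idle_starts,
)
from .io import EEG_CHANNELS, ContinuousRecording
from .preprocess import preprocess_recording
from .simulate import (
    SignalModel,
    TrialSchedule,
    build_schedule,
    default_models,
    high_snr_model,
    synthesize_idle,
    synthesize_recording,
    zero_signal_model,
)

logger = logging.getLogger(__name__)

SCENARIOS: dict[str, tuple[str, EpochWindow, str]] = {
    "hand_rehab": ("hand", REHAB_WINDOW, "emg_onset"),
    "hand_control": ("hand", CONTROL_WINDOW, "emg_onset"),
    "tongue_control": ("tongue", CONTROL_WINDOW, "cue"),
}

ELECTRODE_SETS: dict[str, tuple[str, ...]] = {
    "ear": ("Front", "Over", "Back"),
    "cz": ("Cz",),
}

MODEL_PRESETS = {
    "default": default_models,
    "high_snr": lambda: high_snr_model(),
    "zero_signal": lambda: zero_signal_model(),
}


def default_config() -> dict[str, Any]:
    """Full default configuration (every knob the CLI exposes)."""
    return {
        "master_seed": 0,
        "n_subjects": 1,
        "schedule": {
            "blocks_per_condition": 4,
            "trials_per_block": 25,
            "idle_block_duration": 180.0,
            "n_idle_blocks": 3,
            "fs": 250.0,
        },
        "model": {"preset": "default", "overrides": {}},
        "scenarios": list(SCENARIOS),
        "electrode_sets": list(ELECTRODE_SETS),
        "feature_subsets": ["all", "temporal", "spectral"],
        "classifiers": ["rf", "svm", "knn", "lda"],
        "rejection": {"limit_uv": 100.0},
        "onsets": {"search": [-1.0, 1.0], "smooth_s": 0.1, "threshold": None},
        "welch": {"segment_s": 1.0, "overlap": 0.5},
        "bootstrap": {"n_resamples": 10000},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:12]


def models_from_config(model_cfg: dict) -> dict[str, SignalModel]:
    """Resolve a model preset and apply flat overrides to every condition.

    Recognized overrides: mrcp_peak_amplitude (uV), erd_depth, ers_gain,
    artifact_rate, artifact_amplitude, pink_sd, white_sd.
    """
    preset = MODEL_PRESETS[model_cfg.get("preset", "default")]()
    if isinstance(preset, SignalModel):
        preset = {"hand": preset, "tongue": preset}
    ov = model_cfg.get("overrides") or {}
    out = {}
    for cond, m in preset.items():
        if "mrcp_peak_amplitude" in ov:
            m = dataclasses.replace(
                m, mrcp=dataclasses.replace(m.mrcp, peak_amplitude=ov["mrcp_peak_amplitude"])
            )
        osc_kw = {k: ov[k] for k in ("erd_depth", "ers_gain") if k in ov}
        if osc_kw:
            m = dataclasses.replace(m, oscillation=dataclasses.replace(m.oscillation, **osc_kw))
        art_kw = {}
        if "artifact_rate" in ov:
            art_kw["rate"] = ov["artifact_rate"]
        if "artifact_amplitude" in ov:
            art_kw["amplitude"] = ov["artifact_amplitude"]
        if art_kw:
            m = dataclasses.replace(m, artifacts=dataclasses.replace(m.artifacts, **art_kw))
        noise_kw = {k: ov[k] for k in ("pink_sd", "white_sd") if k in ov}
        if noise_kw:
            m = dataclasses.replace(m, noise=dataclasses.replace(m.noise, **noise_kw))
        out[cond] = m
    return out


@dataclass
class RunReport:
    """All per-cell records plus across-subject summaries and provenance."""

    records: pd.DataFrame
    summary: pd.DataFrame
    config: dict
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.tsv", sep="\t", index=False)
        report = self.summary.copy()
        report["median_accuracy_pct"] = (report["median_accuracy"] * 100).round(2)
        cols = [
            "scenario",
            "classifier",
            "feature_subset",
            "electrode_set",
            "median_accuracy_pct",
            "ci_low_pct",
            "ci_high_pct",
            "n_subjects",
        ]
        report["ci_low_pct"] = (report["ci_low"] * 100).round(2)
        report["ci_high_pct"] = (report["ci_high"] * 100).round(2)
        report[cols].to_csv(outdir / "report.tsv", sep="\t", index=False)
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"config_hash: {config_hash(self.config)}\n")
            fh.write(yaml.safe_dump({"config": self.config}))
            fh.write(yaml.safe_dump({"diagnostics": _plain(self.diagnostics)}))


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Single-subject pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Synthesized and preprocessed signals for one synthetic subject."""

    schedule: TrialSchedule
    recording: ContinuousRecording
    idle_recording: ContinuousRecording
    ground_truth: Any
    eeg: ContinuousRecording  # filtered
    idle_eeg: ContinuousRecording
    envelope: np.ndarray


def simulate_subject(config: dict, subject_seed: int) -> SubjectData:
    schedule = build_schedule(**config["schedule"])
    models = models_from_config(config["model"])
    rec, gt = synthesize_recording(
        schedule, models, seed=derive_seed(subject_seed, "session")
    )
    idle = synthesize_idle(
        models,
        schedule.total_idle_duration,
        seed=derive_seed(subject_seed, "idle"),
        fs=schedule.fs,
    )
    pre = preprocess_recording(rec)
    pre_idle = preprocess_recording(idle)
    return SubjectData(
        schedule, rec, idle, gt, pre.eeg, pre_idle.eeg, pre.envelope
    )


def run_subject(
    config: dict, subject_seed: int, data: SubjectData | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run the requested grid for one subject; returns (records, diagnostics)."""
    if data is None:
        data = simulate_subject(config, subject_seed)
    schedule = data.schedule
    fs = schedule.fs
    onset_cfg = config["onsets"]
    diag: dict[str, Any] = {"subject_seed": subject_seed}

    hand_onsets = None
    if any(SCENARIOS[s][0] == "hand" for s in config["scenarios"]):
        res = detect_onsets(
            data.envelope,
            schedule.cue_times("hand"),
            fs,
            threshold=onset_cfg.get("threshold"),
            search=tuple(onset_cfg["search"]),
            blocks=schedule.block_ids("hand"),
            smooth_s=onset_cfg["smooth_s"],
        )
        hand_onsets = res.onsets
        diag["onset_fallbacks"] = int(res.fallback.sum())
        diag["onset_thresholds"] = res.thresholds

    rows = []
    for scen in config["scenarios"]:
        condition, window, alignment = SCENARIOS[scen]
        t0s = hand_onsets if alignment == "emg_onset" else schedule.cue_times(condition)
        movement_all = extract_epochs(
            data.eeg, t0s, window, EEG_CHANNELS, "movement", alignment
        )
        idle_starts = sample_idle_starts(
            data.idle_eeg.duration,
            n=movement_all.n_epochs,
            epoch_len=window.length,
            seed=derive_seed(subject_seed, f"idle-starts-{scen}"),
        )
        idle_all = extract_epochs(
            data.idle_eeg,
            idle_starts - window.start,
            window,
            EEG_CHANNELS,
            "idle",
            "idle_random",
        )
        diag[f"{scen}_idle_hash"] = hashlib.sha256(
            idle_all.data.tobytes()
        ).hexdigest()[:12]

        for eset in config["electrode_sets"]:
            channels = ELECTRODE_SETS[eset]
            rej = RejectionSpec(config["rejection"]["limit_uv"], channels)
            mov, mov_log = _reject(movement_all.select_channels(channels), rej)
            idl, idl_log = _reject(idle_all.select_channels(channels), rej)
            diag[f"{scen}_{eset}_rejected"] = {
                "movement": len(mov_log),
                "idle": len(idl_log),
            }
            mov, idl = balance_idle(
                mov, idl, seed=derive_seed(subject_seed, f"balance-{scen}-{eset}")
            )
            combined, labels = combine_epochs(mov, idl)
            plan = plan_folds(
                labels, k=5, seed=derive_seed(subject_seed, f"folds-{scen}-{eset}")
            )
            for subset in config["feature_subsets"]:
                for kind in config["classifiers"]:
                    spec = ClassifierSpec(
                        kind=kind,
                        seed=derive_seed(subject_seed, f"clf-{scen}-{eset}-{kind}"),
                    )
                    rec = run_scenario(
                        mov,
                        idl,
                        subset,
                        spec,
                        plan=plan,
                        scenario=scen,
                        electrode_set=eset,
                        welch_segment_s=config["welch"]["segment_s"],
                        welch_overlap=config["welch"]["overlap"],
                    )
                    rows.append(
                        {
                            "scenario": scen,
                            "electrode_set": eset,
                            "feature_subset": subset,
                            "classifier": kind,
                            "median_accuracy": rec.median_accuracy,
                            "fold_accuracies": ",".join(
                                f"{a:.4f}" for a in rec.fold_accuracies
                            ),
                            "n_test_median": int(np.median(rec.n_test_per_fold)),
                            "n_epochs": combined.n_epochs,
                        }
                    )
    return pd.DataFrame(rows), diag


def _reject(epochs, spec):
    from .epochs import reject_artifacts

    return reject_artifacts(epochs, spec)


# ---------------------------------------------------------------------------
# Multi-subject experiment
# ---------------------------------------------------------------------------


def run_experiment(config: dict | None = None) -> RunReport:
    """Execute the full grid for ``n_subjects`` synthetic subjects."""
    config = config or default_config()
    master = int(config["master_seed"])
    all_rows, diagnostics = [], {}
    for i in range(int(config["n_subjects"])):
        subject_seed = derive_seed(master, f"subject-{i}")
        records, diag = run_subject(config, subject_seed)
        records.insert(0, "subject", i)
        all_rows.append(records)
        diagnostics[f"subject_{i}"] = diag
    records = pd.concat(all_rows, ignore_index=True)
    summary = summarize_across_subjects(
        records,
        n_resamples=int(config["bootstrap"]["n_resamples"]),
        seed=derive_seed(master, "bootstrap"),
    )
    n_test = int(records["n_test_median"].median())
    diagnostics["chance_level"] = chance_level(n_test).threshold
    diagnostics["chance_n_test"] = n_test
    return RunReport(records, summary, config, diagnostics)


def summarize_across_subjects(
    records: pd.DataFrame, n_resamples: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Across-subject median and 2.5-97.5 bootstrap percentile range per cell.

    With a single subject the interval collapses to the point.
    """
    rng = np.random.default_rng(seed)
    rows = []
    keys = ["scenario", "electrode_set", "feature_subset", "classifier"]
    for cell, grp in records.groupby(keys, sort=False):
        acc = grp["median_accuracy"].to_numpy()
        med = float(np.median(acc))
        if acc.size > 1:
            boot = np.median(
                rng.choice(acc, size=(n_resamples, acc.size), replace=True), axis=1
            )
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo = hi = med
        rows.append(
            dict(
                zip(keys, cell),
                median_accuracy=med,
                ci_low=float(lo),
                ci_high=float(hi),
                n_subjects=int(acc.size),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Running from recorded files (TSV or EDF + events)
# ---------------------------------------------------------------------------


def run_from_files(
    session_path: str | Path,
    idle_path: str | Path,
    events_path: str | Path,
    config: dict | None = None,
) -> RunReport:
    """Full analysis of a recorded session (no simulation).

    ``session_path``/``idle_path`` may be recording TSVs or EDF files;
    ``events_path`` is the cue table (onset_s, type, block).
    """
    from .io import read_events

    config = config or default_config()
    master = int(config["master_seed"])

    def _load(p):
        p = Path(p)
        if p.suffix.lower() == ".edf":
            return ContinuousRecording.from_edf(p)
        return ContinuousRecording.from_tsv(p)

    rec = _load(session_path)
    idle = _load(idle_path)
    events = read_events(events_path)
    pre = preprocess_recording(rec)
    pre_idle = preprocess_recording(idle)

    # Reconstruct the minimal schedule facts the pipeline needs from events.
    rows = []
    for scen in config["scenarios"]:
        condition, window, alignment = SCENARIOS[scen]
        ev = events[events["type"] == f"cue_{condition}"]
        cues = ev["onset_s"].to_numpy()
        blocks = ev["block"].to_numpy()
        if alignment == "emg_onset":
            res = detect_onsets(
                pre.envelope,
                cues,
                rec.fs,
                threshold=config["onsets"].get("threshold"),
                search=tuple(config["onsets"]["search"]),
                blocks=blocks,
                smooth_s=config["onsets"]["smooth_s"],
            )
            t0s = res.onsets
        else:
            t0s = cues
        movement_all = extract_epochs(
            pre.eeg, t0s, window, EEG_CHANNELS, "movement", alignment
        )
        idle_starts = sample_idle_starts(
            pre_idle.eeg.duration,
            n=movement_all.n_epochs,
            epoch_len=window.length,
            seed=derive_seed(master, f"idle-starts-{scen}"),
        )
        idle_all = extract_epochs(
            pre_idle.eeg, idle_starts - window.start, window, EEG_CHANNELS,
            "idle", "idle_random",
        )
        for eset in config["electrode_sets"]:
            channels = ELECTRODE_SETS[eset]
            rej = RejectionSpec(config["rejection"]["limit_uv"], channels)
            mov, _ = _reject(movement_all.select_channels(channels), rej)
            idl, _ = _reject(idle_all.select_channels(channels), rej)
            mov, idl = balance_idle(
                mov, idl, seed=derive_seed(master, f"balance-{scen}-{eset}")
            )
            combined, labels = combine_epochs(mov, idl)
            plan = plan_folds(
                labels, k=5, seed=derive_seed(master, f"folds-{scen}-{eset}")
            )
            for subset in config["feature_subsets"]:
                for kind in config["classifiers"]:
                    spec = ClassifierSpec(
                        kind=kind, seed=derive_seed(master, f"clf-{scen}-{eset}-{kind}")
                    )
                    r = run_scenario(
                        mov, idl, subset, spec, plan=plan,
                        scenario=scen, electrode_set=eset,
                        welch_segment_s=config["welch"]["segment_s"],
                        welch_overlap=config["welch"]["overlap"],
                    )
                    rows.append(
                        {
                            "subject": 0,
                            "scenario": scen,
                            "electrode_set": eset,
                            "feature_subset": subset,
                            "classifier": kind,
                            "median_accuracy": r.median_accuracy,
                            "fold_accuracies": ",".join(
                                f"{a:.4f}" for a in r.fold_accuracies
                            ),
                            "n_test_median": int(np.median(r.n_test_per_fold)),
                            "n_epochs": combined.n_epochs,
                        }
                    )
    records = pd.DataFrame(rows)
    summary = summarize_across_subjects(records)
    return RunReport(records, summary, config)
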