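"""The three-step classification protocol.

Step 1 sweeps the preictal length L (1, 5, 10, 30, 60, 120 min) with all
electrodes at 256 Hz and selects the best L by patient-averaged accuracy.
Step 2 sweeps the electrode count (top-4/8/16/all by clinical ranking) at the
selected L and 256 Hz.  Step 3 sweeps the sampling rate (128/256/512 Hz) at
the selected L with all electrodes.  Every condition re-runs the full
pipeline: re-group lead seizures with the L-dependent merge gap, label the
timeline, epoch (interictal non-overlapping; preictal overlap chosen to
equalize counts), featurize, under-sample to 1:1, split 6:2:2 stratified,
standardize with training statistics, train a fresh CNN, evaluate.

Steps 2 and 3 refuse to run without a persisted step-1 selection.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd

from .annotations import SeizureEvent, label_periods
from .cnn import TrainingConfig, build_architecture, count_parameters, evaluate, train_model
from .datasets import (
    LabeledDataset, RankedMontage, Standardizer, select_top_channels,
    split_dataset, undersample_balance,
)
from .signal_prep import (
    EPOCH_LEN_S, PrepConfig, Recording, featurize_epochs, freq_mask,
    preictal_step, preprocess, segment_epochs,
)

__all__ = [
    "Patient", "ExperimentGrid", "ExperimentState",
    "build_condition_dataset", "train_eval_condition", "run_condition",
    "run_step1", "run_step2", "run_step3", "average_rows",
]

log = logging.getLogger("preictal")

METRIC_COLS = ["accuracy", "f1", "precision", "recall"]


@dataclass
class Patient:
    """One subject's inputs: native-rate recording, seizure annotations, and
    the clinically ranked channel list."""

    patient_id: str
    recording: Recording
    events: list[SeizureEvent]
    montage: RankedMontage


#: Patients may be supplied lazily (a zero-argument callable) so that only one
#: native-rate recording is in memory at a time.
PatientSource = Union[Patient, Callable[[], Patient]]


def _resolve(source: PatientSource) -> Patient:
    return source() if callable(source) else source


@dataclass(frozen=True)
class ExperimentGrid:
    preictal_lengths_min: tuple = (1, 5, 10, 30, 60, 120)
    channel_counts: tuple = (4, 8, 16, "all")
    sampling_frequencies_hz: tuple = (128, 256, 512)
    default_fs: int = 256


@dataclass
class ExperimentState:
    """Persisted protocol state: step 1's selection feeds steps 2 and 3."""

    best_L: float | None = None
    step1_rows: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"best_L": self.best_L, "step1_rows": self.step1_rows},
                                         indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentState":
        d = json.loads(Path(path).read_text())
        return cls(best_L=d["best_L"], step1_rows=d["step1_rows"])

    def require_best_L(self) -> float:
        if self.best_L is None:
            raise RuntimeError("step 1 has not been run: no persisted preictal-length selection")
        return self.best_L


def _derive_seeds(seed: int, n: int = 3) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def build_condition_dataset(
    recording: Recording,
    events: list[SeizureEvent],
    L_min: float,
    fs_out: int,
    *,
    max_epochs_per_class: int | None = None,
) -> LabeledDataset:
    """Featurize one (recording, L, fs) condition into a labeled dataset.

    Interictal epochs are non-overlapping (30 s step); preictal epochs
    overlap just enough that their count approaches the interictal count from
    above.  ``max_epochs_per_class`` caps the interictal count (evenly spaced
    subset) to bound compute on long recordings.
    """
    prep = preprocess(recording, PrepConfig(fs_out))
    labeling = label_periods(events, L_min, prep.duration_s)
    inter = segment_epochs(prep, labeling, "interictal", EPOCH_LEN_S)
    n_inter = inter.data.shape[0]
    if max_epochs_per_class is not None and n_inter > max_epochs_per_class:
        idx = np.linspace(0, n_inter - 1, max_epochs_per_class).round().astype(int)
        inter = type(inter)(inter.data[idx], inter.start_s[idx])
        n_inter = max_epochs_per_class
    n_leads = len(labeling.lead_onsets) - len(labeling.flagged_leads)
    if n_leads == 0:
        raise ValueError("no valid (non-truncated) lead seizures at this preictal length")
    if n_inter == 0:
        raise ValueError("no interictal epochs: recording too close to lead onsets")
    step = preictal_step(L_min, target_epochs=n_inter, n_leads=n_leads)
    if not step.achieved_target:
        log.warning("preictal step floor reached: %d preictal vs %d interictal epochs",
                    step.total_epochs, n_inter)
    pre = segment_epochs(prep, labeling, "preictal", step.step_s)
    Xi = featurize_epochs(inter, fs_out)
    Xp = featurize_epochs(pre, fs_out)
    X = np.concatenate([Xi, Xp])
    y = np.concatenate([np.zeros(len(Xi), dtype=np.int8), np.ones(len(Xp), dtype=np.int8)])
    start_s = np.concatenate([inter.start_s, pre.start_s])
    return LabeledDataset(X, y, start_s, list(prep.channel_names), freq_mask(fs_out),
                          seed_log={"preictal_step_s": step.step_s})


def train_eval_condition(
    dataset: LabeledDataset,
    montage: RankedMontage,
    k: int | str,
    fs_out: int,
    seed: int,
    train_cfg: TrainingConfig | None = None,
    split_mode: str = "epoch",
) -> dict:
    """Balance, split, standardize, train a fresh CNN, evaluate on the test split."""
    t0 = time.time()
    bal_seed, split_seed, train_seed = _derive_seeds(seed)
    ds = select_top_channels(dataset, montage, k)
    ds = undersample_balance(ds, bal_seed)
    split = split_dataset(ds, seed=split_seed, mode=split_mode)
    scaler = Standardizer().fit(ds.X[split.train])
    Xtr = scaler.transform(ds.X[split.train])
    Xval = scaler.transform(ds.X[split.val])
    Xte = scaler.transform(ds.X[split.test])
    cfg = train_cfg or TrainingConfig()
    cfg = TrainingConfig(**{**cfg.__dict__, "seed": train_seed})
    spec = build_architecture(len(ds.channel_names), fs_out)
    model, history = train_model(spec, (Xtr, ds.y[split.train]), (Xval, ds.y[split.val]), cfg)
    metrics = evaluate(model, (Xte, ds.y[split.test]), threshold=cfg.threshold)
    row = {
        "k": k,
        "fs": fs_out,
        "n_channels": len(ds.channel_names),
        "param_count": count_parameters(spec),
        "n_train": int(split.train.size),
        "n_val": int(split.val.size),
        "n_test": int(split.test.size),
        "seed": seed,
        "split_mode": split_mode,
        "balance_seed": bal_seed,
        "split_seed": split_seed,
        "train_seed": train_seed,
        "epochs_run": len(history["train_loss"]),
        "best_val_loss": history["best_val_loss"],
        "train_time_s": time.time() - t0,
    }
    row.update({m: getattr(metrics, m) for m in METRIC_COLS})
    return row


def run_condition(
    patient: Patient,
    L_min: float,
    k: int | str,
    fs_out: int,
    seed: int,
    train_cfg: TrainingConfig | None = None,
    max_epochs_per_class: int | None = None,
    split_mode: str = "epoch",
) -> dict:
    """Full pipeline for one (patient, L, k, fs) cell."""
    ds = build_condition_dataset(patient.recording, patient.events, L_min, fs_out,
                                 max_epochs_per_class=max_epochs_per_class)
    row = train_eval_condition(ds, patient.montage, k, fs_out, seed, train_cfg,
                               split_mode=split_mode)
    row.update({"patient": patient.patient_id, "L": L_min})
    return row


def average_rows(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Patient-averaged metrics per condition (arithmetic mean over patients)."""
    return df.groupby(by, as_index=False)[METRIC_COLS].mean()


def _sweep(patients, conditions, runner) -> pd.DataFrame:
    rows = []
    for source in patients:
        patient = _resolve(source)
        for cond in conditions:
            try:
                t0 = time.time()
                rows.append(runner(patient, cond))
                log.info("patient %s condition %s done in %.1f s",
                         patient.patient_id, cond, time.time() - t0)
            except ValueError as exc:
                log.warning("patient %s condition %s skipped: %s",
                            patient.patient_id, cond, exc)
                rows.append({"patient": patient.patient_id, "missing": str(exc),
                             **(cond if isinstance(cond, dict) else {})})
        del patient
    return pd.DataFrame(rows)


def run_step1(
    patients: list[PatientSource],
    grid: ExperimentGrid = ExperimentGrid(),
    seed: int = 0,
    train_cfg: TrainingConfig | None = None,
    max_epochs_per_class: int | None = None,
) -> tuple[pd.DataFrame, ExperimentState]:
    """Sweep preictal lengths (all channels, 256 Hz); select best L by
    patient-averaged accuracy."""
    def runner(patient, cond):
        return run_condition(patient, cond["L"], "all", grid.default_fs, seed,
                             train_cfg, max_epochs_per_class)

    df = _sweep(patients, [{"L": L} for L in grid.preictal_lengths_min], runner)
    ok = df[df["accuracy"].notna()] if "accuracy" in df else df.iloc[0:0]
    if ok.empty:
        raise RuntimeError("step 1 produced no successful condition")
    avg = average_rows(ok, ["L"])
    best_L = float(avg.loc[avg["accuracy"].idxmax(), "L"])
    state = ExperimentState(best_L=best_L,
                            step1_rows=json.loads(ok.to_json(orient="records")))
    return df, state


def run_step2(
    patients: list[PatientSource],
    state: ExperimentState,
    grid: ExperimentGrid = ExperimentGrid(),
    seed: int = 0,
    train_cfg: TrainingConfig | None = None,
    max_epochs_per_class: int | None = None,
) -> pd.DataFrame:
    """Sweep electrode counts at the selected L and 256 Hz."""
    best_L = state.require_best_L()

    def runner(patient, cond):
        k = cond["k"]
        if k != "all" and int(k) > patient.recording.n_channels:
            raise ValueError(f"k={k} exceeds {patient.recording.n_channels} channels")
        return run_condition(patient, best_L, k, grid.default_fs, seed,
                             train_cfg, max_epochs_per_class)

    df = _sweep(patients, [{"k": k} for k in grid.channel_counts], runner)
    df["L"] = best_L
    return df


def run_step3(
    patients: list[PatientSource],
    state: ExperimentState,
    grid: ExperimentGrid = ExperimentGrid(),
    seed: int = 0,
    train_cfg: TrainingConfig | None = None,
    max_epochs_per_class: int | None = None,
) -> pd.DataFrame:
    """Sweep sampling rates at the selected L with all channels."""
    best_L = state.require_best_L()

    def runner(patient, cond):
        fs = cond["fs"]
        if fs > patient.recording.fs:
            raise ValueError(f"native rate {patient.recording.fs} below {fs} Hz")
        return run_condition(patient, best_L, "all", fs, seed,
                             train_cfg, max_epochs_per_class)

    df = _sweep(patients, [{"fs": fs} for fs in grid.sampling_frequencies_hz], runner)
    df["L"] = best_L
    return df
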