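"""Plain-format I/O: seizure annotations (CSV/JSON), period-labeling export
(BED-like TSV + JSON summary), ranked-channel configs (YAML), and the HDF5
feature store."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .annotations import PeriodLabeling, SeizureEvent
from .datasets import LabeledDataset, RankedMontage

__all__ = [
    "read_annotations", "write_annotations_csv",
    "write_labeling", "read_montage", "write_montage",
    "save_feature_store", "load_feature_store",
]


def read_annotations(path: str | Path) -> list[SeizureEvent]:
    """Seizure annotations from CSV (columns onset_s,termination_s) or a JSON
    list of objects with those keys."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return [SeizureEvent(float(r["onset_s"]), float(r["termination_s"])) for r in rows]


def write_annotations_csv(events: list[SeizureEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "termination_s"])
        for ev in events:
            w.writerow([f"{ev.onset_s:.3f}", f"{ev.termination_s:.3f}"])


def write_labeling(labeling: PeriodLabeling, tsv_path: str | Path,
                   summary_path: str | Path | None = None) -> None:
    """BED-like TSV ``start_s  end_s  label`` plus a JSON summary with the
    lead count and per-label total hours."""
    with open(tsv_path, "w") as fh:
        for s, e, lab in labeling.intervals:
            fh.write(f"{s:.3f}\t{e:.3f}\t{lab}\n")
    if summary_path is not None:
        summary = {
            "preictal_length_min": labeling.preictal_length_min,
            "duration_h": labeling.duration_s / 3600.0,
            "n_lead_seizures": len(labeling.lead_onsets),
            "n_flagged_leads": len(labeling.flagged_leads),
            "hours": {lab: labeling.total(lab) / 3600.0
                      for lab in ("interictal", "preictal", "postictal", "ictal", "unused")},
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))


def read_montage(path: str | Path) -> RankedMontage:
    """Ranked channel list from YAML ({ranked_channels: [...]} or a bare list)."""
    data = yaml.safe_load(Path(path).read_text())
    ranked = data["ranked_channels"] if isinstance(data, dict) else data
    return RankedMontage(tuple(str(c) for c in ranked))


def write_montage(montage: RankedMontage, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({"ranked_channels": list(montage.ranked_channels)}))


def save_feature_store(dataset: LabeledDataset, path: str | Path, attrs: dict | None = None):
    """Write epochs/labels/start times to HDF5 (datasets /epochs, /labels,
    /start_s; config in root attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=dataset.X, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=dataset.y)
        f.create_dataset("start_s", data=dataset.start_s)
        f.create_dataset("freq_bins", data=np.asarray(dataset.freq_bins))
        f.attrs["channel_names"] = [str(c) for c in dataset.channel_names]
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_feature_store(path: str | Path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        return LabeledDataset(
            X=f["epochs"][...],
            y=f["labels"][...],
            start_s=f["start_s"][...],
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            freq_bins=f["freq_bins"][...],
        )
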