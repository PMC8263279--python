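"""Plain-text persistence: recordings, models, run configuration.

Recordings are written as a CSV channel matrix (one row per time sample,
HbO columns then HbR columns) plus a BIDS-events-like TSV
(onset_seconds, duration_seconds, task_label). Models are saved as a single
JSON file with an embedded manifest and arrays as nested lists; Python's
JSON float round-trip is lossless, so a reloaded model predicts bitwise
identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dbn import DbnModel
from .preprocessing import ChannelScaler
from .rbm import RbmParams
from .simulate import SessionRecording, TrialEvent

__all__ = [
    "write_recording",
    "read_recording",
    "save_model",
    "load_model",
    "ModelContainer",
]

MODEL_FORMAT_VERSION = 1


def write_recording(
    recording: SessionRecording, channel_file, events_file
) -> None:
    n_ch = recording.hbo.shape[0]
    cols = [f"ch{c + 1:02d}_hbo" for c in range(n_ch)] + [
        f"ch{c + 1:02d}_hbr" for c in range(n_ch)
    ]
    mat = np.vstack([recording.hbo, recording.hbr]).T
    pd.DataFrame(mat, columns=cols).to_csv(channel_file, index=False)
    fs = recording.sampling_rate
    ev = pd.DataFrame(
        {
            "onset_seconds": [e.onset_sample / fs for e in recording.events],
            "duration_seconds": [8.0] * len(recording.events),
            "task_label": [e.task for e in recording.events],
        }
    )
    ev.to_csv(events_file, sep="\t", index=False)


def read_recording(
    channel_file, events_file, sampling_rate: float = 20.0
) -> SessionRecording:
    """Parse and validate a written recording; onsets in seconds are rounded
    to the nearest sample."""
    df = pd.read_csv(channel_file)
    hbo_cols = [c for c in df.columns if c.endswith("_hbo")]
    hbr_cols = [c for c in df.columns if c.endswith("_hbr")]
    if not hbo_cols:
        raise ValueError(f"{channel_file}: no *_hbo columns found")
    if df[hbo_cols + hbr_cols].isna().any().any():
        bad = int(df[df[hbo_cols + hbr_cols].isna().any(axis=1)].index[0])
        raise ValueError(f"{channel_file}: NaN at row {bad}")
    hbo = df[hbo_cols].to_numpy().T
    hbr = df[hbr_cols].to_numpy().T

    ev = pd.read_csv(events_file, sep="\t")
    required = {"onset_seconds", "duration_seconds", "task_label"}
    if not required <= set(ev.columns):
        raise ValueError(
            f"{events_file}: missing columns {sorted(required - set(ev.columns))}"
        )
    onsets = ev["onset_seconds"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        raise ValueError(f"{events_file}: non-increasing onset at row {bad}")
    events = []
    total = hbo.shape[1]
    for k, row in ev.iterrows():
        onset = int(round(row["onset_seconds"] * sampling_rate))
        stop = onset + int(round(row["duration_seconds"] * sampling_rate))
        if stop > total:
            raise ValueError(
                f"{events_file}: trial {k} ({row['task_label']}) overruns "
                f"the recording ({stop} > {total})"
            )
        events.append(TrialEvent(onset_sample=onset, task=str(row["task_label"])))
    return SessionRecording(
        hbo=hbo,
        hbr=hbr,
        sampling_rate=sampling_rate,
        events=events,
        subject_id="",
        session_index=0,
    )


@dataclasses.dataclass
class ModelContainer:
    model: DbnModel
    scaler: ChannelScaler | None
    config: dict
    version: int = MODEL_FORMAT_VERSION


def save_model(
    model: DbnModel,
    scaler: ChannelScaler | None,
    config: dict,
    path,
) -> None:
    payload = {
        "manifest": {
            "format": "fnirsdbn-model",
            "version": MODEL_FORMAT_VERSION,
            "hidden_sizes": list(model.hidden_sizes),
            "class_labels": list(model.class_labels),
        },
        "rbm1": {
            "W": model.rbm1.W.tolist(),
            "a": model.rbm1.a.tolist(),
            "b": model.rbm1.b.tolist(),
        },
        "rbm2": {
            "W": model.rbm2.W.tolist(),
            "a": model.rbm2.a.tolist(),
            "b": model.rbm2.b.tolist(),
        },
        "softmax_w": model.softmax_w.tolist(),
        "scaler": None
        if scaler is None
        else {"mins": scaler.mins.tolist(), "maxs": scaler.maxs.tolist()},
        "config": config,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ModelContainer:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    manifest = payload.get("manifest", {})
    if manifest.get("format") != "fnirsdbn-model":
        raise ValueError(f"{path}: not an fnirsdbn model file")
    if manifest.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {manifest.get('version')} != "
            f"{MODEL_FORMAT_VERSION}"
        )

    def rbm(d) -> RbmParams:
        return RbmParams(
            W=np.array(d["W"]), a=np.array(d["a"]), b=np.array(d["b"])
        )

    model = DbnModel(
        rbm1=rbm(payload["rbm1"]),
        rbm2=rbm(payload["rbm2"]),
        softmax_w=np.array(payload["softmax_w"]),
        class_labels=tuple(manifest["class_labels"]),
    )
    scaler = None
    if payload.get("scaler") is not None:
        scaler = ChannelScaler(
            mins=np.array(payload["scaler"]["mins"]),
            maxs=np.array(payload["scaler"]["maxs"]),
        )
    return ModelContainer(
        model=model,
        scaler=scaler,
        config=payload.get("config", {}),
        version=manifest["version"],
    )
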