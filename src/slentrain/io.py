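"""File formats: BIDS-style events TSV, JSON sidecars, array containers.

Continuous recordings and epoch tensors travel as compressed ``.npz``
containers accompanied by a JSON header describing shapes, sampling rate
and units; events are tab-separated tables; configuration is YAML or
JSON. EDF reading is available through the optional ``mne`` dependency
for ingesting real recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simeeg import EEGRecording


def save_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_recording(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as <path>.npz plus <path>.json header and events TSV."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        data=recording.data.astype(np.float32),
        artifact_mask=recording.artifact_mask,
        positions=recording.channel_positions,
    )
    header = {
        "srate_hz": recording.srate_hz,
        "n_channels": int(recording.n_channels),
        "n_samples": int(recording.n_samples),
        "units": "a.u.",
        "arrays": ["data", "artifact_mask", "positions"],
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    save_events_tsv(recording.events, path.with_suffix(".events.tsv"))


def load_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    events = load_events_tsv(path.with_suffix(".events.tsv"))
    return EEGRecording(
        arrays["data"].astype(float),
        header["srate_hz"],
        arrays["positions"],
        events,
        arrays["artifact_mask"].astype(bool),
    )


def load_edf(path: str | Path, events_tsv: str | Path | None = None) -> EEGRecording:
    """Read a continuous EDF recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    events = (
        load_events_tsv(events_tsv)
        if events_tsv is not None
        else pd.DataFrame({"onset": [], "duration": []})
    )
    montage = raw.get_montage()
    if montage is not None:
        pos = np.array([p * 100 for p in montage.get_positions()["ch_pos"].values()])
    else:
        from .montage import make_montage

        pos = make_montage(data.shape[0])
    return EEGRecording(data, raw.info["sfreq"], pos, events)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
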