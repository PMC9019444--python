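"""Delimited-text interchange for recordings, features and cohort manifests.

Recordings travel as tab-separated text: a header row of channel names, one
row per sample, values in microvolt.  Sampling rate and labels ride in
``#``-prefixed header comments so a file round-trips to an identical
:class:`~eegstress.simulate.Recording`.  EDF reading (for real recordings)
is available through :func:`read_recording_edf` when ``mne`` is installed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import Recording, STARecord

__all__ = [
    "write_recording_txt",
    "read_recording_txt",
    "read_recording_edf",
    "write_sta_table",
    "read_sta_table",
    "write_feature_table",
    "read_feature_table",
]

_META_KEYS = ("fs", "subject_id", "group", "condition")


def write_recording_txt(recording: Recording, path):
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs}\n")
        fh.write(f"# subject_id={recording.subject_id}\n")
        fh.write(f"# group={recording.group}\n")
        fh.write(f"# condition={recording.condition}\n")
        fh.write("\t".join(recording.channel_names) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.8g", delimiter="\t")
    return path


def read_recording_txt(path) -> Recording:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        channels = line.strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing header fields {missing}")
    return Recording(
        data=data.T,
        fs=float(meta["fs"]),
        channel_names=tuple(channels),
        subject_id=meta["subject_id"],
        group=meta["group"],
        condition=meta["condition"],
    )


def read_recording_edf(path, subject_id, group, condition) -> Recording:
    """Load a European Data Format file as a Recording (requires mne).

    Values are converted from MNE's volts to microvolt.  Metadata that EDF
    does not carry (group, condition) is supplied by the caller, typically
    from a cohort manifest.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install eegstress[edf])"
        ) from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        subject_id=subject_id,
        group=group,
        condition=condition,
    )


def write_sta_table(records, path):
    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "group": r.group,
             "sta1": r.sta1, "sta2": r.sta2}
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


def read_sta_table(path):
    df = pd.read_csv(path)
    return [
        STARecord(row.subject_id, row.group, float(row.sta1), float(row.sta2))
        for row in df.itertuples()
    ]


def write_feature_table(table: pd.DataFrame, path):
    table.to_csv(path, index=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def recording_filename(recording: Recording) -> str:
    cond = recording.condition.replace("/", "_")
    return f"{recording.subject_id}_{cond}.tsv"


def write_cohort(recordings, sta_records, out_dir):
    """Write every recording plus the STA table and a manifest CSV linking
    (subject, group, condition) to its file and scores."""
    os.makedirs(out_dir, exist_ok=True)
    sta = {r.subject_id: r for r in sta_records}
    manifest = []
    for rec in recordings:
        fname = recording_filename(rec)
        write_recording_txt(rec, os.path.join(out_dir, fname))
        s = sta.get(rec.subject_id)
        manifest.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "condition": rec.condition, "file": fname,
            "sta1": s.sta1 if s else np.nan,
            "sta2": s.sta2 if s else np.nan,
        })
    write_sta_table(sta_records, os.path.join(out_dir, "sta_scores.csv"))
    mpath = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(manifest).to_csv(mpath, index=False)
    return mpath
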