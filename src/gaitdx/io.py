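"""CSV interchange: one file per recording plus a cohort manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import CHANNELS, GaitRecording

MANIFEST_NAME = "manifest.csv"


def write_cohort(recordings: list[GaitRecording], outdir: str | Path) -> Path:
    """Write one CSV per recording (sample_index + the six channels) and a
    manifest CSV (recording_file, subject_id, label, fs). Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    counter: dict[str, int] = {}
    for rec in recordings:
        cycle = counter.get(rec.subject_id, 0)
        counter[rec.subject_id] = cycle + 1
        fname = f"{rec.subject_id}_cycle{cycle:03d}.csv"
        df = pd.DataFrame({"sample_index": np.arange(rec.n_samples)})
        for ch in CHANNELS:
            df[ch] = rec.channels[ch]
        df.to_csv(outdir / fname, index=False, float_format="%.6g")
        manifest_rows.append(
            {"recording_file": fname, "subject_id": rec.subject_id,
             "label": rec.label, "fs": rec.fs}
        )
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[GaitRecording]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(base / row["recording_file"])
        channels = {ch: df[ch].to_numpy(dtype=float) for ch in CHANNELS}
        recordings.append(
            GaitRecording(str(row["subject_id"]), str(row["label"]), channels, float(row["fs"]))
        )
    return recordings
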