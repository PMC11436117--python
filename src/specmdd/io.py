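"""Reading and writing cohorts: delimited matrices, EDF, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import SubjectRecord


def write_cohort(cohort: list[SubjectRecord], out_dir: str | Path,
                 fmt: str = "csv") -> Path:
    """Write per-subject channel matrices plus a subjects.csv manifest.

    Each subject's data goes to ``<id>.csv.gz`` (channels x samples, one row
    per channel, first column the electrode label).  The manifest holds id,
    group and the clinical scores.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "bdi": s.scores.get("bdi"),
                     "bdi_anh": s.scores.get("bdi_anh"),
                     "bdi_mel": s.scores.get("bdi_mel"),
                     "data_file": f"{s.subject_id}.csv.gz" if s.data is not None else ""})
        if s.data is not None:
            df = pd.DataFrame(s.data, index=list(s.channel_labels))
            df.to_csv(out / f"{s.subject_id}.csv.gz", header=False)
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    return out


def read_subject_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read one subject's channels-x-samples matrix.

    ``.edf`` files are read through MNE; anything else is treated as a
    delimited matrix whose first column holds channel labels.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return list(raw.ch_names), raw.get_data() * 1e6  # volts -> uV
    df = pd.read_csv(path, header=None, index_col=0)
    return [str(c) for c in df.index], df.to_numpy(dtype=float)


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (or user-supplied data
    following the same layout)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "subjects.csv")
    cohort = []
    for _, row in manifest.iterrows():
        data = None
        labels: tuple[str, ...] = ()
        if isinstance(row.get("data_file"), str) and row["data_file"]:
            chans, data = read_subject_matrix(in_dir / row["data_file"])
            labels = tuple(chans)
            data = np.asarray(data, dtype=np.float32)
        scores = {k: int(row[k]) for k in ("bdi", "bdi_anh", "bdi_mel")
                  if k in row and pd.notna(row[k])}
        cohort.append(SubjectRecord(subject_id=str(row["subject_id"]),
                                    group=str(row["group"]), data=data,
                                    channel_labels=labels, scores=scores))
    return cohort


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
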