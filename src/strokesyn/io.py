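"""Dataset readers and the packaged clinical characteristics table.

The on-disk layout is the one produced by
:func:`strokesyn.cohort.write_dataset`: a ``subjects.csv`` plus per-subject
directories of plain-CSV signal files and a ``manifest.yaml`` of rates and
MVC values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import ARMS, SubjectProfile, SubjectTruth, _truth_from_json
from .emg import MUSCLES, EmgSession
from .fnirs import N_CHANNELS, WAVELENGTHS, FnirsSession

VALID_BS = {"I", "II", "III", "IV", "V", "VI"}


@dataclass
class DatasetError(Exception):
    file: str
    message: str

    def __str__(self):
        return f"{self.file}: {self.message}"


def load_table1() -> pd.DataFrame:
    """The packaged demographic/clinical characteristics of the 15 patients."""
    with resources.files("strokesyn.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"patient": str})
    bad = set(df["bs"]) - VALID_BS
    if bad:
        raise DatasetError("table1.csv", f"invalid Brunnstrom stage value(s): {bad}")
    return df


def table1_summary(table: Optional[pd.DataFrame] = None) -> dict:
    """Demographic summary: mean age, sample (n-1) SD, counts by sex.

    A single-row table has no sample SD; it is reported as NaN and flagged.
    """
    df = load_table1() if table is None else table
    n = len(df)
    summary = {
        "n": n,
        "age_mean": float(df["age"].mean()) if n else np.nan,
        "age_sd": float(df["age"].std(ddof=1)) if n > 1 else np.nan,
        "sd_defined": n > 1,
        "sex_counts": df["sex"].str.lower().value_counts().to_dict() if n else {},
    }
    summary["female_count"] = int(summary["sex_counts"].get("female", 0))
    return summary


def _require(path: Path, context: str) -> Path:
    if not path.exists():
        raise DatasetError(str(path), f"missing {context}")
    return path


def read_dataset(path):
    """Read a dataset directory back into profiles, truths and sessions.

    Validates channel counts, sampling rates and event consistency;
    schema violations raise :class:`DatasetError` naming file and column.
    """
    root = Path(path)
    subj_df = pd.read_csv(_require(root / "subjects.csv", "subject table"))
    for col in ("subject_id", "group", "age", "lesion_side"):
        if col not in subj_df.columns:
            raise DatasetError("subjects.csv", f"missing column {col!r}")
    truths = {}
    gt_path = root / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            truths = {sid: _truth_from_json(d) for sid, d in json.load(fh).items()}

    profiles, sessions = [], {}
    for _, row in subj_df.iterrows():
        fmul = row.get("fmul")
        fmul = None if pd.isna(fmul) or fmul == "" else int(fmul)
        profiles.append(SubjectProfile(
            subject_id=row.subject_id, group=row.group,
            lesion_side=row.lesion_side, age=float(row.age),
            days_post_stroke=float(row.get("days_after_stroke", 0.0)),
            severity=float(row.get("severity", 0.0)), fmul_true=fmul,
            dominant_hand=row.get("dominant_hand", "right"),
            sex=row.get("sex", ""),
        ))
        sdir = root / row.subject_id
        if not sdir.is_dir():
            continue
        manifest = yaml.safe_load(open(_require(sdir / "manifest.yaml", "manifest")))
        rates = manifest.get("rates", {})
        for arm in ARMS:
            emg_path = sdir / f"emg_{arm}.csv"
            if emg_path.exists():
                force_path = _require(sdir / f"force_{arm}.csv", "force file")
                ev_path = _require(sdir / f"events_{arm}.csv", "events file")
                emg_df = pd.read_csv(emg_path)
                for m in MUSCLES:
                    if m not in emg_df.columns:
                        raise DatasetError(str(emg_path), f"missing muscle column {m!r}")
                force_df = pd.read_csv(force_path)
                if "newtons" not in force_df.columns:
                    raise DatasetError(str(force_path), "missing column 'newtons'")
                events = pd.read_csv(ev_path)
                sessions[(row.subject_id, "emg", arm)] = EmgSession(
                    emg=emg_df[list(MUSCLES)].to_numpy().T,
                    emg_fs=float(rates.get("emg_fs", 1925.9)),
                    force=force_df["newtons"].to_numpy(),
                    force_fs=float(rates.get("force_fs", 10.0)),
                    mvc_trials=np.asarray(manifest["mvc_trials"][arm], dtype=float),
                    events=events, arm=arm,
                )
            fn_path = sdir / f"fnirs_{arm}.csv"
            if fn_path.exists():
                fn_df = pd.read_csv(fn_path)
                intensity = np.empty((N_CHANNELS, 2, len(fn_df)))
                for ch in range(N_CHANNELS):
                    for w, wl in enumerate(WAVELENGTHS):
                        col = f"ch{ch + 1:02d}_w{int(wl)}"
                        if col not in fn_df.columns:
                            raise DatasetError(str(fn_path), f"missing column {col!r}")
                        intensity[ch, w] = fn_df[col].to_numpy()
                events = pd.read_csv(
                    _require(sdir / f"events_fnirs_{arm}.csv", "fNIRS events"))
                sessions[(row.subject_id, "fnirs", arm)] = FnirsSession(
                    intensity=intensity, fs=float(rates.get("fnirs_fs", 10.0)),
                    events=events, arm=arm,
                )
    return profiles, truths, sessions
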