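"""Surface-EMG preprocessing: envelope extraction, force-gated lift
segmentation with exclusion rules, and amplitude/time normalization.

The dynamometer trace (10 Hz) is the segmentation clock: a lift starts when
force rises past baseline + 5% of the target, is padded by two force samples
(0.2 s) of pre-onset context, and ends when force returns to baseline.
Lifts longer than 3 s, or whose plateau force deviates from the 30%-MVC
target by more than 15%, are excluded and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

MUSCLES = ("DA", "DP", "BI", "TI", "BIO")

# segmentation constants (fractions of the target force)
ONSET_FRACTION = 0.05
PLATEAU_FRACTION = 0.50
MAX_LIFT_S = 3.0
MAX_FORCE_DEVIATION = 0.15
PRE_ONSET_FORCE_SAMPLES = 2
Q_TIME_SAMPLES = 50


@dataclass
class EmgSession:
    """One arm's recording: 5-muscle sEMG, synchronized force, MVC trials."""

    emg: np.ndarray              # (5, n_samples) in uV
    emg_fs: float                # ~1925.9 Hz
    force: np.ndarray            # (n_force,) in N at force_fs
    force_fs: float              # 10 Hz
    mvc_trials: np.ndarray       # 3 force maxima (N)
    events: pd.DataFrame         # columns onset_s, duration_s, kind
    arm: str = "unaffected"
    muscle_names: Sequence[str] = MUSCLES

    @property
    def target_force(self) -> float:
        return 0.30 * float(np.mean(self.mvc_trials))

    def __post_init__(self):
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        if self.emg.shape[0] != len(self.muscle_names):
            raise ValueError(
                f"expected {len(self.muscle_names)} muscle rows, got {self.emg.shape[0]}"
            )
        if self.target_force <= 0:
            raise ValueError("target force must be positive")


@dataclass
class LiftSegment:
    X: np.ndarray                # (5, q) normalized in [0,1] after normalize_segment
    lift_index: int
    duration_s: float
    plateau_force: float
    start_s: float = 0.0


@dataclass
class ExclusionRecord:
    lift_index: int
    rule: str                    # "duration" | "force-deviation"
    duration_s: float
    plateau_force: float


def envelope_extract(session: EmgSession) -> np.ndarray:
    """Linear envelope of each sEMG channel.

    Zero-phase 4th-order Butterworth band-pass 20-450 Hz, linear detrend,
    full-wave rectification, then zero-phase 4th-order Butterworth low-pass
    at 5 Hz; residual filter ringing below zero is clipped.
    """
    fs = session.emg_fs
    if fs <= 900.0:
        raise ValueError(f"emg_fs={fs} too low: 450 Hz band edge needs fs > 900 Hz")
    sos_bp = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    sos_lp = signal.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_bp, session.emg, axis=1)
    x = signal.detrend(x, axis=1, type="linear")
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_lp, x, axis=1)
    return np.clip(x, 0.0, None)


def _rest_baseline(force: np.ndarray, force_fs: float, events: pd.DataFrame) -> float:
    """Median force over rest periods (everything outside task windows)."""
    n = force.size
    t = np.arange(n) / force_fs
    in_task = np.zeros(n, dtype=bool)
    task = events[events["kind"] == "task"]
    for _, row in task.iterrows():
        in_task |= (t >= row.onset_s) & (t < row.onset_s + row.duration_s)
    rest = force[~in_task]
    if rest.size == 0:
        raise ValueError("no rest period available to estimate the force baseline")
    return float(np.median(rest))


def segment_lifts(
    envelope: np.ndarray,
    session: EmgSession,
) -> tuple[list[LiftSegment], list[ExclusionRecord]]:
    """Split the envelope into per-lift windows using the force trace.

    Returns raw (un-normalized, native-rate) segments plus the exclusion log;
    segments + exclusions together account for every detected lift.
    """
    force = np.asarray(session.force, dtype=float)
    if force.size == 0:
        raise ValueError("empty force trace")
    target = session.target_force
    baseline = _rest_baseline(force, session.force_fs, session.events)
    thr = baseline + ONSET_FRACTION * target

    above = force > thr
    rises = np.where(~above[:-1] & above[1:])[0] + 1
    segments: list[LiftSegment] = []
    exclusions: list[ExclusionRecord] = []
    last_end = -1
    idx = 0
    for r in rises:
        if r <= last_end:
            continue
        # return to baseline: first sample at/below threshold after the rise
        after = np.where(~above[r:])[0]
        end = r + int(after[0]) if after.size else force.size
        start = max(0, r - PRE_ONSET_FORCE_SAMPLES)
        last_end = end
        dur = (end - start) / session.force_fs
        lift_force = force[start:end]
        plateau_mask = lift_force > PLATEAU_FRACTION * target
        plateau = float(lift_force[plateau_mask].mean()) if plateau_mask.any() else 0.0

        if dur > MAX_LIFT_S:
            exclusions.append(ExclusionRecord(idx, "duration", dur, plateau))
        elif abs(plateau - target) / target > MAX_FORCE_DEVIATION:
            exclusions.append(ExclusionRecord(idx, "force-deviation", dur, plateau))
        else:
            i0 = int(round(start / session.force_fs * session.emg_fs))
            i1 = int(round(end / session.force_fs * session.emg_fs))
            i1 = min(i1, envelope.shape[1])
            if i1 - i0 >= 2:
                segments.append(
                    LiftSegment(
                        X=envelope[:, i0:i1],
                        lift_index=idx,
                        duration_s=dur,
                        plateau_force=plateau,
                        start_s=start / session.force_fs,
                    )
                )
            else:
                exclusions.append(ExclusionRecord(idx, "duration", dur, plateau))
        idx += 1
    return segments, exclusions


def normalize_segment(
    segment: LiftSegment,
    block_min: np.ndarray,
    block_max: np.ndarray,
    q: int = Q_TIME_SAMPLES,
    muscle_names: Sequence[str] = MUSCLES,
) -> LiftSegment:
    """Amplitude (block min-max) and time (resample to q points) normalization.

    The min/max are computed once over the whole block's envelope per muscle
    so relative amplitude differences between lifts survive normalization.
    """
    block_min = np.asarray(block_min, dtype=float)
    block_max = np.asarray(block_max, dtype=float)
    degenerate = np.where(block_max <= block_min)[0]
    if degenerate.size:
        names = ", ".join(muscle_names[i] for i in degenerate)
        raise ValueError(f"degenerate channel(s) with max <= min: {names}")
    X = (segment.X - block_min[:, None]) / (block_max - block_min)[:, None]
    src = np.linspace(0.0, 1.0, X.shape[1])
    dst = np.linspace(0.0, 1.0, q)
    Xr = np.vstack([np.interp(dst, src, row) for row in X])
    Xr = np.clip(Xr, 0.0, 1.0)
    return LiftSegment(
        X=Xr,
        lift_index=segment.lift_index,
        duration_s=segment.duration_s,
        plateau_force=segment.plateau_force,
        start_s=segment.start_s,
    )


def preprocess_session(session: EmgSession) -> tuple[list[LiftSegment], list[ExclusionRecord]]:
    """Full chain: envelope -> segmentation -> block-level normalization."""
    env = envelope_extract(session)
    raw_segments, exclusions = segment_lifts(env, session)
    if not raw_segments:
        return [], exclusions
    bmin = env.min(axis=1)
    bmax = env.max(axis=1)
    normalized = [
        normalize_segment(s, bmin, bmax, muscle_names=session.muscle_names)
        for s in raw_segments
    ]
    return normalized, exclusions
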