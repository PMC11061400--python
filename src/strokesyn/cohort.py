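"""Synthetic cohort generator with known ground truth.

Emulates the study acquisition: per arm, a block of repeated 15 s task /
25 s rest trials of intermittent isometric elbow flexion at 30% MVC
(trapezoid force lifts on a 0.5 Hz auditory cue, one lift per 2 s), with
5-muscle sEMG at 1925.9 Hz synchronized to a 10 Hz dynamometer, and a
24-channel dual-wavelength (830/704 nm) fNIRS recording at 10 Hz.

Every downstream quantity has a planted truth: per-lift synergy vectors are
severity-dependent mixtures of a healthy pattern (biceps-dominant) and an
abnormal pattern with raised anterior-deltoid and brachioradialis weights;
hemodynamic activations are hemisphere-asymmetric with severity shrinking
contralateral and growing ipsilateral responses; the true Fugl-Meyer score
is a linear function of the implied indices.  The severity->physiology maps
are declared, not estimated — they exist to make recovery testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

from .emg import MUSCLES, EmgSession
from .fnirs import (
    N_CHANNELS, WAVELENGTHS, DEFAULT_DPF, FnirsSession,
    mbll_forward, task_regressor,
)
from .indices import closeness_time
from .laterality import REGIONS, RegionMap

ARMS = ("affected", "unaffected")

# healthy biceps-dominant synergy vs the abnormal pattern with extra
# anterior deltoid (DA) and brachioradialis (BIO) recruitment
V_HEALTHY = np.array([0.25, 0.10, 1.00, 0.15, 0.35])
V_HEALTHY = V_HEALTHY / np.linalg.norm(V_HEALTHY)
V_ABNORMAL = np.array([0.90, 0.25, 0.30, 0.40, 0.85])
V_ABNORMAL = V_ABNORMAL / np.linalg.norm(V_ABNORMAL)

# baseline hemodynamic response (uM) per region: (contralateral, ipsilateral)
BETA_BASE = {"PMC": (0.60, 0.25), "M1": (0.70, 0.30), "S1": (0.50, 0.25)}
# how strongly severity perturbs each region
REGION_EFFECT = {"PMC": 1.0, "M1": 0.8, "S1": 0.3}
# severity slopes: contralateral shrink / ipsilateral growth, per moving arm
ARM_SLOPES = {"affected": (0.60, 1.20), "unaffected": (0.20, 0.40)}


@dataclass
class SimulationConfig:
    """All tunable generation parameters (defaults mirror the study paradigm)."""

    n_patients: int = 15
    n_controls: int = 15
    seed: int = 0
    # paradigm timing
    task_s: float = 15.0
    rest_s: float = 25.0
    trials_per_block: int = 6
    cue_hz: float = 0.5
    lift_period_s: float = 2.0      # 0.5 Hz cue, 2/4 beat -> one lift per 2 s
    lead_in_s: float = 5.0
    target_fraction: float = 0.30
    # MVC calibration phase at block start: 3 maximal bursts; these drive all
    # muscles to a common ceiling, so per-muscle block min-max normalization
    # rescales every channel identically and planted synergy directions
    # survive preprocessing
    n_mvc: int = 3
    mvc_burst_s: float = 2.0
    mvc_gap_s: float = 2.0
    mvc_start_s: float = 1.0
    task_activation: float = 0.6    # task envelope amplitude relative to MVC
    # sampling
    emg_fs: float = 1925.9
    force_fs: float = 10.0
    fnirs_fs: float = 10.0
    # sEMG / force noise
    emg_amplitude_uv: float = 200.0
    emg_noise_rel: float = 0.02     # background noise relative to amplitude
    force_jitter_sd: float = 0.05   # relative plateau deviation from target
    force_noise_sd: float = 0.3     # N, sensor noise
    trial_jitter_base: float = 0.02  # synergy-vector jitter at severity 0
    trial_jitter_slope: float = 0.08  # extra jitter per unit severity (affected)
    # fNIRS physiological noise (uM) and artifacts
    cardiac_amp: float = 0.08
    cardiac_hz: float = 1.0
    resp_amp: float = 0.06
    resp_hz: float = 0.3
    mayer_amp: float = 0.05
    mayer_hz: float = 0.1
    drift_amp: float = 0.2
    white_noise_sd: float = 0.05
    artifact_rate_hz: float = 0.02
    artifact_amp: float = 2.0
    li_jitter_sd: float = 0.08      # per-subject log-scale jitter on planted betas
    dpf: float = DEFAULT_DPF
    # planted Fugl-Meyer model: theta0 + theta1*C_V_af + theta2*LI_PMC_un
    #   + theta3*F_r + theta4*C_V_r + noise
    theta: tuple = (60.0, 40.0, 28.0, -10.0, -40.0)
    fmul_noise_sd: float = 2.0
    severity_low: float = 0.1
    severity_high: float = 0.9

    def __post_init__(self):
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must lie in (0, 1)")
        for name in ("task_s", "rest_s", "emg_fs", "force_fs", "fnirs_fs",
                     "cue_hz", "lift_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lifts_per_trial(self) -> int:
        return int(self.task_s // self.lift_period_s)

    @property
    def mvc_phase_s(self) -> float:
        if self.n_mvc == 0:
            return 0.0
        return (self.mvc_start_s + self.n_mvc * self.mvc_burst_s
                + self.n_mvc * self.mvc_gap_s)

    @property
    def block_duration_s(self) -> float:
        return (self.mvc_phase_s + self.lead_in_s
                + self.trials_per_block * (self.task_s + self.rest_s))


@dataclass
class SubjectProfile:
    subject_id: str
    group: str                   # 'patient' | 'control'
    lesion_side: str             # 'left' | 'right' | 'none'
    age: float
    days_post_stroke: float
    severity: float
    fmul_true: Optional[int]
    dominant_hand: str = "right"
    sex: str = "male"

    @property
    def orientation_side(self) -> str:
        """Hemisphere that plays the 'affected' role for channel flipping.

        Patients: the lesioned hemisphere.  Controls: the hemisphere
        contralateral to the non-dominant arm (the right hemisphere for a
        right-hander), so their non-dominant arm mirrors the patients'
        affected arm.  The analysis convention maps this side to the right
        hemisphere; 'right' means no flip.
        """
        if self.group == "patient":
            return self.lesion_side
        return self.dominant_hand


@dataclass
class SubjectTruth:
    """Planted generative state for one subject (the recovery oracle)."""

    severity: float
    mix_unaffected: float
    v_planted: dict              # arm -> mean 5-vector (unit norm)
    trial_jitter_sd: dict        # arm -> sd
    profile_skew: dict           # arm -> exponent offset on the bell profile
    mvc: dict                    # arm -> N
    betas: dict                  # arm -> region -> (beta_contra, beta_ipsi)
    implied: dict                # implied-true feature values (21 predictors)
    fmul_true: Optional[int]
    session_seeds: dict          # (modality, arm) -> int


def _bell(n: int, skew: float = 0.0) -> np.ndarray:
    """Smooth unimodal activation profile; skew > 0 compresses it."""
    x = np.linspace(0.0, 1.0, n)
    return np.sin(np.pi * x) ** (2.0 + skew)


def planted_betas(severity: float, arm: str, jitter: Optional[dict] = None) -> dict:
    """Severity -> planted (contra, ipsi) hemodynamic response per region.

    Contralateral responses shrink and ipsilateral ones grow with severity,
    strongest in PMC; the implied LI is strictly decreasing in severity.
    """
    c_slope, i_slope = ARM_SLOPES[arm]
    out = {}
    for region in REGIONS:
        c0, i0 = BETA_BASE[region]
        e = REGION_EFFECT[region]
        jc, ji = (1.0, 1.0) if jitter is None else jitter[region]
        bc = c0 * (1.0 - c_slope * e * severity) * jc
        bi = i0 * (1.0 + i_slope * e * severity) * ji
        out[region] = (max(bc, 1e-6), max(bi, 1e-6))
    return out


def _li(bc: float, bi: float) -> float:
    return (bc - bi) / (bc + bi)


def _implied_features(truth_partial: dict, config: SimulationConfig, q: int = 50) -> dict:
    """Implied-true values of the 21 predictors for one subject."""
    v_af = truth_partial["v_planted"]["affected"]
    v_un = truth_partial["v_planted"]["unaffected"]
    feats = {
        "C_V_af": float(v_af @ V_HEALTHY),
        "C_V_un": float(v_un @ V_HEALTHY),
    }
    base = _bell(q)
    for arm, suffix in (("affected", "af"), ("unaffected", "un")):
        feats[f"C_T_{suffix}"] = closeness_time(
            _bell(q, truth_partial["profile_skew"][arm]), base
        )
        # expected pairwise Pearson correlation of jittered synergy vectors:
        # between-muscle variance over (variance + jitter variance)
        sv2 = float(np.var(truth_partial["v_planted"][arm]))
        s2 = truth_partial["trial_jitter_sd"][arm] ** 2
        feats[f"SSI_{suffix}"] = sv2 / (sv2 + s2)
        for region in REGIONS:
            bc, bi = truth_partial["betas"][arm][region]
            feats[f"LI_{region}_{suffix}"] = _li(bc, bi)
    for fam in ("LI_PMC", "LI_M1", "LI_S1", "SSI", "C_V", "C_T"):
        feats[f"{fam}_r"] = feats[f"{fam}_un"] / feats[f"{fam}_af"]
    feats["F_r"] = truth_partial["mvc"]["unaffected"] / truth_partial["mvc"]["affected"]
    return feats


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectProfile], dict[str, SubjectTruth]]:
    """Draw subject profiles and their full generative ground truth.

    Deterministic given ``config.seed``.  Patients' severity is
    Uniform(0.1, 0.9); controls generate with severity 0 (healthy-like).
    The true FMul is the planted linear form of the implied indices, with
    Gaussian noise, rounded and clipped to [10, 66].
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[SubjectProfile] = []
    truths: dict[str, SubjectTruth] = {}
    specs = [("patient", i) for i in range(config.n_patients)] + [
        ("control", i) for i in range(config.n_controls)
    ]
    for group, i in specs:
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:02d}"
        if group == "patient":
            severity = float(rng.uniform(config.severity_low, config.severity_high))
            lesion_side = str(rng.choice(["left", "right"]))
            age = float(np.clip(rng.normal(56.0, 18.0), 25.0, 90.0))
            days = float(np.clip(np.exp(rng.normal(4.3, 0.9)), 7.0, 730.0))
            sex = "female" if rng.random() < 4 / 15 else "male"
        else:
            severity = 0.0
            lesion_side = "none"
            age = float(np.clip(rng.normal(52.0, 13.0), 25.0, 90.0))
            days = 0.0
            sex = "female" if rng.random() < 8 / 15 else "male"
        dominant = "right" if rng.random() < 0.9 else "left"

        # each index family gets its own subject-level variation on top of
        # the shared severity drive, so no index is a deterministic proxy
        # for another
        mix_af = float(np.clip(severity + rng.normal(0.0, 0.08), 0.0, 1.0))
        if group == "patient":
            # patients' unaffected arms show mild but genuinely variable
            # involvement (their synergies resemble controls', not exactly)
            mix_un = float(np.clip(0.15 + 0.25 * severity + rng.normal(0.0, 0.12),
                                   0.0, 0.8))
        else:
            mix_un = float(abs(rng.normal(0.0, 0.03)))
        v_planted = {}
        for arm, mix in (("affected", mix_af), ("unaffected", mix_un)):
            v = (1.0 - mix) * V_HEALTHY + mix * V_ABNORMAL
            v_planted[arm] = v / np.linalg.norm(v)
        jitter_sd = {
            "affected": config.trial_jitter_base
            + config.trial_jitter_slope * severity
            * float(np.exp(rng.normal(0.0, 0.4))),
            "unaffected": config.trial_jitter_base
            + 0.25 * config.trial_jitter_slope * severity
            * float(np.exp(rng.normal(0.0, 0.4))),
        }
        skew = {
            "affected": 0.8 * severity * float(np.exp(rng.normal(0.0, 0.4))),
            "unaffected": 0.2 * severity * float(np.exp(rng.normal(0.0, 0.4))),
        }
        mvc_un = float(np.clip(rng.normal(220.0, 30.0), 80.0, None))
        mvc_af = float(
            np.clip(mvc_un * (1.0 - 0.45 * severity + rng.normal(0.0, 0.07)), 20.0, None)
        )
        betas = {}
        for arm in ARMS:
            jit = {
                r: (
                    float(np.exp(rng.normal(0.0, config.li_jitter_sd))),
                    float(np.exp(rng.normal(0.0, config.li_jitter_sd))),
                )
                for r in REGIONS
            }
            betas[arm] = planted_betas(severity, arm, jit)

        partial = {
            "v_planted": v_planted,
            "trial_jitter_sd": jitter_sd,
            "profile_skew": skew,
            "mvc": {"affected": mvc_af, "unaffected": mvc_un},
            "betas": betas,
        }
        implied = _implied_features(partial, config)

        if group == "patient":
            t0, t1, t2, t3, t4 = config.theta
            raw = (
                t0
                + t1 * implied["C_V_af"]
                + t2 * implied["LI_PMC_un"]
                + t3 * implied["F_r"]
                + t4 * implied["C_V_r"]
                + rng.normal(0.0, config.fmul_noise_sd)
            )
            fmul = int(np.clip(round(raw), 10, 66))
        else:
            fmul = None

        session_seeds = {
            (mod, arm): int(rng.integers(0, 2**31 - 1))
            for mod in ("emg", "fnirs")
            for arm in ARMS
        }
        profiles.append(
            SubjectProfile(
                subject_id=sid, group=group, lesion_side=lesion_side, age=age,
                days_post_stroke=days, severity=severity, fmul_true=fmul,
                dominant_hand=dominant, sex=sex,
            )
        )
        truths[sid] = SubjectTruth(
            severity=severity, mix_unaffected=mix_un, v_planted=v_planted,
            trial_jitter_sd=jitter_sd, profile_skew=skew,
            mvc=partial["mvc"], betas=betas, implied=implied,
            fmul_true=fmul, session_seeds=session_seeds,
        )
    return profiles, truths


def implied_feature_frame(
    profiles: list[SubjectProfile], truths: dict[str, SubjectTruth]
) -> pd.DataFrame:
    """Implied-true 21-predictor table (plus FMul, age, days) per subject."""
    rows = []
    for p in profiles:
        t = truths[p.subject_id]
        row = {"subject_id": p.subject_id, "group": p.group, **t.implied,
               "age": p.age, "days_post_stroke": p.days_post_stroke,
               "FMul": np.nan if t.fmul_true is None else float(t.fmul_true)}
        rows.append(row)
    return pd.DataFrame(rows)


def _block_events(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for k in range(config.n_mvc):
        rows.append({"onset_s": config.mvc_start_s
                     + k * (config.mvc_burst_s + config.mvc_gap_s),
                     "duration_s": config.mvc_burst_s, "kind": "mvc"})
    for k in range(config.trials_per_block):
        onset = (config.mvc_phase_s + config.lead_in_s
                 + k * (config.task_s + config.rest_s))
        rows.append({"onset_s": onset, "duration_s": config.task_s, "kind": "task"})
        rows.append({"onset_s": onset + config.task_s, "duration_s": config.rest_s,
                     "kind": "rest"})
    return pd.DataFrame(rows)


def simulate_emg_session(
    profile: SubjectProfile,
    arm: str,
    config: SimulationConfig,
    truth: SubjectTruth,
) -> EmgSession:
    """Simulate one arm's sEMG + force block.

    The sEMG of each muscle is a planted per-lift envelope (synergy weight x
    bell time profile) amplitude-modulating a 20-450 Hz Gaussian carrier,
    plus unmodulated background noise; the force trace is a trapezoid per
    lift peaking near the 30%-MVC target with configured jitter.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    rng = np.random.default_rng(truth.session_seeds[("emg", arm)])
    events = _block_events(config)
    dur = config.block_duration_s
    n_emg = int(round(dur * config.emg_fs))
    n_force = int(round(dur * config.force_fs))
    t_force = np.arange(n_force) / config.force_fs

    mvc_trials = truth.mvc[arm] * (1.0 + rng.normal(0.0, 0.02, size=3))
    target = config.target_fraction * float(np.mean(mvc_trials))

    rise, plateau, fall = 0.3, 1.0, 0.3
    lift_len = rise + plateau + fall
    force = np.zeros(n_force)
    envelope = np.zeros((len(MUSCLES), n_emg))
    n_bell = max(int(round(lift_len * config.emg_fs)), 8)
    bell = _bell(n_bell, truth.profile_skew[arm])

    # MVC calibration bursts: maximal force, all muscles at the ceiling
    for j, (_, ev) in enumerate(events[events.kind == "mvc"].iterrows()):
        n_burst = max(int(round(ev.duration_s * config.emg_fs)), 8)
        burst = _bell(n_burst)
        i0 = int(round(ev.onset_s * config.emg_fs))
        i1 = min(i0 + n_burst, n_emg)
        envelope[:, i0:i1] += config.emg_amplitude_uv * burst[None, : i1 - i0]
        mvc_amp = mvc_trials[j] if j < len(mvc_trials) else float(np.mean(mvc_trials))
        n_fburst = max(int(round(ev.duration_s * config.force_fs)), 2)
        fb = _bell(n_fburst) * mvc_amp
        f0 = int(round(ev.onset_s * config.force_fs))
        f1 = min(f0 + n_fburst, n_force)
        force[f0:f1] += fb[: f1 - f0]

    for _, ev in events[events.kind == "task"].iterrows():
        for k in range(config.lifts_per_trial):
            t0 = ev.onset_s + k * config.lift_period_s
            amp = target * (1.0 + rng.normal(0.0, config.force_jitter_sd))
            # trapezoid on the 10 Hz force clock
            seg = np.interp(
                t_force, [t0, t0 + rise, t0 + rise + plateau, t0 + lift_len],
                [0.0, amp, amp, 0.0],
            )
            seg[(t_force < t0) | (t_force > t0 + lift_len)] = 0.0
            force += seg
            v = truth.v_planted[arm] + rng.normal(0.0, truth.trial_jitter_sd[arm], 5)
            v = np.clip(v, 0.0, None)
            nrm = np.linalg.norm(v)
            v = v / nrm if nrm > 0 else V_HEALTHY
            i0 = int(round(t0 * config.emg_fs))
            i1 = min(i0 + n_bell, n_emg)
            envelope[:, i0:i1] += (
                config.emg_amplitude_uv * config.task_activation
                * v[:, None] * bell[None, : i1 - i0]
            )
    force += rng.normal(0.0, config.force_noise_sd, n_force)
    force = np.clip(force, 0.0, None)

    if config.emg_noise_rel > 0 or envelope.any():
        carrier = rng.standard_normal((len(MUSCLES), n_emg))
        sos = sp_signal.butter(4, [20.0, 450.0], btype="bandpass",
                               fs=config.emg_fs, output="sos")
        carrier = sp_signal.sosfiltfilt(sos, carrier, axis=1)
        carrier /= carrier.std(axis=1, keepdims=True)
        emg = envelope * carrier
        emg += (config.emg_noise_rel * config.emg_amplitude_uv
                * rng.standard_normal((len(MUSCLES), n_emg)))
    else:
        emg = envelope
    return EmgSession(
        emg=emg, emg_fs=config.emg_fs, force=force, force_fs=config.force_fs,
        mvc_trials=mvc_trials, events=events, arm=arm,
    )


def planted_channel_betas(
    profile: SubjectProfile,
    truth: SubjectTruth,
    arm: str,
    region_map: Optional[RegionMap] = None,
) -> np.ndarray:
    """Per-channel planted betas in PHYSICAL head orientation.

    The affected-role hemisphere is ``profile.orientation_side``; the
    affected arm is on the opposite side of the body, so affected-arm
    movement makes that hemisphere contralateral.  The analysis-side
    channel flip maps this layout back to the affected-right convention.
    """
    region_map = region_map or RegionMap.default()
    side = profile.orientation_side
    if side not in ("left", "right"):
        side = "right"
    if arm == "affected":
        contra_hemi = side
    else:
        contra_hemi = "left" if side == "right" else "right"
    ipsi_hemi = "left" if contra_hemi == "right" else "right"
    beta = np.zeros(N_CHANNELS)
    for region in REGIONS:
        bc, bi = truth.betas[arm][region]
        for ch in region_map.channels(region, contra_hemi):
            beta[ch - 1] = bc
        for ch in region_map.channels(region, ipsi_hemi):
            beta[ch - 1] = bi
    return beta


def simulate_fnirs_session(
    profile: SubjectProfile,
    arm: str,
    config: SimulationConfig,
    truth: SubjectTruth,
    region_map: Optional[RegionMap] = None,
) -> FnirsSession:
    """Simulate one arm's 24-channel dual-wavelength intensity block.

    Per channel: planted dHbO = beta_true x (boxcar (*) canonical HRF),
    buried in cardiac/respiratory/Mayer oscillations, linear drift, white
    noise and occasional spike artifacts; dHbR = -0.3 dHbO.  Intensity is
    the exact inverse of the analysis MBLL (same extinction table, DPF and
    30 mm separation), so the processing chain is forward-consistent.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    region_map = region_map or RegionMap.default()
    rng = np.random.default_rng(truth.session_seeds[("fnirs", arm)])
    events = _block_events(config)
    n = int(round(config.block_duration_s * config.fnirs_fs))
    t = np.arange(n) / config.fnirs_fs
    reg = task_regressor(events, n, config.fnirs_fs, bandpass=False)

    beta_true = planted_channel_betas(profile, truth, arm, region_map)

    hbo = beta_true[:, None] * reg[None, :]
    for amp, hz in ((config.cardiac_amp, config.cardiac_hz),
                    (config.resp_amp, config.resp_hz),
                    (config.mayer_amp, config.mayer_hz)):
        phases = rng.uniform(0, 2 * np.pi, N_CHANNELS)
        freqs = hz * (1.0 + rng.normal(0.0, 0.05, N_CHANNELS))
        hbo += amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    hbo += rng.uniform(-config.drift_amp, config.drift_amp, N_CHANNELS)[:, None] \
        * (t[None, :] / max(t[-1], 1.0))
    hbo += config.white_noise_sd * rng.standard_normal((N_CHANNELS, n))
    # spike artifacts: exponential-decay transients at a Poisson rate
    n_spikes = rng.poisson(config.artifact_rate_hz * config.block_duration_s, N_CHANNELS)
    for ch in range(N_CHANNELS):
        for _ in range(n_spikes[ch]):
            pos = rng.integers(0, n)
            width = rng.uniform(0.2, 0.8) * config.fnirs_fs
            sign = rng.choice([-1.0, 1.0])
            dt = np.arange(n) - pos
            hbo[ch] += sign * config.artifact_amp * np.exp(-np.abs(dt) / width)
    hbr = -0.3 * hbo + 0.02 * rng.standard_normal((N_CHANNELS, n))

    od = mbll_forward(hbo, hbr, dpf=config.dpf)
    baseline = rng.uniform(0.5, 2.0, (N_CHANNELS, 2))
    intensity = baseline[:, :, None] * np.exp(-od)
    return FnirsSession(intensity=intensity, fs=config.fnirs_fs, events=events, arm=arm)


# ---------------------------------------------------------------------------
# dataset writing

def _truth_to_json(truth: SubjectTruth) -> dict:
    d = {
        "severity": truth.severity,
        "mix_unaffected": truth.mix_unaffected,
        "v_planted": {a: list(map(float, v)) for a, v in truth.v_planted.items()},
        "trial_jitter_sd": truth.trial_jitter_sd,
        "profile_skew": truth.profile_skew,
        "mvc": truth.mvc,
        "betas": {a: {r: list(b) for r, b in regs.items()}
                  for a, regs in truth.betas.items()},
        "implied": truth.implied,
        "fmul_true": truth.fmul_true,
        "session_seeds": {f"{m}_{a}": s for (m, a), s in truth.session_seeds.items()},
    }
    return d


def _truth_from_json(d: dict) -> SubjectTruth:
    return SubjectTruth(
        severity=d["severity"], mix_unaffected=d["mix_unaffected"],
        v_planted={a: np.array(v) for a, v in d["v_planted"].items()},
        trial_jitter_sd=d["trial_jitter_sd"], profile_skew=d["profile_skew"],
        mvc=d["mvc"],
        betas={a: {r: tuple(b) for r, b in regs.items()}
               for a, regs in d["betas"].items()},
        implied=d["implied"], fmul_true=d["fmul_true"],
        session_seeds={(k.rsplit("_", 1)[0], k.rsplit("_", 1)[1]): s
                       for k, s in d["session_seeds"].items()},
    )


def write_dataset(
    profiles: list[SubjectProfile],
    truths: dict[str, SubjectTruth],
    sessions: dict,
    path,
    config: Optional[SimulationConfig] = None,
) -> Path:
    """Write the CSV/manifest dataset layout consumed by ``read_dataset``.

    ``sessions`` maps (subject_id, modality, arm) -> session object, with
    modality 'emg' or 'fnirs'.  Round-trips losslessly through
    :func:`strokesyn.io.read_dataset`.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    subj_rows = [{
        "subject_id": p.subject_id, "group": p.group, "age": p.age, "sex": p.sex,
        "lesion_side": p.lesion_side, "days_after_stroke": p.days_post_stroke,
        "fmul": "" if p.fmul_true is None else p.fmul_true,
        "dominant_hand": p.dominant_hand, "severity": p.severity,
    } for p in profiles]
    pd.DataFrame(
        subj_rows,
        columns=["subject_id", "group", "age", "sex", "lesion_side",
                 "days_after_stroke", "fmul", "dominant_hand", "severity"],
    ).to_csv(root / "subjects.csv", index=False)
    with open(root / "ground_truth.json", "w") as fh:
        json.dump({sid: _truth_to_json(t) for sid, t in truths.items()},
                  fh, indent=1, sort_keys=True)
    if config is not None:
        with open(root / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)

    for p in profiles:
        sdir = root / p.subject_id
        sdir.mkdir(exist_ok=True)
        manifest = {"subject_id": p.subject_id, "mvc_trials": {}, "rates": {}}
        for arm in ARMS:
            emg = sessions.get((p.subject_id, "emg", arm))
            if emg is not None:
                te = np.arange(emg.emg.shape[1]) / emg.emg_fs
                df = pd.DataFrame({"time_s": te})
                for m, name in enumerate(emg.muscle_names):
                    df[name] = emg.emg[m]
                df.to_csv(sdir / f"emg_{arm}.csv", index=False)
                tf = np.arange(emg.force.size) / emg.force_fs
                pd.DataFrame({"time_s": tf, "newtons": emg.force}).to_csv(
                    sdir / f"force_{arm}.csv", index=False)
                emg.events.to_csv(sdir / f"events_{arm}.csv", index=False)
                manifest["mvc_trials"][arm] = [float(x) for x in emg.mvc_trials]
                manifest["rates"]["emg_fs"] = float(emg.emg_fs)
                manifest["rates"]["force_fs"] = float(emg.force_fs)
            fn = sessions.get((p.subject_id, "fnirs", arm))
            if fn is not None:
                tn = np.arange(fn.intensity.shape[2]) / fn.fs
                cols = {"time_s": tn}
                for ch in range(N_CHANNELS):
                    for w, wl in enumerate(fn.wavelengths):
                        cols[f"ch{ch + 1:02d}_w{int(wl)}"] = fn.intensity[ch, w]
                pd.DataFrame(cols).to_csv(sdir / f"fnirs_{arm}.csv", index=False)
                fn.events.to_csv(sdir / f"events_fnirs_{arm}.csv", index=False)
                manifest["rates"]["fnirs_fs"] = float(fn.fs)
        with open(sdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return root


def simulate_dataset(config: SimulationConfig, with_fnirs: bool = True):
    """Generate a cohort plus all its sessions, in memory."""
    profiles, truths = generate_cohort(config)
    region_map = RegionMap.default()
    sessions = {}
    for p in profiles:
        t = truths[p.subject_id]
        for arm in ARMS:
            sessions[(p.subject_id, "emg", arm)] = simulate_emg_session(
                p, arm, config, t)
            if with_fnirs:
                sessions[(p.subject_id, "fnirs", arm)] = simulate_fnirs_session(
                    p, arm, config, t, region_map)
    return profiles, truths, sessions
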