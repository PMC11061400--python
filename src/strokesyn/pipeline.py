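"""End-to-end orchestration: signals -> indices -> statistics -> regression.

``run_pipeline`` consumes either an on-disk dataset directory or an
in-memory simulated cohort and produces a results bundle: the per-arm index
table, the 21-predictor feature table, assumption-gated group comparisons,
and (when enough patients are present) the exhaustive 4-predictor FMul
model with out-of-sample control predictions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ARMS, SimulationConfig, simulate_dataset
from .emg import preprocess_session
from .fnirs import process_session
from .indices import aggregate_indices
from .io import read_dataset
from .laterality import RegionMap, laterality_index, normalize_lesion_orientation
from .regression import build_feature_table, exhaustive_subset_search, predict_scores
from .stats import compare_two_samples, scheirer_ray_hare
from .synergy import compute_baseline, mcr_als_decompose, select_synergy_count


@dataclass
class PipelineConfig:
    """Everything one run needs; validated on construction."""

    dataset_path: Optional[str] = None     # read this dataset ...
    simulation: Optional[SimulationConfig] = None  # ... or simulate one
    skip_fnirs: bool = False
    skip_emg: bool = False
    k_threshold: float = 3.3
    dpf: float = 6.0
    region_map_path: Optional[str] = None
    ratio_direction: str = "unaffected/affected"
    max_synergies: int = 5
    vaf_threshold: float = 0.80
    subset_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.dataset_path is None and self.simulation is None:
            raise ValueError("need a dataset_path or a simulation config")
        if self.ratio_direction not in ("unaffected/affected", "affected/unaffected"):
            raise ValueError(f"bad ratio_direction {self.ratio_direction!r}")
        if self.k_threshold <= 0 or self.dpf <= 0:
            raise ValueError("k_threshold and dpf must be positive")


@dataclass
class ResultsBundle:
    indices_table: pd.DataFrame
    feature_table: pd.DataFrame
    stats_report: pd.DataFrame
    regression: Optional[dict]
    synergy_count: Optional[int]
    synergy_count_warning: bool
    exclusion_log: pd.DataFrame
    run_info: dict = field(default_factory=dict)


INDEX_COLUMNS = ("ssi", "c_v", "c_t", "li_pmc", "li_m1", "li_s1")


def _control_hand(arm: str) -> str:
    """Controls' block labels: unaffected = dominant, affected = non-dominant."""
    return "dominant" if arm == "unaffected" else "non-dominant"


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    if config.dataset_path is not None:
        profiles, truths, sessions = read_dataset(config.dataset_path)
    else:
        profiles, truths, sessions = simulate_dataset(
            config.simulation, with_fnirs=not config.skip_fnirs)
    region_map = (RegionMap.from_yaml(config.region_map_path)
                  if config.region_map_path else RegionMap.default())
    by_id = {p.subject_id: p for p in profiles}

    # ---- sEMG arm: envelopes, lifts, per-lift synergies -------------------
    models: dict[tuple[str, str], list] = {}
    vaf_by_subject: dict[str, dict[int, float]] = {}
    excl_rows = []
    synergy_count = None
    warning = False
    if not config.skip_emg:
        vaf_acc: dict[str, dict[int, list]] = {}
        for p in profiles:
            for arm in ARMS:
                ses = sessions.get((p.subject_id, "emg", arm))
                if ses is None:
                    continue
                lifts, excl = preprocess_session(ses)
                for e in excl:
                    excl_rows.append({"subject_id": p.subject_id, "arm": arm,
                                      "lift_index": e.lift_index, "rule": e.rule,
                                      "duration_s": e.duration_s,
                                      "plateau_force": e.plateau_force})
                per_lift = []
                for seg in lifts:
                    for n in range(1, config.max_synergies + 1):
                        m = mcr_als_decompose(seg.X, n)
                        vaf_acc.setdefault(p.subject_id, {}).setdefault(n, []).append(m.vaf)
                        if n == 1:
                            per_lift.append(m)
                models[(p.subject_id, arm)] = per_lift
        vaf_by_subject = {
            sid: {n: float(np.mean(v)) for n, v in d.items()}
            for sid, d in vaf_acc.items()
        }
        if vaf_by_subject:
            synergy_count, warning = select_synergy_count(
                vaf_by_subject, {p.subject_id: p.group for p in profiles
                                 if p.subject_id in vaf_by_subject},
                threshold=config.vaf_threshold)

        # control-group baselines, split by hand
        baselines = {}
        for arm in ARMS:
            ctrl = {p.subject_id: models.get((p.subject_id, arm), [])
                    for p in profiles if p.group == "control"
                    and models.get((p.subject_id, arm))}
            if ctrl:
                baselines[arm] = compute_baseline(ctrl, hand=_control_hand(arm))

    # ---- fNIRS arm: betas and laterality ----------------------------------
    li_results: dict[tuple[str, str], dict] = {}
    if not config.skip_fnirs:
        for p in profiles:
            for arm in ARMS:
                ses = sessions.get((p.subject_id, "fnirs", arm))
                if ses is None:
                    continue
                beta, _ = process_session(ses, k_threshold=config.k_threshold,
                                          dpf=config.dpf)
                beta = normalize_lesion_orientation(beta, p.orientation_side,
                                                    region_map)
                li = laterality_index(beta, region_map, moving_arm=arm)
                li_results[(p.subject_id, arm)] = li.as_dict()

    # ---- per subject-arm index table --------------------------------------
    rows = []
    for p in profiles:
        for arm in ARMS:
            row = {"subject_id": p.subject_id, "group": p.group, "arm": arm,
                   "ssi": np.nan, "c_v": np.nan, "c_t": np.nan,
                   "li_pmc": np.nan, "li_m1": np.nan, "li_s1": np.nan,
                   "mvc": np.nan, "lifts_used": 0}
            emg_ses = sessions.get((p.subject_id, "emg", arm))
            if emg_ses is not None:
                row["mvc"] = float(np.mean(emg_ses.mvc_trials))
            ms = models.get((p.subject_id, arm), [])
            if ms and not config.skip_emg and baselines.get(arm) is not None:
                bl = baselines[arm]
                agg = aggregate_indices(
                    [m.V[:, 0] for m in ms], [m.T[0, :] for m in ms],
                    bl.V_B, bl.T_B, arm=arm)
                row.update({"ssi": np.nan if agg.ssi is None else agg.ssi,
                            "c_v": agg.c_v, "c_t": agg.c_t,
                            "lifts_used": agg.lifts_used})
            li = li_results.get((p.subject_id, arm))
            if li is not None:
                row.update({"li_pmc": li["PMC"], "li_m1": li["M1"],
                            "li_s1": li["S1"]})
            rows.append(row)
    indices_table = pd.DataFrame(rows)

    # ---- feature table and statistics -------------------------------------
    subj_df = pd.DataFrame([{
        "subject_id": p.subject_id, "group": p.group, "age": p.age,
        "days_post_stroke": p.days_post_stroke,
        "fmul": np.nan if p.fmul_true is None else p.fmul_true,
    } for p in profiles])
    feature_table = build_feature_table(indices_table, subj_df,
                                        ratio_direction=config.ratio_direction)
    if config.skip_fnirs:
        li_cols = [c for c in feature_table.columns if c.startswith("LI_")]
        feature_table = feature_table.drop(columns=li_cols)

    stats_rows = []
    for col in INDEX_COLUMNS:
        if col.startswith("li") and config.skip_fnirs:
            continue
        sub = indices_table.dropna(subset=[col])
        pat_af = sub[(sub.group == "patient") & (sub.arm == "affected")][col].to_numpy()
        pat_un = sub[(sub.group == "patient") & (sub.arm == "unaffected")][col].to_numpy()
        ctl_af = sub[(sub.group == "control") & (sub.arm == "affected")][col].to_numpy()
        if pat_af.size and ctl_af.size:
            r = compare_two_samples(pat_af, ctl_af)
            stats_rows.append({"index": col, "comparison": "patient-affected vs control-nondominant",
                               "test": r.test_name, "statistic": r.statistic,
                               "p_value": r.p_value})
        if pat_af.size and pat_af.size == pat_un.size and pat_af.size >= 2:
            r = compare_two_samples(pat_af, pat_un, paired=True)
            stats_rows.append({"index": col, "comparison": "patient affected vs unaffected (paired)",
                               "test": r.test_name, "statistic": r.statistic,
                               "p_value": r.p_value})
        if sub.group.nunique() == 2 and sub.arm.nunique() == 2:
            srh = scheirer_ray_hare(sub[col].to_numpy(), sub.group.to_numpy(),
                                    sub.arm.to_numpy())
            for eff, name in (("factor_a", "group"), ("factor_b", "arm"),
                              ("interaction", "group x arm")):
                r = srh[eff]
                stats_rows.append({"index": col, "comparison": f"SRH {name}",
                                   "test": r.test_name, "statistic": r.statistic,
                                   "p_value": r.p_value})
    stats_report = pd.DataFrame(stats_rows)

    # ---- regression --------------------------------------------------------
    regression = None
    candidates = [c for c in feature_table.columns
                  if c not in ("subject_id", "group", "FMul")]
    patients = feature_table[feature_table.group == "patient"]
    complete = patients.dropna(subset=["FMul", *candidates])
    if len(complete) >= config.subset_size + 2:
        res = exhaustive_subset_search(patients, subset_size=config.subset_size,
                                       predictors=candidates)
        fitted, n_above = predict_scores(
            res, feature_table[feature_table.group == "control"])
        regression = {
            "selected": list(res.selected),
            "B": [float(b) for b in res.B],
            "beta_std": [float(b) for b in res.beta_std],
            "p_coef": [float(p) for p in res.p_coef],
            "p_model": float(res.p_model),
            "r2_adj": float(res.r2_adj),
            "n_obs": res.n_obs,
            "n_models_evaluated": res.n_models_evaluated,
            "control_fitted": [None if pd.isna(v) else float(v) for v in fitted],
            "controls_above_60": n_above,
        }

    run_info = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed if config.simulation is None else config.simulation.seed,
        "skip_fnirs": config.skip_fnirs, "skip_emg": config.skip_emg,
        "k_threshold": config.k_threshold, "dpf": config.dpf,
        "ratio_direction": config.ratio_direction,
    }
    return ResultsBundle(
        indices_table=indices_table, feature_table=feature_table,
        stats_report=stats_report, regression=regression,
        synergy_count=synergy_count, synergy_count_warning=warning,
        exclusion_log=pd.DataFrame(
            excl_rows, columns=["subject_id", "arm", "lift_index", "rule",
                                "duration_s", "plateau_force"]),
        run_info=run_info,
    )


def write_results(bundle: ResultsBundle, out_dir) -> Path:
    """Write the bundle as CSV/JSON files plus a parameter log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.indices_table.to_csv(out / "indices.csv", index=False)
    bundle.feature_table.to_csv(out / "features.csv", index=False)
    bundle.stats_report.to_csv(out / "stats.csv", index=False)
    bundle.exclusion_log.to_csv(out / "exclusions.csv", index=False)
    with open(out / "regression.json", "w") as fh:
        json.dump(bundle.regression, fh, indent=1, sort_keys=True)
    with open(out / "run_log.json", "w") as fh:
        json.dump({**bundle.run_info,
                   "synergy_count": bundle.synergy_count,
                   "synergy_count_warning": bundle.synergy_count_warning},
                  fh, indent=1, sort_keys=True)
    return out
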