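"""Fugl-Meyer upper-limb (FMul) score modelling.

A 21-predictor feature table per subject — laterality indices per region for
both moving arms, synergy indices per arm, unaffected/affected ratios of
each index family, age, days post stroke and the MVC force ratio F_r — is
searched exhaustively for the 4-predictor ordinary-least-squares model of
FMul with the highest adjusted R^2 (C(21,4) = 5985 candidate models).  The
model is fitted on patient rows and then applied out-of-sample to controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

PREDICTORS = (
    "LI_PMC_af", "LI_M1_af", "LI_S1_af",
    "LI_PMC_un", "LI_M1_un", "LI_S1_un",
    "SSI_af", "SSI_un", "C_V_af", "C_V_un", "C_T_af", "C_T_un",
    "LI_PMC_r", "LI_M1_r", "LI_S1_r", "SSI_r", "C_V_r", "C_T_r",
    "age", "days_post_stroke", "F_r",
)
RESPONSE = "FMul"

_RATIOS = {
    "LI_PMC_r": ("LI_PMC_un", "LI_PMC_af"),
    "LI_M1_r": ("LI_M1_un", "LI_M1_af"),
    "LI_S1_r": ("LI_S1_un", "LI_S1_af"),
    "SSI_r": ("SSI_un", "SSI_af"),
    "C_V_r": ("C_V_un", "C_V_af"),
    "C_T_r": ("C_T_un", "C_T_af"),
}


@dataclass
class RegressionResult:
    selected: tuple
    B: np.ndarray                # intercept + coefficients
    beta_std: np.ndarray         # standardized coefficients
    p_coef: np.ndarray
    p_model: float
    r2: float
    r2_adj: float
    n_obs: int
    n_models_evaluated: int = 1


def build_feature_table(
    per_arm: pd.DataFrame,
    subjects: pd.DataFrame,
    ratio_direction: str = "unaffected/affected",
) -> pd.DataFrame:
    """Assemble the 21-predictor table, one row per subject.

    ``per_arm`` must hold one row per subject-arm with columns subject_id,
    arm ('affected'/'unaffected'; controls' non-dominant/dominant map onto
    these), ssi, c_v, c_t, li_pmc, li_m1, li_s1 and mvc.  ``subjects`` holds
    subject_id, group, age, days_post_stroke, fmul.  Ratios are
    unaffected/affected by default; an affected-side zero makes the ratio
    missing.  Controls carry days_post_stroke = 0.
    """
    if ratio_direction not in ("unaffected/affected", "affected/unaffected"):
        raise ValueError(f"bad ratio direction {ratio_direction!r}")
    base = {"ssi": "SSI", "c_v": "C_V", "c_t": "C_T",
            "li_pmc": "LI_PMC", "li_m1": "LI_M1", "li_s1": "LI_S1"}
    rows = []
    for _, subj in subjects.iterrows():
        sid = subj.subject_id
        row: dict = {"subject_id": sid, "group": subj.group,
                     "age": float(subj.age),
                     "days_post_stroke": 0.0 if subj.group == "control"
                     else float(subj.days_post_stroke),
                     RESPONSE: float(subj.fmul) if pd.notna(subj.fmul) else np.nan}
        arms = {a.arm: a for _, a in per_arm[per_arm.subject_id == sid].iterrows()}
        for col, name in base.items():
            for arm, suffix in (("affected", "af"), ("unaffected", "un")):
                v = arms[arm][col] if arm in arms else np.nan
                row[f"{name}_{suffix}"] = float(v) if pd.notna(v) else np.nan
        for rname, (un_col, af_col) in _RATIOS.items():
            un, af = row[un_col], row[af_col]
            num, den = (un, af) if ratio_direction == "unaffected/affected" else (af, un)
            row[rname] = num / den if pd.notna(num) and pd.notna(den) and den != 0 else np.nan
        mvc_un = arms["unaffected"]["mvc"] if "unaffected" in arms else np.nan
        mvc_af = arms["affected"]["mvc"] if "affected" in arms else np.nan
        num, den = (mvc_un, mvc_af) if ratio_direction == "unaffected/affected" else (mvc_af, mvc_un)
        row["F_r"] = num / den if pd.notna(num) and pd.notna(den) and den != 0 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    return table[["subject_id", "group", RESPONSE, *PREDICTORS]]


def fit_linear_model(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = RESPONSE,
) -> RegressionResult:
    """OLS fit of the response on the given predictors, with inference.

    Reports unstandardized coefficients B, standardized coefficients
    beta_j = B_j * sd(x_j)/sd(y), per-coefficient t-test p-values, the
    model F-test p-value and adjusted R^2.
    """
    cols = [response, *predictors]
    data = table[cols].dropna()
    n, k = len(data), len(predictors)
    if n < k + 2:
        raise ValueError(f"only {n} complete rows for {k} predictors")
    X = data[list(predictors)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.cond(Xd) > 1e10:
        raise ValueError("collinear predictors (condition number > 1e10)")
    fit = sm.OLS(y, Xd).fit()
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    return RegressionResult(
        selected=tuple(predictors),
        B=np.asarray(fit.params),
        beta_std=np.asarray(fit.params[1:]) * sx / sy,
        p_coef=np.asarray(fit.pvalues[1:]),
        p_model=float(fit.f_pvalue) if k >= 1 else np.nan,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        n_obs=n,
    )


def exhaustive_subset_search(
    table: pd.DataFrame,
    subset_size: int = 4,
    predictors: Sequence[str] = PREDICTORS,
    response: str = RESPONSE,
) -> RegressionResult:
    """Best-subset selection by adjusted R^2 over all predictor combinations.

    Every C(len(predictors), subset_size) subset is fitted by OLS on rows
    with complete data for ALL candidate predictors (listwise deletion once,
    so subsets compete on identical rows); ties resolve to the first subset
    in lexicographic enumeration order.  The winner is refitted with full
    inference.
    """
    predictors = sorted(predictors)
    data = table[[response, *predictors]].dropna()
    n = len(data)
    if n < subset_size + 2:
        raise ValueError(f"only {n} complete rows; need at least {subset_size + 2}")
    X_all = data[predictors].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    ones = np.ones((n, 1))

    best_adj, best_subset, count = -np.inf, None, 0
    for combo in combinations(range(len(predictors)), subset_size):
        Xd = np.hstack([ones, X_all[:, combo]])
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss = float(np.sum((y - Xd @ coef) ** 2))
        r2 = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - subset_size - 1)
        if adj > best_adj + 1e-15:
            best_adj, best_subset = adj, combo
        count += 1

    winner = [predictors[i] for i in best_subset]
    sub = data.rename(columns=str)  # complete-case frame reused for inference
    result = fit_linear_model(sub, winner, response=response)
    result.n_models_evaluated = count
    return result


def predict_scores(
    result: RegressionResult,
    table: pd.DataFrame,
    threshold: float = 60.0,
) -> tuple[pd.Series, int]:
    """Apply a fitted linear model to rows of a feature table.

    Returns fitted values (index-aligned to ``table``; missing predictors
    propagate NaN) and the count of fitted scores above ``threshold``.
    """
    X = table[list(result.selected)].to_numpy(dtype=float)
    fitted = result.B[0] + X @ result.B[1:]
    series = pd.Series(fitted, index=table.index, name="fmul_fitted")
    return series, int((series > threshold).sum())
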