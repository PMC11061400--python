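"""Muscle-synergy extraction by multivariate curve resolution (MCR-ALS).

Each lift is a non-negative matrix ``X`` (p=5 muscles x q=50 time-normalized
samples) factorised as ``X ~ V @ T`` with non-negative base vectors ``V``
(p x n, unit-norm columns) and time profiles ``T`` (n x q).  The alternating
least-squares solver is initialised deterministically from SIMPLISMA-style
pure variables, so repeated runs give identical factors — the property that
motivates MCR-ALS over randomly-initialised NMF for clinical reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls


@dataclass
class SynergyModel:
    """Result of one MCR-ALS decomposition.

    V columns have unit Euclidean norm (scale absorbed into T); E is the raw
    residual X - V @ T.
    """

    V: np.ndarray
    T: np.ndarray
    E: np.ndarray
    vaf: float
    n: int
    iterations: int
    converged: bool


@dataclass
class BaselineSynergy:
    """Control-group reference synergy for one hand (dominant/non-dominant).

    ``V_B`` is unit-norm, ``T_B`` unit-energy (sum of squares = 1).
    """

    V_B: np.ndarray
    T_B: np.ndarray
    hand: str
    n_subjects: int = 0
    skipped: list = field(default_factory=list)


def compute_vaf(X: np.ndarray, M: np.ndarray) -> float:
    """Variance accounted for by a reconstruction M of the data X.

    VAF = 1 - ||X - M||^2 / ||X - mean(X)||^2 where mean(X) replicates the
    column means of X (each column of the centring matrix holds that
    column's mean).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs M {M.shape}")
    col_mean = X.mean(axis=0, keepdims=True)
    denom = float(np.sum((X - col_mean) ** 2))
    if denom <= 0.0:
        raise ValueError("VAF undefined: X is constant within every column")
    return 1.0 - float(np.sum((X - M) ** 2)) / denom


def _purity_init(X: np.ndarray, n: int) -> np.ndarray:
    """Pick n pure columns of X as the initial base vectors.

    Purity of column j is std_j / (mean_j + offset) with offset equal to 5%
    of the largest column mean (the SIMPLISMA noise guard).  After each pick
    the remaining columns are weighted by the fraction of their norm that is
    orthogonal to the span of the columns already chosen, so successive
    picks are maximally independent.
    """
    p, q = X.shape
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    offset = 0.05 * float(mean.max())
    purity = std / (mean + offset + 1e-300)

    picked: list[int] = []
    basis = np.zeros((p, 0))
    for _ in range(n):
        if basis.shape[1] > 0:
            # component of each column orthogonal to already-picked columns
            proj = basis @ (basis.T @ X)
            resid = X - proj
            norms = np.linalg.norm(X, axis=0)
            w = np.linalg.norm(resid, axis=0) / np.where(norms > 0, norms, 1.0)
        else:
            w = np.ones(q)
        score = purity * w
        score[picked] = -np.inf
        j = int(np.argmax(score))
        picked.append(j)
        col = X[:, j].astype(float)
        if np.linalg.norm(col) == 0:
            col = np.ones(p)
        # extend an orthonormal basis of the picked columns
        if basis.shape[1] > 0:
            col = col - basis @ (basis.T @ col)
        nrm = np.linalg.norm(col)
        if nrm > 1e-12:
            basis = np.column_stack([basis, col / nrm])
    V0 = X[:, picked].astype(float).copy()
    V0[:, np.linalg.norm(V0, axis=0) == 0] = 1.0
    return V0


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A @ Z - B|| with Z >= 0, column-wise.

    Columns whose unconstrained least-squares solution is already
    non-negative are kept as-is; only violating columns fall back to the
    active-set NNLS solver.
    """
    Z, *_ = np.linalg.lstsq(A, B, rcond=None)
    bad = np.where((Z < -1e-12).any(axis=0))[0]
    for j in bad:
        Z[:, j], _ = nnls(A, B[:, j])
    return np.clip(Z, 0.0, None)


def mcr_als_decompose(
    X: np.ndarray,
    n: int,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SynergyModel:
    """Factorise a non-negative lift matrix into n synergies.

    Alternates exact non-negative least-squares solves for T given V and V
    given T, starting from pure-variable columns, until the relative VAF
    change drops below ``tol``.  Deterministic: no random initialisation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    p, q = X.shape
    if not 1 <= n <= min(p, q):
        raise ValueError(f"synergy count n={n} outside [1, {min(p, q)}]")

    V = _purity_init(X, n)
    vaf_prev = -np.inf
    obj_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T = _nnls_columns(V, X)
        V = _nnls_columns(T.T, X.T).T
        # guard against an all-zero synergy killing the next solve
        dead = np.linalg.norm(V, axis=0) == 0
        if dead.any():
            V[:, dead] = 1e-12
        M = V @ T
        obj = float(np.sum((X - M) ** 2))
        if obj > obj_prev + 1e-9 * max(obj_prev, 1.0):  # ALS must not diverge
            raise RuntimeError("MCR-ALS objective increased")
        obj_prev = obj
        vaf = compute_vaf(X, M)
        if abs(vaf - vaf_prev) < tol:
            converged = True
            break
        vaf_prev = vaf

    norms = np.linalg.norm(V, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    V = V / norms
    T = T * norms[:, None]
    M = V @ T
    return SynergyModel(
        V=V,
        T=T,
        E=X - M,
        vaf=compute_vaf(X, M),
        n=n,
        iterations=it,
        converged=converged,
    )


def select_synergy_count(
    vaf_by_subject: dict[str, dict[int, float]],
    group_by_subject: dict[str, str],
    threshold: float = 0.80,
) -> tuple[int, bool]:
    """Smallest synergy count at which a strict majority of BOTH groups fit.

    ``vaf_by_subject`` maps subject -> {n: subject-level VAF}, where the
    subject-level VAF is the mean over retained lifts.  Returns (n, warning):
    warning is True when even the largest candidate n fails the criterion.
    """
    if not vaf_by_subject:
        raise ValueError("no subjects")
    groups: dict[str, list[str]] = {}
    for sid, g in group_by_subject.items():
        groups.setdefault(g, []).append(sid)
    candidates = sorted({n for d in vaf_by_subject.values() for n in d})
    for n in candidates:
        ok = True
        for members in groups.values():
            passing = sum(1 for s in members if vaf_by_subject[s].get(n, 0.0) > threshold)
            if not passing * 2 > len(members):  # strict majority
                ok = False
                break
        if ok:
            return n, False
    return candidates[-1], True


def compute_baseline(
    models_by_subject: dict[str, Sequence[SynergyModel]],
    hand: str,
) -> BaselineSynergy:
    """Average control-group synergies into a baseline (V_B, T_B) for a hand.

    Per subject the unit-normalised per-lift V (and unit-energy T) are
    averaged across retained lifts; the across-subject mean is then
    renormalised.  Only n=1 models are expected.
    """
    if not models_by_subject:
        raise ValueError("no control subjects for baseline")
    v_subj, t_subj, skipped = [], [], []
    for sid, models in models_by_subject.items():
        vs, ts = [], []
        for m in models:
            if m.n != 1:
                raise ValueError("baseline requires single-synergy models")
            v = m.V[:, 0]
            t = m.T[0, :]
            vn = np.linalg.norm(v)
            te = np.sqrt(np.sum(t**2))
            if vn == 0 or te == 0:
                continue
            vs.append(v / vn)
            ts.append(t / te)
        if not vs:
            skipped.append(sid)
            continue
        v_subj.append(np.mean(vs, axis=0))
        t_subj.append(np.mean(ts, axis=0))
    if not v_subj:
        raise ValueError("no retained lifts in any control subject")
    V_B = np.mean(v_subj, axis=0)
    T_B = np.mean(t_subj, axis=0)
    V_B = V_B / np.linalg.norm(V_B)
    T_B = T_B / np.sqrt(np.sum(T_B**2))
    return BaselineSynergy(V_B=V_B, T_B=T_B, hand=hand, n_subjects=len(v_subj), skipped=skipped)
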