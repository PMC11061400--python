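"""Per-subject muscle-synergy indices.

Three scalar indices summarise how a subject's per-lift synergies behave:

* ``SSI`` — synergy stability: mean Pearson correlation of the base vector
  over all ordered pairs of lifts (1 = perfectly repeatable pattern).
* ``C_V`` — closeness of the base vector to the control-group baseline,
  as cosine similarity (non-negative vectors give values in [0, 1]).
* ``C_T`` — closeness of the time profile to the baseline profile, as the
  maximum over circular lags of the normalised cross-correlation, so a
  pure timing shift does not count as dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class SubjectSynergyIndices:
    arm: str
    ssi: Optional[float]
    c_v: Optional[float]
    c_t: Optional[float]
    lifts_used: int


def synergy_stability_index(V_list: Sequence[np.ndarray], K: int = 1) -> float:
    """Mean pairwise Pearson correlation of base vectors across lifts.

    SSI = (1 / (K^2 i (i-1))) * sum over ordered pairs l != q of r(V_l, V_q);
    with K = 1 this is the plain mean over the i(i-1) ordered pairs.
    """
    if K != 1:
        raise NotImplementedError("multi-synergy SSI matching not supported")
    V = [np.asarray(v, dtype=float).ravel() for v in V_list]
    i = len(V)
    if i < 2:
        raise ValueError("SSI undefined for fewer than 2 lifts")
    for idx, v in enumerate(V):
        if np.std(v) == 0:
            raise ValueError(f"lift {idx}: constant base vector, Pearson r undefined")
    total = 0.0
    for l in range(i):
        for q in range(i):
            if l == q:
                continue
            total += float(np.corrcoef(V[l], V[q])[0, 1])
    return total / (K**2 * i * (i - 1))


def closeness_vector(V_i: np.ndarray, V_B: np.ndarray) -> float:
    """Cosine similarity between a lift's base vector and the baseline."""
    a = np.asarray(V_i, dtype=float).ravel()
    b = np.asarray(V_B, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("closeness undefined for a zero vector")
    return float(a @ b / (na * nb))


def closeness_time(T_i: np.ndarray, T_B: np.ndarray) -> float:
    """Max-over-lag normalised circular cross-correlation of time profiles.

    C_T = max_tau sum_m T_i(m) T_B(m+tau mod q) / sqrt(sum T_i^2 * sum T_B^2).
    """
    a = np.asarray(T_i, dtype=float).ravel()
    b = np.asarray(T_B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    ea, eb = np.sum(a**2), np.sum(b**2)
    if ea == 0 or eb == 0:
        raise ValueError("closeness undefined for a zero profile")
    # circular cross-correlation for all lags at once via the FFT
    cc = np.fft.irfft(np.fft.rfft(a).conj() * np.fft.rfft(b), n=a.size)
    return float(cc.max() / np.sqrt(ea * eb))


def aggregate_indices(
    V_list: Sequence[np.ndarray],
    T_list: Sequence[np.ndarray],
    V_B: np.ndarray,
    T_B: np.ndarray,
    arm: str,
) -> SubjectSynergyIndices:
    """Combine per-lift synergies into one index set for a subject-arm.

    c_v and c_t are means over retained lifts; ssi is computed once over all
    retained lifts (needs at least two, else reported missing).
    """
    if len(V_list) != len(T_list):
        raise ValueError("V_list and T_list must align")
    n = len(V_list)
    if n == 0:
        return SubjectSynergyIndices(arm=arm, ssi=None, c_v=None, c_t=None, lifts_used=0)
    c_v = float(np.mean([closeness_vector(v, V_B) for v in V_list]))
    c_t = float(np.mean([closeness_time(t, T_B) for t in T_list]))
    ssi = synergy_stability_index(V_list) if n >= 2 else None
    return SubjectSynergyIndices(arm=arm, ssi=ssi, c_v=c_v, c_t=c_t, lifts_used=n)
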