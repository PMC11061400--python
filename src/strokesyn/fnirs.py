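"""fNIRS processing chain: raw intensity -> optical density -> motion
artifact correction -> band-pass -> modified Beer-Lambert conversion ->
per-channel GLM activation coefficients.

Only the oxygenated-hemoglobin (HbO) series feeds downstream laterality
analysis; HbR is computed by the same linear MBLL solve but not consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pywt
from scipy import signal
from scipy.stats import kurtosis

N_CHANNELS = 24
WAVELENGTHS = (830.0, 704.0)
SOURCE_DETECTOR_MM = 30.0

# molar extinction coefficients, 1/(M*cm), (HbO, HbR) rows per wavelength.
# Standard tabulated values; the simulator uses the same table, so analyses
# are forward/inverse-consistent regardless of the exact source compilation.
DEFAULT_EXTINCTION = {
    830.0: (974.0, 693.0),
    704.0: (340.0, 1699.0),
}
DEFAULT_DPF = 6.0


@dataclass
class FnirsSession:
    """Dual-wavelength intensity recording for one arm's block."""

    intensity: np.ndarray        # (24, 2, n_samples), wavelength order = WAVELENGTHS
    fs: float                    # 10 Hz
    events: pd.DataFrame         # onset_s, duration_s, kind
    wavelengths: tuple = WAVELENGTHS
    source_detector_mm: float = SOURCE_DETECTOR_MM
    arm: str = "unaffected"

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must be (channels, 2 wavelengths, samples)")
        if self.intensity.shape[0] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {self.intensity.shape[0]}")


@dataclass
class HemoTimeSeries:
    hbo: np.ndarray              # (24, n_samples), uM
    hbr: np.ndarray              # (24, n_samples), uM — computed, unused downstream


@dataclass
class BetaMap:
    beta: np.ndarray             # (24,)
    design_info: dict = field(default_factory=dict)


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density relative to the temporal mean: OD = -ln(I / mean(I))."""
    I = np.asarray(intensity, dtype=float)
    if (I <= 0).any():
        bad = np.argwhere(I <= 0)[0]
        raise ValueError(f"non-positive intensity sample at channel index {tuple(bad)}")
    mean = I.mean(axis=-1, keepdims=True)
    return -np.log(I / mean)


def _despike_level(coeffs: np.ndarray, k_threshold: float) -> np.ndarray:
    c = coeffs.copy()
    alive = np.ones(c.size, dtype=bool)
    # Pearson kurtosis (normal = 3) of the surviving coefficients; zero the
    # largest-magnitude one until the ensemble is tame
    for _ in range(c.size):
        if alive.sum() < 4 or np.var(c[alive]) == 0:
            break
        if kurtosis(c[alive], fisher=False) <= k_threshold:
            break
        j = np.flatnonzero(alive)[np.argmax(np.abs(c[alive]))]
        c[j] = 0.0
        alive[j] = False
    return c


def kurtosis_wavelet_correct(
    od: np.ndarray,
    k_threshold: float = 3.3,
    wavelet: str = "db5",
    levels: int = 5,
) -> np.ndarray:
    """Kurtosis-gated wavelet despiking of motion artifacts.

    Each series is decomposed with a multilevel DWT (Daubechies-5, symmetric
    extension); detail levels whose coefficient kurtosis exceeds the
    threshold have their largest-magnitude coefficients zeroed until the
    kurtosis is tame, and the series is rebuilt at its original length.
    Heavy-tailed (spiky) levels are edited; Gaussian levels pass unchanged.
    """
    od = np.asarray(od, dtype=float)
    flat = od.reshape(-1, od.shape[-1])
    wav = pywt.Wavelet(wavelet)
    n = od.shape[-1]
    if n < wav.dec_len:
        raise ValueError(f"series of length {n} shorter than {wavelet} filter support")
    out = np.empty_like(flat)
    for i, x in enumerate(flat):
        coeffs = pywt.wavedec(x, wav, mode="symmetric", level=levels)
        new = [coeffs[0]] + [_despike_level(d, k_threshold) for d in coeffs[1:]]
        out[i] = pywt.waverec(new, wav, mode="symmetric")[:n]
    return out.reshape(od.shape)


def bandpass_hemo(series: np.ndarray, fs: float, band=(0.01, 0.08), order: int = 3) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass (default 0.01-0.08 Hz)."""
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} too low for band edge {band[1]} Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def extinction_matrix(
    wavelengths=WAVELENGTHS, table: Optional[dict] = None
) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR), in 1/(uM*mm)."""
    table = DEFAULT_EXTINCTION if table is None else table
    # 1/(M*cm) -> 1/(uM*mm): 1e-6 per uM, 0.1 per mm
    return np.array([table[w] for w in wavelengths], dtype=float) * 1e-7


def mbll_convert(
    od: np.ndarray,
    dpf: float = DEFAULT_DPF,
    distance_mm: float = SOURCE_DETECTOR_MM,
    wavelengths=WAVELENGTHS,
    extinction: Optional[dict] = None,
) -> HemoTimeSeries:
    """Solve the modified Beer-Lambert law for (dHbO, dHbR) per channel.

    [dOD(l1); dOD(l2)] = d * DPF * E @ [dHbO; dHbR], concentrations in uM.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[1] != 2:
        raise ValueError("od must be (channels, 2 wavelengths, samples)")
    E = extinction_matrix(wavelengths, extinction)
    if abs(np.linalg.det(E)) < 1e-30:
        raise ValueError("singular extinction matrix")
    A = distance_mm * dpf * E
    Ainv = np.linalg.inv(A)
    conc = np.einsum("ij,cjs->cis", Ainv, od)
    return HemoTimeSeries(hbo=conc[:, 0, :], hbr=conc[:, 1, :])


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    dpf: float = DEFAULT_DPF,
    distance_mm: float = SOURCE_DETECTOR_MM,
    wavelengths=WAVELENGTHS,
    extinction: Optional[dict] = None,
) -> np.ndarray:
    """Exact inverse of :func:`mbll_convert`: concentrations -> dOD."""
    E = extinction_matrix(wavelengths, extinction)
    A = distance_mm * dpf * E
    conc = np.stack([hbo, hbr], axis=1)
    return np.einsum("ij,cjs->cis", A, conc)


def canonical_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak."""
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, peak) - ratio * gamma_dist.pdf(t, undershoot)
    m = h.max()
    return h / m if m > 0 else h


def task_regressor(
    events: pd.DataFrame,
    n_samples: int,
    fs: float,
    bandpass: bool = True,
) -> np.ndarray:
    """Boxcar of task blocks convolved with the canonical HRF.

    Filtered with the same 0.01-0.08 Hz band-pass applied to the data so the
    GLM stays unbiased within the analysis band.
    """
    box = np.zeros(n_samples)
    t = np.arange(n_samples) / fs
    for _, row in events[events["kind"] == "task"].iterrows():
        box[(t >= row.onset_s) & (t < row.onset_s + row.duration_s)] = 1.0
    hrf = canonical_hrf(np.arange(0, 32.0, 1.0 / fs))
    reg = np.convolve(box, hrf)[:n_samples] / fs
    if bandpass:
        reg = bandpass_hemo(reg, fs)
    return reg


def fit_glm(hbo: np.ndarray, events: pd.DataFrame, fs: float,
            bandpass_regressor: bool = True) -> BetaMap:
    """Per-channel OLS of HbO on the task regressor (+ intercept)."""
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    reg = task_regressor(events, hbo.shape[-1], fs, bandpass=bandpass_regressor)
    X = np.column_stack([reg, np.ones_like(reg)])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("rank-deficient design matrix (constant regressor?)")
    coef, *_ = np.linalg.lstsq(X, hbo.T, rcond=None)
    return BetaMap(beta=coef[0], design_info={
        "regressor": "boxcar*double-gamma HRF",
        "hrf_peak_s": 6.0, "hrf_undershoot_s": 16.0, "undershoot_ratio": 1 / 6,
        "bandpassed": bandpass_regressor,
    })


def process_session(
    session: FnirsSession,
    k_threshold: float = 3.3,
    dpf: float = DEFAULT_DPF,
    extinction: Optional[dict] = None,
) -> tuple[BetaMap, HemoTimeSeries]:
    """Full chain: intensity -> OD -> despike -> band-pass -> MBLL -> GLM."""
    od = intensity_to_od(session.intensity)
    od = kurtosis_wavelet_correct(od, k_threshold=k_threshold)
    od = bandpass_hemo(od, session.fs)
    hemo = mbll_convert(od, dpf=dpf, distance_mm=session.source_detector_mm,
                        wavelengths=session.wavelengths, extinction=extinction)
    beta = fit_glm(hemo.hbo, session.events, session.fs)
    return beta, hemo
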