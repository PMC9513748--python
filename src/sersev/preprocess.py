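"""Spectral preprocessing: baseline removal, denoising, normalization.

The chain applied to every fingerprint, in order:

1. fluorescence background subtraction by asymmetric least squares (ALS):
   the baseline z minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2``
   with iteratively reweighted ``w_i = p`` where ``y_i > z_i`` and
   ``1 - p`` otherwise, so the fit hugs the lower envelope of the spectrum;
2. Savitzky-Golay smoothing (local polynomial least squares);
3. min-max normalization to [0, 1].

Constant (fingerprint-free) spectra cannot be normalized and are dropped
from the cohort rather than propagated as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .core import Cohort
from .errors import ConfigError, DegenerateSpectrumError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ALS smoothness is the second-difference penalty weight (dimensionless;
    1e5 suits fluorescence backgrounds at ~1 cm^-1 spacing); asymmetry is
    the weight given to points above the baseline, in (0, 1).
    """

    als_smoothness: float = 1e5
    als_asymmetry: float = 0.01
    als_max_iter: int = 10
    sg_window: int = 11
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.als_smoothness <= 0:
            raise ConfigError("als_smoothness must be positive")
        if not (0.0 < self.als_asymmetry < 1.0):
            raise ConfigError("als_asymmetry must lie in (0, 1)")
        if self.als_max_iter < 1:
            raise ConfigError("als_max_iter must be >= 1")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ConfigError("sg_window must be an odd count >= 3")
        if not (0 <= self.sg_polyorder < self.sg_window):
            raise ConfigError("sg_polyorder must be < sg_window")


def als_baseline(
    intensities: np.ndarray,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares fluorescence baseline (Eilers-style).

    Iteratively reweighted penalized least squares; iteration stops when
    the weight vector stops changing or after ``max_iter`` passes.
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D intensity vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    n = y.size
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        system = sp.diags(w, format="csc") + penalty
        z = spsolve(system, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def sg_smooth(intensities: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; polynomial edge handling.

    Edges use the polynomial fitted to the first/last full window,
    evaluated off-center ('interp' mode).  This preserves the defining
    property of the filter everywhere: any polynomial of degree <=
    polyorder passes through unchanged (padding schemes such as reflect
    break that at the edges).
    """
    y = np.asarray(intensities, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ConfigError("window must be an odd count >= 3")
    if polyorder >= window:
        raise ConfigError("polyorder must be < window")
    if window > y.size:
        raise ConfigError("window larger than spectrum")
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def minmax_normalize(intensities: np.ndarray) -> np.ndarray:
    """Proportionally compress the intensity range to [0, 1]."""
    y = np.asarray(intensities, dtype=float)
    lo, hi = y.min(), y.max()
    if not hi > lo:
        raise DegenerateSpectrumError("constant spectrum cannot be min-max normalized")
    return (y - lo) / (hi - lo)


@dataclass
class PreprocessLog:
    """Bookkeeping from a cohort preprocessing run."""

    n_input: int = 0
    n_dropped: int = 0
    dropped_ids: list[str] = field(default_factory=list)


def preprocess_spectrum(intensities: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    y = np.asarray(intensities, dtype=float)
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        raise DegenerateSpectrumError("constant spectrum carries no fingerprint")
    baseline = als_baseline(
        intensities, config.als_smoothness, config.als_asymmetry, config.als_max_iter
    )
    corrected = np.asarray(intensities, dtype=float) - baseline
    smoothed = sg_smooth(corrected, config.sg_window, config.sg_polyorder)
    return minmax_normalize(smoothed)


def preprocess_cohort(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> tuple[Cohort, PreprocessLog]:
    """Apply baseline -> smooth -> normalize to every spectrum of a cohort.

    Metadata is untouched; degenerate (constant) spectra are dropped and
    recorded in the returned log.
    """
    config = config or PreprocessConfig()
    log = PreprocessLog(n_input=cohort.n_spectra)
    keep = np.ones(cohort.n_spectra, dtype=bool)
    out = np.empty_like(cohort.intensities)
    for i in range(cohort.n_spectra):
        try:
            out[i] = preprocess_spectrum(cohort.intensities[i], config)
        except DegenerateSpectrumError:
            keep[i] = False
            sid = cohort.meta["spectrum_id"].iloc[i]
            log.dropped_ids.append(sid)
            logger.warning("dropping degenerate spectrum %s", sid)
    log.n_dropped = int((~keep).sum())
    result = Cohort(cohort.grid, cohort.meta[keep], out[keep])
    return result, log
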