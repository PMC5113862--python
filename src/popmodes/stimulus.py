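"""Stimulus-side analyses: STA estimation, logistic LN cells, mode-triggered
averages and separable (rank-1) receptive-field decomposition.

Conventions: stimulus frames are an X x Y x T contrast array aligned with
the raster bins; filters are X x Y x n_lags with lag 0 being the trigger bin
itself and lags increasing into the past.  The LN nonlinearity is

    p(spike) = 1 / (1 + exp(gain * drive - offset)),

kept literally in this form, so *negative* gain gives the conventional
"more drive, more spiking" behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .raster import BinaryRaster

__all__ = [
    "Stimulus",
    "LNModel",
    "compute_sta",
    "mask_sta",
    "filter_drive",
    "fit_ln",
    "ln_probability",
    "simulate_ln_population",
    "mode_triggered_average",
    "separable_approximation",
]


@dataclass
class Stimulus:
    """X x Y x T array of contrast values (e.g. binary +/-1 noise)."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("stimulus must be X x Y x T")
        if not np.isfinite(self.frames).all():
            raise ValueError("stimulus contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.frames.shape[2]


@dataclass
class LNModel:
    """Linear filter + logistic nonlinearity for one cell."""

    filter: np.ndarray  # X x Y x n_lags
    gain: float
    offset: float

    def __post_init__(self) -> None:
        self.filter = np.asarray(self.filter, dtype=float)
        if self.filter.ndim != 3:
            raise ValueError("filter must be X x Y x n_lags")


def _triggered_average(
    trigger: np.ndarray, stim: Stimulus, n_lags: int
) -> np.ndarray:
    trigger = np.asarray(trigger).astype(bool)
    idx = np.nonzero(trigger)[0]
    if idx.size == 0:
        raise ValueError("no trigger events")
    X, Y, T = stim.frames.shape
    out = np.zeros((X, Y, n_lags))
    for lag in range(n_lags):
        sel = idx[idx - lag >= 0]
        if sel.size:
            out[:, :, lag] = stim.frames[:, :, sel - lag].sum(axis=2)
    return out / idx.size


def compute_sta(
    spikes: np.ndarray, stimulus: Stimulus, n_lags: int = 10
) -> np.ndarray:
    """Spike-triggered average: mean stimulus history preceding spikes.

    ``spikes`` is one binary raster row; lag 0 is the spike bin.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if not np.any(spikes):
        raise ValueError("no spikes")
    return _triggered_average(spikes, stimulus, n_lags)


def mode_triggered_average(
    path, mode: int, stimulus: Stimulus, n_lags: int = 10
) -> np.ndarray:
    """Mean stimulus history preceding bins in which ``mode`` was active."""
    p = np.asarray(getattr(path, "path", path))
    trigger = p == mode
    if not trigger.any():
        raise ValueError(f"mode {mode} never active")
    return _triggered_average(trigger, stimulus, n_lags)


def mask_sta(sta: np.ndarray, patch: int = 7) -> np.ndarray:
    """Zero all spatial positions outside a patch centered on the STA peak.

    The peak is the largest |value| over space and lags; the patch is
    clipped at array boundaries.
    """
    if patch % 2 == 0:
        raise ValueError("patch size must be odd")
    sta = np.asarray(sta, dtype=float)
    X, Y, _ = sta.shape
    flat = np.abs(sta).max(axis=2)
    px, py = np.unravel_index(np.argmax(flat), flat.shape)
    half = patch // 2
    out = np.zeros_like(sta)
    x0, x1 = max(0, px - half), min(X, px + half + 1)
    y0, y1 = max(0, py - half), min(Y, py + half + 1)
    out[x0:x1, y0:y1, :] = sta[x0:x1, y0:y1, :]
    return out


def filter_drive(filt: np.ndarray, stimulus: Stimulus) -> np.ndarray:
    """Spatial sum + temporal convolution of filter with stimulus, per bin.

    drive[t] = sum_x sum_lag K[x, lag] * s[x, t - lag]; out-of-range history
    treated as zero.
    """
    X, Y, n_lags = filt.shape
    T = stimulus.n_bins
    drive = np.zeros(T)
    flat_s = stimulus.frames.reshape(X * Y, T)
    flat_k = filt.reshape(X * Y, n_lags)
    for lag in range(n_lags):
        proj = flat_k[:, lag] @ flat_s  # (T,)
        drive[lag:] += proj[: T - lag]
    return drive


def ln_probability(model: LNModel, stimulus: Stimulus) -> np.ndarray:
    drive = filter_drive(model.filter, stimulus)
    z = model.gain * drive - model.offset
    return 1.0 / (1.0 + np.exp(z))


def fit_ln(
    spikes: np.ndarray, stimulus: Stimulus, filt: np.ndarray
) -> tuple[float, float]:
    """Maximum-likelihood (gain, offset) of the logistic LN model.

    The filter is held fixed; per-bin spiking is Bernoulli with
    p = 1/(1 + exp(gain*drive - offset)).  The negative log-likelihood is
    convex in (gain, offset); solved with analytic gradients.
    """
    sigma = np.asarray(spikes, dtype=float)
    drive = filter_drive(filt, stimulus)

    def nll_grad(params):
        gain, offset = params
        z = offset - gain * drive  # p = sigmoid(z)
        # log-likelihood: sum sigma*log p + (1-sigma)*log(1-p)
        nll = float(np.logaddexp(0, z).sum() - (sigma * z).sum())
        resid = 1.0 / (1.0 + np.exp(-z)) - sigma  # p - sigma
        return nll, np.array([-(resid * drive).sum(), resid.sum()])

    res = minimize(nll_grad, x0=np.zeros(2), jac=True, method="L-BFGS-B")
    if not res.success:
        raise RuntimeError(f"LN fit did not converge: {res.message}")
    return float(res.x[0]), float(res.x[1])


def simulate_ln_population(
    models: list[LNModel],
    stimulus: Stimulus,
    seed: int,
    bin_width: float = 0.020,
) -> BinaryRaster:
    """Conditionally independent Bernoulli spiking of LN cells."""
    rng = np.random.default_rng(seed)
    T = stimulus.n_bins
    data = np.zeros((len(models), T), dtype=np.uint8)
    for i, m in enumerate(models):
        p = ln_probability(m, stimulus)
        data[i] = rng.random(T) < p
    return BinaryRaster(data, bin_width)


def separable_approximation(field: np.ndarray) -> dict:
    """Best rank-1 space (x) time approximation of an X x Y x tau field.

    The leading singular triplet of the (space, time) unfolding.  Sign fixed
    so that the temporal factor's largest-magnitude sample is positive; the
    spatial factor absorbs the overall sign.  The residual fraction is
    1 - s1^2 / sum s_k^2.
    """
    field = np.asarray(field, dtype=float)
    X, Y, n_lags = field.shape
    mat = field.reshape(X * Y, n_lags)
    if not np.any(mat):
        raise ValueError("all-zero field")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    spatial = u[:, 0] * s[0]
    temporal = vt[0]
    peak = np.argmax(np.abs(temporal))
    if temporal[peak] < 0:
        temporal = -temporal
        spatial = -spatial
    residual = 1.0 - s[0] ** 2 / (s**2).sum()
    sp = spatial.reshape(X, Y)
    peak_idx = np.unravel_index(np.argmax(np.abs(sp)), sp.shape)
    return {
        "spatial": sp,
        "temporal": temporal,
        "residual_fraction": float(residual),
        "polarity": "on" if sp[peak_idx] > 0 else "off",
    }
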