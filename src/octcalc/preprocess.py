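"""Two-channel network input: log-compressed intensity + attenuation map.

The segmenter consumes polar frames as two channels, both normalized to
``[-1, 1]`` by the exact affine map ``(x - 127.5) / 127.5``:

1. the acquired intensity, log-compressed and rescaled to 8-bit range;
2. a per-pixel depth-resolved attenuation-coefficient estimate computed
   along each A-line, gamma-adjusted and rescaled to 8-bit range.

The attenuation estimate uses the depth-resolved tail-sum form

    mu_hat[i] = I[i] / (2 * dr * sum_{j > i} I[j])

which for a noiseless exponential A-line ``I0 * exp(-2 mu z)`` recovers
``mu`` up to discretisation bias of order ``mu * dr``.  The signal beyond
the imaging window is treated as zero, so the estimate diverges near the
distal end of the line; the final ``attenuation_window`` samples are
masked to zero.  The estimator is derived for linear detector intensity,
so it always runs on the raw frame, never on log-compressed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

NORM_CENTER = 127.5
NORM_SCALE = 127.5


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs; normalization constants are fixed at 127.5."""

    log_compress: bool = True
    gamma: float = 0.5
    attenuation_window: int = 32
    radial_res_mm: float = 0.01
    norm_center: float = NORM_CENTER
    norm_scale: float = NORM_SCALE

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.attenuation_window < 1:
            raise ValueError("attenuation_window must be >= 1")
        if self.radial_res_mm <= 0:
            raise ValueError("radial_res_mm must be positive")


def log_polar(frame: np.ndarray) -> np.ndarray:
    """Log-compress a polar intensity frame and rescale to [0, 255].

    Returns ``255 * (log1p(I) - log1p(min)) / (log1p(max) - log1p(min))``;
    strictly monotone in the input, so pixel ordering is preserved.  A
    constant frame is returned unchanged.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if np.any(frame < 0):
        raise ValueError("log_polar requires nonnegative intensities")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        return frame.copy()
    compressed = np.log1p(frame)
    c_lo, c_hi = np.log1p(lo), np.log1p(hi)
    # clip guards float round-off at the endpoints
    return np.clip(255.0 * (compressed - c_lo) / (c_hi - c_lo), 0.0, 255.0)


def attenuation_coefficient(
    frame: np.ndarray, radial_res_mm: float, attenuation_window: int = 32
) -> np.ndarray:
    """Raw depth-resolved attenuation estimate in 1/mm, per pixel.

    ``frame`` is a polar frame with the radial axis first (rows = depth,
    columns = A-lines).  A-lines whose tail sum is zero (e.g. an all-zero
    line) yield zeros instead of a division blow-up, and the last
    ``attenuation_window`` samples of every line are zeroed because their
    tail sums are unreliable.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D (n_samples, n_alines)")
    # Exclusive tail sums along depth: tail[i] = sum_{j > i} I[j].
    rev_cumsum = np.cumsum(frame[::-1], axis=0)[::-1]
    tail = rev_cumsum - frame
    mu = np.zeros_like(frame)
    valid = tail > 0
    mu[valid] = frame[valid] / (2.0 * radial_res_mm * tail[valid])
    w = min(attenuation_window, frame.shape[0])
    mu[frame.shape[0] - w :, :] = 0.0
    return mu


def attenuation_channel(frame: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Gamma-adjusted attenuation channel scaled to [0, 255].

    The raw per-pixel estimate is scaled to [0, 1] by a robust frame
    maximum (99.5th percentile, so isolated speckle spikes do not crush
    tissue contrast), clipped, raised to ``cfg.gamma`` (the default 0.5
    brightens weakly attenuating tissue), and rescaled to 8-bit range.
    An all-zero frame maps to an all-zero channel.
    """
    mu = attenuation_coefficient(frame, cfg.radial_res_mm, cfg.attenuation_window)
    top = np.percentile(mu, 99.5)
    if top <= 0:
        top = mu.max()
    if top <= 0:
        return np.zeros_like(mu)
    scaled = np.clip(mu / top, 0.0, 1.0)
    return np.clip(255.0 * scaled**cfg.gamma, 0.0, 255.0)


def normalize(x: np.ndarray) -> np.ndarray:
    """Exact affine map [0, 255] -> [-1, 1]: ``(x - 127.5) / 127.5``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > 255):
        raise ValueError("normalize expects values in [0, 255]")
    return (x - NORM_CENTER) / NORM_SCALE


def denormalize(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`: [-1, 1] -> [0, 255]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size and (x.min() < -1 or x.max() > 1):
        raise ValueError("denormalize expects values in [-1, 1]")
    return x * NORM_SCALE + NORM_CENTER


class PolarPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer from raw polar frames to network tensors.

    ``transform`` maps a stack ``(n_frames, n_samples, n_alines)`` of
    8-bit polar frames to ``(n_frames, 2, n_samples, n_alines)`` float32
    tensors in ``[-1, 1]`` (channel 0: log-compressed intensity,
    channel 1: attenuation).
    """

    def __init__(
        self,
        log_compress: bool = True,
        gamma: float = 0.5,
        attenuation_window: int = 32,
        radial_res_mm: float = 0.01,
    ) -> None:
        self.log_compress = log_compress
        self.gamma = gamma
        self.attenuation_window = attenuation_window
        self.radial_res_mm = radial_res_mm

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            log_compress=self.log_compress,
            gamma=self.gamma,
            attenuation_window=self.attenuation_window,
            radial_res_mm=self.radial_res_mm,
        )

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        frames = np.asarray(X)
        if frames.ndim == 2:
            frames = frames[None]
        out = np.empty((frames.shape[0], 2, frames.shape[1], frames.shape[2]), dtype=np.float32)
        for i, frame in enumerate(frames):
            ch0 = log_polar(frame) if cfg.log_compress else np.asarray(frame, dtype=np.float64)
            ch1 = attenuation_channel(frame, cfg)
            out[i, 0] = normalize(ch0)
            out[i, 1] = normalize(ch1)
        return out
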