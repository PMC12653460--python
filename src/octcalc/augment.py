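"""Training-time simulation of intravascular OCT acquisition artifacts.

Three artifacts are modelled, each as a spatial map applied identically to
the image (interpolated) and to the label map (nearest-neighbour), so a
pixel's class is always transported by the same map as its intensity:

* **NURD** (non-uniform rotational distortion): a smooth single-harmonic
  angular displacement field, the first-order signature of variable
  catheter rotation speed;
* **motion**: a rigid radial shift of the whole frame, as caused by
  longitudinal/axial catheter motion between A-line sweeps;
* **multiple reflection**: a ghost of each A-line's proximal half added
  at double depth, mimicking re-reflections between catheter sheath and
  tissue (intensity only, labels untouched).

Augmentations compose in the fixed order NURD -> motion -> reflection so a
single seed determines the whole stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from octcalc.phantom import BACKGROUND


@dataclass(frozen=True)
class AugmentConfig:
    """Artifact magnitudes and per-artifact application probabilities."""

    nurd_amplitude_deg: float = 2.0
    nurd_frequency: float = 1.0  # cycles per revolution
    motion_shift_px: int = 4
    reflection_gain: float = 0.3
    p_nurd: float = 0.5
    p_motion: float = 0.5
    p_reflection: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nurd_amplitude_deg < 0 or self.motion_shift_px < 0:
            raise ValueError("artifact amplitudes must be nonnegative")
        if not 0.0 <= self.reflection_gain <= 1.0:
            raise ValueError("reflection gain must lie in [0, 1]")
        for p in (self.p_nurd, self.p_motion, self.p_reflection):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def nurd_displacement(cfg: AugmentConfig, n_alines: int, phase: float) -> np.ndarray:
    """Angular displacement in A-line bins for each output column."""
    theta = np.arange(n_alines) * (360.0 / n_alines)
    deg = cfg.nurd_amplitude_deg * np.sin(
        2.0 * np.pi * cfg.nurd_frequency * theta / 360.0 + phase
    )
    return deg * n_alines / 360.0


def nurd_warp(
    image: np.ndarray,
    labels: Optional[np.ndarray],
    cfg: AugmentConfig,
    phase: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    invert: bool = False,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Warp the angular axis by a smooth periodic displacement field.

    Output column ``j`` samples source angle ``j + delta(j)`` (negated when
    ``invert=True``, which approximately undoes the forward warp for small
    amplitudes).  Intensities are linearly interpolated with wrap-around;
    labels take the nearest source column.  Configs whose displacement
    slope would make the warp non-monotone in theta are rejected.
    """
    slope = cfg.nurd_amplitude_deg * 2.0 * np.pi * cfg.nurd_frequency / 360.0
    if slope >= 1.0:
        raise ValueError(
            "NURD amplitude*frequency too large: angular warp would fold "
            f"(max displacement slope {slope:.2f} >= 1)"
        )
    image = np.asarray(image)
    n_alines = image.shape[-1]
    if labels is not None and labels.shape[-1] != n_alines:
        raise ValueError("image and labels must be spatially aligned")
    if phase is None:
        phase = (rng or np.random.default_rng(cfg.seed)).uniform(0.0, 2.0 * np.pi)
    if cfg.nurd_amplitude_deg == 0:
        return image.copy(), None if labels is None else labels.copy()

    delta = nurd_displacement(cfg, n_alines, phase)
    if invert:
        delta = -delta
    src = np.arange(n_alines) + delta
    lo = np.floor(src).astype(int)
    frac = src - lo
    lo_m = lo % n_alines
    hi_m = (lo + 1) % n_alines
    warped = image[..., lo_m] * (1.0 - frac) + image[..., hi_m] * frac
    if np.issubdtype(image.dtype, np.integer):
        warped = np.rint(warped).astype(image.dtype)
    if labels is None:
        return warped, None
    nearest = np.rint(src).astype(int) % n_alines
    return warped, labels[..., nearest]


def motion_shift(
    image: np.ndarray,
    labels: Optional[np.ndarray],
    cfg: AugmentConfig,
    shift: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Shift all A-lines jointly along the radial axis.

    A positive shift ``s`` maps pixel ``(r, theta)`` to ``(r + s, theta)``;
    vacated rows are zero-filled and labelled background.  The same shift
    is applied to image and labels.
    """
    image = np.asarray(image)
    n_samples = image.shape[-2]
    if shift is None:
        m = int(cfg.motion_shift_px)
        shift = int((rng or np.random.default_rng(cfg.seed)).integers(-m, m + 1))
    if abs(shift) >= n_samples:
        raise ValueError(f"radial shift {shift} exceeds frame depth {n_samples}")

    def _shift(arr: np.ndarray, fill) -> np.ndarray:
        out = np.full_like(arr, fill)
        if shift == 0:
            return arr.copy()
        if shift > 0:
            out[..., shift:, :] = arr[..., :-shift, :]
        else:
            out[..., :shift, :] = arr[..., -shift:, :]
        return out

    shifted = _shift(image, 0)
    if labels is None:
        return shifted, None
    return shifted, _shift(labels, BACKGROUND)


def multiple_reflection(
    image: np.ndarray,
    cfg: AugmentConfig,
    gain: Optional[float] = None,
) -> np.ndarray:
    """Add a ghost of each A-line's proximal segment at double depth.

    A pixel at radius ``r`` contributes ``gain * I(r)`` at radius ``2r``;
    the result is clipped to [0, 255].  Labels are unchanged by multiple
    reflection (the ghost carries no tissue), so only the image is
    returned.
    """
    if gain is None:
        gain = cfg.reflection_gain
    if not 0.0 <= gain <= 1.0:
        raise ValueError("reflection gain must lie in [0, 1]")
    image = np.asarray(image)
    out = image.astype(np.float64)
    if gain > 0:
        n_samples = image.shape[-2]
        half = (n_samples + 1) // 2
        src = np.arange(half)
        ghost = np.zeros_like(out)
        ghost[..., 2 * src, :] = out[..., src, :]
        out = out + gain * ghost
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).astype(image.dtype)
    return out


def augment_pair(
    image: np.ndarray,
    labels: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the artifact stack to one frame with its label map.

    Each artifact fires independently with its configured probability;
    the draw order is fixed (NURD, motion, reflection) so a seeded
    generator reproduces the same augmentation stream.
    """
    if image.shape != labels.shape:
        raise ValueError("image and labels must be spatially aligned")
    do_nurd = rng.uniform() < cfg.p_nurd
    do_motion = rng.uniform() < cfg.p_motion
    do_reflect = rng.uniform() < cfg.p_reflection
    if do_nurd and cfg.nurd_amplitude_deg > 0:
        image, labels = nurd_warp(image, labels, cfg, rng=rng)
    if do_motion and cfg.motion_shift_px > 0:
        image, labels = motion_shift(image, labels, cfg, rng=rng)
    if do_reflect and cfg.reflection_gain > 0:
        image = multiple_reflection(image, cfg)
    return image, labels
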