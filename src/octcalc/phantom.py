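"""Seeded synthetic polar OCT pullbacks with ground-truth label maps.

A phantom frame is a polar image: rows are radial samples along an A-line,
columns are A-lines over 360 degrees.  Each A-line is rendered as a
piecewise signal model — a bright catheter ring, a signal-void lumen, a
thin bright lumen border, and beyond it tissue with class-specific
entry brightness and round-trip exponential depth attenuation
``I0 * exp(-2 * mu * depth)`` — multiplied by gamma-distributed speckle.
Plaques are annular sectors embedded in the vessel wall:

* calcified plaque — signal-poor, sharply delineated, low attenuation;
* lipidic plaque — signal-poor, diffusely delineated, high attenuation;
* fibrous plaque — signal-rich and homogeneous.

A metallic guidewire renders as a bright arc inside the lumen and casts a
radial shadow that overrides everything behind it.  The label map records
the generating class of every pixel, so arcs, thicknesses and lesion
lengths measured downstream can be compared against the generating
geometry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

# Pixel-class vocabulary (10 classes).  Indices are stable across the
# package; plaque classes are 5/6/7.
BACKGROUND = 0
CATHETER = 1
LUMEN = 2
LUMEN_BORDER = 3
TISSUE = 4
CALCIUM = 5
LIPID = 6
FIBROUS = 7
GUIDEWIRE = 8
GUIDEWIRE_SHADOW = 9

CLASS_NAMES: Tuple[str, ...] = (
    "background",
    "catheter",
    "lumen",
    "lumen_border",
    "tissue",
    "calcium",
    "lipid",
    "fibrous",
    "guidewire",
    "guidewire_shadow",
)

PLAQUE_CLASSES: Tuple[int, int, int] = (CALCIUM, LIPID, FIBROUS)

_PLAQUE_BY_NAME = {"calcium": CALCIUM, "lipid": LIPID, "fibrous": FIBROUS}

# Entry brightness per tissue class (8-bit scale, at the proximal border
# of the region).
DEFAULT_I0: Dict[int, float] = {
    TISSUE: 200.0,
    CALCIUM: 70.0,
    LIPID: 170.0,
    FIBROUS: 235.0,
}

# Attenuation coefficients in 1/mm.  Lipid attenuates strongly, calcium
# weakly — the contrast the attenuation channel is designed to expose.
DEFAULT_MU: Dict[int, float] = {
    TISSUE: 2.0,
    CALCIUM: 0.6,
    LIPID: 5.0,
    FIBROUS: 1.8,
}


@dataclass(frozen=True)
class PlaqueSpec:
    """One annular-sector plaque across a run of frames.

    ``tissue`` is one of ``"calcium" | "lipid" | "fibrous"``; the sector is
    centred at ``center_deg``, spans ``arc_deg`` degrees, starts radially
    ``depth_offset_mm`` behind the lumen border and extends
    ``thickness_mm`` outward, on frames
    ``[start_frame, start_frame + n_frames)``.
    """

    tissue: str
    arc_deg: float
    thickness_mm: float
    start_frame: int = 0
    n_frames: int = 1
    center_deg: float = 180.0
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue not in _PLAQUE_BY_NAME:
            raise ValueError(f"unknown plaque tissue {self.tissue!r}")
        if not 0.0 < self.arc_deg <= 360.0:
            raise ValueError("plaque arc must lie in (0, 360] degrees")
        if self.thickness_mm <= 0:
            raise ValueError("plaque thickness must be positive")
        if self.depth_offset_mm < 0:
            raise ValueError("plaque depth offset must be nonnegative")
        if self.n_frames < 1 or self.start_frame < 0:
            raise ValueError("plaque frame range invalid")

    @property
    def class_index(self) -> int:
        return _PLAQUE_BY_NAME[self.tissue]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and randomness of a synthetic pullback.

    Angular and radial sample counts must be divisible by 16 so frames can
    pass through a depth-4 encoder unchanged.
    """

    n_frames: int = 8
    n_alines: int = 480
    n_samples: int = 512
    radial_res_mm: float = 0.01
    frame_spacing_mm: float = 0.2
    lumen_radius_mm: float = 1.0
    lumen_radius_var: float = 0.05  # fractional amplitude of border waviness
    plaque_specs: Tuple[PlaqueSpec, ...] = ()
    speckle_shape: float = 4.0
    tissue_mu: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    tissue_i0: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_I0))
    catheter_radius_mm: float = 0.06
    border_mm: float = 0.03
    guidewire_center_deg: float = 0.0
    guidewire_arc_deg: float = 20.0
    guidewire_thickness_mm: float = 0.12
    background_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alines % 16 or self.n_samples % 16:
            raise ValueError("n_alines and n_samples must be divisible by 16")
        if self.radial_res_mm <= 0 or self.frame_spacing_mm <= 0:
            raise ValueError("calibration fields must be strictly positive")
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen radius must be positive")
        if self.speckle_shape <= 0:
            raise ValueError("speckle shape must be positive")
        if any(mu <= 0 for mu in self.tissue_mu.values()):
            raise ValueError("all attenuation coefficients must be positive")
        object.__setattr__(self, "plaque_specs", tuple(self.plaque_specs))
        depth = self.imaging_depth_mm
        max_lumen = self.lumen_radius_mm * (1 + abs(self.lumen_radius_var))
        for spec in self.plaque_specs:
            outer = max_lumen + self.border_mm + spec.depth_offset_mm + spec.thickness_mm
            if outer >= depth:
                raise ValueError(
                    f"plaque {spec.tissue} radial extent {outer:.3f} mm exceeds "
                    f"imaging depth {depth:.3f} mm"
                )
            if spec.start_frame + spec.n_frames > self.n_frames:
                raise ValueError("plaque frame range exceeds pullback length")

    @property
    def imaging_depth_mm(self) -> float:
        return self.n_samples * self.radial_res_mm

    @property
    def deg_per_aline(self) -> float:
        return 360.0 / self.n_alines

    def with_seed(self, seed: int) -> "PhantomConfig":
        return replace(self, seed=seed)


@dataclass
class PullbackImage:
    """Stack of polar frames plus the physical calibration of the pullback."""

    frames: np.ndarray  # (n_frames, n_samples, n_alines) uint8
    radial_res_mm: float
    frame_spacing_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_samples, n_alines)")
        if not np.all(np.isfinite(self.frames.astype(np.float64))):
            raise ValueError("intensities must be finite")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.radial_res_mm <= 0 or self.frame_spacing_mm <= 0:
            raise ValueError("calibration fields must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class LabelMap:
    """Per-pixel class indices aligned to a pullback."""

    classes: np.ndarray  # (n_frames, n_samples, n_alines) uint8 in 0..9
    class_names: Tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if len(self.class_names) != 10:
            raise ValueError("class vocabulary must have 10 entries")
        if self.classes.min() < 0 or self.classes.max() > 9:
            raise ValueError("class indices must lie in 0..9")


def attenuation_profile(tissue_class: int, depth_mm, config: PhantomConfig):
    """Noiseless round-trip intensity ``I0 * exp(-2 * mu * depth)``.

    ``depth_mm`` is depth into the tissue region (mm, scalar or array);
    strictly decreasing in depth.
    """
    depth = np.asarray(depth_mm, dtype=np.float64)
    if np.any(depth < 0):
        raise ValueError("depth must be nonnegative")
    if tissue_class not in config.tissue_mu:
        raise KeyError(f"unknown tissue class {tissue_class}")
    mu = config.tissue_mu[tissue_class]
    i0 = config.tissue_i0[tissue_class]
    return i0 * np.exp(-2.0 * mu * depth)


def _angular_mask(n_alines: int, center_deg: float, arc_deg: float) -> np.ndarray:
    """Boolean mask over A-line columns covered by a (possibly wrapping) arc."""
    deg = 360.0 / n_alines
    n_cols = int(round(arc_deg / deg))
    n_cols = max(1, min(n_alines, n_cols))
    start = int(round((center_deg - arc_deg / 2.0) / deg))
    cols = (start + np.arange(n_cols)) % n_alines
    mask = np.zeros(n_alines, dtype=bool)
    mask[cols] = True
    return mask


def random_phantom_config(
    seed: int,
    n_frames: int = 8,
    n_alines: int = 480,
    n_samples: int = 512,
    radial_res_mm: float = 0.01,
    frame_spacing_mm: float = 0.2,
    lumen_radius_mm: float = 1.0,
    arc_range_deg: Tuple[float, float] = (45.0, 150.0),
    thickness_range_mm: Tuple[float, float] = (0.3, 1.0),
    max_plaques: int = 2,
    tissues: Sequence[str] = ("calcium", "lipid", "fibrous"),
) -> PhantomConfig:
    """Draw a pullback configuration with randomized plaque geometry.

    Plaque centres are kept within [60, 300] degrees so sectors never
    reach the guidewire shadow at 0 degrees, and arcs are snapped to the
    angular sampling grid and thicknesses to the radial grid so the
    generated masks coincide with their nominal geometry.
    """
    rng = np.random.default_rng(seed)
    deg = 360.0 / n_alines
    specs = []
    n_plaques = int(rng.integers(1, max_plaques + 1))
    for i in range(n_plaques):
        tissue = str(rng.choice(list(tissues)))
        arc = float(rng.uniform(*arc_range_deg))
        arc = max(1, round(arc / deg)) * deg  # snap to angular grid
        thick = float(rng.uniform(*thickness_range_mm))
        thick = max(1, round(thick / radial_res_mm)) * radial_res_mm
        lo, hi = 60.0 + arc / 2.0, 300.0 - arc / 2.0
        center = float(rng.uniform(lo, max(lo + 1e-6, hi)))
        start = int(rng.integers(0, max(1, n_frames - 1)))
        length = int(rng.integers(1, n_frames - start + 1))
        specs.append(
            PlaqueSpec(
                tissue=tissue,
                arc_deg=arc,
                thickness_mm=thick,
                start_frame=start,
                n_frames=length,
                center_deg=center,
            )
        )
    return PhantomConfig(
        n_frames=n_frames,
        n_alines=n_alines,
        n_samples=n_samples,
        radial_res_mm=radial_res_mm,
        frame_spacing_mm=frame_spacing_mm,
        lumen_radius_mm=lumen_radius_mm,
        plaque_specs=tuple(specs),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_pullback(config: PhantomConfig) -> Tuple[PullbackImage, LabelMap]:
    """Render a seeded pullback and its ground-truth label map.

    Deterministic for a fixed ``config.seed``: the same config yields a
    bit-identical image stack and label map.
    """
    rng = np.random.default_rng(config.seed)
    n_f, n_s, n_a = config.n_frames, config.n_samples, config.n_alines
    dr = config.radial_res_mm
    r = (np.arange(n_s, dtype=np.float64) + 0.5) * dr  # pixel-centre radii
    theta = np.arange(n_a, dtype=np.float64) * config.deg_per_aline

    # Slowly varying lumen border: one angular harmonic whose phase drifts
    # along the pullback.
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    drift = rng.uniform(-0.15, 0.15)

    frames = np.empty((n_f, n_s, n_a), dtype=np.uint8)
    labels = np.empty((n_f, n_s, n_a), dtype=np.uint8)

    gw_mask = _angular_mask(n_a, config.guidewire_center_deg, config.guidewire_arc_deg)

    for f in range(n_f):
        r_lum = config.lumen_radius_mm * (
            1.0
            + config.lumen_radius_var
            * np.sin(np.deg2rad(theta) + phase0 + drift * f)
        )
        wall_start = r_lum + config.border_mm  # per A-line, mm

        depth_wall = r[:, None] - wall_start[None, :]
        intensity = np.where(
            depth_wall >= 0,
            config.tissue_i0[TISSUE] * np.exp(-2.0 * config.tissue_mu[TISSUE] * np.clip(depth_wall, 0, None)),
            0.0,
        )
        label = np.where(depth_wall >= 0, TISSUE, LUMEN).astype(np.uint8)

        # Background beyond effective penetration of the wall signal.
        bg = (depth_wall >= 0) & (intensity < config.background_threshold)
        label[bg] = BACKGROUND
        intensity[bg] = 1.0

        # Lumen interior and bright border.
        border = (r[:, None] >= r_lum[None, :]) & (r[:, None] < wall_start[None, :])
        label[border] = LUMEN_BORDER
        intensity[border] = 250.0
        interior = r[:, None] < r_lum[None, :]
        intensity[interior] = 2.0

        # Catheter ring around the probe.
        cath = r < config.catheter_radius_mm
        label[cath, :] = CATHETER
        intensity[cath, :] = 180.0

        # Plaques: annular sectors behind the lumen border.
        lipid_mask_frame = np.zeros((n_s, n_a), dtype=bool)
        for spec in config.plaque_specs:
            if not (spec.start_frame <= f < spec.start_frame + spec.n_frames):
                continue
            cols = _angular_mask(n_a, spec.center_deg, spec.arc_deg)
            inner = wall_start + spec.depth_offset_mm  # per A-line
            depth_plaque = r[:, None] - inner[None, :]
            sector = (
                cols[None, :]
                & (depth_plaque >= 0)
                & (depth_plaque < spec.thickness_mm)
            )
            cls = spec.class_index
            label[sector] = cls
            intensity[sector] = (
                config.tissue_i0[cls]
                * np.exp(-2.0 * config.tissue_mu[cls] * np.clip(depth_plaque, 0, None))
            )[sector]
            if cls == LIPID:
                lipid_mask_frame |= sector

        # Lipid borders are diffuse: locally smooth the noiseless signal
        # around lipid sectors (calcium borders stay sharp).
        if lipid_mask_frame.any():
            blurred = ndimage.gaussian_filter(intensity, sigma=(2.0, 1.0), mode="nearest")
            near = ndimage.binary_dilation(lipid_mask_frame, iterations=3)
            intensity = np.where(near, blurred, intensity)

        # Guidewire arc inside the lumen, shadow behind it.
        gw_inner = np.minimum(0.5 * r_lum, r_lum - config.guidewire_thickness_mm)
        gw_inner = np.maximum(gw_inner, config.catheter_radius_mm + dr)
        gw_body = (
            gw_mask[None, :]
            & (r[:, None] >= gw_inner[None, :])
            & (r[:, None] < (gw_inner + config.guidewire_thickness_mm)[None, :])
        )
        gw_shadow = gw_mask[None, :] & (
            r[:, None] >= (gw_inner + config.guidewire_thickness_mm)[None, :]
        )
        label[gw_shadow] = GUIDEWIRE_SHADOW
        intensity[gw_shadow] = 1.0
        label[gw_body] = GUIDEWIRE
        intensity[gw_body] = 255.0

        speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, size=(n_s, n_a))
        frame = np.clip(intensity * speckle, 0.0, 255.0)
        frames[f] = np.rint(frame).astype(np.uint8)
        labels[f] = label

    image = PullbackImage(frames, config.radial_res_mm, config.frame_spacing_mm)
    label_map = LabelMap(labels)
    return image, label_map
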