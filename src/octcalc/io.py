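"""File formats: multi-frame TIFF stacks with a JSON metadata sidecar.

Pullback images and label maps travel as multi-frame 8-bit grayscale
TIFF; the physical calibration and class vocabulary live in a JSON
sidecar so the pixel data stays self-contained and dependency-light.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile

from octcalc.phantom import CLASS_NAMES, LabelMap, PullbackImage


@dataclass
class PullbackMeta:
    """Sidecar metadata paired with a pullback TIFF."""

    radial_res_mm: float
    frame_spacing_mm: float
    n_frames: int
    n_alines: int
    n_samples: int
    class_names: Tuple[str, ...] = CLASS_NAMES

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self) | {"class_names": list(self.class_names)}, indent=2))

    @classmethod
    def from_json(cls, path) -> "PullbackMeta":
        data = json.loads(Path(path).read_text())
        data["class_names"] = tuple(data["class_names"])
        return cls(**data)

    def check_shape(self, shape: Tuple[int, int, int], what: str) -> None:
        expected = (self.n_frames, self.n_samples, self.n_alines)
        if tuple(shape) != expected:
            raise ValueError(
                f"{what} shape {tuple(shape)} does not match metadata "
                f"(n_frames, n_samples, n_alines) = {expected}"
            )


def write_pullback(image: PullbackImage, tiff_path, meta_path) -> None:
    """Write an 8-bit pullback stack and its metadata sidecar."""
    frames = np.asarray(image.frames, dtype=np.uint8)
    tifffile.imwrite(tiff_path, frames)
    PullbackMeta(
        radial_res_mm=image.radial_res_mm,
        frame_spacing_mm=image.frame_spacing_mm,
        n_frames=frames.shape[0],
        n_samples=frames.shape[1],
        n_alines=frames.shape[2],
    ).to_json(meta_path)


def read_pullback(tiff_path, meta_path) -> Tuple[PullbackImage, PullbackMeta]:
    """Read a pullback stack; lossless round-trip for 8-bit stacks."""
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = PullbackMeta.from_json(meta_path)
    meta.check_shape(frames.shape, "pullback stack")
    return PullbackImage(frames, meta.radial_res_mm, meta.frame_spacing_mm), meta


def write_labels(labels: LabelMap, tiff_path, meta_path: Optional[str] = None,
                 radial_res_mm: float = 0.01, frame_spacing_mm: float = 0.2) -> None:
    """Write a label map as a multi-frame 8-bit TIFF (+ optional sidecar)."""
    classes = np.asarray(labels.classes, dtype=np.uint8)
    tifffile.imwrite(tiff_path, classes)
    if meta_path is not None:
        PullbackMeta(
            radial_res_mm=radial_res_mm,
            frame_spacing_mm=frame_spacing_mm,
            n_frames=classes.shape[0],
            n_samples=classes.shape[1],
            n_alines=classes.shape[2],
            class_names=labels.class_names,
        ).to_json(meta_path)


def read_labels(tiff_path, meta_path: Optional[str] = None) -> Tuple[LabelMap, Optional[PullbackMeta]]:
    classes = tifffile.imread(tiff_path)
    if classes.ndim == 2:
        classes = classes[None]
    meta = None
    if meta_path is not None:
        meta = PullbackMeta.from_json(meta_path)
        meta.check_shape(classes.shape, "label stack")
        return LabelMap(classes, meta.class_names), meta
    return LabelMap(classes), meta
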