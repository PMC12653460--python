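"""Clinical calcium quantification from per-pixel label maps.

From a segmented polar frame, calcified plaques are extracted as
angularly connected components (8-connectivity with wrap-around across
the 0/360 degree seam).  Per plaque and frame the clinically reported
measures are:

* **arc** — angular extent in degrees, referenced to the lumen centre
  (in polar acquisition geometry the A-line axis is exactly the angle
  subtended at the catheter/lumen centre);
* **minimum / maximum thickness** — min/max over the plaque's A-lines of
  its radial pixel extent times the radial calibration (mm);
* **length** — the longest contiguous run of frames carrying the plaque,
  times the frame spacing (mm).

The OCT-calcium score sums 1 point for maximum thickness > 0.5 mm,
2 points for maximum arc > 180 degrees and 1 point for length > 5 mm
(strict inequalities; equalling a threshold earns no point), and is
dichotomized into non-severe (0-2) versus severe (3-4) calcification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from octcalc.phantom import BACKGROUND, CALCIUM, GUIDEWIRE_SHADOW

NON_SEVERE = "non-severe"
SEVERE = "severe"


@dataclass(frozen=True)
class ScoreRule:
    """Point thresholds of the OCT-calcium score (strict inequalities)."""

    thickness_threshold_mm: float = 0.5
    thickness_points: int = 1
    arc_threshold_deg: float = 180.0
    arc_points: int = 2
    length_threshold_mm: float = 5.0
    length_points: int = 1

    @property
    def max_score(self) -> int:
        return self.thickness_points + self.arc_points + self.length_points


@dataclass
class PlaqueMeasure:
    """One plaque's measurements on one cross-sectional frame."""

    frame_index: int
    arc_deg: float
    min_thickness_mm: float
    max_thickness_mm: float
    angular_span: Tuple[float, float]  # half-open degrees, may wrap
    n_pixels: int = 0
    truncated: bool = False  # abluminal border abuts a signal void

    def __post_init__(self) -> None:
        if not 0.0 < self.arc_deg <= 360.0:
            raise ValueError("arc must lie in (0, 360]")
        if not 0.0 < self.min_thickness_mm <= self.max_thickness_mm:
            raise ValueError("0 < min_thickness <= max_thickness required")


@dataclass
class LesionSummary:
    """Cross-frame summary of one lesion: maxima, length, score, severity."""

    length_mm: float
    max_arc_deg: float
    max_thickness_mm: float
    min_thickness_mm: float
    score: int
    severity: str
    n_frames: int = 0
    frame_range: Tuple[int, int] = (0, 0)
    truncated: bool = False

    def to_dict(self) -> Dict:
        return {
            "type": "lesion",
            "length_mm": self.length_mm,
            "max_arc_deg": self.max_arc_deg,
            "max_thickness_mm": self.max_thickness_mm,
            "min_thickness_mm": self.min_thickness_mm,
            "score": self.score,
            "severity": self.severity,
            "n_frames": self.n_frames,
            "frame_range": list(self.frame_range),
            "truncated": self.truncated,
        }


def _merge_wrap_labels(lab: np.ndarray) -> np.ndarray:
    """Union component ids that touch across the theta = 0/360 seam."""
    n_s = lab.shape[0]
    left, right = lab[:, 0], lab[:, -1]
    parent: Dict[int, int] = {}

    def find(a: int) -> int:
        root = a
        while parent.get(root, root) != root:
            root = parent[root]
        parent[a] = root
        return root

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n_s):
        if right[i] == 0:
            continue
        for j in (i - 1, i, i + 1):  # 8-connectivity across the seam
            if 0 <= j < n_s and left[j] != 0:
                union(int(right[i]), int(left[j]))
    if parent:
        out = lab.copy()
        for v in np.unique(lab):
            if v != 0 and find(int(v)) != v:
                out[lab == v] = find(int(v))
        return out
    return lab


def _circular_span(cols: np.ndarray, n_alines: int) -> Tuple[int, int]:
    """(start_bin, n_bins) of a circularly contiguous column set."""
    occupied = np.zeros(n_alines, dtype=bool)
    occupied[cols] = True
    n_occ = int(occupied.sum())
    if n_occ == n_alines:
        return 0, n_alines
    # Start is the first occupied bin after a gap.
    gap_then_occ = occupied & ~np.roll(occupied, 1)
    start = int(np.argmax(gap_then_occ))
    return start, n_occ


def extract_plaques(
    frame_labels: np.ndarray,
    radial_res_mm: float,
    target_class: int = CALCIUM,
    frame_index: int = 0,
    void_classes: Sequence[int] = (BACKGROUND, GUIDEWIRE_SHADOW),
) -> List[PlaqueMeasure]:
    """Measure every connected plaque of ``target_class`` on one frame.

    Components are found with 8-connectivity in the polar grid including
    wrap-around across theta = 0/360.  If more than one plaque of the
    class is present, each is measured separately.  A plaque whose outer
    border abuts a signal void (image background or guidewire shadow) is
    flagged ``truncated``: near-infrared shadowing means its true
    abluminal boundary may not have been imaged.
    """
    if radial_res_mm <= 0:
        raise ValueError("radial_res_mm calibration must be strictly positive")
    frame_labels = np.asarray(frame_labels)
    if frame_labels.ndim != 2:
        raise ValueError("frame_labels must be a single 2-D frame")
    n_s, n_a = frame_labels.shape
    deg = 360.0 / n_a
    mask = frame_labels == target_class
    if not mask.any():
        return []
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    lab = _merge_wrap_labels(lab)

    void = np.isin(frame_labels, void_classes)
    measures: List[PlaqueMeasure] = []
    for comp_id in np.unique(lab):
        if comp_id == 0:
            continue
        comp = lab == comp_id
        rows, cols = np.nonzero(comp)
        col_counts = np.bincount(cols, minlength=n_a)
        occupied = np.nonzero(col_counts)[0]
        start_bin, n_bins = _circular_span(occupied, n_a)
        arc = n_bins * deg
        thick_px = col_counts[occupied]
        truncated = False
        for c in occupied:
            outer = rows[cols == c].max()
            if outer + 1 >= n_s or void[outer + 1, c]:
                truncated = True
                break
        measures.append(
            PlaqueMeasure(
                frame_index=frame_index,
                arc_deg=arc,
                min_thickness_mm=float(thick_px.min()) * radial_res_mm,
                max_thickness_mm=float(thick_px.max()) * radial_res_mm,
                angular_span=(start_bin * deg, ((start_bin + n_bins) % n_a) * deg),
                n_pixels=int(comp.sum()),
                truncated=truncated,
            )
        )
    measures.sort(key=lambda m: m.angular_span[0])
    return measures


def arc_bins(span: Tuple[float, float], n_bins: int = 360) -> np.ndarray:
    """Boolean occupancy of a half-open angular span over ``n_bins`` bins."""
    start, end = span
    grid = (np.arange(n_bins) + 0.5) * (360.0 / n_bins)
    start %= 360.0
    end %= 360.0
    if start < end:
        return (grid >= start) & (grid < end)
    if start == end:
        return np.ones(n_bins, dtype=bool)
    return (grid >= start) | (grid < end)


def frame_calcium_bins(
    frame_labels: np.ndarray, target_class: int = CALCIUM, n_bins: int = 360
) -> np.ndarray:
    """Angular occupancy (boolean, ``n_bins`` over 360 deg) of a class."""
    frame_labels = np.asarray(frame_labels)
    n_a = frame_labels.shape[1]
    occupied_cols = (frame_labels == target_class).any(axis=0)
    idx = (np.floor(np.arange(n_a) * (n_bins / n_a))).astype(int)
    out = np.zeros(n_bins, dtype=bool)
    np.maximum.at(out, idx, occupied_cols)
    return out


def sample_frames(n_frames: int, frame_spacing_mm: float, interval_mm: float) -> np.ndarray:
    """Frame indices annotated at a fixed longitudinal interval.

    Returns ``0, k, 2k, ...`` with ``k = round(interval / spacing)``;
    with the default 0.2 mm spacing, a 1 mm interval samples every fifth
    frame.
    """
    if frame_spacing_mm <= 0:
        raise ValueError("frame spacing must be positive")
    if interval_mm < frame_spacing_mm:
        raise ValueError("sampling interval must be >= frame spacing")
    stride = int(round(interval_mm / frame_spacing_mm))
    return np.arange(0, n_frames, stride)


def _longest_run(flags: Sequence[bool], chain_ok: Sequence[bool]) -> int:
    """Longest run of True flags where consecutive members satisfy chain_ok."""
    best = cur = 0
    for i, f in enumerate(flags):
        if not f:
            cur = 0
            continue
        if cur > 0 and not chain_ok[i]:
            cur = 0
        cur += 1
        best = max(best, cur)
    return best


def lesion_length(
    frame_bins: Sequence[np.ndarray],
    mode: str,
    frame_spacing_mm: float,
    interval_mm: float = 1.0,
) -> float:
    """Longest continuous calcified segment of a pullback, in mm.

    ``frame_bins`` holds, for every frame in order, the boolean angular
    occupancy of calcium (any bin count; empty = no calcium).

    * ``every_frame`` — every frame is interrogated; the run continues
      between consecutive frames whose arcs share at least one angular
      bin; length = run count x frame spacing.
    * ``interval_quadrant`` — frames are sampled every ``interval_mm``;
      the run continues when consecutive sampled frames carry calcium in
      the same 90-degree quadrant; length = run count x interval.
    """
    frame_bins = [np.asarray(b, dtype=bool) for b in frame_bins]
    if mode == "every_frame":
        flags = [b.any() for b in frame_bins]
        chain = [False] + [
            bool((frame_bins[i] & frame_bins[i - 1]).any())
            for i in range(1, len(frame_bins))
        ]
        return _longest_run(flags, chain) * frame_spacing_mm
    if mode == "interval_quadrant":
        idx = sample_frames(len(frame_bins), frame_spacing_mm, interval_mm)
        quads = []
        for i in idx:
            b = frame_bins[i]
            n = b.size
            q = set()
            for k in range(4):
                if b[k * n // 4 : (k + 1) * n // 4].any():
                    q.add(k)
            quads.append(q)
        flags = [bool(q) for q in quads]
        chain = [False] + [bool(quads[i] & quads[i - 1]) for i in range(1, len(quads))]
        return _longest_run(flags, chain) * interval_mm
    raise ValueError(f"unknown lesion length mode {mode!r}")


def oct_calcium_score(
    max_thickness_mm: float,
    max_arc_deg: float,
    length_mm: float,
    rule: ScoreRule = ScoreRule(),
) -> int:
    """0-4 OCT-calcium score from maximum thickness, maximum arc, length.

    Points: thickness > 0.5 mm -> 1, arc > 180 deg -> 2, length > 5 mm
    -> 1; all comparisons strict, so a measurement exactly at a threshold
    earns no point.
    """
    if min(max_thickness_mm, max_arc_deg, length_mm) < 0:
        raise ValueError("score inputs must be nonnegative")
    score = 0
    if max_thickness_mm > rule.thickness_threshold_mm:
        score += rule.thickness_points
    if max_arc_deg > rule.arc_threshold_deg:
        score += rule.arc_points
    if length_mm > rule.length_threshold_mm:
        score += rule.length_points
    return score


def dichotomize(score: int) -> str:
    """Severity class: scores 0-2 are non-severe, 3-4 severe."""
    if score not in (0, 1, 2, 3, 4):
        raise ValueError(f"score must be an integer in 0..4, got {score!r}")
    return SEVERE if score >= 3 else NON_SEVERE


def summarize_lesions(
    labels: np.ndarray,
    radial_res_mm: float,
    frame_spacing_mm: float,
    target_class: int = CALCIUM,
    mode: str = "every_frame",
    interval_mm: float = 1.0,
    rule: ScoreRule = ScoreRule(),
) -> Tuple[List[LesionSummary], List[PlaqueMeasure]]:
    """Quantify all calcium lesions of a segmented pullback.

    A lesion is a maximal run of consecutive frames whose calcium arcs
    chain with angular overlap (the ``every_frame`` contiguity rule).
    Per lesion the maxima over its frames enter the score; the lesion
    length itself is measured in the requested ``mode``.  Multiple
    plaques on one frame are measured individually and pooled into the
    lesion maxima.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be (n_frames, n_samples, n_alines)")
    n_frames = labels.shape[0]
    per_frame: List[List[PlaqueMeasure]] = []
    bins: List[np.ndarray] = []
    for f in range(n_frames):
        per_frame.append(
            extract_plaques(labels[f], radial_res_mm, target_class, frame_index=f)
        )
        bins.append(frame_calcium_bins(labels[f], target_class))

    all_measures = [m for frame in per_frame for m in frame]

    # Split the pullback into lesions: runs of frames chained by overlap.
    lesions: List[LesionSummary] = []
    f = 0
    while f < n_frames:
        if not per_frame[f]:
            f += 1
            continue
        start = f
        while (
            f + 1 < n_frames
            and per_frame[f + 1]
            and (bins[f] & bins[f + 1]).any()
        ):
            f += 1
        end = f  # inclusive
        run_measures = [m for g in range(start, end + 1) for m in per_frame[g]]
        length = lesion_length(
            bins[start : end + 1], mode, frame_spacing_mm, interval_mm
        )
        max_th = max(m.max_thickness_mm for m in run_measures)
        min_th = min(m.min_thickness_mm for m in run_measures)
        max_arc = max(m.arc_deg for m in run_measures)
        score = oct_calcium_score(max_th, max_arc, length, rule)
        lesions.append(
            LesionSummary(
                length_mm=length,
                max_arc_deg=max_arc,
                max_thickness_mm=max_th,
                min_thickness_mm=min_th,
                score=score,
                severity=dichotomize(score),
                n_frames=end - start + 1,
                frame_range=(start, end + 1),
                truncated=any(m.truncated for m in run_measures),
            )
        )
        f += 1
    return lesions, all_measures
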