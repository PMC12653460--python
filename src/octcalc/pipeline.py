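"""End-to-end pipeline: phantom -> preprocess -> segment -> quantify -> evaluate.

``run_pipeline`` chains the package on a seeded phantom pullback (or, in
*truth mode*, bypasses the network and feeds the ground-truth labels as
one-hot predictions, so the quantification and evaluation stages can be
exercised deterministically without a trained checkpoint).  Every output
file embeds the seed and a hash of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from octcalc.evaluate import evaluate_segmentation
from octcalc.phantom import CALCIUM, PhantomConfig, PlaqueSpec, generate_pullback
from octcalc.preprocess import PolarPreprocessor
from octcalc.quantify import summarize_lesions
from octcalc.segnet import UNetSegmenter


def config_hash(config: Dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _phantom_from_dict(cfg: Dict, seed: int) -> PhantomConfig:
    cfg = dict(cfg)
    specs = tuple(PlaqueSpec(**s) for s in cfg.pop("plaque_specs", ()))
    return PhantomConfig(plaque_specs=specs, seed=seed, **cfg)


def run_pipeline(
    config: Dict,
    out_dir,
    seed: int = 0,
    checkpoint: Optional[str] = None,
) -> Dict:
    """Run the full chain on a seeded phantom and write result files.

    ``config`` holds a ``phantom`` block (PhantomConfig fields, plaques as
    dicts), optional ``preprocess`` block (PolarPreprocessor kwargs) and
    optional ``quantify`` block (mode, interval_mm).  Without a
    ``checkpoint`` the pipeline runs in truth mode.  Returns a summary
    dict; writes ``lesions.jsonl`` and ``report.json`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    provenance = {"seed": seed, "config_hash": chash}

    phantom_cfg = _phantom_from_dict(config.get("phantom", {}), seed)
    image, truth = generate_pullback(phantom_cfg)

    pre_kwargs = dict(config.get("preprocess", {}))
    pre_kwargs.setdefault("radial_res_mm", phantom_cfg.radial_res_mm)
    pre = PolarPreprocessor(**pre_kwargs)
    tensors = pre.transform(image.frames)

    if checkpoint is None:
        # Truth mode: ground-truth labels stand in for the prediction.
        pred_labels = truth.classes.astype(np.int64)
        n_classes = 10
        proba = np.zeros(
            (pred_labels.shape[0], n_classes, *pred_labels.shape[1:]), dtype=np.float32
        )
        np.put_along_axis(proba, pred_labels[:, None], 1.0, axis=1)
    else:
        est = UNetSegmenter.load(checkpoint)
        proba = est.predict_proba(tensors)
        pred_labels = proba.argmax(axis=1)

    qcfg = config.get("quantify", {})
    lesions, measures = summarize_lesions(
        pred_labels,
        radial_res_mm=phantom_cfg.radial_res_mm,
        frame_spacing_mm=phantom_cfg.frame_spacing_mm,
        target_class=CALCIUM,
        mode=qcfg.get("mode", "every_frame"),
        interval_mm=qcfg.get("interval_mm", 1.0),
    )

    lesions_path = out_dir / "lesions.jsonl"
    with open(lesions_path, "w") as fh:
        for m in measures:
            rec = {
                "type": "plaque",
                "frame_index": m.frame_index,
                "arc_deg": m.arc_deg,
                "min_thickness_mm": m.min_thickness_mm,
                "max_thickness_mm": m.max_thickness_mm,
                "angular_span": list(m.angular_span),
                "truncated": m.truncated,
            } | provenance
            fh.write(json.dumps(rec) + "\n")
        for lesion in lesions:
            fh.write(json.dumps(lesion.to_dict() | provenance) + "\n")

    report = evaluate_segmentation(proba, pred_labels, truth.classes, seed=seed)
    report_path = out_dir / "report.json"
    report_dict = report.to_dict() | provenance
    report_path.write_text(json.dumps(report_dict, indent=2))

    return {
        "lesions": lesions,
        "measures": measures,
        "report": report,
        "lesions_path": str(lesions_path),
        "report_path": str(report_path),
        **provenance,
    }
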