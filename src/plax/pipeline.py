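"""Two-stage orchestration: label maps (predicted or oracle) feeding
every geometric analysis, with a consolidated per-placenta report.

Stage II consumes Stage I only through the label-map / keypoint
contracts, so a report computed from ground-truth labels ("oracle
mode") and one computed from a perfect model prediction are identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from . import coiling as coil_mod
from . import morphometry as morpho
from . import shape as shape_mod
from .io import validate_report, write_report
from .morphometry import RulerUnreadableError
from .scene import CORD, DISC, SceneTruth

__all__ = ["run_pipeline", "batch", "PipelineConfig"]


class PipelineConfig(dict):
    """Free-form config; recognized keys with defaults below."""

    DEFAULTS = {
        "shape_threshold": shape_mod.IRREGULARITY_THRESHOLD,
        "hypercoil_threshold": coil_mod.HYPERCOIL_THRESHOLD,
        "t_marginal": morpho.DEFAULT_T_MARGINAL,
        "t_central": morpho.DEFAULT_T_CENTRAL,
        "tick_unit": "cm",
        "seed": 0,
    }

    def get_opt(self, key):
        return self.get(key, self.DEFAULTS[key])

    def digest(self) -> str:
        merged = {**self.DEFAULTS, **self}
        return hashlib.sha256(
            json.dumps(merged, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def run_pipeline(image_path, labels_path=None, model_checkpoint=None,
                 truth_path=None, config: PipelineConfig | None = None) -> dict:
    """Analyze one placenta photo end to end.

    Exactly one of ``labels_path`` (oracle mode) or ``model_checkpoint``
    (inference mode) must be given.  In oracle mode the side and the
    insertion point come from the scene-truth JSON (``truth_path``); in
    inference mode from the Classification Subnet and IPDecoder.
    """
    if (labels_path is None) == (model_checkpoint is None):
        raise ValueError("give exactly one of labels_path or model_checkpoint")
    config = config if isinstance(config, PipelineConfig) \
        else PipelineConfig(config or {})
    image = _load_image(image_path)
    truth = None
    if truth_path is not None:
        truth = SceneTruth.from_json(Path(truth_path).read_text())

    if labels_path is not None:
        from .io import read_label_png
        labels = read_label_png(labels_path)
        labels_source = "oracle-labels"
        model = None
    else:
        from .net import load_checkpoint
        model = load_checkpoint(model_checkpoint)
        labels = model.predict_labels(image)
        labels_source = "checkpoint:" + hashlib.sha256(
            Path(model_checkpoint).read_bytes()).hexdigest()[:12]

    if not (labels == DISC).any():
        raise ValueError("no disc pixels in the segmentation; cannot analyze")

    # side
    if model is not None:
        from .net import crop_disc
        crop = crop_disc(image, labels, out_size=model.crop_size)
        side = model.predict_side(crop.image)
    elif truth is not None:
        side = truth.side
    else:
        # fall back on the cord class touching the disc (fetal surface)
        side = "fetal" if (labels == CORD).any() else "maternal"

    # ruler scale
    scale = None
    scale_section = None
    try:
        scale = morpho.ruler_scale(image, labels,
                                   tick_unit=config.get_opt("tick_unit"))
        scale_section = {"pixels_per_cm": scale.pixels_per_cm,
                         "n_crests": len(scale.crest_positions),
                         "rect_angle_deg": float(np.degrees(scale.rect_angle))}
    except RulerUnreadableError as exc:
        warnings.warn(f"no usable ruler scale: {exc}; reporting pixel units",
                      stacklevel=2)

    recovered = morpho.recover_disc(labels)
    fit = shape_mod.fit_ellipse(recovered)
    irr = shape_mod.irregularity(recovered, fit)
    shape_section = {
        "center_xy": [float(v) for v in fit.center],
        "alpha_deg": float(np.degrees(fit.alpha)),
        "a_px": fit.semi_axes[0], "b_px": fit.semi_axes[1],
        "n1": irr.n1, "n2": irr.n2, "n3": irr.n3,
        "irregularity": irr.index,
        "shape_class": shape_mod.classify_shape(
            irr.index, config.get_opt("shape_threshold")),
    }

    counts = np.bincount(labels.ravel(), minlength=4)
    seg_section = {"class_fractions": (counts / counts.sum()).tolist()}

    insertion_section = None
    coiling_section = None
    if side == "fetal":
        if model is not None:
            ip = model.predict_insertion(crop)
        elif truth is not None and truth.insertion_point is not None:
            ip = truth.insertion_point
        else:
            raise ValueError("fetal scene needs an insertion point: give "
                             "truth_path in oracle mode")
        thresholds = morpho.CategoryThresholds(config.get_opt("t_marginal"),
                                               config.get_opt("t_central"))
        meas = morpho.measure_insertion(labels, ip, scale=scale,
                                        thresholds=thresholds,
                                        disc_mask=recovered)
        insertion_section = meas.to_dict()

        cord_mask = labels == CORD
        if cord_mask.any():
            geom = coil_mod.cord_geometry(cord_mask)
            segs = coil_mod.detect_crevices(image, cord_mask, geom)
            res = coil_mod.count_coils(segs, geom)
            coiling_section = {"n": res.n, "n_segments": len(res.segments),
                               "length_px": geom.length_px,
                               "length_cm": None, "coilness": None,
                               "hypercoiled": None}
            if scale is not None:
                length_cm = morpho.px_to_cm(geom.length_px, scale)
                C = coil_mod.coilness(res.n, length_cm)
                coiling_section.update(
                    length_cm=length_cm, coilness=C,
                    hypercoiled=coil_mod.classify_hypercoiled(
                        C, config.get_opt("hypercoil_threshold")))
        else:
            coiling_section = {"n": 0, "n_segments": 0, "length_px": 0.0,
                               "length_cm": None, "coilness": None,
                               "hypercoiled": None}

    report = {
        "side": side,
        "segmentation": seg_section,
        "shape": shape_section,
        "scale": scale_section,
        "insertion": insertion_section,
        "coiling": coiling_section,
        "provenance": {
            "labels_source": labels_source,
            "config": config.digest(),
            "seed": config.get_opt("seed"),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }
    validate_report(report)
    return report


CSV_FIELDS = ["scene", "side", "long_axis_cm", "short_axis_cm",
              "margin_distance_cm", "ratio", "category", "irregularity",
              "shape_class", "n_coils", "coilness", "hypercoiled"]


def batch(directory, out_dir=None, config: PipelineConfig | None = None,
          model_checkpoint=None) -> Path:
    """Analyze every scene in a directory; one CSV row per scene.

    Scenes follow the generator layout: ``<stem>.png``,
    ``<stem>_labels.png``, ``<stem>_truth.json``.  Failures are logged
    per scene and do not abort the batch.  Rows are ordered by filename.
    """
    directory = Path(directory)
    out_dir = Path(out_dir) if out_dir else directory
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = sorted(p.stem for p in directory.glob("*.png")
                   if not p.stem.endswith("_labels"))
    if not stems:
        raise ValueError(f"no scenes found in {directory}")
    rows = []
    for stem in stems:
        try:
            truth = directory / f"{stem}_truth.json"
            report = run_pipeline(
                directory / f"{stem}.png",
                labels_path=None if model_checkpoint else directory / f"{stem}_labels.png",
                model_checkpoint=model_checkpoint,
                truth_path=truth if truth.exists() else None,
                config=config)
            write_report(report, out_dir / f"{stem}_report.json")
            ins = report["insertion"] or {}
            coilsec = report["coiling"] or {}
            rows.append({
                "scene": stem, "side": report["side"],
                "long_axis_cm": ins.get("long_axis_cm"),
                "short_axis_cm": ins.get("short_axis_cm"),
                "margin_distance_cm": ins.get("margin_distance_cm"),
                "ratio": ins.get("ratio"), "category": ins.get("category"),
                "irregularity": report["shape"]["irregularity"],
                "shape_class": report["shape"]["shape_class"],
                "n_coils": coilsec.get("n"),
                "coilness": coilsec.get("coilness"),
                "hypercoiled": coilsec.get("hypercoiled"),
            })
        except Exception as exc:            # noqa: BLE001 - per-scene isolation
            warnings.warn(f"scene {stem} failed: {exc}", stacklevel=2)
    csv_path = out_dir / "batch_report.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        writer.writeheader()
        writer.writerows(rows)
    return csv_path
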