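"""File I/O for label maps and analysis reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_label_png", "write_label_png", "validate_report",
           "REPORT_SCHEMA"]

VALID_LABELS = frozenset((0, 1, 2, 3))


def read_label_png(path) -> np.ndarray:
    """Read an 8-bit single-channel PNG with values in {0, 1, 2, 3}."""
    try:
        img = Image.open(path)
    except Exception as exc:
        raise ValueError(f"cannot read label PNG {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"label PNG must be single-channel, got shape {arr.shape}")
    bad = sorted(set(np.unique(arr).tolist()) - VALID_LABELS)
    if bad:
        raise ValueError(f"label PNG contains invalid values {bad}; "
                         "expected subset of {0, 1, 2, 3}")
    return arr.astype(np.uint8)


def write_label_png(label_map: np.ndarray, path) -> None:
    arr = np.asarray(label_map)
    bad = sorted(set(np.unique(arr).tolist()) - VALID_LABELS)
    if bad:
        raise ValueError(f"label map contains invalid values {bad}")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


# Minimal published schema for the per-placenta report: required keys and
# types per section.  Kept hand-rolled so the report contract is explicit.
REPORT_SCHEMA = {
    "side": str,
    "segmentation": dict,
    "shape": dict,
    "scale": (dict, type(None)),
    "insertion": (dict, type(None)),
    "coiling": (dict, type(None)),
    "provenance": dict,
}

_SECTION_FIELDS = {
    "shape": ("n1", "n2", "n3", "irregularity", "shape_class"),
    "provenance": ("labels_source", "seed"),
}


def validate_report(report: dict) -> None:
    """Raise ValueError when a report violates the schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type "
                             f"{type(report[key]).__name__}")
    if report["side"] not in ("fetal", "maternal"):
        raise ValueError(f"invalid side {report['side']!r}")
    for section, fields in _SECTION_FIELDS.items():
        sec = report[section]
        if sec is None:
            continue
        for f in fields:
            if f not in sec:
                raise ValueError(f"report section {section!r} missing {f!r}")
    if report["side"] == "fetal":
        if report["insertion"] is None or report["coiling"] is None:
            raise ValueError("fetal report requires insertion and coiling")
    else:
        if report["insertion"] is not None or report["coiling"] is not None:
            raise ValueError("maternal report must omit insertion and coiling")


def write_report(report: dict, path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2))
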