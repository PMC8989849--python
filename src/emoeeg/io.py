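"""Plain-text I/O: segment CSVs with metadata headers, model JSON documents.

Segment files are one CSV per trial — comment lines carry sampling rate and
labels, columns are channels — plus an index CSV listing the files of a
collection.  Fitted models (tree or forest) serialize to a single JSON
document that round-trips predictions exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .forest import ImprovedRandomForestClassifier, WeightedTree
from .segments import EEGSegment
from .tree import C45TreeClassifier, DecisionNode

__all__ = [
    "write_segment_csv",
    "read_segment_csv",
    "write_segments",
    "read_segments",
    "save_model",
    "load_model",
]

_META_KEYS = ("fs", "label", "subject_id", "segment_id")


def write_segment_csv(segment: EEGSegment, path: str | Path) -> Path:
    """One trial to CSV: ``# key=value`` comment lines, then channel columns."""
    path = Path(path)
    lines = [f"# fs={segment.fs!r}"]
    for key in ("label", "subject_id", "segment_id"):
        value = getattr(segment, key)
        if value is not None:
            lines.append(f"# {key}={value}")
    header = ",".join(f"ch{c}" for c in range(segment.n_channels))
    body = "\n".join(
        ",".join(repr(float(v)) for v in segment.data[:, i])
        for i in range(segment.n_samples)
    )
    path.write_text("\n".join(lines) + "\n" + header + "\n" + body + "\n")
    return path


def read_segment_csv(path: str | Path) -> EEGSegment:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key] = value
    if "fs" not in meta:
        raise ValueError(f"{path}: missing '# fs=' metadata line")
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return EEGSegment(
        data=frame.to_numpy().T,
        fs=float(meta["fs"]),
        label=meta.get("label"),
        subject_id=meta.get("subject_id"),
        segment_id=meta.get("segment_id"),
    )


def write_segments(segments: Iterable[EEGSegment], out_dir: str | Path) -> Path:
    """Write a segment collection (one CSV each) plus ``index.csv``.

    Returns the index path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        seg_id = seg.segment_id or f"seg-{i:04d}"
        filename = f"{seg_id}.csv"
        write_segment_csv(seg, out_dir / filename)
        rows.append(
            dict(
                file=filename,
                segment_id=seg_id,
                subject_id=seg.subject_id,
                label=seg.label,
                fs=seg.fs,
                n_channels=seg.n_channels,
                n_samples=seg.n_samples,
            )
        )
    index_path = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path


def read_segments(index_path: str | Path) -> list[EEGSegment]:
    index_path = Path(index_path)
    index = pd.read_csv(index_path)
    return [
        read_segment_csv(index_path.parent / filename) for filename in index["file"]
    ]


# ---------------------------------------------------------------------------
# model (de)serialization


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted tree or forest classifier to JSON."""
    path = Path(path)
    if isinstance(model, C45TreeClassifier):
        doc = {
            "type": "c45_tree",
            "params": model.get_params(),
            "classes": list(model.classes_),
            "feature_names": list(model.feature_names_in_),
            "tree": model.tree_.to_dict(),
        }
    elif isinstance(model, ImprovedRandomForestClassifier):
        doc = {
            "type": "improved_forest",
            "params": model.get_params(),
            "classes": list(model.classes_),
            "feature_names": list(model.feature_names_in_),
            "trees": [
                {
                    "tree": member.tree.to_dict(),
                    "weight": member.weight,
                    "in_bag": member.in_bag.tolist(),
                    "out_of_bag": member.out_of_bag.tolist(),
                }
                for member in model.estimators_
            ],
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(json.dumps(doc) + "\n")
    return path


def load_model(path: str | Path):
    """Rebuild a fitted classifier from :func:`save_model` output."""
    doc = json.loads(Path(path).read_text())
    kind = doc.get("type")
    if kind == "c45_tree":
        model = C45TreeClassifier(**doc["params"])
        model.classes_ = np.asarray(doc["classes"], dtype=object)
        model.feature_names_in_ = list(doc["feature_names"])
        model.n_features_in_ = len(model.feature_names_in_)
        model.tree_ = DecisionNode.from_dict(doc["tree"])
        return model
    if kind == "improved_forest":
        model = ImprovedRandomForestClassifier(**doc["params"])
        model.classes_ = np.asarray(doc["classes"], dtype=object)
        model.feature_names_in_ = list(doc["feature_names"])
        model.n_features_in_ = len(model.feature_names_in_)
        model.estimators_ = [
            WeightedTree(
                tree=DecisionNode.from_dict(t["tree"]),
                weight=float(t["weight"]),
                in_bag=np.asarray(t["in_bag"], dtype=int),
                out_of_bag=np.asarray(t["out_of_bag"], dtype=int),
            )
            for t in doc["trees"]
        ]
        return model
    raise ValueError(f"unknown model type {kind!r} in {path}")
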