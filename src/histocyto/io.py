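"""Readers and writers for the package's on-disk formats.

Canonical formats: one single-channel TIFF per stain channel
(``<stem>_<channel>.tif``), 16-bit TIFF label maps, CSV feature tables
(``cell_id,image_id[,cluster_id][,label],feat...``, floats at 12 significant
digits so CSV roundtrips are lossless at working precision), and JSON for
models, ground truth and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .active import ClassifierModel
from .datatypes import DEFAULT_PIXEL_SIZE_UM, GroundTruth, MultiChannelImage
from .exceptions import FormatError

__all__ = [
    "read_image",
    "write_image",
    "read_channels",
    "write_channels",
    "read_label_map",
    "write_label_map",
    "read_feature_table",
    "write_feature_table",
    "model_to_json",
    "model_from_json",
    "write_model",
    "read_model",
    "write_ground_truth",
    "read_ground_truth",
    "write_json_report",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel grayscale TIFF or PNG."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # RGB(A) -> first channel
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel 2-D image")
    return arr


def write_image(path: str | Path, array: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(array))
    else:
        iio.imwrite(path, np.asarray(array))


def read_channels(
    channel_paths: dict[str, str | Path],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> MultiChannelImage:
    """Read named channel files into a stack; all must share one shape."""
    channels = {name: read_image(p) for name, p in channel_paths.items()}
    shapes = {name: ch.shape for name, ch in channels.items()}
    if len(set(shapes.values())) > 1:
        detail = ", ".join(f"{n}: {s}" for n, s in shapes.items())
        raise FormatError(f"channel shapes differ ({detail})")
    return MultiChannelImage(channels, pixel_size_um=pixel_size_um)


def write_channels(image: MultiChannelImage, stem: str | Path) -> dict[str, Path]:
    """Write one TIFF per channel as ``<stem>_<channel>.tif``."""
    stem = Path(stem)
    out = {}
    for name, ch in image.channels.items():
        path = stem.parent / f"{stem.name}_{name}.tif"
        tifffile.imwrite(path, ch)
        out[name] = path
    return out


def write_label_map(path: str | Path, label_map: np.ndarray) -> None:
    """Label maps are stored as 16-bit TIFF (cell counts can exceed 255)."""
    lm = np.asarray(label_map)
    if lm.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("label map has more than 65535 nuclei")
    tifffile.imwrite(Path(path), lm.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    if "cell_id" not in table.columns:
        raise FormatError(f"{path}: feature table lacks a cell_id column")
    keys = (
        table[["image_id", "cell_id"]] if "image_id" in table.columns
        else table[["cell_id"]]
    )
    if keys.duplicated().any():
        raise FormatError(f"{path}: duplicate cell keys in feature table")
    return table


def model_to_json(model: ClassifierModel, gain_history: list[float] | None = None) -> dict:
    doc = {
        "beta": model.beta.tolist(),
        "feature_names": list(model.feature_names),
        "standardization": {
            "mean": model.mean.tolist(),
            "scale": model.scale.tolist(),
        },
        "lambda": model.lam,
        "l1_eps": model.l1_eps,
        "fim_eps": model.fim_eps,
    }
    if gain_history is not None:
        doc["gain_history"] = [float(g) for g in gain_history]
    return doc


def model_from_json(doc: dict) -> ClassifierModel:
    try:
        return ClassifierModel(
            beta=np.asarray(doc["beta"], dtype=float),
            feature_names=list(doc["feature_names"]),
            mean=np.asarray(doc["standardization"]["mean"], dtype=float),
            scale=np.asarray(doc["standardization"]["scale"], dtype=float),
            lam=float(doc.get("lambda", 0.0)),
            l1_eps=float(doc.get("l1_eps", 1e-6)),
            fim_eps=float(doc.get("fim_eps", 1e-9)),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model document: {exc}") from exc


def write_model(
    model: ClassifierModel, path: str | Path, gain_history: list[float] | None = None
) -> None:
    Path(path).write_text(json.dumps(model_to_json(model, gain_history), indent=2))


def read_model(path: str | Path) -> ClassifierModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    return model_from_json(doc)


def write_ground_truth(truth: GroundTruth, stem: str | Path) -> tuple[Path, Path]:
    """Ground truth = JSON (cell types, analyte status) + label-map TIFF."""
    stem = Path(stem)
    json_path = stem.parent / f"{stem.name}_truth.json"
    tif_path = stem.parent / f"{stem.name}_labels.tif"
    json_path.write_text(
        json.dumps(
            {
                "cell_types": {str(k): v for k, v in truth.cell_types.items()},
                "analyte_status": {
                    str(k): bool(v) for k, v in truth.analyte_status.items()
                },
            },
            indent=2,
        )
    )
    write_label_map(tif_path, truth.label_map)
    return json_path, tif_path


def read_ground_truth(json_path: str | Path, label_map_path: str | Path) -> GroundTruth:
    doc = json.loads(Path(json_path).read_text())
    return GroundTruth(
        label_map=read_label_map(label_map_path),
        cell_types={int(k): v for k, v in doc["cell_types"].items()},
        analyte_status={int(k): bool(v) for k, v in doc.get("analyte_status", {}).items()},
    )


def write_json_report(doc: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=2, default=_default))
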