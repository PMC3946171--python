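"""Per-cell analyte (immunohistochemistry marker) quantification.

DAB-stained analytes such as Ki67 or p-STAT3 read out in the nucleus;
p-ERK also occupies the cytoplasm, so it is measured inside the nucleus
*dilated by a small perimeter* (2 px = 0.5 µm at 400X by default).  Spurious
DAB background varies between tumors and between regions of one tumor, so an
extranuclear background estimate (mean intensity outside all dilated nuclei)
is subtracted from the channel — images free of background are left
essentially unchanged — and a cell is called analyte-positive when its
corrected expression exceeds a strict threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import expand_labels

from .exceptions import ParameterError, ValidationError

__all__ = [
    "AnalyteConfig",
    "AnalyteReport",
    "background_subtract",
    "measure_expression",
    "classify_positive",
    "summarize",
]


@dataclass(frozen=True)
class AnalyteConfig:
    """How one analyte channel is measured.

    ``compartment`` is ``"nuclear"`` (mean corrected intensity within the
    nucleus; Ki67, p-STAT3) or ``"nuclear_dilated"`` (within the nucleus
    expanded by ``dilation_px``; p-ERK).  The mean — not the sum — is used so
    ``threshold`` has intensity units independent of nucleus size.
    """

    analyte_name: str = "analyte"
    compartment: str = "nuclear"
    dilation_px: int = 2
    background_subtract: bool = True
    threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "nuclear_dilated"):
            raise ParameterError("compartment must be nuclear or nuclear_dilated")
        if self.dilation_px < 0:
            raise ParameterError("dilation_px must be >= 0")
        if self.threshold < 0:
            raise ParameterError("threshold must be >= 0")


@dataclass
class AnalyteReport:
    """Per-cell values plus image- and tumor-level summaries.

    ``per_cell``: cell_id, value, positive.  ``per_image``: image_id,
    ec_fraction (EC among all cells), positive_fraction (analyte-positive
    among EC; NaN when the image has no EC).  ``per_tumor``: tumor_id with
    median/25th/75th percentile of the per-image fractions.
    """

    per_cell: pd.DataFrame
    per_image: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_tumor: pd.DataFrame = field(default_factory=pd.DataFrame)


def background_subtract(
    analyte_channel: np.ndarray, label_map: np.ndarray, dilation_px: int = 2
) -> tuple[np.ndarray, float]:
    """Estimate and remove the extranuclear background.

    Background = mean intensity over pixels outside all nuclei dilated by
    ``dilation_px`` (the dilation keeps perinuclear bleed out of the
    estimate); corrected channel = max(channel - background, 0).
    """
    channel = np.asarray(analyte_channel, dtype=float)
    label_map = np.asarray(label_map)
    if channel.shape != label_map.shape:
        raise ValidationError("channel and label map shapes differ")
    nuclei = label_map > 0
    if dilation_px > 0 and nuclei.any():
        nuclei = ndi.binary_dilation(nuclei, structure=disk(dilation_px))
    outside = ~nuclei
    if not outside.any():
        raise ValidationError("no extranuclear pixels to estimate background from")
    background = float(channel[outside].mean())
    corrected = np.clip(channel - background, 0.0, None)
    return corrected, background


def measure_expression(
    corrected: np.ndarray, label_map: np.ndarray, config: AnalyteConfig
) -> pd.DataFrame:
    """Mean corrected intensity per cell in the configured compartment.

    For ``nuclear_dilated`` the label map is expanded by ``dilation_px``
    with contested dilation pixels claimed by the nearest nucleus, so no
    pixel is counted for two cells.  Returns cell_id, value.
    """
    corrected = np.asarray(corrected, dtype=float)
    label_map = np.asarray(label_map)
    if corrected.shape != label_map.shape:
        raise ValidationError("channel and label map shapes differ")
    if config.compartment == "nuclear_dilated" and config.dilation_px > 0:
        measure_map = expand_labels(label_map, distance=config.dilation_px)
    else:
        measure_map = label_map
    ids = np.unique(label_map[label_map > 0])
    if len(ids) == 0:
        return pd.DataFrame({"cell_id": [], "value": []})
    means = ndi.mean(corrected, labels=measure_map, index=ids)
    return pd.DataFrame({"cell_id": ids.astype(int), "value": np.asarray(means, float)})


def classify_positive(values: np.ndarray | pd.Series, threshold: float) -> np.ndarray:
    """Positive iff value > threshold (strictly)."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    return np.asarray(values, dtype=float) > threshold


def summarize(
    positive: np.ndarray,
    cell_classes: np.ndarray,
    image_ids: np.ndarray,
    tumor_ids: np.ndarray | None = None,
    ec_label: str | int = "EC",
) -> AnalyteReport:
    """Image- and tumor-level positivity summaries for the EC class.

    Per image: fraction of all cells that are EC, and fraction of EC that are
    analyte-positive (NaN, not 0, for images without EC).  Per tumor: median
    and 25th/75th percentiles of the per-image fractions.
    """
    positive = np.asarray(positive, dtype=bool)
    cell_classes = np.asarray(cell_classes)
    image_ids = np.asarray(image_ids)
    if not (len(positive) == len(cell_classes) == len(image_ids)):
        raise ValidationError("per-cell vectors must be aligned")
    if tumor_ids is None:
        tumor_ids = np.zeros(len(positive), dtype=int)
    tumor_ids = np.asarray(tumor_ids)
    df = pd.DataFrame(
        {
            "positive": positive,
            "is_ec": cell_classes == ec_label,
            "image_id": image_ids,
            "tumor_id": tumor_ids,
        }
    )
    per_cell = df[["positive"]].copy()

    def _img(group: pd.DataFrame) -> pd.Series:
        n_ec = int(group["is_ec"].sum())
        return pd.Series(
            {
                "ec_fraction": group["is_ec"].mean(),
                "positive_fraction": (
                    group.loc[group["is_ec"], "positive"].mean() if n_ec else np.nan
                ),
                "n_cells": len(group),
                "n_ec": n_ec,
            }
        )

    per_image = (
        df.groupby(["tumor_id", "image_id"]).apply(_img, include_groups=False).reset_index()
    )

    def _tumor(group: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("ec_fraction", "positive_fraction"):
            vals = group[col].dropna()
            if len(vals):
                q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            else:
                q25 = q50 = q75 = np.nan
            out[f"{col}_median"] = q50
            out[f"{col}_q25"] = q25
            out[f"{col}_q75"] = q75
        out["n_images"] = len(group)
        return pd.Series(out)

    per_tumor = (
        per_image.groupby("tumor_id").apply(_tumor, include_groups=False).reset_index()
    )
    return AnalyteReport(per_cell=per_cell, per_image=per_image, per_tumor=per_tumor)
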