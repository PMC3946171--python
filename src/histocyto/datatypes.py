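"""Shared in-memory containers.

A label map is a plain integer :class:`numpy.ndarray` (0 = background, k > 0 =
pixels of nucleus k); no wrapper class is imposed on it.  Feature tables are
:class:`pandas.DataFrame` objects keyed by ``cell_id`` (and ``image_id`` when
several images are pooled), with one named numeric column per feature and an
optional ``label`` column taking values in {-1, +1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Columns of a feature table that are bookkeeping, not features.
META_COLUMNS = ("cell_id", "image_id", "cluster_id", "label")

#: Default physical pixel size (µm/px) of a 400X field.
DEFAULT_PIXEL_SIZE_UM = 0.25


@dataclass
class MultiChannelImage:
    """Named single-channel grayscale images of identical shape.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"nuclear"``, ``"CD34"``, ``"Ki67"``)
        to a 2-D array.  All channels must share one shape.
    pixel_size_um
        Physical size of a pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class GroundTruth:
    """Ground truth attached to a synthetic image.

    ``label_map`` assigns each pixel to a nucleus id; ``cell_types`` maps each
    nucleus id to ``"EC"`` or ``"non-EC"``; ``analyte_status`` maps each
    nucleus id to True (analyte-positive) or False.
    """

    label_map: np.ndarray
    cell_types: dict[int, str] = field(default_factory=dict)
    analyte_status: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(np.unique(self.label_map).tolist()) - {0}
        missing = ids - set(self.cell_types)
        if missing:
            raise ValueError(f"nuclei without a cell-type entry: {sorted(missing)}")
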