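"""Per-nucleus feature computation.

Two families of features are measured from a label map:

* *intrinsic* features of the nuclear channel — size (area, perimeter),
  shape (elongation, eccentricity, convexity) and intensity/texture (mean,
  total, variance, gradient energy as a chromatin-texture surrogate);
* *associative* features of any other stain channel — mean and total
  intensity inside the nucleus plus the mean in a surrounding ring just
  outside it (e.g. ``CD34_surround``, the signature of an endothelial cell
  whose marker sits in the perinuclear vessel wall rather than the nucleus).

Shape statistics come from :func:`skimage.measure.regionprops`; elongation is
the major/minor axis ratio of the moments-equivalent ellipse, i.e. the square
root of the eigenvalue ratio of the second central moment matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk

from .exceptions import AssemblyError, ParameterError, ValidationError

__all__ = [
    "intrinsic_features",
    "associative_features",
    "assemble",
    "extract_feature_table",
]

INTRINSIC_NAMES = (
    "area",
    "perimeter",
    "elongation",
    "eccentricity",
    "convexity",
    "intensity_mean",
    "intensity_total",
    "intensity_var",
    "gradient_energy",
)


def _check_shapes(label_map: np.ndarray, channel: np.ndarray) -> None:
    if label_map.shape != channel.shape:
        raise ValidationError(
            f"label map {label_map.shape} and channel {channel.shape} differ in shape"
        )


def intrinsic_features(label_map: np.ndarray, nuclear_channel: np.ndarray) -> pd.DataFrame:
    """Shape, size, intensity and texture features per nucleus.

    Returns a DataFrame indexed by ``cell_id`` with the columns in
    :data:`INTRINSIC_NAMES`.  Empty label map gives an empty table.
    """
    label_map = np.asarray(label_map)
    channel = np.asarray(nuclear_channel, dtype=float)
    _check_shapes(label_map, channel)
    gy, gx = np.gradient(channel)
    grad_sq = gy**2 + gx**2

    rows = []
    for rp in regionprops(label_map, intensity_image=channel):
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        elong = major / minor if minor > 0 else np.inf
        mask = rp.image
        vals = rp.image_intensity[mask]
        sl = rp.slice
        rows.append(
            {
                "cell_id": rp.label,
                "area": float(rp.area),
                "perimeter": float(rp.perimeter),
                "elongation": float(elong),
                "eccentricity": float(rp.eccentricity),
                "convexity": float(rp.area / rp.area_convex),
                "intensity_mean": float(vals.mean()),
                "intensity_total": float(vals.sum()),
                "intensity_var": float(vals.var()),
                "gradient_energy": float(grad_sq[sl][mask].mean()),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["cell_id", *INTRINSIC_NAMES]).set_index("cell_id")
    out = pd.DataFrame(rows).set_index("cell_id")
    if np.isinf(out["elongation"]).any():
        # degenerate 1-px-wide regions: cap at the largest finite value seen
        finite = out.loc[np.isfinite(out["elongation"]), "elongation"]
        cap = float(finite.max()) if len(finite) else 1.0
        out["elongation"] = out["elongation"].replace(np.inf, cap)
    return out


def associative_features(
    label_map: np.ndarray,
    channel: np.ndarray,
    channel_name: str,
    ring_width: int = 2,
) -> pd.DataFrame:
    """Inside and surround statistics of a stain channel per nucleus.

    Columns: ``<name>_average`` (mean inside), ``<name>_total`` (sum inside),
    ``<name>_surround`` (mean in the ring obtained by dilating the nucleus by
    ``ring_width`` px, minus all nucleus pixels — the ring never includes any
    nucleus, its own or a neighbor's).  A ring fully occupied by neighbors
    yields surround 0 with ``<name>_surround_empty`` flagged True.
    """
    if ring_width < 1:
        raise ParameterError("ring_width must be >= 1")
    label_map = np.asarray(label_map)
    channel = np.asarray(channel, dtype=float)
    _check_shapes(label_map, channel)
    any_nucleus = label_map > 0
    selem = disk(ring_width)
    pad = ring_width

    rows = []
    for rp in regionprops(label_map):
        r0, c0, r1, c1 = rp.bbox
        r0e, c0e = max(r0 - pad, 0), max(c0 - pad, 0)
        r1e, c1e = min(r1 + pad, label_map.shape[0]), min(c1 + pad, label_map.shape[1])
        window = label_map[r0e:r1e, c0e:c1e]
        blob = window == rp.label
        ring = ndi.binary_dilation(blob, structure=selem) & ~any_nucleus[r0e:r1e, c0e:c1e]
        inside_vals = channel[r0e:r1e, c0e:c1e][blob]
        ring_vals = channel[r0e:r1e, c0e:c1e][ring]
        empty = ring_vals.size == 0
        rows.append(
            {
                "cell_id": rp.label,
                f"{channel_name}_average": float(inside_vals.mean()),
                f"{channel_name}_total": float(inside_vals.sum()),
                f"{channel_name}_surround": 0.0 if empty else float(ring_vals.mean()),
                f"{channel_name}_surround_empty": bool(empty),
            }
        )
    cols = [
        "cell_id",
        f"{channel_name}_average",
        f"{channel_name}_total",
        f"{channel_name}_surround",
        f"{channel_name}_surround_empty",
    ]
    if not rows:
        return pd.DataFrame(columns=cols).set_index("cell_id")
    return pd.DataFrame(rows).set_index("cell_id")


def assemble(row_sets: list[pd.DataFrame], image_id) -> pd.DataFrame:
    """Join per-nucleus row sets (indexed by cell_id) into one feature table.

    All row sets must cover exactly the same cell ids and contribute disjoint
    column names; violations raise :class:`AssemblyError` naming the
    offenders rather than silently introducing NaN.
    """
    if not row_sets:
        raise AssemblyError("no row sets to assemble")
    base_ids = set(row_sets[0].index)
    for i, rs in enumerate(row_sets[1:], start=2):
        if set(rs.index) != base_ids:
            diff = sorted(set(rs.index) ^ base_ids)
            raise AssemblyError(f"row set {i} has mismatched cell ids: {diff}")
    seen: dict[str, int] = {}
    for i, rs in enumerate(row_sets, start=1):
        for col in rs.columns:
            if col in seen:
                raise AssemblyError(
                    f"column {col!r} appears in row sets {seen[col]} and {i}"
                )
            seen[col] = i
    table = pd.concat(row_sets, axis=1).sort_index().reset_index()
    numeric = table.select_dtypes(include=[np.number])
    if not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise AssemblyError("assembled table contains non-finite feature values")
    table.insert(1, "image_id", image_id)
    return table


def extract_feature_table(
    label_map: np.ndarray,
    channels: dict[str, np.ndarray],
    image_id,
    nuclear_channel: str = "nuclear",
    ring_width: int = 2,
) -> pd.DataFrame:
    """One-call pipeline: intrinsic features of the nuclear channel plus
    associative features of every other channel, assembled into a table.

    Boolean surround-empty flags are carried as 0/1 numeric columns so the
    table is uniformly numeric downstream.
    """
    if nuclear_channel not in channels:
        raise ValidationError(f"missing nuclear channel {nuclear_channel!r}")
    parts = [intrinsic_features(label_map, channels[nuclear_channel])]
    for name, ch in channels.items():
        if name == nuclear_channel:
            continue
        assoc = associative_features(label_map, ch, name, ring_width=ring_width)
        flag = f"{name}_surround_empty"
        if assoc[flag].any():
            assoc[flag] = assoc[flag].astype(float)
        else:  # all-False flag would be a constant pseudo-feature downstream
            assoc = assoc.drop(columns=[flag])
        parts.append(assoc)
    return assemble(parts, image_id)
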