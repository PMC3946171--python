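"""Synthetic data emulating multiplex-stained tumor images and feature tables.

The generator produces the two kinds of input the rest of the package
consumes, with known ground truth:

* two-class Gaussian feature tables with a controlled informative/noise
  feature split and per-image (cluster) batch shifts, for exercising the
  active-learning classifier and the feature-selection baselines;
* multi-channel grayscale images (nuclear stain, CD34 endothelial marker,
  analyte such as Ki67) in which endothelial-cell (EC) nuclei are elongated
  and carry a bright CD34 ring just outside the nuclear boundary, plus a
  matching pixel-level label map and per-nucleus cell types.

Everything is driven by a single integer seed through
:class:`numpy.random.Generator`; identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as _draw_ellipse
from skimage.morphology import disk

from .datatypes import GroundTruth, MultiChannelImage
from .exceptions import GenerationError, LookupError_, ParameterError

__all__ = [
    "TabularSpec",
    "ImageSpec",
    "make_feature_dataset",
    "make_image",
    "simulated_oracle",
    "SimulatedOracle",
]

#: Rendering intensities (8-bit gray levels) for synthetic channels.
NUCLEAR_FOREGROUND = 160.0
NUCLEAR_BACKGROUND = 8.0
CD34_BACKGROUND = 4.0
ANALYTE_FOREGROUND = 150.0
CD34_RING_WIDTH_PX = 2


def _round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TabularSpec:
    """Parameters of a two-class Gaussian feature dataset.

    ``effect_size`` is the separation of the class means of each informative
    feature, in units of the within-class standard deviation (which is 1).
    ``n_clusters`` image groups receive an additive per-cluster shift on every
    feature, drawn once per cluster from N(0, ``cluster_sd``^2), emulating
    between-image staining/illumination variability.
    """

    n_cells: int = 1000
    n_informative: int = 4
    n_noise: int = 40
    effect_size: float = 2.0
    ec_fraction: float = 0.25
    n_clusters: int = 5
    cluster_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ParameterError("n_cells must be >= 4")
        if self.n_informative < 1:
            raise ParameterError("n_informative must be >= 1")
        if self.n_noise < 0:
            raise ParameterError("n_noise must be >= 0")
        if not 0.0 < self.ec_fraction < 1.0:
            raise ParameterError("ec_fraction must lie strictly in (0, 1)")
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        if self.cluster_sd < 0:
            raise ParameterError("cluster_sd must be >= 0")


def make_feature_dataset(spec: TabularSpec) -> pd.DataFrame:
    """Generate a labeled two-class feature table.

    Returns a DataFrame with columns ``cell_id``, ``image_id``, ``label``
    (+1 = EC, -1 = non-EC), then ``inf_01..`` informative features whose class
    means differ by ``effect_size`` standard deviations, then ``noise_01..``
    features identically distributed in both classes.  The ``label`` column is
    the hidden ground truth: training code must obtain labels through an
    oracle, not by peeking at the column.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    n_pos = _round_half_up(spec.ec_fraction * n)
    if n_pos == 0 or n_pos == n:
        raise ParameterError("ec_fraction leaves one class empty at this n_cells")

    y = np.full(n, -1, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    # round-robin cluster sizes, randomly assigned to cells
    cluster_of = rng.permutation(np.arange(n) % spec.n_clusters)

    half = spec.effect_size / 2.0
    inf = rng.standard_normal((n, spec.n_informative)) + half * y[:, None]
    noise = rng.standard_normal((n, spec.n_noise))
    X = np.hstack([inf, noise])

    shifts = rng.normal(0.0, spec.cluster_sd, size=(spec.n_clusters, X.shape[1]))
    X += shifts[cluster_of]

    cols = [f"inf_{i + 1:02d}" for i in range(spec.n_informative)]
    cols += [f"noise_{i + 1:02d}" for i in range(spec.n_noise)]
    table = pd.DataFrame(X, columns=cols)
    table.insert(0, "label", y)
    table.insert(0, "image_id", cluster_of)
    table.insert(0, "cell_id", np.arange(1, n + 1))
    return table


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic multi-channel tumor image.

    EC nuclei are ellipses with major/minor axis ratio ``ec_elongation``
    (area-preserving relative to a circle of the sampled radius); non-EC
    nuclei are near-circular.  The CD34 channel is bright only in a ring of
    width 2 px immediately outside EC nuclei.  The analyte channel is bright
    inside analyte-positive nuclei and carries a constant
    ``analyte_background`` outside all nuclei.  ``analyte_positive_fraction``
    is the fraction of EC nuclei that are analyte-positive (non-EC nuclei are
    always analyte-negative).
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 20
    nucleus_radius_mean: float = 7.0
    nucleus_radius_sd: float = 1.0
    ec_fraction: float = 0.25
    ec_elongation: float = 2.5
    cd34_ring_intensity: float = 200.0
    analyte_positive_fraction: float = 0.3
    analyte_background: float = 0.0
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ParameterError("image must be at least 32x32 pixels")
        if self.n_nuclei < 1:
            raise ParameterError("n_nuclei must be >= 1")
        if not 0.0 <= self.ec_fraction <= 1.0:
            raise ParameterError("ec_fraction must lie in [0, 1]")
        if self.ec_elongation < 1.0:
            raise ParameterError("ec_elongation is a major/minor ratio >= 1")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ParameterError("noise_model must be poisson, gaussian or none")
        if not 0.0 <= self.analyte_positive_fraction <= 1.0:
            raise ParameterError("analyte_positive_fraction must lie in [0, 1]")
        if self.analyte_background < 0:
            raise ParameterError("analyte_background must be >= 0")
        if not 0 <= self.cd34_ring_intensity <= 255:
            raise ParameterError("cd34_ring_intensity must fit in 8 bits")


def _place_nuclei(spec: ImageSpec, rng: np.random.Generator):
    """Place non-overlapping ellipses; returns (label_map, is_ec array).

    EC assignment is decided up front: exactly ``round_half_up(ec_fraction *
    n_nuclei)`` nuclei (a seeded random subset) are EC.  Placement retries up
    to 200 times per nucleus; failure raises :class:`GenerationError`.
    """
    h, w = spec.height, spec.width
    n = spec.n_nuclei
    n_ec = _round_half_up(spec.ec_fraction * n)
    is_ec = np.zeros(n, dtype=bool)
    is_ec[rng.permutation(n)[:n_ec]] = True

    label_map = np.zeros((h, w), dtype=np.int32)
    # keep-out zone: nuclei plus a 3 px margin, so CD34 rings do not touch
    occupied = np.zeros((h, w), dtype=bool)
    margin_selem = disk(3)

    for k in range(n):
        elong = spec.ec_elongation if is_ec[k] else 1.05
        placed = False
        for _ in range(200):
            r = rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd)
            r = float(np.clip(r, 3.0, min(h, w) / 4.0))
            a = r * math.sqrt(elong)  # major semi-axis
            b = r / math.sqrt(elong)  # minor semi-axis
            theta = rng.uniform(0.0, math.pi)
            pad = a + 4.0
            cy = rng.uniform(pad, h - pad)
            cx = rng.uniform(pad, w - pad)
            rr, cc = _draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            if rr.size < 9 or occupied[rr, cc].any():
                continue
            label_map[rr, cc] = k + 1
            blob = np.zeros((h, w), dtype=bool)
            blob[rr, cc] = True
            occupied |= binary_dilation(blob, margin_selem)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {k + 1}/{n} without overlap; "
                "reduce n_nuclei or nucleus size"
            )
    return label_map, is_ec


def _apply_noise(mean_image: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "poisson":
        noisy = rng.poisson(mean_image).astype(np.float64)
    elif model == "gaussian":
        noisy = mean_image + rng.normal(0.0, 5.0, size=mean_image.shape)
    else:  # "none"
        noisy = mean_image
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def make_image(spec: ImageSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a synthetic multi-channel image with its ground truth.

    Channels: ``nuclear`` (all nuclei bright), ``CD34`` (bright 2 px ring
    around EC nuclei only), ``analyte`` (bright inside analyte-positive
    nuclei, constant background elsewhere outside nuclei).  Noise is applied
    to the rendered mean image per ``spec.noise_model``.
    """
    rng = np.random.default_rng(spec.seed)
    label_map, is_ec = _place_nuclei(spec, rng)
    nuclei = label_map > 0

    nuclear_mean = np.where(nuclei, NUCLEAR_FOREGROUND, NUCLEAR_BACKGROUND)

    ring_selem = disk(CD34_RING_WIDTH_PX)
    cd34_mean = np.full(label_map.shape, CD34_BACKGROUND)
    for k in np.flatnonzero(is_ec):
        blob = label_map == (k + 1)
        ring = binary_dilation(blob, ring_selem) & ~nuclei
        cd34_mean[ring] = spec.cd34_ring_intensity

    ec_ids = (np.flatnonzero(is_ec) + 1).tolist()
    n_pos = _round_half_up(spec.analyte_positive_fraction * len(ec_ids))
    pos_ids = set(
        np.array(ec_ids, dtype=int)[rng.permutation(len(ec_ids))[:n_pos]].tolist()
    ) if ec_ids else set()

    # spurious DAB background is a property of the whole slide, so it adds
    # uniformly — inside nuclei as well as outside
    analyte_mean = np.full(label_map.shape, float(spec.analyte_background))
    for k in pos_ids:
        analyte_mean[label_map == k] += ANALYTE_FOREGROUND

    channels = {
        "nuclear": _apply_noise(nuclear_mean, spec.noise_model, rng),
        "CD34": _apply_noise(cd34_mean, spec.noise_model, rng),
        "analyte": _apply_noise(analyte_mean, spec.noise_model, rng),
    }
    truth = GroundTruth(
        label_map=label_map,
        cell_types={
            k + 1: ("EC" if is_ec[k] else "non-EC") for k in range(spec.n_nuclei)
        },
        analyte_status={k + 1: (k + 1) in pos_ids for k in range(spec.n_nuclei)},
    )
    return MultiChannelImage(channels), truth


class SimulatedOracle:
    """Callable standing in for the human trainer.

    Maps a cell id to its ±1 label from ground truth, optionally flipping each
    answer independently with probability ``flip_probability`` to model rater
    inconsistency.  Flips are memoized so repeated queries for the same cell
    are answered consistently, as a single human rater would within a session.
    """

    def __init__(
        self,
        labels: dict[int, int],
        flip_probability: float = 0.0,
        seed: int | None = None,
    ) -> None:
        if not 0.0 <= flip_probability <= 1.0:
            raise ParameterError("flip_probability must lie in [0, 1]")
        self._labels = dict(labels)
        self._flip_p = flip_probability
        self._rng = np.random.default_rng(seed)
        self._answers: dict[int, int] = {}
        self.n_queries = 0

    def __call__(self, cell_id: int) -> int:
        cell_id = int(cell_id)
        if cell_id not in self._labels:
            raise LookupError_(f"unknown cell id {cell_id}")
        self.n_queries += 1
        if cell_id not in self._answers:
            label = self._labels[cell_id]
            if self._flip_p > 0 and self._rng.random() < self._flip_p:
                label = -label
            self._answers[cell_id] = int(label)
        return self._answers[cell_id]

    def ids(self) -> list[int]:
        return sorted(self._labels)


def simulated_oracle(
    truth: GroundTruth | pd.DataFrame,
    flip_probability: float = 0.0,
    seed: int | None = None,
) -> SimulatedOracle:
    """Build a labeling oracle from a :class:`GroundTruth` or a labeled table.

    For a ground-truth object, EC maps to +1 and non-EC to -1.  For a
    DataFrame, the ``cell_id`` and ``label`` columns are used.
    """
    if isinstance(truth, GroundTruth):
        labels = {
            int(k): (1 if t == "EC" else -1) for k, t in truth.cell_types.items()
        }
    else:
        if "label" not in truth.columns or "cell_id" not in truth.columns:
            raise ParameterError("labeled table needs cell_id and label columns")
        labels = {
            int(c): int(l) for c, l in zip(truth["cell_id"], truth["label"])
        }
    return SimulatedOracle(labels, flip_probability=flip_probability, seed=seed)
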