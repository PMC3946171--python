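"""Classifier/rater agreement metrics.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV) with the EC
class (+1) as positive; Cohen's kappa for chance-corrected pairwise rater
agreement, kappa matrices for several raters, agreement partitions over the
union-positive subset, and cluster (per-image) bootstrap confidence
intervals for the plug-in metrics, which respect the correlation between
nuclei sampled from the same image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics",
    "cohen_kappa",
    "kappa_matrix",
    "agreement_partition",
    "cluster_bootstrap_ci",
    "match_label_maps",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN); a zero denominator gives NaN (reported missing)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _binary(v) -> np.ndarray:
    a = np.asarray(v)
    vals = set(np.unique(a).tolist())
    if not vals <= {-1, 1}:
        raise ValidationError(f"ratings must be -1/+1, got values {sorted(vals)}")
    return a.astype(int)


def confusion(truth, predicted) -> ConfusionCounts:
    """Standard confusion counts with +1 (EC) as the positive class."""
    t, p = _binary(truth), _binary(predicted)
    if len(t) != len(p):
        raise ValidationError("truth and prediction lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == -1) & (p == 1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fn=int(np.sum((t == 1) & (p == -1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> MetricReport:
    return MetricReport(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        counts=counts,
    )


def cohen_kappa(rating_a, rating_b) -> float:
    """Chance-corrected agreement kappa = (Po - Pe)/(1 - Pe).

    Po is the observed agreement proportion; Pe the agreement expected if the
    two raters called positives independently at their observed marginal
    rates.  When both raters are constant and identical, Pe = 1 and kappa is
    undefined (NaN).
    """
    a, b = _binary(rating_a), _binary(rating_b)
    if len(a) != len(b):
        raise ValidationError("rating vectors must be aligned")
    if len(a) == 0:
        raise ValidationError("empty rating vectors")
    n = len(a)
    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a == 1)), float(np.mean(b == 1))
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def kappa_matrix(ratings: list[np.ndarray]) -> np.ndarray:
    """Pairwise Cohen's kappa; symmetric, diagonal 1 (self-agreement)."""
    r = len(ratings)
    out = np.ones((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = cohen_kappa(ratings[i], ratings[j])
    return out


def agreement_partition(ratings: list[np.ndarray]) -> pd.DataFrame:
    """How many raters call each union-positive cell positive.

    Cells negative by all raters are excluded.  Returns one row per count
    k = 1..R with the number and fraction of union-positive cells called
    positive by exactly k raters; fractions sum to 1 (empty union-positive
    set gives an empty frame).
    """
    mats = np.stack([_binary(r) for r in ratings])
    if len({m.shape for m in mats}) > 1:
        raise ValidationError("rating vectors must be aligned")
    pos_counts = (mats == 1).sum(axis=0)
    union = pos_counts > 0
    kept = pos_counts[union]
    if kept.size == 0:
        return pd.DataFrame(columns=["n_raters_positive", "count", "fraction"])
    ks = np.arange(1, len(ratings) + 1)
    counts = np.array([(kept == k).sum() for k in ks])
    return pd.DataFrame(
        {"n_raters_positive": ks, "count": counts, "fraction": counts / len(kept)}
    )


def match_label_maps(segmented: np.ndarray, reference: np.ndarray) -> pd.DataFrame:
    """Match each segmented region to the reference nucleus it overlaps most.

    Returns one row per segmented id with the best-overlapping reference id
    (0 when the region is mostly background), the overlap pixel count and
    the Jaccard index with that reference nucleus.  Used to transfer
    ground-truth cell types onto segmented cells.
    """
    seg = np.asarray(segmented)
    ref = np.asarray(reference)
    if seg.shape != ref.shape:
        raise ValidationError("label maps must share a shape")
    rows = []
    for sid in np.unique(seg[seg > 0]):
        region = seg == sid
        ids, counts = np.unique(ref[region], return_counts=True)
        best = ids[np.argmax(counts)]
        overlap = int(counts.max())
        if best == 0:
            jacc = 0.0
        else:
            ref_region = ref == best
            jacc = float(overlap / np.logical_or(region, ref_region).sum())
        rows.append(
            {"cell_id": int(sid), "reference_id": int(best),
             "overlap": overlap, "jaccard": jacc}
        )
    return pd.DataFrame(rows, columns=["cell_id", "reference_id", "overlap", "jaccard"])


def cluster_bootstrap_ci(
    truth,
    predicted,
    image_ids,
    metric: str = "sensitivity",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a confusion metric, resampling images.

    Whole images (clusters) are drawn with replacement so within-image
    correlation between nuclei is respected.  Resamples on which the metric
    is undefined are redrawn (bounded retries) with a warning.  Returns the
    (2.5th, 97.5th) percentile interval; deterministic given ``seed``.
    """
    t, p = _binary(truth), _binary(predicted)
    imgs = np.asarray(image_ids)
    if not (len(t) == len(p) == len(imgs)):
        raise ValidationError("aligned truth, prediction and image ids required")
    unique_imgs = np.unique(imgs)
    if len(unique_imgs) < 2:
        raise ParameterError("cluster bootstrap needs at least two images")
    if metric not in ("sensitivity", "specificity", "ppv", "npv"):
        raise ParameterError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    by_img = {g: np.flatnonzero(imgs == g) for g in unique_imgs}

    stats = []
    attempts = 0
    max_attempts = 10 * n_boot
    warned = False
    while len(stats) < n_boot and attempts < max_attempts:
        attempts += 1
        draw = rng.choice(unique_imgs, size=len(unique_imgs), replace=True)
        idx = np.concatenate([by_img[g] for g in draw])
        value = getattr(metrics(confusion(t[idx], p[idx])), metric)
        if np.isnan(value):
            if not warned:
                warnings.warn(f"{metric} undefined in a bootstrap resample; redrawing")
                warned = True
            continue
        stats.append(value)
    if not stats:
        raise ValidationError("metric undefined in every bootstrap resample")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)
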