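"""Hybrid nuclear segmentation.

Pipeline: (1) a two-component Poisson-mixture minimum-error threshold
separates nuclear foreground from background; (2) the binary mask is refined
either morphologically or by a graph-cut binary MRF whose data terms are the
per-class Poisson negative log-likelihoods; (3) scale-normalized
Laplacian-of-Gaussian filtering over a geometric scale ladder detects one
seed per nucleus; (4) mask pixels are partitioned among seeds by ascent on
the LoG response (watershed from the seed markers); (5) adjacent fragments
are merged whenever the merged region scores as more nucleus-like (log-normal
size prior + moments-ellipse fit quality) than either fragment alone.

The module is fully deterministic: there is no randomness anywhere, and ties
are broken by gray level (thresholding), row-major position (seeds) or
smallest label id (merging).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.special import gammaln, xlogy
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

from .exceptions import ParameterError, ValidationError

__all__ = [
    "SegConfig",
    "PoissonMixtureFit",
    "poisson_minimum_error_threshold",
    "binarize",
    "multiscale_log_seeds",
    "local_max_clustering",
    "region_score",
    "merge_refinement",
    "segment_nuclei",
]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation parameters.

    ``scale_min``/``scale_max`` bound the LoG sigma ladder in pixels (a
    nucleus of radius r responds most strongly near sigma = r/sqrt(2));
    ``min_size``/``max_size`` are area bounds in pixels applied before
    merging; ``size_prior_mean`` is the prior mean nucleus area in pixels
    (None = use the median area of the initial fragments) and
    ``size_prior_sd`` its log-scale spread; ``merge_alpha`` weights the size
    prior against ellipse-fit quality in the merge score.
    """

    scale_min: float = 3.0
    scale_max: float = 10.0
    min_size: int = 20
    max_size: int = 2000
    use_graphcut: bool = False
    smoothness: float = 2.0
    merge_alpha: float = 0.5
    size_prior_mean: float | None = None
    size_prior_sd: float = 0.6
    n_scales: int = 6

    def __post_init__(self) -> None:
        if self.scale_min <= 0 or self.scale_min > self.scale_max:
            raise ParameterError("need 0 < scale_min <= scale_max")
        if self.min_size >= self.max_size:
            raise ParameterError("need min_size < max_size")
        if not 0.0 <= self.merge_alpha <= 1.0:
            raise ParameterError("merge_alpha must lie in [0, 1]")


@dataclass(frozen=True)
class PoissonMixtureFit:
    """Two-component Poisson mixture split at a gray-level threshold."""

    threshold: int
    prior0: float
    prior1: float
    mu0: float
    mu1: float
    criterion: float


def poisson_minimum_error_threshold(histogram: np.ndarray) -> PoissonMixtureFit:
    """Exhaustive minimum-error threshold under a two-Poisson mixture.

    For every candidate threshold T, the gray levels <= T form the background
    class and > T the foreground class; priors and Poisson means are the
    plug-in estimates from the histogram, and the criterion is the total
    negative log-likelihood of the labeled mixture.  The argmin T is returned
    (smallest T on exact ties).
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or np.any(h < 0):
        raise ValidationError("histogram must be a 1-D array of nonnegative counts")
    occupied = np.flatnonzero(h)
    if len(occupied) < 2:
        raise ValidationError("histogram has fewer than two occupied bins")

    g = np.arange(len(h), dtype=float)
    n_cum = np.cumsum(h)
    m_cum = np.cumsum(h * g)
    lgf_cum = np.cumsum(h * gammaln(g + 1.0))
    n_tot, m_tot, lgf_tot = n_cum[-1], m_cum[-1], lgf_cum[-1]

    # candidate T: both sides nonempty
    ts = np.arange(occupied[0], occupied[-1])
    n0, m0, l0 = n_cum[ts], m_cum[ts], lgf_cum[ts]
    n1, m1, l1 = n_tot - n0, m_tot - m0, lgf_tot - l0
    p0, p1 = n0 / n_tot, n1 / n_tot
    mu0, mu1 = m0 / n0, m1 / n1
    # sum_g h(g) * [-ln P - g ln mu + mu + ln g!]
    j0 = -n0 * np.log(p0) - xlogy(m0, mu0) + n0 * mu0 + l0
    j1 = -n1 * np.log(p1) - xlogy(m1, mu1) + n1 * mu1 + l1
    crit = j0 + j1
    k = int(np.argmin(crit))  # first minimum -> smallest T
    return PoissonMixtureFit(
        threshold=int(ts[k]),
        prior0=float(p0[k]),
        prior1=float(p1[k]),
        mu0=float(mu0[k]),
        mu1=float(mu1[k]),
        criterion=float(crit[k]),
    )


def _poisson_nll(values: np.ndarray, prior: float, mu: float) -> np.ndarray:
    """Per-pixel -ln[P * Pois(g; mu)]; mu is floored away from zero."""
    mu = max(mu, 1e-6)
    return (
        -math.log(max(prior, 1e-12))
        - xlogy(values, mu)
        + mu
        + gammaln(values + 1.0)
    )


def _graphcut_refine(image: np.ndarray, fit: PoissonMixtureFit, smoothness: float) -> np.ndarray:
    """Binary MRF min cut: Poisson NLL data terms + Potts smoothness.

    Solved exactly by max-flow (scipy); the foreground is the source side of
    the minimum cut, recovered by BFS on the residual graph.
    """
    g = np.maximum(np.rint(image).astype(np.int64), 0).astype(float)
    cost_bg = _poisson_nll(g, fit.prior0, fit.mu0).ravel()
    cost_fg = _poisson_nll(g, fit.prior1, fit.mu1).ravel()

    h, w = image.shape
    n = h * w
    s, t = n, n + 1
    scale = 100.0
    cap_max = 10**7

    def q(x):
        return np.clip(np.rint(x * scale), 0, cap_max).astype(np.int64)

    rows, cols, caps = [], [], []
    # t-links: cut s->i pays the background cost, i->t the foreground cost
    idx = np.arange(n)
    rows.append(np.full(n, s)); cols.append(idx); caps.append(q(cost_bg))
    rows.append(idx); cols.append(np.full(n, t)); caps.append(q(cost_fg))
    # n-links (4-connectivity), both directions
    lam = int(round(smoothness * scale))
    if lam > 0:
        ii = np.arange(n).reshape(h, w)
        for a, b in ((ii[:-1, :], ii[1:, :]), (ii[:, :-1], ii[:, 1:])):
            a, b = a.ravel(), b.ravel()
            rows.append(a); cols.append(b); caps.append(np.full(len(a), lam))
            rows.append(b); cols.append(a); caps.append(np.full(len(a), lam))
    graph = csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
        dtype=np.int64,
    )
    graph.sum_duplicates()
    res = maximum_flow(graph.astype(np.int32), s, t)
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    fg = np.zeros(n + 2, dtype=bool)
    fg[order] = True
    return fg[:n].reshape(h, w)


def binarize(image: np.ndarray, fit: PoissonMixtureFit, config: SegConfig) -> np.ndarray:
    """Foreground mask from the mixture threshold, refined.

    With ``use_graphcut`` the threshold only initializes nothing — the MRF is
    solved from the data terms directly (smoothness=0 reduces exactly to the
    per-pixel likelihood-ratio mask).  Otherwise the thresholded mask gets a
    morphological clean-up (hole fill + opening, radius 1).
    """
    image = np.asarray(image)
    if config.use_graphcut:
        return _graphcut_refine(image, fit, config.smoothness)
    mask = image > fit.threshold
    mask = ndi.binary_fill_holes(mask)
    # opening by reconstruction: drops specks that do not survive a radius-1
    # erosion but restores surviving components pixel-exactly
    seed = ndi.binary_erosion(mask, structure=disk(1))
    return ndi.binary_propagation(seed, mask=mask)


def _log_response(image: np.ndarray, config: SegConfig):
    """Across-scale max of the scale-normalized LoG response and the argmax
    scale per pixel (bright blobs give positive response)."""
    img = np.asarray(image, dtype=float)
    # remove the DC offset: LoG of a constant is zero analytically, but the
    # truncated kernel leaves a residue proportional to the offset
    img = img - img.mean()
    sigmas = np.geomspace(config.scale_min, config.scale_max, config.n_scales)
    best = np.full(img.shape, -np.inf)
    best_sigma = np.full(img.shape, sigmas[0])
    for s in sigmas:
        resp = -(s**2) * ndi.gaussian_laplace(img, s)
        upd = resp > best
        best[upd] = resp[upd]
        best_sigma[upd] = s
    return best, best_sigma


def multiscale_log_seeds(
    image: np.ndarray, mask: np.ndarray, config: SegConfig
) -> list[tuple[int, int, float]]:
    """Blob seeds as (row, col, scale) from the multiscale LoG response.

    Local maxima of the across-scale maximum response inside the mask are
    collected, then greedily pruned in descending response order so that no
    two surviving seeds are closer than the stronger seed's detected scale.
    The result is sorted row-major for a deterministic ordering.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    resp, sigma_at = _log_response(image, config)
    labels = mask.astype(np.uint8)
    coords = peak_local_max(
        resp, min_distance=1, threshold_abs=1e-9, labels=labels, exclude_border=False
    )
    if len(coords) == 0:
        return []
    r, c = coords[:, 0], coords[:, 1]
    vals = resp[r, c]
    # a genuinely flat field produces only numerical LoG residue
    strong = vals > 1e-6
    r, c, vals = r[strong], c[strong], vals[strong]
    if len(r) == 0:
        return []
    # descending response, ties row-major
    order = np.lexsort((c, r, -vals))
    kept: list[tuple[int, int, float]] = []
    for i in order:
        ri, ci, si = int(r[i]), int(c[i]), float(sigma_at[r[i], c[i]])
        ok = True
        for rk, ck, sk in kept:
            if (ri - rk) ** 2 + (ci - ck) ** 2 < sk**2:
                ok = False
                break
        if ok:
            kept.append((ri, ci, si))
    kept.sort(key=lambda p: (p[0], p[1]))
    return kept


def local_max_clustering(
    response: np.ndarray, seeds: list[tuple[int, int, float]], mask: np.ndarray
) -> np.ndarray:
    """Partition mask pixels among seeds by ascent on the response field.

    Implemented as a marker-based watershed of the inverted response (the
    catchment basin of a seed is exactly the set of pixels whose steepest
    ascent path ends at that seed); background stays 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not seeds:
        if mask.any():
            warnings.warn("no seeds inside a nonempty mask; one region returned")
            return mask.astype(np.int32)
        return np.zeros(mask.shape, dtype=np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c, _s) in enumerate(seeds, start=1):
        markers[r, c] = i
    return watershed(-np.asarray(response, float), markers, mask=mask).astype(np.int32)


def _moments_ellipse_area(coords_r: np.ndarray, coords_c: np.ndarray) -> float:
    """Area of the ellipse with the region's second central moments."""
    if len(coords_r) < 2:
        return 0.0
    rc = np.stack([coords_r, coords_c]).astype(float)
    cov = np.cov(rc, bias=True) + np.eye(2) * (1.0 / 12.0)  # pixel extent
    ev = np.linalg.eigvalsh(cov)
    if np.any(ev <= 0):
        return 0.0
    return float(math.pi * 4.0 * math.sqrt(ev[0] * ev[1]))


def region_score(
    region_mask: np.ndarray, image: np.ndarray, config: SegConfig,
    size_prior_mean: float | None = None,
) -> float:
    """Plausibility that a pixel set is a single whole nucleus.

    ``merge_alpha`` weights a log-normal size prior (0 at the prior-mean
    area, increasingly negative away from it) against ellipse-fit quality
    (region area / area of the moments-fit ellipse, capped at 1, which drops
    for dumbbell-shaped unions of two nuclei).  Higher is more nucleus-like.
    """
    rr, cc = np.nonzero(np.asarray(region_mask, bool))
    area = len(rr)
    if area == 0:
        raise ValidationError("empty region")
    prior_mean = size_prior_mean or config.size_prior_mean
    if prior_mean is None or prior_mean <= 0:
        prior_mean = 150.0
    size_term = -0.5 * ((math.log(area) - math.log(prior_mean)) / config.size_prior_sd) ** 2
    e_area = _moments_ellipse_area(rr, cc)
    quality = min(area / e_area, 1.0) if e_area > 0 else 0.0
    return config.merge_alpha * size_term + (1.0 - config.merge_alpha) * quality


def _adjacent_pairs(label_map: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of distinct positive labels sharing a 4-adjacent boundary."""
    pairs: set[tuple[int, int]] = set()
    for a, b in (
        (label_map[:-1, :], label_map[1:, :]),
        (label_map[:, :-1], label_map[:, 1:]),
    ):
        sel = (a != b) & (a > 0) & (b > 0)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            pairs.add((int(min(x, y)), int(max(x, y))))
    return pairs


def relabel_sequential(label_map: np.ndarray) -> np.ndarray:
    """Relabel positive ids to a contiguous 1..K, ordered by original id."""
    out = np.zeros_like(label_map, dtype=np.int32)
    for new, old in enumerate(np.unique(label_map[label_map > 0]), start=1):
        out[label_map == old] = new
    return out


def merge_refinement(
    initial: np.ndarray, image: np.ndarray, config: SegConfig
) -> np.ndarray:
    """Merge adjacent fragments that score better together than apart.

    Repeatedly scans adjacent label pairs in ascending (min id, max id) order
    and merges a pair whenever the union's region score exceeds both
    fragments' scores; stops when a full pass makes no merge.  Output ids are
    relabeled contiguously.  Because merges require a strict score
    improvement over the maximum, the minimum score present in the map never
    decreases, and the procedure is idempotent.
    """
    lm = np.asarray(initial).copy()
    labels = [int(l) for l in np.unique(lm[lm > 0])]
    if not labels:
        return lm.astype(np.int32)
    prior_mean = config.size_prior_mean
    if prior_mean is None:
        areas = [int((lm == l).sum()) for l in labels]
        prior_mean = float(np.median(areas))
    scores = {
        l: region_score(lm == l, image, config, size_prior_mean=prior_mean)
        for l in labels
    }
    changed = True
    while changed:
        changed = False
        for a, b in sorted(_adjacent_pairs(lm)):
            if a not in scores or b not in scores:
                continue
            union = (lm == a) | (lm == b)
            s_union = region_score(union, image, config, size_prior_mean=prior_mean)
            if s_union > max(scores[a], scores[b]):
                lm[lm == b] = a
                scores[a] = s_union
                del scores[b]
                changed = True
    return relabel_sequential(lm)


def segment_nuclei(image: np.ndarray, config: SegConfig | None = None) -> np.ndarray:
    """Full hybrid pipeline: threshold, binarize, seed, cluster, filter, merge.

    Returns an int32 label map with contiguous ids 1..K (0 = background).
    Deterministic: the same image always yields the identical map.
    """
    config = config or SegConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("expected a 2-D grayscale image")
    values = np.maximum(np.rint(image).astype(np.int64), 0).ravel()
    hist = np.bincount(values)
    try:
        fit = poisson_minimum_error_threshold(hist)
    except ValidationError:
        return np.zeros(image.shape, dtype=np.int32)  # blank/constant image
    mask = binarize(image, fit, config)
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    resp, _ = _log_response(image, config)
    seeds = multiscale_log_seeds(image, mask, config)
    initial = local_max_clustering(resp, seeds, mask)
    # size filter before merging
    ids, counts = np.unique(initial[initial > 0], return_counts=True)
    bad = ids[(counts < config.min_size) | (counts > config.max_size)]
    if len(bad):
        initial[np.isin(initial, bad)] = 0
    if not (initial > 0).any():
        return np.zeros(image.shape, dtype=np.int32)
    return merge_refinement(initial, image, config)
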