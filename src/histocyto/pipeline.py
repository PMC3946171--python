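"""End-to-end convenience pipeline on synthetic cohorts.

Chains the full analysis — render images, segment nuclei, extract features,
pool cells across images, train the active-learning EC classifier against a
simulated oracle, classify every remaining cell — and scores the result
against generator ground truth.  Used by the reproduction script and the
acceptance suite; each stage is the same public function a user would call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import active
from .evaluation import MetricReport, confusion, match_label_maps, metrics
from .features import extract_feature_table
from .segmentation import SegConfig, segment_nuclei
from .synthetic import ImageSpec, SimulatedOracle, make_image

__all__ = ["CohortResult", "build_synthetic_cohort", "classify_synthetic_cohort"]


@dataclass
class CohortResult:
    """Pooled feature table with ground-truth labels, AL state, metrics."""

    pool: pd.DataFrame
    truth_labels: dict[int, int]
    state: active.ALState
    report: MetricReport
    n_evaluated: int = 0
    mean_jaccard: float = field(default=float("nan"))


def build_synthetic_cohort(
    image_seeds: list[int],
    image_kwargs: dict | None = None,
    seg_config: SegConfig | None = None,
) -> tuple[pd.DataFrame, dict[int, int], float]:
    """Render, segment and featurize a cohort of synthetic images.

    Cells are re-keyed with unique integer ids across images.  Each segmented
    cell inherits the type of the ground-truth nucleus it overlaps most
    (spurious regions that overlap only background count as non-EC).
    Returns (pooled feature table, cell-id -> ±1 truth map, mean Jaccard of
    matched cells).
    """
    image_kwargs = image_kwargs or {}
    frames, truth_labels, jaccards = [], {}, []
    next_id = 1
    for img_idx, seed in enumerate(image_seeds):
        image, truth = make_image(ImageSpec(seed=seed, **image_kwargs))
        label_map = segment_nuclei(image["nuclear"], seg_config)
        table = extract_feature_table(label_map, image.channels, image_id=img_idx)
        matched = match_label_maps(label_map, truth.label_map).set_index("cell_id")
        new_ids = {}
        for cid in table["cell_id"]:
            ref = int(matched.loc[int(cid), "reference_id"])
            truth_labels[next_id] = 1 if truth.cell_types.get(ref) == "EC" else -1
            jaccards.append(float(matched.loc[int(cid), "jaccard"]))
            new_ids[int(cid)] = next_id
            next_id += 1
        table = table.assign(cell_id=table["cell_id"].map(new_ids))
        frames.append(table)
    pool = pd.concat(frames, ignore_index=True)
    return pool, truth_labels, float(np.mean(jaccards)) if jaccards else float("nan")


def classify_synthetic_cohort(
    image_seeds: list[int],
    al_config: active.ALConfig | None = None,
    image_kwargs: dict | None = None,
    seg_config: SegConfig | None = None,
) -> CohortResult:
    """Full pipeline: cohort -> AL training -> classification -> metrics.

    The simulated oracle answers label queries from ground truth; after
    training, every cell outside the training set is classified and
    sensitivity/specificity are computed against the generator's cell types.
    """
    al_config = al_config or active.ALConfig()
    pool, truth_labels, mean_jacc = build_synthetic_cohort(
        image_seeds, image_kwargs, seg_config
    )
    oracle = SimulatedOracle(truth_labels)
    state = active.run_active_learning(pool, oracle, al_config)
    rest = pool[~pool["cell_id"].isin(state.labeled_ids)]
    _, predicted = active.predict_table(state.model, rest)
    truth_vec = np.array([truth_labels[int(c)] for c in rest["cell_id"]])
    report = metrics(confusion(truth_vec, predicted))
    return CohortResult(
        pool=pool,
        truth_labels=truth_labels,
        state=state,
        report=report,
        n_evaluated=len(rest),
        mean_jaccard=mean_jacc,
    )
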