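"""Scoring the pipeline against synthetic ground truth.

Detections are matched to ground-truth cells greedily by centroid
distance (nearest first, one-to-one, within a match radius); a match
with the right class counts toward recall.  Detections left unmatched
are false positives — on recipes whose platelets sit below the area
filter, any false positive indicates a platelet or artifact leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import WBCClass
from .pipeline import PipelineConfig, analyze_image
from .synthetic import generate_smear, random_composition, random_recipe


@dataclass
class SuiteResult:
    """Aggregate scores of a multi-image synthetic run."""

    n_images: int
    truth_counts: dict[WBCClass, int]
    correct_counts: dict[WBCClass, int]
    false_positives: int
    max_count_error: int
    images_within_1: int
    per_image: pd.DataFrame = field(repr=False, default=None)

    def recall(self, cls: WBCClass) -> float | None:
        n = self.truth_counts[cls]
        return None if n == 0 else self.correct_counts[cls] / n

    @property
    def overall_recall(self) -> float:
        total = sum(self.truth_counts.values())
        return sum(self.correct_counts.values()) / total if total else 1.0


def match_detections(
    detections, truth: pd.DataFrame, match_radius_px: float = 60.0
) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy one-to-one nearest matching of detections to truth cells.

    Returns (matches, unmatched_detection_indices); matches are
    (detection index, truth row index) pairs.
    """
    if len(detections) == 0 or len(truth) == 0:
        return [], list(range(len(detections)))
    det_xy = np.array([d.group_centroid_xy for d in detections])
    tru_xy = truth[["center_x", "center_y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(det_xy[:, None, :] - tru_xy[None, :, :], axis=-1)
    pairs = sorted(
        ((dist[i, j], i, j) for i in range(len(detections)) for j in range(len(truth))),
    )
    used_d, used_t = set(), set()
    matches = []
    for d, i, j in pairs:
        if d > match_radius_px:
            break
        if i in used_d or j in used_t:
            continue
        matches.append((i, j))
        used_d.add(i)
        used_t.add(j)
    unmatched = [i for i in range(len(detections)) if i not in used_d]
    return matches, unmatched


def score_image(result, truth: pd.DataFrame, match_radius_px: float = 60.0):
    """Per-class truth/correct counts, count errors and false positives
    for one image."""
    matches, unmatched = match_detections(
        result.detections, truth, match_radius_px
    )
    truth_counts = {c: 0 for c in WBCClass}
    correct = {c: 0 for c in WBCClass}
    for _, row in truth.iterrows():
        truth_counts[WBCClass[row["wbc_class"]]] += 1
    for i, j in matches:
        true_cls = WBCClass[truth.iloc[j]["wbc_class"]]
        if result.detections[i].wbc_class == true_cls:
            correct[true_cls] += 1
    count_err = max(
        abs(result.counts[c] - truth_counts[c]) for c in WBCClass
    )
    return truth_counts, correct, len(unmatched), count_err


def run_synthetic_suite(
    n_images: int = 50,
    cells_per_image: int = 12,
    seed: int = 0,
    image_shape: tuple[int, int] = (1200, 1600),
    n_platelets: int = 10,
    config: PipelineConfig | None = None,
) -> SuiteResult:
    """Generate, analyze and score a seeded batch of synthetic smears.

    Each image draws its composition from the adult reference
    frequencies; seeds are derived deterministically from ``seed``.
    """
    cfg = config or PipelineConfig()
    truth_tot = {c: 0 for c in WBCClass}
    correct_tot = {c: 0 for c in WBCClass}
    fp_tot = 0
    max_err = 0
    within_1 = 0
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    for i in range(n_images):
        s = int(child_seeds[i])
        comp = random_composition(cells_per_image, seed=s)
        recipe = random_recipe(
            comp, seed=s, image_shape=image_shape, n_platelets=n_platelets
        )
        img, _, truth = generate_smear(recipe)
        result = analyze_image(img, cfg)
        tc, cc, fp, err = score_image(result, truth)
        for c in WBCClass:
            truth_tot[c] += tc[c]
            correct_tot[c] += cc[c]
        fp_tot += fp
        max_err = max(max_err, err)
        within_1 += int(err <= 1)
        rows.append(
            {
                "image": i,
                "seed": s,
                "n_cells": len(truth),
                "n_detections": len(result.detections),
                "false_positives": fp,
                "max_class_count_error": err,
            }
        )
    return SuiteResult(
        n_images=n_images,
        truth_counts=truth_tot,
        correct_counts=correct_tot,
        false_positives=fp_tot,
        max_count_error=max_err,
        images_within_1=within_1,
        per_image=pd.DataFrame(rows),
    )
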