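"""Fragment merging, cytoplasm color sampling, and 5-class assignment.

Neutrophil nuclei are often segmented into separate lobes; region pairs
whose centroids lie closer than a merge threshold (115 px at the
1200x1600 reference resolution, scaled with linear image dimension) are
grouped into one cell.  Each cell then takes one of two branches:

* polymorphonuclear (multiple merged lobes, or a single lobed nucleus
  with low solidity): neutrophil vs eosinophil vs basophil, decided by
  which class's cytoplasm color prototype is nearest to the sampled
  peri-nuclear color (the same Gaussian-RBF similarity used for
  segmentation, now against one prototype per class);
* mononuclear (single compact nucleus): lymphocyte vs monocyte, decided
  the same way.

Cytoplasm color is the mean over an annulus around the nucleus (between
dilations by an inner and an outer radius), excluding pixels claimed by
any other cell's nucleus or annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateAnnulusError, InvalidParameterError
from .preprocess import SmearImage
from .regions import NucleusRegion, dilate_disk
from .segmentation import LabeledMask


class WBCClass(Enum):
    """The five normal peripheral leukocyte populations."""

    NEUTROPHIL = 1
    LYMPHOCYTE = 2
    BASOPHIL = 3
    MONOCYTE = 4
    EOSINOPHIL = 5


POLYMORPHONUCLEAR = (WBCClass.NEUTROPHIL, WBCClass.EOSINOPHIL, WBCClass.BASOPHIL)
MONONUCLEAR = (WBCClass.LYMPHOCYTE, WBCClass.MONOCYTE)

#: Default cytoplasm color prototypes (RGB, Wright-stain tones):
#: neutrophil pale pink-lilac, eosinophil orange-red granules, basophil
#: blue-violet granules, lymphocyte sky-blue rim, monocyte blue-gray.
DEFAULT_PROTOTYPES: dict[WBCClass, tuple[float, float, float]] = {
    WBCClass.NEUTROPHIL: (230.0, 200.0, 210.0),
    WBCClass.EOSINOPHIL: (235.0, 140.0, 120.0),
    WBCClass.BASOPHIL: (180.0, 160.0, 220.0),
    WBCClass.LYMPHOCYTE: (170.0, 190.0, 230.0),
    WBCClass.MONOCYTE: (180.0, 180.0, 200.0),
}


@dataclass(frozen=True)
class ClassifierConfig:
    merge_distance_px: float = 115.0
    solidity_compact_min: float = 0.90
    reference_resolution: tuple[int, int] = (1200, 1600)
    annulus_inner_px: int = 3
    annulus_outer_px: int = 15
    alpha: float = 255.0
    prototypes: dict[WBCClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROTOTYPES)
    )
    prototype_color_space: str = "RGB"
    # optional lymphocyte/monocyte disambiguation by nucleus size when the
    # cytoplasm colors nearly tie (monocyte nuclei are larger); off by
    # default — color alone separates the default prototypes
    use_area_tiebreaker: bool = False
    area_tie_window: float = 0.02
    mononuclear_area_split_px: int = 2700

    def __post_init__(self) -> None:
        if self.merge_distance_px <= 0:
            raise InvalidParameterError("merge_distance_px must be > 0")
        if not (0.0 < self.solidity_compact_min <= 1.0):
            raise InvalidParameterError("solidity_compact_min must be in (0, 1]")
        if not (self.annulus_outer_px > self.annulus_inner_px >= 0):
            raise InvalidParameterError("need annulus_outer_px > annulus_inner_px >= 0")

    def scaled_merge_distance(self, image_shape: tuple[int, int]) -> float:
        """Merge threshold rescaled to another resolution.

        Unlike the area filter this is a length, so it scales with the
        linear image dimension sqrt(H*W / ref)."""
        ref = self.reference_resolution[0] * self.reference_resolution[1]
        return self.merge_distance_px * math.sqrt(
            (image_shape[0] * image_shape[1]) / ref
        )

    def scaled_annuli(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        """Annulus radii rescaled to another resolution (lengths)."""
        ref = self.reference_resolution[0] * self.reference_resolution[1]
        s = math.sqrt((image_shape[0] * image_shape[1]) / ref)
        inner = int(round(self.annulus_inner_px * s))
        outer = max(int(round(self.annulus_outer_px * s)), inner + 1)
        return inner, outer


@dataclass(frozen=True)
class CellDetection:
    """One identified leukocyte: merged nucleus fragments plus class call."""

    region_labels: tuple[int, ...]
    group_centroid_xy: tuple[float, float]
    combined_area_px: int
    min_solidity: float
    n_lobes: int
    cytoplasm_color: tuple[float, float, float]
    wbc_class: WBCClass
    rule_trace: tuple[str, ...]


def centroid_distance(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Euclidean distance between two centroids (Pythagorean hypotenuse)."""
    return math.hypot(c1[0] - c2[0], c1[1] - c2[1])


def merge_fragments(
    regions: list[NucleusRegion],
    cfg: ClassifierConfig,
    image_shape: tuple[int, int],
) -> list[list[NucleusRegion]]:
    """Partition regions into cells by transitive centroid proximity.

    Two regions are joined when their centroid distance is strictly below
    the scaled merge threshold; groups are the connected components of
    that proximity graph.  Output is deterministic: groups ordered by
    their smallest member label, members ordered by label.
    """
    if not regions:
        return []
    thr = cfg.scaled_merge_distance(image_shape)
    order = sorted(regions, key=lambda r: r.label)
    n = len(order)
    pts = np.array([r.centroid_xy for r in order])
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    adj = d2 < thr * thr
    rows, cols = np.nonzero(adj)
    graph = coo_matrix((np.ones_like(rows), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)
    groups: dict[int, list[NucleusRegion]] = {}
    for r, c in zip(order, comp):
        groups.setdefault(int(c), []).append(r)
    return sorted(groups.values(), key=lambda g: g[0].label)


def _group_mask(labels: np.ndarray, group: list[NucleusRegion]) -> np.ndarray:
    return np.isin(labels, [r.label for r in group])


def _crop_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation restricted to the mask's padded bounding box (cheap on
    large images with small objects)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return mask.copy()
    r0 = max(int(rows[0]) - radius, 0)
    r1 = min(int(rows[-1]) + radius + 1, mask.shape[0])
    c0 = max(int(cols[0]) - radius, 0)
    c1 = min(int(cols[-1]) + radius + 1, mask.shape[1])
    out = np.zeros_like(mask)
    out[r0:r1, c0:c1] = dilate_disk(mask[r0:r1, c0:c1], radius)
    return out


def group_annuli(
    labeled: LabeledMask,
    groups: list[list[NucleusRegion]],
    inner_px: int,
    outer_px: int,
) -> list[np.ndarray]:
    """Peri-nuclear annulus mask for every group (before cross-group
    exclusion): dilation by the outer radius minus dilation by the inner."""
    out = []
    for g in groups:
        m = _group_mask(labeled.labels, g)
        out.append(_crop_dilate(m, outer_px) & ~_crop_dilate(m, inner_px))
    return out


def sample_cytoplasm_color(
    img: SmearImage,
    labeled: LabeledMask,
    groups: list[list[NucleusRegion]],
    inner_px: int,
    outer_px: int,
) -> list[tuple[float, float, float]]:
    """Mean color in each group's annulus, excluding contested pixels.

    A pixel counts toward a group only if it lies in that group's annulus
    alone and in no nucleus.  If nothing remains (nucleus flush against
    the border and neighbors), sampling falls back to the non-nucleus
    pixels of the group's bounding box padded by the outer radius; an
    empty fallback raises :class:`DegenerateAnnulusError`.
    """
    if not (outer_px > inner_px >= 0):
        raise InvalidParameterError("need outer_px > inner_px >= 0")
    if not groups:
        return []
    annuli = group_annuli(labeled, groups, inner_px, outer_px)
    claim = np.zeros(labeled.labels.shape, dtype=np.uint8)
    for a in annuli:
        claim += a
    nucleus_any = labeled.labels > 0
    px = img.pixels.astype(np.float64)
    colors: list[tuple[float, float, float]] = []
    for g, ann in zip(groups, annuli):
        valid = ann & (claim == 1) & ~nucleus_any
        if not valid.any():
            valid = _bbox_margin(labeled, g, outer_px) & ~nucleus_any
            if not valid.any():
                raise DegenerateAnnulusError(
                    f"no cytoplasm pixels for group with labels "
                    f"{[r.label for r in g]}"
                )
        mean = px[valid].mean(axis=0)
        colors.append((float(mean[0]), float(mean[1]), float(mean[2])))
    return colors


def _bbox_margin(labeled: LabeledMask, group: list[NucleusRegion], pad: int) -> np.ndarray:
    h, w = labeled.labels.shape
    out = np.zeros((h, w), dtype=bool)
    for r in group:
        r0, c0, r1, c1 = r.bbox
        out[max(r0 - pad, 0):min(r1 + pad, h), max(c0 - pad, 0):min(c1 + pad, w)] = True
    return out


def _nearest_prototype(
    cytoplasm: tuple[float, float, float],
    cfg: ClassifierConfig,
    candidates: tuple[WBCClass, ...],
) -> tuple[WBCClass, float]:
    """Highest-activation prototype; ties broken by candidate order."""
    best: WBCClass | None = None
    best_e = -1.0
    for cls in candidates:
        proto = np.asarray(cfg.prototypes[cls], dtype=np.float64)
        d = float(np.linalg.norm(np.asarray(cytoplasm) - proto))
        e = math.exp(-d / cfg.alpha)
        if e > best_e:
            best, best_e = cls, e
    assert best is not None
    return best, best_e


def classify_cell(
    group: list[NucleusRegion],
    cytoplasm: tuple[float, float, float],
    cfg: ClassifierConfig,
) -> CellDetection:
    """Assign a leukocyte class to one merged region group.

    Branch rule: >= 2 merged lobes, or minimum solidity below
    ``solidity_compact_min``, marks the cell polymorphonuclear; the
    nearest cytoplasm prototype within the branch decides the class.
    """
    if not group:
        raise InvalidParameterError("empty region group")
    trace: list[str] = []
    n_lobes = len(group)
    min_solidity = min(r.solidity for r in group)
    total_area = sum(r.area_px for r in group)
    cx = sum(r.centroid_xy[0] * r.area_px for r in group) / total_area
    cy = sum(r.centroid_xy[1] * r.area_px for r in group) / total_area
    if n_lobes >= 2:
        trace.append(f"polymorphonuclear:n_lobes={n_lobes}>=2")
        branch = POLYMORPHONUCLEAR
    elif min_solidity < cfg.solidity_compact_min:
        trace.append(
            f"polymorphonuclear:solidity={min_solidity:.3f}<{cfg.solidity_compact_min}"
        )
        branch = POLYMORPHONUCLEAR
    else:
        trace.append(
            f"mononuclear:solidity={min_solidity:.3f}>={cfg.solidity_compact_min}"
        )
        branch = MONONUCLEAR
    cls, e = _nearest_prototype(cytoplasm, cfg, branch)
    trace.append(f"color:{cls.name}:E={e:.4f}")
    if cfg.use_area_tiebreaker and branch is MONONUCLEAR:
        activations = {
            c: math.exp(
                -float(
                    np.linalg.norm(
                        np.asarray(cytoplasm) - np.asarray(cfg.prototypes[c])
                    )
                )
                / cfg.alpha
            )
            for c in MONONUCLEAR
        }
        if abs(activations[WBCClass.LYMPHOCYTE] - activations[WBCClass.MONOCYTE]) < cfg.area_tie_window:
            cls = (
                WBCClass.MONOCYTE
                if total_area >= cfg.mononuclear_area_split_px
                else WBCClass.LYMPHOCYTE
            )
            trace.append(f"area_tiebreak:{cls.name}:area={total_area}")
    return CellDetection(
        region_labels=tuple(sorted(r.label for r in group)),
        group_centroid_xy=(cx, cy),
        combined_area_px=total_area,
        min_solidity=min_solidity,
        n_lobes=n_lobes,
        cytoplasm_color=tuple(float(v) for v in cytoplasm),
        wbc_class=cls,
        rule_trace=tuple(trace),
    )


def differential_count(detections: list[CellDetection]) -> dict[WBCClass, int]:
    """Per-class tally; every class is present as a key (zero allowed)."""
    counts = {cls: 0 for cls in WBCClass}
    for det in detections:
        counts[det.wbc_class] += 1
    return counts
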