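"""Synthetic blood-smear generator with exact ground truth.

Emulates the features of a Wright-stained smear that the pipeline keys
on, and nothing more: dark-purple compact or lobed nuclei, a
class-specific cytoplasm halo around each nucleus, small platelet specks
sharing the nucleus tonality, and a pale red-cell-carpet background.
Cells are drawn as disks (mononuclear classes) or as chains of nucleus
lobes (polymorphonuclear classes); lobe chains with spacing below twice
the lobe radius render connected scalloped nuclei, wider spacing renders
disjoint fragments that exercise the centroid-distance merge rule.

Every image comes with a pixel-exact nucleus label mask and a per-cell
ground-truth table, so segmentation, morphology, merging and
classification can each be scored against construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .classification import WBCClass, DEFAULT_PROTOTYPES
from .errors import InvalidRecipeError, PlacementError
from .preprocess import RGB, SmearImage

#: Mean Wright-stain nucleus color (dark purple) shared by nuclei and platelets.
NUCLEUS_COLOR: tuple[float, float, float] = (80.0, 40.0, 110.0)
#: Pale pink red-cell-carpet background.
BACKGROUND_COLOR: tuple[float, float, float] = (228.0, 200.0, 192.0)

#: Adult reference differential frequencies (fractions of leukocytes).
ADULT_FREQUENCIES: dict[WBCClass, float] = {
    WBCClass.NEUTROPHIL: 0.62,
    WBCClass.LYMPHOCYTE: 0.30,
    WBCClass.MONOCYTE: 0.053,
    WBCClass.EOSINOPHIL: 0.023,
    WBCClass.BASOPHIL: 0.004,
}

#: Per-class rendering geometry: (n_lobes, lobe radius, chain spacing,
#: cytoplasm radius), in pixels at the 1200x1600 reference resolution.
#: Polymorphonuclear classes use two disjoint lobes (spacing > 2r) whose
#: centroids fall well inside the 115-px merge threshold; mononuclear
#: classes are single compact disks.  Lobe areas all exceed the 1500-px
#: platelet filter.
CLASS_GEOMETRY: dict[WBCClass, tuple[int, int, int, int]] = {
    WBCClass.NEUTROPHIL: (2, 24, 70, 80),
    WBCClass.EOSINOPHIL: (2, 24, 68, 79),
    WBCClass.BASOPHIL: (2, 24, 64, 77),
    WBCClass.LYMPHOCYTE: (1, 26, 0, 47),
    WBCClass.MONOCYTE: (1, 32, 0, 53),
}


@dataclass(frozen=True)
class CellSpec:
    """Geometry and colors of one synthetic leukocyte."""

    wbc_class: WBCClass
    center_xy: tuple[float, float]
    nucleus_radius_px: int
    n_lobes: int = 1
    lobe_spacing_px: float = 0.0
    lobe_angle_deg: float = 0.0
    nucleus_color: tuple[float, float, float] = NUCLEUS_COLOR
    cytoplasm_color: tuple[float, float, float] | None = None
    cytoplasm_radius_px: int | None = None

    def resolved(self) -> "CellSpec":
        """Fill class-dependent defaults from the prototype tables."""
        cyto_color = self.cytoplasm_color or DEFAULT_PROTOTYPES[self.wbc_class]
        cyto_r = self.cytoplasm_radius_px
        if cyto_r is None:
            cyto_r = int(math.ceil(self.lobe_extent_px)) + 21
        return replace(self, cytoplasm_color=cyto_color, cytoplasm_radius_px=cyto_r)

    @property
    def lobe_extent_px(self) -> float:
        """Distance from cell center to the farthest nucleus pixel."""
        return (self.n_lobes - 1) / 2.0 * self.lobe_spacing_px + self.nucleus_radius_px

    def lobe_centers(self) -> list[tuple[float, float]]:
        """Lobe centers along a chain through the cell center."""
        ang = math.radians(self.lobe_angle_deg)
        ux, uy = math.cos(ang), math.sin(ang)
        x0, y0 = self.center_xy
        return [
            (
                x0 + (k - (self.n_lobes - 1) / 2.0) * self.lobe_spacing_px * ux,
                y0 + (k - (self.n_lobes - 1) / 2.0) * self.lobe_spacing_px * uy,
            )
            for k in range(self.n_lobes)
        ]


def make_cell(
    wbc_class: WBCClass,
    center_xy: tuple[float, float],
    lobe_angle_deg: float = 0.0,
    scale: float = 1.0,
    **overrides,
) -> CellSpec:
    """Build a CellSpec with the class's default geometry.

    ``scale`` shrinks/grows all lengths linearly for images away from the
    1200x1600 reference resolution (cells span fewer pixels at lower
    magnification-equivalent resolutions).
    """
    n_lobes, radius, spacing, cyto_r = CLASS_GEOMETRY[wbc_class]
    spec = CellSpec(
        wbc_class=wbc_class,
        center_xy=center_xy,
        nucleus_radius_px=max(int(round(radius * scale)), 1),
        n_lobes=n_lobes,
        lobe_spacing_px=spacing * scale,
        lobe_angle_deg=lobe_angle_deg,
        cytoplasm_radius_px=max(int(round(cyto_r * scale)), 2),
    )
    if overrides:
        spec = replace(spec, **overrides)
    return spec.resolved()


@dataclass(frozen=True)
class SmearRecipe:
    """Deterministic description of one synthetic smear.

    The seed drives platelet placement and pixel noise only; cell
    geometry is fully specified by ``cells``, so two recipes differing
    only in seed share identical ground truth.
    """

    image_shape: tuple[int, int] = (1200, 1600)
    cells: tuple[CellSpec, ...] = ()
    n_platelets: int = 0
    platelet_radius_px: int = 9
    background_color: tuple[float, float, float] = BACKGROUND_COLOR
    channel_noise_sd: float = 4.0
    seed: int = 0
    merge_distance_px: float = 115.0  # separation contract checked at render

    def to_json(self) -> str:
        d = {
            "image_shape": list(self.image_shape),
            "n_platelets": self.n_platelets,
            "platelet_radius_px": self.platelet_radius_px,
            "background_color": list(self.background_color),
            "channel_noise_sd": self.channel_noise_sd,
            "seed": self.seed,
            "merge_distance_px": self.merge_distance_px,
            "cells": [
                {
                    "wbc_class": c.wbc_class.name,
                    "center_xy": list(c.center_xy),
                    "nucleus_radius_px": c.nucleus_radius_px,
                    "n_lobes": c.n_lobes,
                    "lobe_spacing_px": c.lobe_spacing_px,
                    "lobe_angle_deg": c.lobe_angle_deg,
                    "nucleus_color": list(c.nucleus_color),
                    "cytoplasm_color": list(c.cytoplasm_color)
                    if c.cytoplasm_color
                    else None,
                    "cytoplasm_radius_px": c.cytoplasm_radius_px,
                }
                for c in self.cells
            ],
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SmearRecipe":
        d = json.loads(text)
        cells = tuple(
            CellSpec(
                wbc_class=WBCClass[c["wbc_class"]],
                center_xy=tuple(c["center_xy"]),
                nucleus_radius_px=c["nucleus_radius_px"],
                n_lobes=c["n_lobes"],
                lobe_spacing_px=c["lobe_spacing_px"],
                lobe_angle_deg=c["lobe_angle_deg"],
                nucleus_color=tuple(c["nucleus_color"]),
                cytoplasm_color=tuple(c["cytoplasm_color"])
                if c["cytoplasm_color"]
                else None,
                cytoplasm_radius_px=c["cytoplasm_radius_px"],
            ).resolved()
            for c in d["cells"]
        )
        return cls(
            image_shape=tuple(d["image_shape"]),
            cells=cells,
            n_platelets=d["n_platelets"],
            platelet_radius_px=d["platelet_radius_px"],
            background_color=tuple(d["background_color"]),
            channel_noise_sd=d["channel_noise_sd"],
            seed=d["seed"],
            merge_distance_px=d.get("merge_distance_px", 115.0),
        )


def _validate_recipe(recipe: SmearRecipe) -> list[CellSpec]:
    cells = [c.resolved() for c in recipe.cells]
    h, w = recipe.image_shape
    scale = math.sqrt(h * w / (1200.0 * 1600.0))
    merge = recipe.merge_distance_px * scale
    for c in cells:
        # disjoint same-cell lobes must merge back: consecutive lobe
        # centroids inside the merge threshold (overlapping lobes render
        # one connected nucleus, so any spacing below 2r is fine)
        disjoint = c.lobe_spacing_px >= 2 * c.nucleus_radius_px
        if c.n_lobes > 1 and disjoint and c.lobe_spacing_px >= merge:
            raise InvalidRecipeError(
                f"lobe spacing of a {c.wbc_class.name} reaches the merge "
                f"threshold {merge:.0f}"
            )
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            dmin = min(
                math.hypot(p[0] - q[0], p[1] - q[1])
                for p in a.lobe_centers()
                for q in b.lobe_centers()
            )
            if dmin <= merge:
                raise InvalidRecipeError(
                    f"cells at {a.center_xy} and {b.center_xy}: nearest lobe "
                    f"centroids {dmin:.1f} px apart, within merge threshold {merge:.0f}"
                )
    # platelets must be removable by the area filter
    plate_area = math.pi * recipe.platelet_radius_px**2
    if recipe.n_platelets and plate_area >= 1500.0 * (h * w) / (1200.0 * 1600.0):
        raise InvalidRecipeError("platelet area reaches the nucleus-area filter")
    return cells


def _paint(canvas: np.ndarray, center_xy, radius, color, shape) -> np.ndarray:
    rr, cc = draw_disk((center_xy[1], center_xy[0]), radius, shape=shape)
    canvas[rr, cc] = color
    return canvas


def generate_smear(
    recipe: SmearRecipe,
) -> tuple[SmearImage, np.ndarray, pd.DataFrame]:
    """Render a recipe into an image, a label mask, and a truth table.

    Returns
    -------
    image : SmearImage (RGB)
    label_mask : (H, W) int32 array — cell id (1-based) on nucleus
        pixels, -1 on platelets, 0 elsewhere
    truth : DataFrame with one row per cell: cell_id, wbc_class,
        center_x, center_y, n_lobes, nucleus_area_px, lobe_centroids
        (JSON-encoded list of [x, y])
    """
    cells = _validate_recipe(recipe)
    h, w = recipe.image_shape
    rng = np.random.default_rng(recipe.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = recipe.background_color
    labels = np.zeros((h, w), dtype=np.int32)

    for c in cells:
        _paint(img, c.center_xy, c.cytoplasm_radius_px, c.cytoplasm_color, (h, w))
    for idx, c in enumerate(cells, start=1):
        for lc in c.lobe_centers():
            rr, cc = draw_disk((lc[1], lc[0]), c.nucleus_radius_px, shape=(h, w))
            img[rr, cc] = c.nucleus_color
            labels[rr, cc] = idx

    # Platelets: nucleus-toned specks kept clear of every cell's halo.
    pr = recipe.platelet_radius_px
    placed = 0
    attempts = 0
    max_attempts = 200 * max(recipe.n_platelets, 1)
    centers: list[tuple[float, float]] = []
    while placed < recipe.n_platelets:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed only {placed}/{recipe.n_platelets} platelets"
            )
        x = rng.uniform(pr + 2, w - pr - 2)
        y = rng.uniform(pr + 2, h - pr - 2)
        if any(
            math.hypot(x - c.center_xy[0], y - c.center_xy[1])
            < c.cytoplasm_radius_px + pr + 8
            for c in cells
        ):
            continue
        if any(math.hypot(x - px, y - py) < 2 * pr + 6 for px, py in centers):
            continue
        rr, cc = draw_disk((y, x), pr, shape=(h, w))
        img[rr, cc] = NUCLEUS_COLOR
        labels[rr, cc] = -1
        centers.append((x, y))
        placed += 1

    if recipe.channel_noise_sd > 0:
        img = img + rng.normal(0.0, recipe.channel_noise_sd, size=img.shape)
    pixels = np.clip(np.floor(np.abs(img) + 0.5) * np.sign(img), 0, 255).astype(
        np.uint8
    )

    rows = []
    for idx, c in enumerate(cells, start=1):
        rows.append(
            {
                "cell_id": idx,
                "wbc_class": c.wbc_class.name,
                "center_x": c.center_xy[0],
                "center_y": c.center_xy[1],
                "n_lobes": c.n_lobes,
                "nucleus_area_px": int((labels == idx).sum()),
                "lobe_centroids": json.dumps(
                    [[round(x, 2), round(y, 2)] for x, y in c.lobe_centers()]
                ),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "wbc_class",
            "center_x",
            "center_y",
            "n_lobes",
            "nucleus_area_px",
            "lobe_centroids",
        ],
    )
    return SmearImage(pixels=pixels, color_space=RGB), labels, truth


def random_composition(
    n_cells: int,
    seed: int,
    frequencies: dict[WBCClass, float] | None = None,
) -> dict[WBCClass, int]:
    """Multinomial draw of a differential composition (adult reference
    frequencies by default)."""
    freqs = frequencies or ADULT_FREQUENCIES
    classes = list(freqs.keys())
    p = np.array([freqs[c] for c in classes], dtype=np.float64)
    p = p / p.sum()
    counts = np.random.default_rng(seed).multinomial(n_cells, p)
    return {c: int(k) for c, k in zip(classes, counts)}


def random_recipe(
    composition: dict[WBCClass, int],
    seed: int,
    image_shape: tuple[int, int] = (1200, 1600),
    n_platelets: int = 10,
    channel_noise_sd: float = 4.0,
    max_attempts_per_cell: int = 2000,
) -> SmearRecipe:
    """Place the requested cells uniformly at random without conflicts.

    Rejection sampling enforces a center-to-center separation that keeps
    every cross-cell lobe pair beyond the merge threshold and keeps
    cytoplasm halos disjoint.
    """
    if any(v < 0 for v in composition.values()):
        raise InvalidRecipeError("negative class count")
    h, w = image_shape
    scale = math.sqrt(h * w / (1200.0 * 1600.0))
    merge = 115.0 * scale
    rng = np.random.default_rng(seed)
    order = [
        cls for cls in WBCClass for _ in range(composition.get(cls, 0))
    ]
    cells: list[CellSpec] = []
    for cls in order:
        n_lobes, radius, spacing, cyto_r = CLASS_GEOMETRY[cls]
        ext = ((n_lobes - 1) / 2.0 * spacing + radius) * scale
        margin = int(math.ceil(cyto_r * scale)) + 2
        if w - 2 * margin <= 0 or h - 2 * margin <= 0:
            raise PlacementError("image too small for requested cells")
        for attempt in range(max_attempts_per_cell):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            ok = all(
                math.hypot(x - c.center_xy[0], y - c.center_xy[1])
                > merge + ext + c.lobe_extent_px + 10
                for c in cells
            )
            if ok:
                cells.append(
                    make_cell(
                        cls,
                        (x, y),
                        lobe_angle_deg=float(rng.uniform(0, 180)),
                        scale=scale,
                    )
                )
                break
        else:
            raise PlacementError(
                f"could not place cell {len(cells) + 1} of {len(order)}"
            )
    return SmearRecipe(
        image_shape=image_shape,
        cells=tuple(cells),
        n_platelets=n_platelets,
        channel_noise_sd=channel_noise_sd,
        seed=seed,
    )
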