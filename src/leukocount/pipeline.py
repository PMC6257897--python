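"""End-to-end pipeline configuration and execution.

Stages, in order: YCbCr conversion (optional), RBF distance to the
reference nucleus color, activation thresholding, connected-component
labeling, platelet-area filtering, disk dilation, hole filling, shape
description, centroid-distance fragment merging, cytoplasm sampling,
rule-based classification, differential count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Any

import numpy as np
import yaml

from . import classification as cls_mod
from . import regions as reg_mod
from . import segmentation as seg_mod
from .classification import CellDetection, ClassifierConfig, WBCClass
from .preprocess import RGB, YCBCR, SmearImage, convert_triplet, rgb_to_ycbcr
from .regions import MorphologyConfig, NucleusRegion
from .segmentation import LabeledMask, RBFParams, ReferencePixel
from .synthetic import NUCLEUS_COLOR

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the identification pipeline.

    ``reference_pixel_rgb`` is the mean nucleus color in RGB (fit from
    labeled nucleus patches for real smears; the default is the dark
    purple of the synthetic generator), converted internally into the
    working color space.
    """

    color_space: str = YCBCR
    alpha: float = 255.0
    activation_cutoff: float = 0.70
    connectivity: int = 8
    min_area_px: int = 1500
    dilation_radius_px: int = 3
    fill_holes: bool = True
    merge_distance_px: float = 115.0
    solidity_compact_min: float = 0.90
    annulus_inner_px: int = 3
    annulus_outer_px: int = 15
    reference_resolution: tuple[int, int] = (1200, 1600)
    reference_pixel_rgb: tuple[float, float, float] = NUCLEUS_COLOR
    prototypes_rgb: dict[WBCClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(cls_mod.DEFAULT_PROTOTYPES)
    )

    def morphology(self) -> MorphologyConfig:
        return MorphologyConfig(
            min_area_px=self.min_area_px,
            reference_resolution=self.reference_resolution,
            dilation_radius_px=self.dilation_radius_px,
            fill_holes=self.fill_holes,
        )

    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(
            merge_distance_px=self.merge_distance_px,
            solidity_compact_min=self.solidity_compact_min,
            reference_resolution=self.reference_resolution,
            annulus_inner_px=self.annulus_inner_px,
            annulus_outer_px=self.annulus_outer_px,
            alpha=self.alpha,
            prototypes=dict(self.prototypes_rgb),
        )

    def rbf_params(self) -> RBFParams:
        return RBFParams(alpha=self.alpha, activation_cutoff=self.activation_cutoff)

    def reference_pixel(self) -> ReferencePixel:
        if self.color_space == YCBCR:
            mean = convert_triplet(self.reference_pixel_rgb)
        else:
            mean = tuple(float(v) for v in self.reference_pixel_rgb)
        return ReferencePixel(channel_mean=mean, color_space=self.color_space)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        """Build from a plain mapping; missing keys take package defaults."""
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        if "reference_resolution" in kw:
            kw["reference_resolution"] = tuple(kw["reference_resolution"])
        if "reference_pixel_rgb" in kw:
            kw["reference_pixel_rgb"] = tuple(kw["reference_pixel_rgb"])
        if "prototypes_rgb" in kw:
            kw["prototypes_rgb"] = {
                (WBCClass[k] if isinstance(k, str) else k): tuple(v)
                for k, v in kw["prototypes_rgb"].items()
            }
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "color_space": self.color_space,
            "alpha": self.alpha,
            "activation_cutoff": self.activation_cutoff,
            "connectivity": self.connectivity,
            "min_area_px": self.min_area_px,
            "dilation_radius_px": self.dilation_radius_px,
            "fill_holes": self.fill_holes,
            "merge_distance_px": self.merge_distance_px,
            "solidity_compact_min": self.solidity_compact_min,
            "annulus_inner_px": self.annulus_inner_px,
            "annulus_outer_px": self.annulus_outer_px,
            "reference_resolution": list(self.reference_resolution),
            "reference_pixel_rgb": list(self.reference_pixel_rgb),
            "prototypes_rgb": {
                k.name: list(v) for k, v in self.prototypes_rgb.items()
            },
        }

    def override(self, **kw) -> "PipelineConfig":
        kw = {k: v for k, v in kw.items() if v is not None}
        return replace(self, **kw) if kw else self


@dataclass(frozen=True)
class PipelineResult:
    """Everything one image's analysis produced."""

    detections: list[CellDetection]
    regions: list[NucleusRegion]
    labeled: LabeledMask
    counts: dict[WBCClass, int]
    activation: np.ndarray | None = None


def analyze_image(
    img: SmearImage,
    config: PipelineConfig | None = None,
    keep_activation: bool = False,
) -> PipelineResult:
    """Run the full identification pipeline on one RGB smear image."""
    cfg = config or PipelineConfig()
    if img.color_space != RGB:
        raise ValueError("analyze_image expects an RGB image")
    work = rgb_to_ycbcr(img) if cfg.color_space == YCBCR else img
    ref = cfg.reference_pixel()
    dist = seg_mod.distance_map(work, ref)
    act = seg_mod.rbf_activation(dist, cfg.rbf_params())
    mask = seg_mod.threshold_activation(act, cfg.activation_cutoff)
    labeled = seg_mod.label_components(mask, connectivity=cfg.connectivity)
    labeled = reg_mod.clean_mask(labeled, cfg.morphology(), img.shape)
    regions = reg_mod.region_descriptors(labeled)
    ccfg = cfg.classifier()
    groups = cls_mod.merge_fragments(regions, ccfg, img.shape)
    inner, outer = ccfg.scaled_annuli(img.shape)
    colors = cls_mod.sample_cytoplasm_color(img, labeled, groups, inner, outer)
    detections = [
        cls_mod.classify_cell(g, c, ccfg) for g, c in zip(groups, colors)
    ]
    counts = cls_mod.differential_count(detections)
    log.info(
        "%s: %d nucleus objects, %d cells, counts %s",
        img.source_path or "<array>",
        labeled.n_objects,
        len(detections),
        {k.name: v for k, v in counts.items() if v},
    )
    return PipelineResult(
        detections=detections,
        regions=regions,
        labeled=labeled,
        counts=counts,
        activation=act.values if keep_activation else None,
    )
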