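"""Gaussian radial-basis-function pixel segmentation of leukocyte nuclei.

Each pixel is scored by its similarity to a single reference prototype:
the mean color of known nucleus pixels.  With D the Euclidean distance in
color space between a pixel and the prototype, the activation

    E = exp(-D / alpha),   alpha = 255 by default (the channel range),

lies in (0, 1]: 1 for an exact color match, falling off smoothly with
distance.  Thresholding E at a cutoff tau selects pixels within
D <= -alpha * ln(tau) of the prototype; connected groups of selected
pixels are candidate nuclei (platelets share the nucleus tonality and are
removed later by an area filter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _sk_label

from .errors import InsufficientDataError, InvalidParameterError, ColorSpaceError
from .preprocess import SmearImage


@dataclass(frozen=True)
class ReferencePixel:
    """Mean nucleus color prototype of the RBF classifier."""

    channel_mean: tuple[float, float, float]
    color_space: str
    n_training_pixels: int = 1

    def __post_init__(self) -> None:
        if self.n_training_pixels < 1:
            raise InvalidParameterError("n_training_pixels must be >= 1")
        for c in self.channel_mean:
            if not (0.0 <= c <= 255.0):
                raise InvalidParameterError(
                    f"channel mean {c} outside [0, 255]"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "color_space": self.color_space,
                "channel_mean": list(self.channel_mean),
                "n_training_pixels": self.n_training_pixels,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferencePixel":
        d = json.loads(text)
        return cls(
            channel_mean=tuple(float(v) for v in d["channel_mean"]),
            color_space=d["color_space"],
            n_training_pixels=int(d["n_training_pixels"]),
        )


@dataclass(frozen=True)
class RBFParams:
    """Width and decision threshold of the Gaussian RBF.

    ``alpha`` is the kernel width; the default 255 is the number of values
    an 8-bit channel can take.  ``activation_cutoff`` is the similarity
    below which a pixel is considered background.
    """

    alpha: float = 255.0
    activation_cutoff: float = 0.70

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise InvalidParameterError("alpha must be > 0")
        if not (0.0 < self.activation_cutoff < 1.0):
            raise InvalidParameterError("activation_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class ActivationMap:
    """Per-pixel RBF response E = exp(-D/alpha) and underlying distance D."""

    values: np.ndarray
    distance: np.ndarray


@dataclass(frozen=True)
class LabeledMask:
    """Connected-component labeling of a binary nucleus mask.

    Labels are 1..n_objects in raster-scan discovery order; 0 is background.
    """

    labels: np.ndarray
    n_objects: int
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise InvalidParameterError("connectivity must be 4 or 8")


def fit_reference_pixel(
    nucleus_pixels, color_space: str
) -> ReferencePixel:
    """Average a set of labeled nucleus pixels into the RBF prototype.

    Parameters
    ----------
    nucleus_pixels : sequence of (c0, c1, c2) triplets or (N, 3) array
    color_space : the space the pixels were sampled in
    """
    arr = np.asarray(nucleus_pixels, dtype=np.float64)
    if arr.size == 0:
        raise InsufficientDataError("no nucleus pixels supplied")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidParameterError(f"expected N x 3 pixel array, got {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidParameterError("pixel values outside [0, 255]")
    mean = arr.mean(axis=0)
    return ReferencePixel(
        channel_mean=(float(mean[0]), float(mean[1]), float(mean[2])),
        color_space=color_space,
        n_training_pixels=arr.shape[0],
    )


def distance_map(img: SmearImage, ref: ReferencePixel) -> np.ndarray:
    """Euclidean color distance of every pixel to the reference prototype."""
    if img.color_space != ref.color_space:
        raise ColorSpaceError(
            f"image is {img.color_space}, reference is {ref.color_space}"
        )
    diff = img.pixels.astype(np.float64) - np.asarray(ref.channel_mean)
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def rbf_activation(distance: np.ndarray, params: RBFParams) -> ActivationMap:
    """Evaluate the Gaussian radial basis function E = exp(-D/alpha)."""
    d = np.asarray(distance, dtype=np.float64)
    if d.size and d.min() < 0:
        raise InvalidParameterError("distances must be non-negative")
    return ActivationMap(values=np.exp(-d / params.alpha), distance=d)


def threshold_activation(act: ActivationMap, cutoff: float) -> np.ndarray:
    """Binary nucleus mask: pixels whose activation reaches the cutoff.

    Inclusive at the boundary (E == cutoff is foreground).  Equivalent to
    D <= -alpha * ln(cutoff).
    """
    if not (0.0 < cutoff < 1.0):
        raise InvalidParameterError("cutoff must be in (0, 1)")
    return act.values >= cutoff


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledMask:
    """Label connected foreground components of a binary mask.

    4-connectivity joins edge neighbors only; 8 also joins diagonals.
    """
    if connectivity not in (4, 8):
        raise InvalidParameterError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n = _sk_label(
        mask, connectivity=1 if connectivity == 4 else 2, return_num=True
    )
    return LabeledMask(labels=labels.astype(np.int32), n_objects=int(n),
                       connectivity=connectivity)


def d_threshold(params: RBFParams) -> float:
    """Color-distance radius selected by the activation cutoff."""
    return -params.alpha * float(np.log(params.activation_cutoff))
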