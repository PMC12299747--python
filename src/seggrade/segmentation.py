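"""Pluggable segmentation backends.

The grading pipeline only needs a :class:`~seggrade.mask.LabelMask`; where
it comes from is a backend decision.  Three backends satisfy the same
contract (output dimensions equal input dimensions, labels in {0, 1, 2}):

* ``file`` — masks supplied alongside the images (e.g. exported by a
  trained instance-segmentation network);
* ``reference`` — the deterministic color-rule segmenter below, which
  classifies pixels by hue/saturation/value bounds; it segments the
  synthetic fixtures (cap green, stalk red) exactly and exists so the
  whole pipeline is testable without trained weights;
* any object implementing :class:`Segmenter` plugged in by the caller.

One mushroom per frame is assumed (single-file feeding on the line);
multi-instance frames are rejected upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from skimage import color as skcolor
from skimage.morphology import closing, footprint_rectangle

from .mask import BACKGROUND, CAP, PALETTE, STALK, LabelMask


@runtime_checkable
class Segmenter(Protocol):
    """Contract every segmentation backend satisfies."""

    name: str

    def segment(self, image: np.ndarray) -> LabelMask:
        """Map an RGB image (H, W, 3) uint8 to a same-sized label mask."""
        ...


@dataclass(frozen=True)
class HSVBounds:
    """Inclusive hue/saturation/value bounds, each channel in [0, 1]."""

    h: tuple[float, float]
    s: tuple[float, float]
    v: tuple[float, float]

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.h
        if lo <= hi:
            in_h = (h >= lo) & (h <= hi)
        else:  # hue interval wrapping around 1.0 (reds)
            in_h = (h >= lo) | (h <= hi)
        return (
            in_h
            & (s >= self.s[0]) & (s <= self.s[1])
            & (v >= self.v[0]) & (v <= self.v[1])
        )


@dataclass(frozen=True)
class ColorRule:
    """Per-class HSV bounds for the reference color segmenter.

    Defaults target the fixture palette: cap pure green (hue 1/3), stalk
    pure red (hue 0).  The value floor of 0.45 sits near half intensity:
    a linear blur of a saturated shape on black crosses half level at the
    original edge, so thresholding there recovers the true boundary
    rather than the blur halo.
    """

    cap: HSVBounds = field(default_factory=lambda: HSVBounds(h=(0.22, 0.45), s=(0.3, 1.0), v=(0.45, 1.0)))
    stalk: HSVBounds = field(default_factory=lambda: HSVBounds(h=(0.93, 0.07), s=(0.3, 1.0), v=(0.45, 1.0)))


def reference_segment(
    image: np.ndarray, rules: ColorRule | None = None, *, cleanup: bool = True
) -> LabelMask:
    """Segment an RGB image into cap/stalk by per-pixel color rules.

    Pixels matching the cap rule get label 1, the stalk rule label 2,
    everything else background.  With ``cleanup`` a one-iteration 3x3
    morphological closing removes isolated speckle per class; disable it
    for exact round-trip tests on noiseless input.

    Emits an ``empty-output`` :class:`UserWarning` for each class that
    matches zero pixels.
    """
    rules = rules or ColorRule()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    hsv = skcolor.rgb2hsv(img[..., :3])
    labels = np.zeros(img.shape[:2], dtype=np.uint8)
    for class_id, bounds, part in ((CAP, rules.cap, "cap"), (STALK, rules.stalk, "stalk")):
        hit = bounds.contains(hsv)
        if cleanup:
            hit = closing(hit, footprint_rectangle((3, 3)))
        if not hit.any():
            warnings.warn(f"empty-output: no pixels matched the {part} rule", stacklevel=2)
        labels[hit] = class_id
    return LabelMask(labels)


def colorize_mask(mask: LabelMask) -> np.ndarray:
    """Render a label mask as RGB: cap green, stalk red, background black."""
    out = np.zeros((mask.height, mask.width, 3), dtype=np.uint8)
    for class_id, rgb in PALETTE.items():
        if class_id == BACKGROUND:
            continue
        out[mask.labels == class_id] = rgb
    return out


@dataclass
class ReferenceSegmenter:
    """The color-rule segmenter wrapped as a pluggable backend."""

    rules: ColorRule = field(default_factory=ColorRule)
    cleanup: bool = True
    name: str = "reference"

    def segment(self, image: np.ndarray) -> LabelMask:
        return reference_segment(image, self.rules, cleanup=self.cleanup)
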