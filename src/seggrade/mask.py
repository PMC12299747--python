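"""Label masks: the per-pixel class map exchanged between pipeline stages.

A mask assigns each pixel one of three classes: 0 background, 1 cap
(pileus), 2 stalk (stipe).  The image origin is the top-left corner and y
increases downward; all modules share this convention.

On disk a mask is a single-channel 8-bit PNG whose pixel values are the
raw labels {0, 1, 2}.  The RGB visualization (cap green, stalk red,
background black) is produced by :func:`seggrade.segmentation.colorize_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND = 0
CAP = 1
STALK = 2

#: RGB palette for visualization: background black, cap green, stalk red.
PALETTE = {
    BACKGROUND: (0, 0, 0),
    CAP: (0, 255, 0),
    STALK: (255, 0, 0),
}


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel class map for one frame.

    Parameters
    ----------
    labels
        2-D uint8 array of shape ``(height, width)`` with values in
        {0, 1, 2}; row-major, origin top-left, y down.
    """

    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.uint8)
        if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
            raise ValueError(f"mask must be a non-empty 2-D array, got shape {arr.shape}")
        if arr.max(initial=0) > 2:
            raise ValueError("mask labels must be in {0, 1, 2}")
        object.__setattr__(self, "labels", arr)

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    def class_pixels(self, class_id: int) -> int:
        """Number of pixels carrying ``class_id``."""
        return int(np.count_nonzero(self.labels == class_id))

    def binary(self, class_id: int) -> np.ndarray:
        """Boolean array marking pixels of ``class_id``."""
        return self.labels == class_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:  # frozen dataclass contract
        return hash((self.labels.shape, self.labels.tobytes()))


def read_mask(path: str | Path) -> LabelMask:
    """Read a label mask from a single-channel 8-bit PNG."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    return LabelMask(arr)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a single-channel 8-bit PNG."""
    Image.fromarray(mask.labels, mode="L").save(path, format="PNG")
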