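"""Synthetic mushroom fixtures with exact ground truth.

Real data for this problem is photographs of *Stropharia rugoso-annulata*
on a conveyor belt, segmented by a trained network.  The fixtures below
replace both: each fixture is an analytically rasterized mushroom —
cap drawn as a half-ellipse of width ``D1`` and height ``H`` (flat side
down), stalk as a ``D2 x L`` rectangle attached beneath the cap's
midpoint — rendered at an arbitrary in-plane rotation and position, with
the palette the reference segmenter expects (cap green, stalk red).  The
generating dimensions are the ground truth, so recovery of ``D1, H, L,
D2`` and of the RDHP/RLDS indexes can be checked to the pixel.

Broken variants (missing cap, missing stalk, fragmented stalk) exercise
the broken-specimen bypass.  Optional Gaussian blur and brightness shifts
emulate the mild motion blur and uneven lighting of belt photography.
Everything is deterministic given the spec (and, for datasets, the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import OutOfCanvasError
from .grading import GradeCriteria, assign_grade
from .mask import CAP, STALK, LabelMask, write_mask
from .morphometry import CapMeasurement, MushroomMeasurement, StalkMeasurement
from .segmentation import colorize_mask

#: Rows of stalk tucked under the cap so the two classes stay contiguous.
STALK_OVERLAP_PX = 2.0


@dataclass(frozen=True)
class NoiseSpec:
    """Image-degradation knobs; the ground-truth mask is never degraded."""

    blur_sigma: float = 0.0
    brightness_delta: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    """Generating parameters of one synthetic mushroom."""

    D1: float
    H: float
    L: float
    D2: float
    rotation_deg: float = 0.0
    center: tuple[float, float] | None = None   # (x, y); canvas middle if None
    canvas: tuple[int, int] | None = None       # (width, height); auto-fit if None
    broken_mode: str = "none"                   # none | no_cap | no_stalk | fragmented
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.D1 >= self.H > 0:
            raise ValueError(f"require D1 >= H > 0, got D1={self.D1}, H={self.H}")
        if not (self.L > 0 and self.D2 > 0):
            raise ValueError("require L > 0 and D2 > 0")
        if self.broken_mode not in ("none", "no_cap", "no_stalk", "fragmented"):
            raise ValueError(f"unknown broken_mode {self.broken_mode!r}")
        if self.broken_mode == "fragmented" and self.L < 12:
            raise ValueError("fragmented mode needs L >= 12 px to leave two major fragments")

    @property
    def true_RDHP(self) -> float:
        return self.D1 / self.H

    @property
    def true_RLDS(self) -> float:
        return self.L / self.D2

    def true_measurement(self) -> MushroomMeasurement:
        return MushroomMeasurement(
            cap=CapMeasurement(D1=self.D1, H=self.H, tilt_deg=0.0),
            stalk=StalkMeasurement(L=self.L, D2=self.D2),
            RDHP=self.true_RDHP,
            RLDS=self.true_RLDS,
        )

    def extent_radius(self) -> float:
        """Upper bound on the distance of any shape point from the anchor."""
        cap_r = math.hypot(self.D1 / 2.0, self.H)
        stalk_r = math.hypot(self.D2 / 2.0, max(self.L - STALK_OVERLAP_PX, 0.0))
        return max(cap_r, stalk_r)


@dataclass(frozen=True)
class FixtureRecord:
    """A rendered fixture: image, ground-truth mask, and labels."""

    spec: FixtureSpec
    image: np.ndarray            # (H, W, 3) uint8
    mask: LabelMask              # ground truth, rendered before noise
    true_RDHP: float
    true_RLDS: float
    true_grade: int | str        # 1/2/3 or "BROKEN"
    image_path: Path | None = None
    mask_path: Path | None = None


def render_mushroom(spec: FixtureSpec, criteria: GradeCriteria | None = None) -> FixtureRecord:
    """Rasterize one fixture analytically.

    Membership of every pixel center is tested in the mushroom's local
    (upright) frame after inverse rotation, so no resampling artifacts
    enter the ground truth.  The anchor of the local frame is the cap's
    bottom-center; the stalk spans ``y in [-overlap, L - overlap]`` there
    and takes label priority in the overlap rows, keeping the stalk's
    drawn length exactly ``L``.

    Raises
    ------
    OutOfCanvasError
        If any foreground pixel lands on (or beyond) the canvas border.
    """
    if spec.canvas is None:
        side = 2 * int(math.ceil(spec.extent_radius())) + 8
        canvas_w = canvas_h = side
    else:
        canvas_w, canvas_h = spec.canvas
    if spec.center is None:
        cx, cy = canvas_w / 2.0, canvas_h / 2.0
    else:
        cx, cy = spec.center

    yy, xx = np.mgrid[0:canvas_h, 0:canvas_w].astype(float)
    # inverse-rotate pixel centers into the upright local frame (y down)
    phi = math.radians(spec.rotation_deg)
    dx, dy = xx - cx, yy - cy
    lx = math.cos(phi) * dx + math.sin(phi) * dy
    ly = -math.sin(phi) * dx + math.cos(phi) * dy

    a = spec.D1 / 2.0
    cap_hit = (ly <= 0) & ((lx / a) ** 2 + (ly / spec.H) ** 2 <= 1.0)
    half_w = spec.D2 / 2.0
    stalk_hit = (
        (np.abs(lx) <= half_w)
        & (ly >= -STALK_OVERLAP_PX)
        & (ly <= spec.L - STALK_OVERLAP_PX)
    )
    if spec.broken_mode == "fragmented":
        gap_center = spec.L / 2.0 - STALK_OVERLAP_PX
        stalk_hit &= ~((ly >= gap_center - 1.5) & (ly <= gap_center + 1.5))
    if spec.broken_mode == "no_cap":
        cap_hit[:] = False
    if spec.broken_mode == "no_stalk":
        stalk_hit[:] = False

    labels = np.zeros((canvas_h, canvas_w), dtype=np.uint8)
    labels[cap_hit] = CAP
    labels[stalk_hit] = STALK  # stalk priority in the overlap rows

    fg = labels != 0
    if not fg.any():
        raise OutOfCanvasError("fixture rendered no foreground pixels")
    if fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any():
        raise OutOfCanvasError("fixture clips the canvas border; enlarge canvas or recenter")

    mask = LabelMask(labels)
    image = colorize_mask(mask)
    if spec.noise.blur_sigma > 0:
        image = ndimage.gaussian_filter(
            image.astype(float), sigma=(spec.noise.blur_sigma, spec.noise.blur_sigma, 0)
        )
        image = np.clip(image, 0, 255).astype(np.uint8)
    if spec.noise.brightness_delta:
        image = np.clip(
            image.astype(int) + spec.noise.brightness_delta, 0, 255
        ).astype(np.uint8)

    if spec.broken_mode != "none":
        true_grade: int | str = "BROKEN"
    else:
        result = assign_grade(spec.true_measurement(), criteria)
        true_grade = int(result.grade.value)
    return FixtureRecord(
        spec=spec,
        image=image,
        mask=mask,
        true_RDHP=spec.true_RDHP,
        true_RLDS=spec.true_RLDS,
        true_grade=true_grade,
    )


@dataclass(frozen=True)
class SamplingRanges:
    """Per-parameter sampling bounds for dataset generation.

    Index values are sampled inside each grade's band with a 0.1 inset
    from the band edges, so a fixture's true grade is robust to the
    roughly one-pixel rasterization uncertainty of the measured
    dimensions.  Grade-3 specimens keep a cap wider than tall (RDHP
    sampled from the slender end of the legal range): in this species the
    third grade is defined by its elongated stalk, which the
    RLDS-prevails rule captures, not by an inverted cap shape.
    """

    H: tuple[float, float] = (26.0, 40.0)
    D2: tuple[float, float] = (14.0, 22.0)
    rdhp_by_grade: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (1.6, 2.4), 2: (1.1, 1.4), 3: (1.1, 1.6)}
    )
    rlds_by_grade: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.6, 1.4), 2: (1.6, 2.4), 3: (2.6, 3.5)}
    )
    rotation_deg: tuple[float, float] = (0.0, 360.0)

    def validate(self) -> None:
        if self.H[0] <= 0 or self.H[1] < self.H[0]:
            raise ValueError(f"infeasible H range {self.H}")
        if self.D2[0] <= 0 or self.D2[1] < self.D2[0]:
            raise ValueError(f"infeasible D2 range {self.D2}")
        for g, (lo, hi) in self.rdhp_by_grade.items():
            if lo < 1.0 or hi < lo:
                raise ValueError(f"RDHP range for grade {g} violates D1 >= H: {(lo, hi)}")


def sample_specs(
    n: int,
    ranges: SamplingRanges | None = None,
    grade_mix: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    broken_fraction: float = 0.0,
    noise: NoiseSpec | None = None,
) -> Iterator[FixtureSpec]:
    """Sample ``n`` fixture specs with the requested grade proportions.

    Grade counts are apportioned largest-remainder so they match the
    requested proportions within one fixture.  A ``broken_fraction`` of
    the batch (rounded down, taken off the grade counts evenly) is
    rendered in a broken mode instead.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ranges = ranges or SamplingRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)

    n_broken = int(n * broken_fraction)
    n_graded = n - n_broken
    weights = np.asarray(grade_mix, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("grade_mix must have positive total")
    ideal = weights / weights.sum() * n_graded
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: n_graded - counts.sum()]:
        counts[i] += 1

    grades = np.repeat([1, 2, 3], counts)
    broken_modes = rng.choice(["no_cap", "no_stalk", "fragmented"], size=n_broken)
    order = rng.permutation(n)

    specs: list[FixtureSpec] = []
    for k in range(n):
        if k < len(grades):
            g = int(grades[k])
            H = rng.uniform(*ranges.H)
            rdhp = rng.uniform(*ranges.rdhp_by_grade[g])
            rlds = rng.uniform(*ranges.rlds_by_grade[g])
            D1 = rdhp * H
            d2_hi = min(ranges.D2[1], D1 - 6.0)  # keep cap shoulders outside the stalk
            D2 = rng.uniform(ranges.D2[0], max(d2_hi, ranges.D2[0] + 1e-9))
            L = max(rlds * D2, 6.0)
            mode = "none"
        else:
            mode = str(broken_modes[k - len(grades)])
            H = rng.uniform(*ranges.H)
            D1 = rng.uniform(1.3, 2.2) * H
            D2 = rng.uniform(*ranges.D2)
            L = rng.uniform(1.0, 3.0) * D2
            if mode == "fragmented":
                L = max(L, 14.0)
        specs.append(
            FixtureSpec(
                D1=D1, H=H, L=L, D2=D2,
                rotation_deg=float(rng.uniform(*ranges.rotation_deg)),
                broken_mode=mode,
                noise=noise or NoiseSpec(),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for k in order:
        yield specs[k]


MANIFEST_COLUMNS = [
    "image", "mask", "D1", "H", "L", "D2", "rotation_deg", "broken_mode",
    "true_RDHP", "true_RLDS", "true_grade", "seed",
]


def generate_dataset(
    n: int,
    out_dir: str | Path,
    ranges: SamplingRanges | None = None,
    grade_mix: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    broken_fraction: float = 0.0,
    noise: NoiseSpec | None = None,
    criteria: GradeCriteria | None = None,
) -> pd.DataFrame:
    """Render ``n`` fixtures to ``out_dir`` and write a manifest CSV.

    Returns the manifest as a DataFrame; it is also saved as
    ``manifest.csv`` with one row per fixture and the columns in
    :data:`MANIFEST_COLUMNS`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(sample_specs(n, ranges, grade_mix, seed, broken_fraction, noise)):
        rec = render_mushroom(spec, criteria)
        image_path = out / f"fixture_{i:04d}.png"
        mask_path = out / f"fixture_{i:04d}_mask.png"
        Image.fromarray(rec.image).save(image_path, format="PNG")
        write_mask(rec.mask, mask_path)
        rows.append({
            "image": image_path.name, "mask": mask_path.name,
            "D1": spec.D1, "H": spec.H, "L": spec.L, "D2": spec.D2,
            "rotation_deg": spec.rotation_deg, "broken_mode": spec.broken_mode,
            "true_RDHP": rec.true_RDHP, "true_RLDS": rec.true_RLDS,
            "true_grade": rec.true_grade, "seed": spec.seed,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
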