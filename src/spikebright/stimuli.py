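"""Parametric construction of grayscale square stimuli.

Every stimulus is a square grayscale image composed of rectangular
regions painted in a fixed order: background(s) first, then distractors,
then the target.  Rectangles use the row-major, 0-based, half-open
convention ``[r0, r1) x [c0, c1)``.  Pixel values are real numbers in
``[0, 1]``; quantization happens only at file export.

Generation is fully deterministic: no randomness enters here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class StimulusError(ValueError):
    """Invalid stimulus parameters."""


class GeometryError(StimulusError):
    """Regions that do not fit together (out of bounds, overlaps)."""


def _check_gray(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise StimulusError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle ``[r0, r1) x [c0, c1)``."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise GeometryError(f"degenerate rectangle {self}")
        if self.r0 < 0 or self.c0 < 0:
            raise GeometryError(f"negative origin in {self}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def inside(self, height: int, width: int) -> bool:
        return self.r1 <= height and self.c1 <= width

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.r1 <= other.r0
            or other.r1 <= self.r0
            or self.c1 <= other.c0
            or other.c1 <= self.c0
        )

    def to_dict(self) -> dict:
        return {"r0": self.r0, "r1": self.r1, "c0": self.c0, "c1": self.c1}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["r0"]), int(d["r1"]), int(d["c0"]), int(d["c1"]))

    @classmethod
    def centered(cls, image_size: int, size: int) -> "Rect":
        off = (image_size - size) // 2
        return cls(off, off + size, off, off + size)


def _paint(
    shape: tuple[int, int],
    backgrounds: Sequence[tuple[float, "Rect"]],
    distractors: Sequence[tuple[float, "Rect"]],
    target_region: "Rect",
    target_value: float,
) -> np.ndarray:
    out = np.full(shape, np.nan)
    for value, rect in backgrounds:
        out[rect.slices] = value
    for value, rect in distractors:
        out[rect.slices] = value
    out[target_region.slices] = target_value
    if np.isnan(out).any():
        raise GeometryError("backgrounds do not tile the image")
    return out


@dataclass
class StimulusImage:
    """A grayscale image plus the region bookkeeping that built it.

    Attributes
    ----------
    pixels : ndarray
        ``(H, W)`` float array with values in ``[0, 1]``.
    target_region : Rect
        Location of the target patch.
    target_value : float
        Gray value of the target patch.
    backgrounds : list of (value, Rect)
        One or two background regions that jointly tile the image.
    distractors : list of (value, Rect)
        Distractor rectangles, painted after backgrounds, before target.
    label : int
        1-based stimulus index within its experiment set.
    """

    pixels: np.ndarray
    target_region: Rect
    target_value: float
    backgrounds: list[tuple[float, Rect]]
    distractors: list[tuple[float, Rect]] = field(default_factory=list)
    label: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def render(self) -> np.ndarray:
        """Repaint the image from its regions (background -> distractors -> target)."""
        return _paint(
            self.shape, self.backgrounds, self.distractors,
            self.target_region, self.target_value,
        )

    def validate(self) -> None:
        h, w = self.pixels.shape
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise StimulusError("pixel values outside [0, 1]")
        _check_gray(self.target_value, "target_value")
        for value, _ in self.backgrounds + self.distractors:
            _check_gray(value, "region value")
        if not self.target_region.inside(h, w):
            raise GeometryError("target_region extends beyond the image")
        for _, rect in self.distractors:
            if not rect.inside(h, w):
                raise GeometryError(f"distractor {rect} extends beyond the image")
            if rect.overlaps(self.target_region):
                raise GeometryError(f"distractor {rect} overlaps the target")
        if not np.array_equal(self.render(), self.pixels):
            raise StimulusError("pixels inconsistent with region specification")

    def target_pixels(self) -> np.ndarray:
        return self.pixels[self.target_region.slices]

    @classmethod
    def from_regions(
        cls,
        image_size: int,
        target_region: Rect,
        target_value: float,
        backgrounds: Sequence[tuple[float, Rect]],
        distractors: Sequence[tuple[float, Rect]] = (),
        label: int = 1,
    ) -> "StimulusImage":
        backgrounds = [(float(v), r) for v, r in backgrounds]
        distractors = [(float(v), r) for v, r in distractors]
        pixels = _paint(
            (image_size, image_size), backgrounds, distractors,
            target_region, float(target_value),
        )
        return cls(pixels, target_region, float(target_value),
                   backgrounds, distractors, int(label))


def _background_halves(
    image_size: int, dark_bg: float, light_bg: float
) -> list[tuple[float, Rect]]:
    """Vertical split: left half dark, right half light."""
    half = image_size // 2
    return [
        (dark_bg, Rect(0, image_size, 0, half)),
        (light_bg, Rect(0, image_size, half, image_size)),
    ]


def _target_in_half(image_size: int, target_size: int, half: str) -> Rect:
    w = image_size // 2
    r0 = (image_size - target_size) // 2
    c0 = (w - target_size) // 2
    if half == "light":
        c0 += w
    elif half != "dark":
        raise StimulusError(f"half must be 'dark' or 'light', got {half!r}")
    return Rect(r0, r0 + target_size, c0, c0 + target_size)


def make_sbc_pair(
    target_value: float = 0.5,
    dark_bg: float = 0.2,
    light_bg: float = 0.8,
    image_size: int = 60,
    target_size: int = 20,
) -> list[StimulusImage]:
    """Identical centered target on a uniform dark vs light background.

    Returns the simultaneous-brightness-contrast pair: stimulus 1 on the
    darker background, stimulus 2 on the lighter one.
    """
    for v, n in [(target_value, "target_value"), (dark_bg, "dark_bg"), (light_bg, "light_bg")]:
        _check_gray(v, n)
    if target_size >= image_size:
        raise GeometryError("target must be smaller than the image")
    target = Rect.centered(image_size, target_size)
    full = Rect(0, image_size, 0, image_size)
    return [
        StimulusImage.from_regions(image_size, target, target_value, [(bg, full)], label=i + 1)
        for i, bg in enumerate([dark_bg, light_bg])
    ]


def make_combined_background_pair(
    target_value: float = 0.5,
    dark_bg: float = 0.2,
    light_bg: float = 0.8,
    image_size: int = 60,
    target_size: int = 20,
    labels: tuple[int, int] = (1, 2),
) -> list[StimulusImage]:
    """Split-background pair: each image half dark / half light.

    The target sits centered within the dark half in the first image and
    within the light half in the second.
    """
    for v, n in [(target_value, "target_value"), (dark_bg, "dark_bg"), (light_bg, "light_bg")]:
        _check_gray(v, n)
    if target_size >= image_size // 2:
        raise GeometryError("target must fit inside one background half")
    backgrounds = _background_halves(image_size, dark_bg, light_bg)
    return [
        StimulusImage.from_regions(
            image_size,
            _target_in_half(image_size, target_size, half),
            target_value,
            backgrounds,
            label=lab,
        )
        for half, lab in zip(["dark", "light"], labels)
    ]


def corner_distractors(
    image_size: int, size: int, inset: int = 0
) -> list[Rect]:
    """Four square distractor rectangles, one per corner.

    ``inset = 0`` places them flush with the image boundary; positive
    ``inset`` moves each diagonally inward by ``(inset, inset)`` pixels.
    """
    if inset < 0:
        raise GeometryError("inset must be nonnegative")
    lo = inset
    hi = image_size - inset - size
    if hi < lo:
        raise GeometryError("distractors collide in the image center")
    return [
        Rect(lo, lo + size, lo, lo + size),
        Rect(lo, lo + size, hi, hi + size),
        Rect(hi, hi + size, lo, lo + size),
        Rect(hi, hi + size, hi, hi + size),
    ]


def make_distractor_image(
    target_value: float = 0.5,
    bg_spec: float | tuple[float, float] = (0.2, 0.8),
    distractor_value: float = 1.0,
    distractor_size: int = 10,
    distractor_inset: int = 0,
    image_size: int = 60,
    target_size: int = 20,
    target_half: str = "dark",
    label: int = 1,
) -> StimulusImage:
    """Target plus four corner distractors at a configurable inset.

    ``bg_spec`` is either a single gray value (uniform background) or a
    ``(dark, light)`` pair rendered as vertical halves; with halves, the
    target is placed in ``target_half``.
    """
    _check_gray(distractor_value, "distractor_value")
    if isinstance(bg_spec, (tuple, list)):
        dark, light = bg_spec
        backgrounds = _background_halves(image_size, _check_gray(dark, "dark_bg"),
                                         _check_gray(light, "light_bg"))
        target = _target_in_half(image_size, target_size, target_half)
    else:
        backgrounds = [(_check_gray(bg_spec, "background"), Rect(0, image_size, 0, image_size))]
        target = Rect.centered(image_size, target_size)
    distractors = [(distractor_value, r) for r in
                   corner_distractors(image_size, distractor_size, distractor_inset)]
    return StimulusImage.from_regions(
        image_size, target, target_value, backgrounds, distractors, label=label
    )


def make_anchoring_set(
    light_bg_values: Sequence[float] = (0.8, 0.9, 1.0),
    target_value: float = 0.5,
    dark_bg: float = 0.2,
    image_size: int = 60,
    target_size: int = 20,
) -> list[StimulusImage]:
    """One dark-background image plus one image per lighter background value."""
    target = Rect.centered(image_size, target_size)
    full = Rect(0, image_size, 0, image_size)
    values = [dark_bg] + [_check_gray(v, "light background") for v in light_bg_values]
    return [
        StimulusImage.from_regions(image_size, target, target_value, [(v, full)], label=i + 1)
        for i, v in enumerate(values)
    ]


# ---------------------------------------------------------------------------
# lossless raster I/O (8-bit PNG + JSON sidecar with region metadata)

def quantize(pixels: np.ndarray, bits: int = 8) -> np.ndarray:
    """Quantize real-valued pixels to the grid representable at ``bits`` depth."""
    levels = 2**bits - 1
    return np.round(np.asarray(pixels, dtype=float) * levels) / levels


def write_png(stim: StimulusImage, path: str | Path) -> Path:
    import imageio.v3 as iio

    path = Path(path)
    data = np.round(stim.pixels * 255).astype(np.uint8)
    iio.imwrite(path, data)
    meta = {
        "label": stim.label,
        "target_value": stim.target_value,
        "target_region": stim.target_region.to_dict(),
        "backgrounds": [{"value": v, "rect": r.to_dict()} for v, r in stim.backgrounds],
        "distractors": [{"value": v, "rect": r.to_dict()} for v, r in stim.distractors],
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_png(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read pixels (rescaled to [0, 1]) and the sidecar metadata if present."""
    import imageio.v3 as iio

    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float) / 255.0
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return pixels, meta
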