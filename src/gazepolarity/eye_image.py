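"""Parametric eye stimuli and their colorimetric manipulation.

This module renders simplified, fully parameterized face/eye stimuli for two
species morphs — a human-like eye (uniformly white sclera, dark iris,
horizontally elongated opening) and a chimpanzee-like eye (uniformly dark
sclera, brighter iris, rounder opening) — and implements the image operations
used in gaze-discrimination experiments:

* contrast-polarity reversal of the eyeball region (invert CIELAB lightness,
  keep chromaticity),
* joint size/brightness degradation levels L1–L4 (with half levels) that
  emulate distancing and shading,
* iris-diameter normalization and 4:1 eye-region cropping,
* ROI colorimetry (mean CIELAB color per region and the iris–sclera ΔE).

The renderer is deterministic: a given :class:`EyeGeometry` and
:class:`EyeAppearance` always produce the same 8-bit sRGB raster and the same
boolean ROI masks, so every downstream measurement is reproducible bit for
bit.  All color math is done in CIELAB under the D65 white point and the 2°
standard observer, the conventional pairing for sRGB imagery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "LabColor",
    "RasterImage",
    "RoiMasks",
    "EyeGeometry",
    "EyeAppearance",
    "EyeStimulus",
    "StimulusLevel",
    "ColorimetryReport",
    "LEVEL_TABLE",
    "srgb_to_lab",
    "lab_to_srgb",
    "image_to_lab",
    "lab_to_image",
    "default_geometry",
    "default_appearance",
    "shift_for_angle",
    "render_eye_stimulus",
    "reverse_polarity",
    "apply_level",
    "normalize_by_iris",
    "crop_eye_region",
    "measure_colorimetry",
    "mean_luminance",
    "reports_to_frame",
]

Species = Literal["human", "chimpanzee"]
Gaze = Literal["left", "front", "right"]


# ---------------------------------------------------------------------------
# Color primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color (D65 / 2° observer).

    ``L`` is lightness in [0, 100]; ``a`` and ``b`` are the green–red and
    blue–yellow opponent axes (unbounded, typically within ±128).
    """

    L: float
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)

    def delta_e(self, other: "LabColor") -> float:
        """CIE76 color difference: Euclidean distance in CIELAB."""
        return float(np.linalg.norm(self.as_array() - other.as_array()))


def srgb_to_lab(pixel: Iterable[float]) -> LabColor:
    """Convert an 8-bit sRGB triple to CIELAB (D65 / 2°)."""
    arr = np.asarray(tuple(pixel), dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected an (R, G, B) triple")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("sRGB channels must lie in [0, 255]")
    lab = _skcolor.rgb2lab(arr.reshape(1, 1, 3) / 255.0)[0, 0]
    return LabColor(float(lab[0]), float(lab[1]), float(lab[2]))


# Linear-RGB-from-XYZ matrix (sRGB primaries, D65); used only to detect
# out-of-gamut colors before the clipped conversion.
_LIN_RGB_FROM_XYZ = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def lab_to_srgb(lab: LabColor) -> tuple[tuple[int, int, int], bool]:
    """Convert CIELAB to an 8-bit sRGB triple, clipping out-of-gamut colors.

    Returns ``(rgb, was_clipped)`` where ``was_clipped`` flags colors whose
    linear-RGB representation fell outside [0, 1] before clipping.
    """
    arr = lab.as_array().reshape(1, 1, 3)
    xyz = _skcolor.lab2xyz(arr)[0, 0]
    lin = _LIN_RGB_FROM_XYZ @ xyz
    clipped = bool((lin < -1e-6).any() or (lin > 1 + 1e-6).any())
    rgb = _skcolor.lab2rgb(arr)[0, 0]
    rgb8 = tuple(int(v) for v in np.clip(np.round(rgb * 255.0), 0, 255).astype(int))
    return rgb8, clipped


def image_to_lab(pixels: np.ndarray) -> np.ndarray:
    """Vectorized 8-bit sRGB image -> CIELAB float image."""
    return _skcolor.rgb2lab(pixels.astype(float) / 255.0)


def lab_to_image(lab: np.ndarray) -> np.ndarray:
    """CIELAB float image -> 8-bit sRGB image (gamut-clipped, rounded)."""
    rgb = _skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Raster containers
# ---------------------------------------------------------------------------


@dataclass
class RasterImage:
    """An 8-bit sRGB raster, row-major with the origin at the top left."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy())

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="RGB")

    @classmethod
    def from_pil(cls, im: Image.Image) -> "RasterImage":
        return cls(np.asarray(im.convert("RGB")))

    def save(self, path: str | Path) -> None:
        self.to_pil().save(Path(path), format="PNG")

    @classmethod
    def load(cls, path: str | Path) -> "RasterImage":
        with Image.open(Path(path)) as im:
            return cls.from_pil(im)


@dataclass
class RoiMasks:
    """Boolean ROI rasters aligned with a stimulus image.

    Invariants: iris and sclera are disjoint and both contained in the
    eyeball mask (the pupil belongs to the eyeball but to neither ROI).
    """

    iris_mask: np.ndarray
    sclera_mask: np.ndarray
    eyeball_mask: np.ndarray

    def __post_init__(self) -> None:
        self.iris_mask = np.asarray(self.iris_mask, dtype=bool)
        self.sclera_mask = np.asarray(self.sclera_mask, dtype=bool)
        self.eyeball_mask = np.asarray(self.eyeball_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if not (self.iris_mask.shape == self.sclera_mask.shape == self.eyeball_mask.shape):
            raise ValueError("masks must share one shape")
        if (self.iris_mask & self.sclera_mask).any():
            raise ValueError("iris and sclera masks overlap")
        if (self.iris_mask & ~self.eyeball_mask).any() or (
            self.sclera_mask & ~self.eyeball_mask
        ).any():
            raise ValueError("iris/sclera masks extend outside the eyeball mask")

    def copy(self) -> "RoiMasks":
        return RoiMasks(self.iris_mask.copy(), self.sclera_mask.copy(), self.eyeball_mask.copy())

    def save(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        for name, mask in (
            ("iris", self.iris_mask),
            ("sclera", self.sclera_mask),
            ("eyeball", self.eyeball_mask),
        ):
            arr = (mask.astype(np.uint8)) * 255
            Image.fromarray(arr, mode="L").save(directory / f"{stem}_{name}.png")

    @classmethod
    def load(cls, directory: str | Path, stem: str) -> "RoiMasks":
        directory = Path(directory)
        masks = {}
        for name in ("iris", "sclera", "eyeball"):
            with Image.open(directory / f"{stem}_{name}.png") as im:
                masks[name] = np.asarray(im.convert("L")) > 127
        return cls(masks["iris"], masks["sclera"], masks["eyeball"])


# ---------------------------------------------------------------------------
# Geometry / appearance
# ---------------------------------------------------------------------------

#: Eyeball radius (px) implied by a 6 px iris shift at a 20 degree rotation.
EYEBALL_RADIUS_PX = 6.0 / math.sin(math.radians(20.0))


def shift_for_angle(angle_deg: float, eyeball_radius_px: float = EYEBALL_RADIUS_PX) -> int:
    """Horizontal iris shift (px) for an eyeball rotation of ``angle_deg``.

    With the default radius the canonical pairs are 20° -> 6 px, 30° -> 9 px,
    38° -> 11 px.
    """
    return int(round(eyeball_radius_px * math.sin(math.radians(angle_deg))))


@dataclass(frozen=True)
class EyeGeometry:
    """Geometry of a rendered single-eye stimulus on a square canvas."""

    canvas_px: int = 400
    iris_diameter_px: float = 16.0
    pupil_diameter_px: float = 8.0
    eye_outline_semiaxes_px: tuple[float, float] = (24.0, 9.0)
    eyeball_radius_px: float = EYEBALL_RADIUS_PX
    gaze: Gaze = "front"
    shift_px: float = 6.0
    species_tag: Species = "human"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        a, b = self.eye_outline_semiaxes_px
        if self.canvas_px < 1:
            raise ValueError("canvas must be at least 1 px")
        if self.iris_diameter_px > 2 * a:
            raise ValueError("iris wider than the eye opening")
        if self.shift_px < 0:
            raise ValueError("shift_px must be nonnegative")
        if self.shift_px > self.eyeball_radius_px:
            raise ValueError("shift_px exceeds the eyeball radius")
        if self.gaze not in ("left", "front", "right"):
            raise ValueError(f"unknown gaze {self.gaze!r}")
        if self.pupil_diameter_px >= self.iris_diameter_px:
            raise ValueError("pupil must be smaller than the iris")


@dataclass(frozen=True)
class EyeAppearance:
    """CIELAB colors of the stimulus regions."""

    iris_color: LabColor
    sclera_color: LabColor
    pupil_color: LabColor
    skin_color: LabColor
    background: LabColor = field(default_factory=lambda: srgb_to_lab((128, 128, 128)))


def default_geometry(species: Species = "human", gaze: Gaze = "front") -> EyeGeometry:
    """Species-preset geometry.

    The human-like opening is horizontally more elongated (48x18 px,
    width/height ratio ~2.7) than the chimpanzee-like one (36x20 px, ~1.8);
    both share the 16 px normalized iris.
    """
    if species == "human":
        semiaxes = (24.0, 9.0)
    elif species == "chimpanzee":
        semiaxes = (18.0, 10.0)
    else:
        raise ValueError(f"unknown species {species!r}")
    return EyeGeometry(eye_outline_semiaxes_px=semiaxes, gaze=gaze, species_tag=species)


def default_appearance(species: Species = "human") -> EyeAppearance:
    """Species-preset colors: white sclera/dark iris (human) vs dark
    sclera/bright iris (chimpanzee), moderate in-gamut chroma throughout."""
    if species == "human":
        return EyeAppearance(
            iris_color=LabColor(30.0, 8.0, 12.0),
            sclera_color=LabColor(92.0, 0.0, 4.0),
            pupil_color=LabColor(8.0, 0.0, 0.0),
            skin_color=LabColor(65.0, 10.0, 16.0),
        )
    if species == "chimpanzee":
        return EyeAppearance(
            iris_color=LabColor(55.0, 10.0, 30.0),
            sclera_color=LabColor(22.0, 6.0, 8.0),
            pupil_color=LabColor(8.0, 0.0, 0.0),
            skin_color=LabColor(35.0, 8.0, 10.0),
        )
    raise ValueError(f"unknown species {species!r}")


@dataclass
class EyeStimulus:
    """A rendered stimulus together with its aligned ROI masks."""

    image: RasterImage
    masks: RoiMasks
    geometry: EyeGeometry | None = None
    appearance: EyeAppearance | None = None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_eye_stimulus(
    geometry: EyeGeometry, appearance: EyeAppearance
) -> tuple[RasterImage, RoiMasks]:
    """Deterministically render a single-eye stimulus.

    The eye opening is an ellipse centered on the canvas; the iris is a disc
    clipped to the opening, displaced horizontally by ``shift_px`` for averted
    gaze ("right" = viewer's right = +x), with a concentric pupil.  Sclera
    fills the remaining opening, including the areas exposed by the shift.
    """
    geometry.validate()
    n = geometry.canvas_px
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n].astype(float)

    a, b = geometry.eye_outline_semiaxes_px
    opening = ((x - c) / a) ** 2 + ((y - c) / b) ** 2 < 1.0

    # Face patch behind the eye; proportions are cosmetic only.
    fa, fb = 0.45 * n, 0.48 * n
    face = ((x - c) / fa) ** 2 + ((y - c) / fb) ** 2 < 1.0

    shift = {"left": -geometry.shift_px, "front": 0.0, "right": geometry.shift_px}[
        geometry.gaze
    ]
    icx = c + shift
    r_iris = geometry.iris_diameter_px / 2.0
    r_pupil = geometry.pupil_diameter_px / 2.0
    iris_disc = (x - icx) ** 2 + (y - c) ** 2 < r_iris**2
    pupil_disc = (x - icx) ** 2 + (y - c) ** 2 < r_pupil**2

    colors = {
        name: np.array(lab_to_srgb(lab)[0], dtype=np.uint8)
        for name, lab in (
            ("background", appearance.background),
            ("skin", appearance.skin_color),
            ("sclera", appearance.sclera_color),
            ("iris", appearance.iris_color),
            ("pupil", appearance.pupil_color),
        )
    }

    img = np.empty((n, n, 3), dtype=np.uint8)
    img[:] = colors["background"]
    img[face] = colors["skin"]
    img[opening] = colors["sclera"]
    img[iris_disc & opening] = colors["iris"]
    img[pupil_disc & opening] = colors["pupil"]

    masks = RoiMasks(
        iris_mask=iris_disc & opening & ~pupil_disc,
        sclera_mask=opening & ~iris_disc,
        eyeball_mask=opening,
    )
    return RasterImage(img), masks


# ---------------------------------------------------------------------------
# Polarity reversal
# ---------------------------------------------------------------------------

# ITU-R BT.601 luma weights, used only by the optional grayscale mode.
_LUMA = np.array([0.299, 0.587, 0.114])


def reverse_polarity(
    image: RasterImage,
    eyeball_mask: np.ndarray,
    mode: Literal["cielab", "grayscale"] = "cielab",
) -> RasterImage:
    """Reverse the contrast polarity of the eyeball region.

    In the default ``"cielab"`` mode every pixel inside ``eyeball_mask`` has
    its lightness inverted (L* -> 100 − L*) with chromaticity (a*, b*) left
    unchanged, then is converted back to sRGB with gamut clipping.  This turns
    a light-sclera/dark-iris eye into its negative without changing any
    within-eye CIELAB color differences.  The ``"grayscale"`` mode instead
    inverts the BT.601 luma while keeping the chroma offsets.  Pixels outside
    the mask are returned bit-identical.
    """
    mask = np.asarray(eyeball_mask, dtype=bool)
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape does not match the image")
    out = image.pixels.copy()
    if not mask.any():
        return RasterImage(out)
    sub = image.pixels[mask].astype(float)  # (k, 3)
    if mode == "cielab":
        lab = _skcolor.rgb2lab(sub.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
        lab[:, 0] = 100.0 - lab[:, 0]
        rgb = _skcolor.lab2rgb(lab.reshape(-1, 1, 3)).reshape(-1, 3)
        out[mask] = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    elif mode == "grayscale":
        yv = sub @ _LUMA
        new = sub + (255.0 - 2.0 * yv)[:, None]
        out[mask] = np.clip(np.round(new), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RasterImage(out)


# ---------------------------------------------------------------------------
# Stimulus levels (distancing / shading)
# ---------------------------------------------------------------------------

#: level -> (width_px at L1-scale input of 400 px, brightness fraction)
LEVEL_TABLE: dict[float, tuple[int, float]] = {
    1.0: (400, 1.00),
    1.5: (300, 0.75),
    2.0: (200, 0.50),
    2.5: (150, 0.42),
    3.0: (100, 0.33),
    3.5: (75, 0.29),
    4.0: (50, 0.25),
}


@dataclass(frozen=True)
class StimulusLevel:
    """One joint size/brightness degradation step (L1 largest/brightest)."""

    level: float
    width_px: int
    brightness_fraction: float

    @classmethod
    def from_value(cls, level: "float | StimulusLevel") -> "StimulusLevel":
        if isinstance(level, StimulusLevel):
            return level
        key = float(level)
        if key not in LEVEL_TABLE:
            raise ValueError(f"unknown stimulus level {level!r}")
        w, f = LEVEL_TABLE[key]
        return cls(key, w, f)

    @classmethod
    def table(cls) -> list["StimulusLevel"]:
        return [cls.from_value(k) for k in sorted(LEVEL_TABLE)]


def _srgb_to_linear(v: np.ndarray) -> np.ndarray:
    v = v / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, 1.0)
    out = np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)
    return out * 255.0


def apply_level(
    image: RasterImage,
    level: float | StimulusLevel,
    space: Literal["srgb", "linear"] = "srgb",
) -> RasterImage:
    """Rescale and darken an L1-scale image to a stimulus level.

    Width is resampled to the level's target (aspect preserved, area-averaging
    ``BOX`` filter) and brightness is scaled multiplicatively.  The default
    scales 8-bit sRGB channel values directly (image-editor semantics); pass
    ``space="linear"`` to scale linear light instead.  L1 is the identity and
    returns a bit-identical copy.
    """
    lvl = StimulusLevel.from_value(level)
    px = image.pixels
    if image.width_px != lvl.width_px:
        new_h = max(1, round(image.height_px * lvl.width_px / image.width_px))
        pil = image.to_pil().resize((lvl.width_px, new_h), Image.Resampling.BOX)
        px = np.asarray(pil)
    if lvl.brightness_fraction != 1.0:
        if space == "srgb":
            px = np.clip(np.round(px.astype(float) * lvl.brightness_fraction), 0, 255)
        elif space == "linear":
            lin = _srgb_to_linear(px.astype(float)) * lvl.brightness_fraction
            px = np.round(_linear_to_srgb(lin))
        else:
            raise ValueError(f"unknown space {space!r}")
        px = px.astype(np.uint8)
    return RasterImage(px.copy())


# ---------------------------------------------------------------------------
# Normalization / cropping
# ---------------------------------------------------------------------------


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray(mask.astype(np.uint8) * 255, mode="L")
    return np.asarray(im.resize(size, Image.Resampling.NEAREST)) > 127


def _iris_extent_px(iris_mask: np.ndarray) -> int:
    cols = np.flatnonzero(iris_mask.any(axis=0))
    if cols.size == 0:
        raise ValueError("iris mask is empty")
    return int(cols[-1] - cols[0] + 1)


def normalize_by_iris(
    image: RasterImage, masks: RoiMasks, target_iris_px: int = 16
) -> tuple[RasterImage, RoiMasks]:
    """Uniformly rescale so the iris mask's horizontal extent is ~16 px.

    This is the size normalization that equates stimuli across face images:
    after it, eye-shape comparisons are made at a fixed iris diameter.
    """
    extent = _iris_extent_px(masks.iris_mask)
    scale = target_iris_px / extent
    if extent == target_iris_px:
        return image.copy(), masks.copy()
    new_w = max(1, round(image.width_px * scale))
    new_h = max(1, round(image.height_px * scale))
    method = Image.Resampling.BOX if scale < 1 else Image.Resampling.BILINEAR
    pil = image.to_pil().resize((new_w, new_h), method)
    out_masks = RoiMasks(
        _resize_mask(masks.iris_mask, (new_w, new_h)),
        _resize_mask(masks.sclera_mask, (new_w, new_h)),
        _resize_mask(masks.eyeball_mask, (new_w, new_h)),
    )
    # NEAREST resampling can create stray overlaps at region boundaries.
    out_masks.iris_mask &= out_masks.eyeball_mask & ~out_masks.sclera_mask
    out_masks.sclera_mask &= out_masks.eyeball_mask
    return RasterImage(np.asarray(pil)), out_masks


def crop_eye_region(
    image: RasterImage,
    masks: RoiMasks,
    aspect: float = 4.0,
    background: tuple[int, int, int] = (128, 128, 128),
) -> tuple[RasterImage, RoiMasks]:
    """Crop the full-width eye strip with the given width:height aspect.

    The window spans the full image width with height ``width / aspect``,
    vertically centered on the eyeball mask (400x400 -> 400x100 at default
    aspect).  If the window would exceed the canvas it is padded with the
    background color.  The crop always contains the whole eyeball mask and is
    idempotent.
    """
    if not masks.eyeball_mask.any():
        raise ValueError("eyeball mask is empty")
    w = image.width_px
    h = max(1, round(w / aspect))
    rows = np.flatnonzero(masks.eyeball_mask.any(axis=1))
    cy = (rows[0] + rows[-1] + 1) / 2.0
    top = math.floor(cy - h / 2.0 + 0.5)

    if h < rows[-1] - rows[0] + 1:
        raise ValueError("eye region taller than the crop window")

    def _slice_pad(arr: np.ndarray, fill) -> np.ndarray:
        out_shape = (h,) + arr.shape[1:]
        out = np.full(out_shape, fill, dtype=arr.dtype)
        src_lo, src_hi = max(top, 0), min(top + h, arr.shape[0])
        dst_lo = src_lo - top
        out[dst_lo : dst_lo + (src_hi - src_lo)] = arr[src_lo:src_hi]
        return out

    px = _slice_pad(image.pixels, 0)
    if top < 0 or top + h > image.height_px:
        pad_rows = np.ones(h, dtype=bool)
        pad_rows[max(-top, 0) : max(-top, 0) + (min(top + h, image.height_px) - max(top, 0))] = False
        px[pad_rows] = np.array(background, dtype=np.uint8)
    out_masks = RoiMasks(
        _slice_pad(masks.iris_mask, False),
        _slice_pad(masks.sclera_mask, False),
        _slice_pad(masks.eyeball_mask, False),
    )
    return RasterImage(px), out_masks


# ---------------------------------------------------------------------------
# Colorimetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorimetryReport:
    """ROI colorimetry and shape metrics of one stimulus."""

    iris_mean: LabColor
    sclera_mean: LabColor
    iris_sclera_difference: float
    eye_width_px: int
    eye_height_px: int
    width_height_ratio: float
    sclera_area_px: int
    iris_area_px: int

    def to_dict(self) -> dict:
        return {
            "iris_L": self.iris_mean.L,
            "iris_a": self.iris_mean.a,
            "iris_b": self.iris_mean.b,
            "sclera_L": self.sclera_mean.L,
            "sclera_a": self.sclera_mean.a,
            "sclera_b": self.sclera_mean.b,
            "iris_sclera_difference": self.iris_sclera_difference,
            "eye_width_px": self.eye_width_px,
            "eye_height_px": self.eye_height_px,
            "width_height_ratio": self.width_height_ratio,
            "sclera_area_px": self.sclera_area_px,
            "iris_area_px": self.iris_area_px,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def measure_colorimetry(image: RasterImage, masks: RoiMasks) -> ColorimetryReport:
    """Mean CIELAB color per ROI, their ΔE, and eye-shape metrics.

    The iris–sclera difference is the Euclidean distance between the two ROI
    means, i.e. sqrt(ΔL² + Δa² + Δb²).
    """
    if not masks.iris_mask.any() or not masks.sclera_mask.any():
        raise ValueError("iris and sclera masks must be non-empty")
    lab = image_to_lab(image.pixels)
    iris = lab[masks.iris_mask].mean(axis=0)
    sclera = lab[masks.sclera_mask].mean(axis=0)
    iris_mean = LabColor(float(np.clip(iris[0], 0, 100)), float(iris[1]), float(iris[2]))
    sclera_mean = LabColor(float(np.clip(sclera[0], 0, 100)), float(sclera[1]), float(sclera[2]))
    diff = float(np.linalg.norm(iris - sclera))
    rows = np.flatnonzero(masks.eyeball_mask.any(axis=1))
    cols = np.flatnonzero(masks.eyeball_mask.any(axis=0))
    width = int(cols[-1] - cols[0] + 1)
    height = int(rows[-1] - rows[0] + 1)
    return ColorimetryReport(
        iris_mean=iris_mean,
        sclera_mean=sclera_mean,
        iris_sclera_difference=diff,
        eye_width_px=width,
        eye_height_px=height,
        width_height_ratio=width / height,
        sclera_area_px=int(masks.sclera_mask.sum()),
        iris_area_px=int(masks.iris_mask.sum()),
    )


def mean_luminance(image: RasterImage) -> float:
    """Mean BT.601 luma of the image, in [0, 255]."""
    return float((image.pixels.astype(float) @ _LUMA).mean())


def reports_to_frame(reports: dict[str, ColorimetryReport]):
    """Stack named colorimetry reports into a pandas DataFrame."""
    import pandas as pd

    rows = {name: rep.to_dict() for name, rep in reports.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
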