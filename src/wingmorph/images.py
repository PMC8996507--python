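"""Image standardization and pixel-matrix construction.

Wing photographs become comparable pixel matrices through a fixed sequence:
greyscale conversion, brightness/contrast normalization of the wing content
(background stays white), mirroring of right wings into left pose, and
scaling/centering into a standard frame — 200 x 56 px for forewings and
200 x 81 px for hindwings.  Flattened row-major, those frames give
11 200- and 16 200-dimensional pixel variables for the linear analyses; the
convolutional analyses first step the frames down to small square thumbnails
by exact area-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image as PILImage

from .template import FRAME_FOREWING, FRAME_HINDWING

#: luminance weights (ITU-R BT.709) for RGB -> grey conversion
_LUMA = np.array([0.2126, 0.7152, 0.0722])

#: grey levels above this are treated as (white) background
_BACKGROUND_LEVEL = 250

DEFAULT_BRIGHTNESS = 200.0
DEFAULT_CONTRAST = 40.0


class NoContentError(ValueError):
    """Raised when an image is empty or contains only background."""


class FrameMismatchError(ValueError):
    """Raised when images with different frames are combined."""


@dataclass
class WingImage:
    """A greyscale wing image in a standardized frame.

    ``frame`` is (width, height) in pixels; ``pixels`` has shape
    (height, width), dtype uint8, origin top-left, row-major.
    """

    pixels: np.ndarray
    frame: tuple[int, int]
    wing_type: str = "forewing"
    pose: str = "left"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        w, h = self.frame
        if self.pixels.shape != (h, w):
            raise FrameMismatchError(
                f"pixels shape {self.pixels.shape} does not match frame {self.frame}")


def default_frame(wing_type: str) -> tuple[int, int]:
    return FRAME_FOREWING if wing_type == "forewing" else FRAME_HINDWING


def _to_grey(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:
        raw = raw[..., :3] @ _LUMA
    if raw.ndim != 2:
        raise ValueError("expected a 2D greyscale or 3D RGB array")
    if raw.max() <= 1.0 + 1e-12 and raw.min() >= 0.0:
        raw = raw * 255.0
    return raw


def standardize_image(raw, frame: tuple[int, int], pose: str = "left",
                      target_mean: float = DEFAULT_BRIGHTNESS,
                      target_sd: float = DEFAULT_CONTRAST,
                      wing_type: str = "forewing",
                      metadata: dict | None = None) -> WingImage:
    """Standardize a raw wing image into a comparable frame.

    The non-background (wing) pixels are linearly rescaled to the package
    brightness/contrast targets and the content is scaled (aspect preserved)
    and centered in a white frame.  Right-side wings are mirrored to left
    pose first.  Idempotent up to clipping/rounding: a second pass changes
    no pixel by more than one grey level.
    """
    if isinstance(raw, WingImage):
        metadata = {**raw.metadata, **(metadata or {})}
        wing_type = raw.wing_type
        raw = raw.pixels
    img = _to_grey(raw)
    if img.size == 0:
        raise NoContentError("empty image")
    if pose == "mirrored-from-right":
        img = img[:, ::-1]
    elif pose != "left":
        raise ValueError(f"unknown pose {pose!r}")

    mask = img < _BACKGROUND_LEVEL
    if not mask.any():
        raise NoContentError("image contains only background")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]

    w, h = frame
    margin = 2
    bh, bw = crop.shape
    scale = min((w - 2 * margin) / bw, (h - 2 * margin) / bh)
    if abs(scale - 1.0) > 1.0 / max(bw, bh):
        new_shape = (max(1, int(round(bh * scale))), max(1, int(round(bw * scale))))
        crop = _area_resize(crop, new_shape) if scale < 1 else _bilinear_resize(crop, new_shape)

    cmask = crop < _BACKGROUND_LEVEL
    vals = crop[cmask]
    out = crop.copy()
    if vals.size and vals.std() > 1e-9:
        a = target_sd / vals.std()
        b = target_mean - a * vals.mean()
        out[cmask] = a * vals + b
    elif vals.size:
        out[cmask] = target_mean

    canvas = np.full((h, w), 255.0)
    r0 = (h - crop.shape[0]) // 2
    c0 = (w - crop.shape[1]) // 2
    canvas[r0:r0 + crop.shape[0], c0:c0 + crop.shape[1]] = out
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return WingImage(pixels=pixels, frame=frame, wing_type=wing_type,
                     pose="left", metadata=metadata or {})


def _overlap_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """Exact area-weighted 1D resampling operator (rows sum to 1)."""
    A = np.zeros((n_dst, n_src))
    step = n_src / n_dst
    for i in range(n_dst):
        lo, hi = i * step, (i + 1) * step
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_src)):
            A[i, j] = min(hi, j + 1) - max(lo, j)
    A /= A.sum(axis=1, keepdims=True)
    return A


def _area_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    Ar = _overlap_matrix(img.shape[0], shape[0])
    Ac = _overlap_matrix(img.shape[1], shape[1])
    return Ar @ img @ Ac.T


def _bilinear_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    r = np.linspace(0, img.shape[0] - 1, shape[0])
    c = np.linspace(0, img.shape[1] - 1, shape[1])
    r0 = np.clip(np.floor(r).astype(int), 0, img.shape[0] - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, img.shape[1] - 2)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    return ((1 - fr) * (1 - fc) * img[np.ix_(r0, c0)]
            + (1 - fr) * fc * img[np.ix_(r0, c0 + 1)]
            + fr * (1 - fc) * img[np.ix_(r0 + 1, c0)]
            + fr * fc * img[np.ix_(r0 + 1, c0 + 1)])


def mirror(image: WingImage) -> WingImage:
    """Horizontal flip (pose mirroring); an involution."""
    return WingImage(pixels=image.pixels[:, ::-1].copy(), frame=image.frame,
                     wing_type=image.wing_type,
                     pose="mirrored-from-right" if image.pose == "left" else "left",
                     metadata=dict(image.metadata))


def flatten_to_matrix(images: Sequence[WingImage]) -> tuple[np.ndarray, tuple[int, int]]:
    """Row-major flattening of same-frame images into an n x p matrix.

    p = width * height (11 200 for the forewing frame, 16 200 for the
    hindwing frame).  Pixel (r, c) maps to column r * width + c.
    """
    if not images:
        raise ValueError("no images supplied")
    frame = images[0].frame
    for im in images:
        if im.frame != frame:
            raise FrameMismatchError("all images must share one frame")
    X = np.stack([im.pixels.reshape(-1).astype(float) for im in images])
    return X, frame


def reshape_vector(vec: np.ndarray, frame: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_to_matrix` for one row."""
    w, h = frame
    return np.asarray(vec, dtype=float).reshape(h, w)


def downsample_thumbnail(image: WingImage | np.ndarray,
                         target: tuple[int, int] = (40, 40)) -> np.ndarray:
    """Step an image down to a small thumbnail by area-weighted averaging.

    ``target`` is (rows, cols).  Mean brightness is preserved exactly by
    construction; upscaling in both dimensions is refused.
    """
    px = image.pixels if isinstance(image, WingImage) else np.asarray(image)
    tr, tc = target
    if tr <= 0 or tc <= 0:
        raise ValueError("target dimensions must be positive")
    if tr > px.shape[0] and tc > px.shape[1]:
        raise ValueError("refusing to upscale: target exceeds source in both dims")
    out = _area_resize(px.astype(float), (tr, tc))
    return np.clip(out, 0, 255)


def dimensionality_reduction_pct(frame: tuple[int, int],
                                 target: tuple[int, int]) -> int:
    """Percent reduction in variable count from ``frame`` (w, h) to a
    ``target`` (rows, cols) thumbnail, rounded to the nearest integer."""
    w, h = frame
    if w <= 0 or h <= 0:
        raise ValueError("zero-area frame")
    tr, tc = target
    return int(round(100.0 * (1.0 - (tr * tc) / (w * h))))


def write_tiff(path: str | Path, image: WingImage) -> None:
    """Uncompressed TIFF writer (bit-exact round trip)."""
    tifffile.imwrite(str(path), image.pixels, compression=None)


def read_tiff(path: str | Path, wing_type: str = "forewing",
              metadata: dict | None = None) -> WingImage:
    px = tifffile.imread(str(path))
    h, w = px.shape
    return WingImage(pixels=px, frame=(w, h), wing_type=wing_type,
                     metadata=metadata or {})


def write_png(path: str | Path, image: WingImage) -> None:
    PILImage.fromarray(image.pixels).save(str(path))


def read_png(path: str | Path, wing_type: str = "forewing") -> WingImage:
    px = np.asarray(PILImage.open(str(path)).convert("L"))
    h, w = px.shape
    return WingImage(pixels=px, frame=(w, h), wing_type=wing_type)
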