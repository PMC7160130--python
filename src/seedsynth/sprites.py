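"""Seed-image and background pools.

A *sprite* is a background-free cutout of a single seed: an RGB raster plus a
per-pixel opacity (alpha) mask, tagged with the cultivar it came from.  Sprites
are harvested from flat-bed scans of seeds on a uniform colored background by
chroma-key thresholding, or synthesised as textured superellipse silhouettes
for testing and pipeline development.  Scenes are composited from a
:class:`SpritePool` by the :mod:`seedsynth.compose` module.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class EmptySpriteError(ValueError):
    """Raised when background removal leaves no foreground pixel."""


@dataclasses.dataclass
class SeedSprite:
    """A background-free seed cutout.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        RGB raster; pixels outside the alpha support are (0, 0, 0).
    alpha : ndarray, shape (H, W), float
        Opacity in [0, 1].  Binary at extraction time; fractional values only
        arise from the perimeter blur applied during compositing.
    cultivar : str
        Variety tag used to group sprites.
    source_id : str
        Identifier of the scan or generator the sprite came from.
    """

    pixels: np.ndarray
    alpha: np.ndarray
    cultivar: str
    source_id: str

    @property
    def area_px(self) -> int:
        """Number of pixels with opacity above 0.5."""
        return int(np.count_nonzero(self.alpha > 0.5))

    def validate(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 raster")
        if self.alpha.shape != self.pixels.shape[:2]:
            raise ValueError("alpha shape must match pixels")
        support = self.alpha > 0.5
        if not support.any():
            raise EmptySpriteError("sprite has no opaque pixel")
        _, n = ndimage.label(support)
        if n != 1:
            raise ValueError(f"alpha support has {n} connected components, expected 1")
        if self.pixels[~support].any():
            raise ValueError("pixels outside the alpha support must be (0,0,0)")


@dataclasses.dataclass
class BackgroundTile:
    """A square background raster at the compositing canvas size."""

    pixels: np.ndarray

    def validate(self, canvas_size: int = 1024) -> None:
        h, w = self.pixels.shape[:2]
        if h != w or h != canvas_size:
            raise ValueError(
                f"background must be {canvas_size} x {canvas_size}, got {h} x {w}"
            )


@dataclasses.dataclass
class SpritePool:
    """The seed-image pool and background pool composition draws from."""

    sprites: list[SeedSprite]
    backgrounds: list[BackgroundTile]

    def validate(self) -> None:
        if not self.sprites or not self.backgrounds:
            raise ValueError("sprite and background pools must both be non-empty")


def extract_sprite(
    scan_region: np.ndarray,
    background_color: tuple[int, int, int],
    tolerance: float = 60.0,
    cultivar: str = "",
    source_id: str = "",
) -> SeedSprite:
    """Chroma-key a single seed out of a uniform-background scan crop.

    A pixel is foreground when its Euclidean RGB distance from
    ``background_color`` exceeds ``tolerance`` (8-bit scale).  The largest
    connected foreground component is kept, interior holes are filled, the
    raster is cropped to the tight bounding box of the support, and background
    pixels are zeroed.

    Raises
    ------
    EmptySpriteError
        If no pixel survives thresholding.
    """
    img = np.asarray(scan_region, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("scan_region must be an H x W x 3 RGB raster")
    bg = np.asarray(background_color, dtype=np.float64)
    dist = np.sqrt(((img - bg) ** 2).sum(axis=2))
    fg = dist > tolerance
    if not fg.any():
        raise EmptySpriteError("no foreground pixel after chroma thresholding")

    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    fg = ndimage.binary_fill_holes(fg)

    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    sl = np.s_[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    support = fg[sl]
    pixels = np.asarray(scan_region, dtype=np.uint8)[sl].copy()
    pixels[~support] = 0
    sprite = SeedSprite(
        pixels=pixels,
        alpha=support.astype(np.float64),
        cultivar=cultivar,
        source_id=source_id,
    )
    sprite.validate()
    return sprite


def _superellipse_mask(
    length: float, width: float, exponent: float
) -> np.ndarray:
    """Rasterize a filled superellipse |x/a|^n + |y/b|^n <= 1."""
    a, b = length / 2.0, width / 2.0
    h = int(np.ceil(width)) + 2
    w = int(np.ceil(length)) + 2
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r = (np.abs((xx - cx) / a)) ** exponent + (np.abs((yy - cy) / b)) ** exponent
    return r <= 1.0


def make_fixture_pool(
    rng_seed: int,
    n_cultivars: int = 20,
    per_cultivar: int = 20,
    length_range: tuple[float, float] = (60.0, 110.0),
    aspect_range: tuple[float, float] = (1.6, 3.0),
    exponent_range: tuple[float, float] = (1.5, 3.0),
    canvas_size: int = 1024,
    n_backgrounds: int = 4,
) -> SpritePool:
    """Generate a synthetic sprite pool of textured superellipse "seeds".

    Each cultivar gets its own size, aspect-ratio, squareness and base-color
    distribution; individual sprites jitter around those and carry
    multiplicative pixel noise for texture.  Backgrounds are uniform colored
    tiles at ``canvas_size``.  Fully deterministic for a fixed ``rng_seed``.

    With the defaults of 20 cultivars and 20 sprites per cultivar the pool
    holds 400 seed images, mirroring a typical scan-derived pool.
    """
    if n_cultivars < 1 or per_cultivar < 1:
        raise ValueError("counts must be >= 1")
    if length_range[0] <= 0 or aspect_range[0] <= 0 or exponent_range[0] <= 0:
        raise ValueError("shape parameter ranges must be positive")

    rng = np.random.default_rng(rng_seed)
    sprites: list[SeedSprite] = []
    for c in range(n_cultivars):
        name = f"cv{c:02d}"
        base_len = rng.uniform(*length_range)
        base_aspect = rng.uniform(*aspect_range)
        base_exp = rng.uniform(*exponent_range)
        # warm seed-like hues: reddish-brown to straw yellow
        base_color = np.array(
            [rng.uniform(120, 210), rng.uniform(90, 180), rng.uniform(40, 110)]
        )
        for i in range(per_cultivar):
            length = base_len * rng.uniform(0.9, 1.1)
            aspect = np.clip(base_aspect * rng.uniform(0.92, 1.08), 1.05, None)
            width = length / aspect
            exponent = np.clip(base_exp * rng.uniform(0.9, 1.1), 1.2, 4.0)
            mask = _superellipse_mask(length, width, exponent)
            h, w = mask.shape
            texture = rng.normal(1.0, 0.08, size=(h, w, 1))
            pixels = np.clip(base_color * texture, 0, 255).astype(np.uint8)
            pixels[~mask] = 0
            sprites.append(
                SeedSprite(
                    pixels=pixels,
                    alpha=mask.astype(np.float64),
                    cultivar=name,
                    source_id=f"{name}_{i:03d}",
                )
            )

    backgrounds = []
    for _ in range(max(1, n_backgrounds)):
        color = rng.uniform(25, 70, size=3)  # dark scanner-lid background
        tile = np.empty((canvas_size, canvas_size, 3), dtype=np.uint8)
        tile[:] = color.astype(np.uint8)
        backgrounds.append(BackgroundTile(pixels=tile))

    pool = SpritePool(sprites=sprites, backgrounds=backgrounds)
    pool.validate()
    return pool


def save_pool(pool: SpritePool, out_dir: str | Path) -> None:
    """Write a pool to disk: RGBA PNG per sprite, RGB PNG per background."""
    out = Path(out_dir)
    (out / "sprites").mkdir(parents=True, exist_ok=True)
    (out / "backgrounds").mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    for sp in pool.sprites:
        idx = counters.get(sp.cultivar, 0)
        counters[sp.cultivar] = idx + 1
        rgba = np.dstack([sp.pixels, (sp.alpha * 255).round().astype(np.uint8)])
        Image.fromarray(rgba, mode="RGBA").save(
            out / "sprites" / f"{sp.cultivar}_{idx:03d}.png"
        )
    for j, bg in enumerate(pool.backgrounds):
        Image.fromarray(bg.pixels, mode="RGB").save(
            out / "backgrounds" / f"bg_{j:02d}.png"
        )


def load_pool(in_dir: str | Path) -> SpritePool:
    """Read a pool written by :func:`save_pool`."""
    root = Path(in_dir)
    sprites = []
    for p in sorted((root / "sprites").glob("*.png")):
        arr = np.asarray(Image.open(p).convert("RGBA"))
        cultivar = p.stem.rsplit("_", 1)[0]
        sprites.append(
            SeedSprite(
                pixels=arr[..., :3].copy(),
                alpha=arr[..., 3].astype(np.float64) / 255.0,
                cultivar=cultivar,
                source_id=p.stem,
            )
        )
    backgrounds = [
        BackgroundTile(pixels=np.asarray(Image.open(p).convert("RGB")))
        for p in sorted((root / "backgrounds").glob("*.png"))
    ]
    pool = SpritePool(sprites=sprites, backgrounds=backgrounds)
    pool.validate()
    return pool
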