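"""Domain-randomized scene composition.

Synthetic training images are built by copy-paste compositing: sprites from a
:class:`~seedsynth.sprites.SpritePool` are rotated by a random angle and pasted
at random in-canvas positions over a background tile, with alpha blending and
a Gaussian-blurred perimeter to soften cut-out artifacts.  A candidate
placement is accepted only if the fraction of its footprint already covered by
seed pixels does not exceed ``overlap_threshold`` (default 0.25); a rejected
position consumes a trial and a new position is drawn for the same rotated
sprite.  A fixed budget of ``max_trials`` (default 70) pasting trials is spent
per scene.  The per-pixel instance label map is built simultaneously: each new
paste overwrites earlier labels inside its support (foreground replacement),
so earlier instances' visible masks shrink under occlusion, exactly as they
would in a photograph of touching seeds.  Finally the canvas (default
1024 x 1024) is center-cropped to the output size (default 768 x 768) so that
border seeds are cut off, as in real scans.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .sprites import SeedSprite, SpritePool


@dataclasses.dataclass
class ComposeConfig:
    canvas_size: int = 1024
    out_size: int = 768
    overlap_threshold: float = 0.25
    max_trials: int = 70
    blur_sigma: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.out_size > self.canvas_size:
            raise ValueError("out_size must not exceed canvas_size")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if self.max_trials < 0:
            raise ValueError("max_trials must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PlacementSpec:
    """Rotation angle (degrees) and canvas position of a sprite paste.

    ``x``/``y`` locate the top-left corner of the *rotated* sprite raster;
    the whole rotated bounding box must lie inside the canvas.
    """

    angle: float
    x: int
    y: int


@dataclasses.dataclass
class SceneInstance:
    instance_id: int
    visible_mask: np.ndarray  # bool, scene-sized
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    pasted_area_px: int
    cultivar: str
    overlap_at_paste: float = 0.0


@dataclasses.dataclass
class SyntheticScene:
    image: np.ndarray  # uint8 RGB, out_size x out_size
    label_map: np.ndarray  # int32, 0 = background
    instances: list[SceneInstance]
    config: ComposeConfig
    rng_seed: int

    def validate(self) -> None:
        union = np.zeros(self.label_map.shape, dtype=bool)
        for inst in self.instances:
            m = inst.visible_mask
            if not m.any():
                raise ValueError(f"instance {inst.instance_id} has empty visible mask")
            if (union & m).any():
                raise ValueError("instance visible masks overlap")
            union |= m
            if not (self.label_map[m] == inst.instance_id).all():
                raise ValueError("label map disagrees with visible mask")
            if inst.bbox != _tight_bbox(m):
                raise ValueError(f"bbox of instance {inst.instance_id} is not tight")
        if ((self.label_map > 0) != union).any():
            raise ValueError("label map foreground != union of visible masks")


class _SceneState:
    """Mutable canvas-resolution state during composition."""

    def __init__(self, background: np.ndarray, canvas_size: int):
        if background.shape[0] < canvas_size or background.shape[1] < canvas_size:
            raise ValueError("background smaller than canvas size")
        # oversized backgrounds are center-cropped to the canvas
        oy = (background.shape[0] - canvas_size) // 2
        ox = (background.shape[1] - canvas_size) // 2
        background = background[oy : oy + canvas_size, ox : ox + canvas_size]
        self.image = background.astype(np.float32).copy()
        self.label_map = np.zeros((canvas_size, canvas_size), dtype=np.int32)
        self.records: list[dict] = []
        self.next_id = 1


def overlap_fraction(candidate_mask: np.ndarray, occupancy: np.ndarray) -> float:
    """Fraction of the candidate's pixels already covered by occupancy."""
    if candidate_mask.shape != occupancy.shape:
        raise ValueError("masks must share shape")
    n = int(np.count_nonzero(candidate_mask))
    if n == 0:
        raise ValueError("candidate mask is empty; overlap fraction undefined")
    inter = int(np.count_nonzero(candidate_mask & occupancy))
    return inter / n


def _rotate_sprite(sprite: SeedSprite, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate RGB+alpha with bilinear interpolation, expanding the raster."""
    rgba = np.dstack(
        [sprite.pixels, np.clip(sprite.alpha * 255.0, 0, 255).round().astype(np.uint8)]
    )
    rot = np.asarray(
        Image.fromarray(rgba, mode="RGBA").rotate(angle, expand=True, resample=Image.BILINEAR)
    )
    rgb = rot[..., :3].astype(np.float32)
    alpha = rot[..., 3].astype(np.float32) / 255.0
    # tighten to the alpha footprint to keep later per-paste work local
    nz_r = np.flatnonzero(alpha.max(axis=1) > 1e-3)
    nz_c = np.flatnonzero(alpha.max(axis=0) > 1e-3)
    if nz_r.size == 0:
        return rgb[:1, :1], alpha[:1, :1]
    sl = np.s_[nz_r[0] : nz_r[-1] + 1, nz_c[0] : nz_c[-1] + 1]
    return rgb[sl], alpha[sl]


def _blur_perimeter(alpha: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur alpha inside a 3-px band around the support boundary."""
    if sigma <= 0:
        return alpha
    support = alpha > 0.5
    band = ndimage.binary_dilation(support, iterations=3) & ~ndimage.binary_erosion(
        support, iterations=3, border_value=0
    )
    blurred = ndimage.gaussian_filter(alpha, sigma=sigma)
    out = alpha.copy()
    out[band] = blurred[band]
    return out


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def paste_sprite(
    state: _SceneState,
    sprite: SeedSprite,
    placement: PlacementSpec,
    blur_sigma: float = 1.0,
    *,
    _rotated: tuple[np.ndarray, np.ndarray] | None = None,
) -> int:
    """Alpha-composite a rotated sprite onto the scene state.

    The new instance's support overwrites earlier labels in the label map.
    Returns the instance id assigned to the paste.
    """
    rgb, alpha = _rotated if _rotated is not None else _rotate_sprite(sprite, placement.angle)
    alpha = _blur_perimeter(alpha, blur_sigma)
    h, w = alpha.shape
    H, W = state.label_map.shape
    x, y = placement.x, placement.y
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError("placement puts the rotated sprite outside the canvas")
    region = np.s_[y : y + h, x : x + w]
    a = alpha[..., None]
    state.image[region] = a * rgb + (1.0 - a) * state.image[region]
    support = alpha > 0.5
    inst_id = state.next_id
    state.next_id += 1
    lm = state.label_map[region]
    lm[support] = inst_id
    state.records.append(
        {
            "instance_id": inst_id,
            "cultivar": sprite.cultivar,
            "pasted_area_px": int(support.sum()),
        }
    )
    return inst_id


def _finalize(state: _SceneState, config: ComposeConfig, rng_seed: int) -> SyntheticScene:
    """Center-crop to the output size and materialize per-instance masks."""
    off = (config.canvas_size - config.out_size) // 2
    sl = np.s_[off : off + config.out_size, off : off + config.out_size]
    image = np.clip(np.rint(state.image[sl]), 0, 255).astype(np.uint8)
    label_map = state.label_map[sl].copy()
    instances = []
    for rec in state.records:
        mask = label_map == rec["instance_id"]
        if not mask.any():
            continue  # instance fell wholly in the cropped margin or was occluded away
        instances.append(
            SceneInstance(
                instance_id=rec["instance_id"],
                visible_mask=mask,
                bbox=_tight_bbox(mask),
                pasted_area_px=rec["pasted_area_px"],
                cultivar=rec["cultivar"],
                overlap_at_paste=rec.get("overlap", 0.0),
            )
        )
    return SyntheticScene(
        image=image, label_map=label_map, instances=instances, config=config, rng_seed=rng_seed
    )


def crop_borders(scene: SyntheticScene, out_size: int) -> SyntheticScene:
    """Center-crop a scene; drop instances that lose all visible pixels."""
    side = scene.label_map.shape[0]
    if out_size > side:
        raise ValueError("out_size must not exceed the current scene size")
    off = (side - out_size) // 2
    sl = np.s_[off : off + out_size, off : off + out_size]
    label_map = scene.label_map[sl].copy()
    instances = []
    for inst in scene.instances:
        mask = inst.visible_mask[sl]
        if not mask.any():
            continue
        instances.append(
            SceneInstance(
                instance_id=inst.instance_id,
                visible_mask=mask,
                bbox=_tight_bbox(mask),
                pasted_area_px=inst.pasted_area_px,
                cultivar=inst.cultivar,
                overlap_at_paste=inst.overlap_at_paste,
            )
        )
    cfg = dataclasses.replace(scene.config, out_size=out_size)
    return SyntheticScene(
        image=scene.image[sl].copy(),
        label_map=label_map,
        instances=instances,
        config=cfg,
        rng_seed=scene.rng_seed,
    )


def generate_scene(
    pool: SpritePool, config: ComposeConfig, rng: np.random.Generator
) -> SyntheticScene:
    """Compose one scene: background, randomized pastes, border crop."""
    config.validate()
    pool.validate()
    bg = pool.backgrounds[rng.integers(len(pool.backgrounds))]
    state = _SceneState(bg.pixels, config.canvas_size)
    occupancy = state.label_map  # >0 means seed pixel

    rotated: tuple[np.ndarray, np.ndarray] | None = None
    sprite: SeedSprite | None = None
    angle = 0.0
    overlaps: list[float] = []
    trial = 0
    while trial < config.max_trials:
        trial += 1
        if rotated is None:
            sprite = pool.sprites[rng.integers(len(pool.sprites))]
            angle = float(rng.uniform(0.0, 360.0))
            rotated = _rotate_sprite(sprite, angle)
        rgb, alpha = rotated
        h, w = alpha.shape
        if h > config.canvas_size or w > config.canvas_size:
            rotated = None  # sprite cannot fit at this rotation; redraw
            continue
        x = int(rng.integers(0, config.canvas_size - w + 1))
        y = int(rng.integers(0, config.canvas_size - h + 1))
        support = alpha > 0.5
        frac = overlap_fraction(support, occupancy[y : y + h, x : x + w] > 0)
        if frac > config.overlap_threshold:
            continue  # trial consumed; keep the rotated sprite, redraw position
        paste_sprite(
            state,
            sprite,
            PlacementSpec(angle=angle, x=x, y=y),
            config.blur_sigma,
            _rotated=rotated,
        )
        state.records[-1]["overlap"] = frac
        overlaps.append(frac)
        rotated = None

    assert all(f <= config.overlap_threshold for f in overlaps)
    return _finalize(state, config, config.rng_seed)


def generate_dataset(
    pool: SpritePool,
    config: ComposeConfig,
    n_images: int,
    rng_seed: int,
    out_dir: str | Path,
    write_coco_json: bool = True,
) -> dict:
    """Generate ``n_images`` (image PNG, 16-bit label-map PNG) pairs.

    Image ``i`` is composed from an RNG seeded by ``SeedSequence([rng_seed, i])``
    so any single image is reproducible in isolation.  Returns the manifest
    (also written to ``manifest.json``), listing images, sizes, config and the
    seed derivation.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)

    from . import dataset_io  # deferred: dataset_io imports nothing from here

    images = []
    annotations = []
    for i in range(n_images):
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, i]))
        cfg = dataclasses.replace(config, rng_seed=rng_seed)
        scene = generate_scene(pool, cfg, rng)
        name = f"img_{i:05d}.png"
        Image.fromarray(scene.image, mode="RGB").save(out / "images" / name)
        lab = scene.label_map.astype(np.uint16)
        Image.fromarray(lab).save(out / "labels" / f"lab_{i:05d}.png")
        images.append(
            {
                "id": i,
                "file_name": f"images/{name}",
                "width": scene.image.shape[1],
                "height": scene.image.shape[0],
            }
        )
        if write_coco_json:
            annotations.extend(dataset_io.annotations_for_scene(i, scene, len(annotations) + 1))

    manifest = {
        "images": images,
        "config": config.to_dict(),
        "rng_seed": rng_seed,
        "seed_derivation": "SeedSequence([rng_seed, image_id])",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if write_coco_json:
        doc = {
            "info": {"description": "seedsynth synthetic seed dataset"},
            "images": images,
            "annotations": annotations,
            "categories": [dataset_io.CATEGORY],
        }
        (out / "annotations.json").write_text(json.dumps(doc))
    return manifest
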