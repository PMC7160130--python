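"""COCO-format annotation I/O and the train/validation/test split.

Scenes are serialized as COCO 1.0 instance-segmentation JSON with a single
"seed" category.  Masks are stored as uncompressed run-length encodings
(column-major counts starting with the background run, the COCO convention),
so the files are plain text and readable by any COCO-aware tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .compose import SceneInstance, SyntheticScene, _tight_bbox

CATEGORY = {"id": 1, "name": "seed", "supercategory": "seed"}


def encode_rle(mask: np.ndarray) -> dict:
    """Encode a binary mask as COCO uncompressed RLE.

    Counts are run lengths down the columns (Fortran order), alternating
    background/foreground and starting with background.
    """
    flat = np.asarray(mask, dtype=np.uint8).ravel(order="F")
    changes = np.flatnonzero(np.diff(flat)) + 1
    boundaries = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(boundaries).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def decode_rle(rle: dict) -> np.ndarray:
    """Decode COCO uncompressed RLE back to a boolean mask."""
    h, w = rle["size"]
    counts = np.asarray(rle["counts"], dtype=np.int64)
    if counts.sum() != h * w:
        raise ValueError("RLE counts do not cover the mask size")
    vals = np.zeros(len(counts), dtype=np.uint8)
    vals[1::2] = 1
    flat = np.repeat(vals, counts)
    return flat.reshape((h, w), order="F").astype(bool)


def _annotation(image_id: int, ann_id: int, inst: SceneInstance) -> dict:
    x0, y0, x1, y1 = inst.bbox
    return {
        "id": ann_id,
        "image_id": image_id,
        "category_id": CATEGORY["id"],
        "segmentation": encode_rle(inst.visible_mask),
        "area": int(inst.visible_mask.sum()),
        "bbox": [x0, y0, x1 - x0, y1 - y0],
        "iscrowd": 0,
        "attributes": {"cultivar": inst.cultivar, "instance_id": inst.instance_id},
    }


def annotations_for_scene(image_id: int, scene: SyntheticScene, start_ann_id: int) -> list[dict]:
    """JSON-ready annotation records for one scene (RLE-encoded, compact)."""
    return [
        _annotation(image_id, start_ann_id + k, inst)
        for k, inst in enumerate(scene.instances)
    ]


def write_coco(scenes, path: str | Path) -> dict:
    """Write scenes as a COCO 1.0 instance-segmentation JSON.

    ``scenes`` is an iterable of ``(image_id, SyntheticScene)`` pairs or bare
    scenes (then numbered from 0).  Returns the document written.
    """
    images, annotations = [], []
    ann_id = 1
    for item in scenes:
        image_id, scene = item if isinstance(item, tuple) else (len(images), item)
        h, w = scene.label_map.shape
        images.append(
            {
                "id": image_id,
                "file_name": f"images/img_{image_id:05d}.png",
                "width": w,
                "height": h,
            }
        )
        for inst in scene.instances:
            annotations.append(_annotation(image_id, ann_id, inst))
            ann_id += 1
    doc = {
        "info": {"description": "seedsynth synthetic seed dataset"},
        "images": images,
        "annotations": annotations,
        "categories": [CATEGORY],
    }
    Path(path).write_text(json.dumps(doc))
    return doc


def read_coco(path: str | Path, validate: bool = True, image_ids=None) -> dict:
    """Read a COCO JSON and decode masks.

    Returns ``{"images": [...], "annotations": {image_id: [record, ...]}}``
    where each record carries ``mask`` (bool array), ``bbox`` (x0,y0,x1,y1
    half-open), ``area``, ``score`` (if present) and ``attributes``.

    With ``validate`` on, each annotation's decoded mask is checked against
    its stored area and its bbox against the image bounds and mask extent.
    ``image_ids`` restricts decoding to a subset of images: decoded masks of
    a large dataset can easily dwarf the PNGs they came from, so callers
    iterating a big file should decode per image.
    """
    doc = json.loads(Path(path).read_text())
    sizes = {im["id"]: (im["height"], im["width"]) for im in doc["images"]}
    wanted = set(image_ids) if image_ids is not None else None
    if wanted is not None:
        doc["images"] = [im for im in doc["images"] if im["id"] in wanted]
    out: dict[int, list[dict]] = {im["id"]: [] for im in doc["images"]}
    for ann in doc["annotations"]:
        img_id = ann["image_id"]
        if wanted is not None and img_id not in wanted:
            continue
        if img_id not in sizes:
            raise ValueError(f"annotation {ann['id']} references unknown image {img_id}")
        h, w = sizes[img_id]
        mask = decode_rle(ann["segmentation"])
        x, y, bw, bh = ann["bbox"]
        bbox = (int(x), int(y), int(x + bw), int(y + bh))
        if validate:
            if mask.shape != (h, w):
                raise ValueError(f"annotation {ann['id']}: mask size mismatch")
            area = int(mask.sum())
            if area == 0:
                raise ValueError(f"annotation {ann['id']}: zero-area segmentation")
            if area != ann["area"]:
                raise ValueError(
                    f"annotation {ann['id']}: stored area {ann['area']} != decoded {area}"
                )
            if bbox[0] < 0 or bbox[1] < 0 or bbox[2] > w or bbox[3] > h:
                raise ValueError(f"annotation {ann['id']}: bbox outside image bounds")
            tx0, ty0, tx1, ty1 = _tight_bbox(mask)
            if tx0 < bbox[0] or ty0 < bbox[1] or tx1 > bbox[2] or ty1 > bbox[3]:
                raise ValueError(f"annotation {ann['id']}: bbox does not enclose mask")
        out[img_id].append(
            {
                "id": ann["id"],
                "mask": mask,
                "bbox": bbox,
                "area": ann["area"],
                "score": ann.get("score"),
                "attributes": ann.get("attributes", {}),
            }
        )
    return {"images": doc["images"], "annotations": out}


def split_dataset(
    manifest: dict, counts: tuple[int, int, int], rng_seed: int
) -> dict:
    """Partition manifest images into train/val/test by a seeded shuffle.

    ``counts`` must sum to the number of images (the reference configuration
    splits 1200 synthetic pairs as 989 train / 11 validation / 200 test).
    Returns the manifest with a ``splits`` mapping added.
    """
    ids = [im["id"] for im in manifest["images"]]
    if sum(counts) != len(ids):
        raise ValueError(
            f"split counts {counts} sum to {sum(counts)}, but there are {len(ids)} images"
        )
    rng = np.random.default_rng(rng_seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_tr, n_va, n_te = counts
    splits = {
        "train": sorted(order[:n_tr]),
        "val": sorted(order[n_tr : n_tr + n_va]),
        "test": sorted(order[n_tr + n_va :]),
    }
    out = dict(manifest)
    out["splits"] = splits
    out["split_rng_seed"] = rng_seed
    return out
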