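"""Selection of isolated seeds before morphometry.

Instance-segmentation output contains seeds cut off at the image border and
seeds partly hidden by neighbours; measuring those would bias every shape
trait.  The cascade removes, in order:

1. *margin*: instances whose bounding box protrudes into a 5-px border band;
2. *solidity*: survivors below the population's lower-quartile solidity
   (occluded fragments are ragged, so their solidity collapses);
3. *length-to-width ratio (LWR)*: survivors outside the population's 5%/95%
   quantiles.

Quantile thresholds are recomputed on the survivors of the previous stage,
per population (one cultivar per image in the intended use), using the
linear-interpolation (type-7) quantile.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class FilterConfig:
    margin: int = 5
    solidity_lower_q: float = 0.25
    lwr_lower_q: float = 0.05
    lwr_upper_q: float = 0.95

    def validate(self) -> None:
        qs = (self.solidity_lower_q, self.lwr_lower_q, self.lwr_upper_q)
        if any(not 0.0 <= q <= 1.0 for q in qs):
            raise ValueError("quantiles must be in [0, 1]")
        if self.lwr_lower_q >= self.lwr_upper_q:
            raise ValueError("LWR lower quantile must be below the upper quantile")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclasses.dataclass
class FilterReport:
    kept: list
    removed: dict  # instance id -> "margin" | "solidity" | "lwr"
    thresholds: dict  # stage -> threshold value(s)


def margin_filter(
    bboxes: dict, image_size: tuple[int, int], margin: int
) -> tuple[list, list]:
    """Split ids into (kept, removed): removed iff the bbox enters the margin band.

    ``bboxes`` maps instance id -> (x0, y0, x1, y1) half-open; ``image_size``
    is (width, height).
    """
    w, h = image_size
    if margin >= min(w, h) / 2:
        raise ValueError("margin must be smaller than half the image side")
    kept, removed = [], []
    for iid, (x0, y0, x1, y1) in bboxes.items():
        if x0 < margin or y0 < margin or x1 > w - margin or y1 > h - margin:
            removed.append(iid)
        else:
            kept.append(iid)
    return kept, removed


def quantile_filter(
    values: dict,
    lower_q: float | None = None,
    upper_q: float | None = None,
) -> tuple[list, list, tuple[float | None, float | None]]:
    """Remove ids whose value lies strictly outside the population quantiles.

    Thresholds come from the type-7 (linear interpolation) quantile of the
    input values themselves; returns (kept, removed, (lo, hi)).
    """
    if not values:
        raise ValueError("no values to filter")
    ids = list(values)
    arr = np.asarray([values[i] for i in ids], dtype=float)
    lo = float(np.quantile(arr, lower_q)) if lower_q is not None else None
    hi = float(np.quantile(arr, upper_q)) if upper_q is not None else None
    kept, removed = [], []
    for iid, v in zip(ids, arr):
        out = (lo is not None and v < lo) or (hi is not None and v > hi)
        (removed if out else kept).append(iid)
    return kept, removed, (lo, hi)


def apply_filters(
    instances: dict,
    image_size: tuple[int, int],
    config: FilterConfig | None = None,
) -> FilterReport:
    """Run the margin -> solidity -> LWR cascade on one population.

    ``instances`` maps instance id to a record with ``bbox`` (half-open),
    ``solidity`` and ``lwr`` (precomputed, e.g. by
    :func:`seedsynth.morpho.compute_descriptors`).  Each stage's quantile
    thresholds are computed over the survivors of the previous stage.
    """
    config = config or FilterConfig()
    config.validate()
    removed: dict = {}
    thresholds: dict = {}

    bboxes = {i: rec["bbox"] for i, rec in instances.items()}
    kept, out = margin_filter(bboxes, image_size, config.margin)
    removed.update({i: "margin" for i in out})

    if kept:
        sol = {i: instances[i]["solidity"] for i in kept}
        kept, out, (lo, _) = quantile_filter(sol, lower_q=config.solidity_lower_q)
        removed.update({i: "solidity" for i in out})
        thresholds["solidity_lower"] = lo

    if kept:
        lwr = {i: instances[i]["lwr"] for i in kept}
        kept, out, (lo, hi) = quantile_filter(
            lwr, lower_q=config.lwr_lower_q, upper_q=config.lwr_upper_q
        )
        removed.update({i: "lwr" for i in out})
        thresholds["lwr_lower"] = lo
        thresholds["lwr_upper"] = hi

    return FilterReport(kept=kept, removed=removed, thresholds=thresholds)
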