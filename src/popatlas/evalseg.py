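"""Segmentation similarity metrics and per-region statistics.

Per-region agreement is the Dice coefficient

    DC_r = 2 |A_r ∩ B_r| / (|A_r| + |B_r|),

and global matching is its label-aggregated form, summing intersections and
sizes over all non-background regions before dividing (background would
inflate agreement and is excluded; a per-region-mean variant is available
for sensitivity analysis).  The confusion matrix row r gives the percentage
of reference-region-r voxels assigned to each region (background included
as its own row and column); non-empty rows sum to 100.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volio import LabelMap, RegionTable, Volume

__all__ = [
    "EvalReport",
    "dice",
    "global_index",
    "confusion_matrix",
    "evaluate",
    "merge_bilateral",
    "merge_bilateral_table",
    "region_statistics",
    "plot_confusion",
]


@dataclass
class EvalReport:
    """Bundle of similarity metrics between two parcellations."""

    per_region_dice: dict
    global_index: float
    confusion: pd.DataFrame
    voxel_counts: dict

    def to_json(self, path=None):
        obj = {
            "per_region_dice": {str(k): float(v) for k, v in self.per_region_dice.items()},
            "global_index": float(self.global_index),
            "voxel_counts": {str(k): int(v) for k, v in self.voxel_counts.items()},
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    def save(self, json_path, confusion_tsv_path=None):
        self.to_json(json_path)
        if confusion_tsv_path is not None:
            self.confusion.to_csv(confusion_tsv_path, sep="\t")


def _check_shapes(a: LabelMap, b: LabelMap):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: LabelMap, b: LabelMap, r: int) -> float:
    """Dice coefficient of region r between two label maps.

    1 when the region is empty in both maps, 0 when empty in exactly one.
    """
    _check_shapes(a, b)
    in_a = a.labels == r
    in_b = b.labels == r
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((in_a & in_b).sum()) / (na + nb)


def global_index(a: LabelMap, b: LabelMap, variant: str = "aggregated") -> float:
    """Global matching index between two parcellations.

    ``variant="aggregated"`` (default): 2 Σ_r |A_r ∩ B_r| / Σ_r (|A_r| +
    |B_r|) over non-background regions — 1 for identical maps, 0 when no
    region overlaps anywhere.  ``variant="mean"``: unweighted mean of the
    per-region Dice values, for sensitivity analysis.
    """
    _check_shapes(a, b)
    ids = a.regions.ids
    if variant == "mean":
        return float(np.mean([dice(a, b, int(r)) for r in ids]))
    if variant != "aggregated":
        raise ValueError(f"unknown variant {variant!r}")
    inter = 0
    total = 0
    for r in ids:
        in_a = a.labels == r
        in_b = b.labels == r
        inter += int((in_a & in_b).sum())
        total += int(in_a.sum()) + int(in_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def confusion_matrix(reference: LabelMap, test: LabelMap) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent.

    ``C[r, s]`` is the percentage of voxels labeled r in the reference that
    the test map assigns to s.  Background (0) gets its own row and column.
    Empty reference regions yield an all-zero (undefined) row.
    """
    _check_shapes(reference, test)
    ids = [0] + [int(r) for r in reference.regions.ids]
    k = max(ids) + 1
    lut = np.full(k, -1, dtype=np.int64)
    for pos, r in enumerate(ids):
        lut[r] = pos
    ref = lut[reference.labels.ravel()]
    tst = lut[test.labels.ravel()]
    n = len(ids)
    counts = np.bincount(ref * n + tst, minlength=n * n).reshape(n, n).astype(float)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums[:, None] > 0, 100.0 * counts / row_sums[:, None], 0.0)
    return pd.DataFrame(pct, index=ids, columns=ids)


def evaluate(reference: LabelMap, test: LabelMap) -> EvalReport:
    """Full similarity report: per-region Dice, global index, confusion."""
    _check_shapes(reference, test)
    ids = [int(r) for r in reference.regions.ids]
    per_dice = {r: dice(reference, test, r) for r in ids}
    counts = {r: int((reference.labels == r).sum()) for r in ids}
    return EvalReport(
        per_region_dice=per_dice,
        global_index=global_index(reference, test),
        confusion=confusion_matrix(reference, test),
        voxel_counts=counts,
    )


def merge_bilateral_table(regions: RegionTable):
    """Collapse left/right pairs of the same structure into one region.

    Returns ``(merged_table, mapping)`` where ``mapping`` sends every old id
    to its merged id (the smaller of the pair).  Midline regions pass
    through; an unpaired left or right entry is kept as-is with a warning.
    """
    df = regions.table
    mapping: dict[int, int] = {}
    rows = []
    seen = set()
    for _, row in df.iterrows():
        rid = int(row["region_id"])
        if rid in seen:
            continue
        if row["hemisphere"] == "midline":
            mapping[rid] = rid
            rows.append((rid, row["name"], row["group"], "midline"))
            seen.add(rid)
            continue
        partner = df[
            (df["name"] == row["name"])
            & (df["group"] == row["group"])
            & (df["hemisphere"] != row["hemisphere"])
            & (df["hemisphere"] != "midline")
        ]
        if partner.empty:
            warnings.warn(
                f"region {row['name']!r} ({row['hemisphere']}) has no "
                "contralateral partner; kept as-is"
            )
            mapping[rid] = rid
            rows.append((rid, row["name"], row["group"], row["hemisphere"]))
            seen.add(rid)
            continue
        pid = int(partner["region_id"].iloc[0])
        new_id = min(rid, pid)
        mapping[rid] = new_id
        mapping[pid] = new_id
        rows.append((new_id, row["name"], row["group"], "midline"))
        seen.update({rid, pid})
    merged = RegionTable.from_rows(rows)
    return merged, mapping


def merge_bilateral(labels: LabelMap) -> LabelMap:
    """Relabel a map so left/right sides of each structure share one id."""
    merged, mapping = merge_bilateral_table(labels.regions)
    k = int(labels.regions.ids.max()) + 1
    lut = np.arange(k, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return LabelMap(lut[labels.labels], merged, labels.spacing, labels.origin)


def region_statistics(v: Volume, labels: LabelMap, normalize: bool = False) -> pd.DataFrame:
    """Per-region volume fraction and mean intensity.

    Volume fraction is the percentage of *labeled* voxels in each region.
    With ``normalize=True`` the mean intensity is divided by the mean over
    all labeled voxels, so relative values above 1 mean brighter than the
    brain average — the same normalization applies to FA or MD volumes
    passed in place of the structural image.
    """
    if v.shape != labels.shape:
        raise ValueError("volume and labels must share a grid")
    lab = labels.labels
    inside = lab > 0
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("no labeled voxels")
    brain_mean = float(v.data[inside].mean())
    rows = []
    for r in labels.regions.ids:
        sel = lab == r
        n = int(sel.sum())
        mean_i = float(v.data[sel].mean()) if n else float("nan")
        if normalize and n:
            mean_i /= brain_mean
        rows.append(
            {
                "region_id": int(r),
                "name": labels.regions.name_of(int(r)),
                "n_voxels": n,
                "volume_pct": 100.0 * n / n_inside,
                "mean_intensity": mean_i,
            }
        )
    return pd.DataFrame(rows)


def plot_confusion(confusion: pd.DataFrame, path) -> None:
    """Heat-map rendering of a confusion matrix (percent scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(confusion.to_numpy(), cmap="gray", vmin=0, vmax=100)
    ax.set_xlabel("assigned region")
    ax.set_ylabel("reference region")
    ax.set_xticks(range(len(confusion.columns)))
    ax.set_xticklabels(confusion.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(confusion.index)))
    ax.set_yticklabels(confusion.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="% of reference voxels")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
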