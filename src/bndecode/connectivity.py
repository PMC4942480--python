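"""Post-hoc summaries of selected voxels and learned connectivities:
Brodmann-area contribution tables, edge frequencies by BA pair, and the
distribution of edge lengths in millimetres."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import VoxelMeta


def _meta_by_id(meta: list[VoxelMeta]) -> dict[int, VoxelMeta]:
    return {m.voxel_id: m for m in meta}


def ba_contribution(
    selections: list[np.ndarray],
    meta: list[VoxelMeta],
    threshold_pct: float = 15.0,
) -> pd.DataFrame:
    """Mean per-fold percentage of selected voxels falling in each BA.

    Within each fold the BA contributions partition the selected set and
    sum to 100%; the table averages those per-fold percentages and flags
    BAs whose mean contribution exceeds ``threshold_pct`` (default 15%).
    Selections are voxel ids.
    """
    lookup = _meta_by_id(meta)
    per_fold: list[dict[str, float]] = []
    bas = sorted({m.ba for m in meta})
    for sel in selections:
        sel = np.asarray(sel)
        missing = [int(v) for v in sel if int(v) not in lookup]
        if missing:
            raise ValueError(f"selected voxel ids without metadata: {missing}")
        counts = Counter(lookup[int(v)].ba for v in sel)
        per_fold.append({ba: 100.0 * counts.get(ba, 0) / len(sel) for ba in bas})
    rows = []
    for ba in bas:
        mean_pct = float(np.mean([f[ba] for f in per_fold]))
        rows.append(
            {
                "ba": ba,
                "lobe": next(m.lobe for m in meta if m.ba == ba),
                "mean_contribution_pct": mean_pct,
                "above_threshold": mean_pct > threshold_pct,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "mean_contribution_pct", ascending=False, ignore_index=True
    )


def edge_ba_frequency(
    edges: list[tuple[int, int]],
    meta: list[VoxelMeta],
    threshold_pct: float = 5.0,
) -> pd.DataFrame:
    """Percentage of pooled edges per unordered BA pair.

    Edge direction is discarded; within-area pairs like {BA6, BA6} are
    counted.  Pairs with a frequency strictly above ``threshold_pct``
    (default 5%) are flagged.
    """
    lookup = _meta_by_id(meta)
    pair_counts: Counter = Counter()
    for a, b in edges:
        for v in (a, b):
            if int(v) not in lookup:
                raise ValueError(f"edge endpoint voxel {v} has no metadata")
        pair = tuple(sorted((lookup[int(a)].ba, lookup[int(b)].ba)))
        pair_counts[pair] += 1
    total = sum(pair_counts.values())
    rows = [
        {
            "ba_a": pair[0],
            "ba_b": pair[1],
            "count": count,
            "pct": 100.0 * count / total,
            "above_threshold": 100.0 * count / total > threshold_pct,
        }
        for pair, count in pair_counts.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["count", "ba_a", "ba_b"], ascending=[False, True, True], ignore_index=True
    )


def edge_distances(edges: list[tuple[int, int]], meta: list[VoxelMeta]) -> np.ndarray:
    """Euclidean endpoint distance (mm) of every edge."""
    lookup = _meta_by_id(meta)
    out = np.empty(len(edges))
    for i, (a, b) in enumerate(edges):
        for v in (a, b):
            if int(v) not in lookup:
                raise ValueError(f"edge endpoint voxel {v} has no metadata")
        ca = np.asarray(lookup[int(a)].coord)
        cb = np.asarray(lookup[int(b)].coord)
        out[i] = np.linalg.norm(ca - cb)
    return out


def edge_distance_distribution(
    edges: list[tuple[int, int]],
    meta: list[VoxelMeta],
    bin_width_mm: float = 10.0,
    range_mm: tuple[float, float] = (0.0, 80.0),
) -> pd.DataFrame:
    """Histogram of edge lengths over ``range_mm`` as percentages of all
    edges.  Bins are half-open [lo, lo + width) with the final in-range bin
    closed; edges beyond the range land in an overflow bin."""
    d = edge_distances(edges, meta)
    lo, hi = range_mm
    edges_mm = np.arange(lo, hi + bin_width_mm / 2, bin_width_mm)
    rows = []
    for b_lo, b_hi in zip(edges_mm[:-1], edges_mm[1:]):
        last = b_hi >= hi
        mask = (d >= b_lo) & ((d <= b_hi) if last else (d < b_hi))
        rows.append({"bin_lo": b_lo, "bin_hi": b_hi, "count": int(mask.sum())})
    overflow = int(np.sum(d > hi) + np.sum(d < lo))
    rows.append({"bin_lo": hi, "bin_hi": np.inf, "count": overflow})
    df = pd.DataFrame(rows)
    total = max(len(d), 1)
    df["pct"] = 100.0 * df["count"] / total
    return df


@dataclass
class EdgeSummary:
    """Bundled BA-pair frequencies and distance histogram for one edge pool."""

    ba_pairs: pd.DataFrame
    distance_histogram: pd.DataFrame
    total_edges: int

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[int, int]],
        meta: list[VoxelMeta],
        pair_threshold_pct: float = 5.0,
        bin_width_mm: float = 10.0,
        range_mm: tuple[float, float] = (0.0, 80.0),
    ) -> "EdgeSummary":
        return cls(
            ba_pairs=edge_ba_frequency(edges, meta, pair_threshold_pct),
            distance_histogram=edge_distance_distribution(
                edges, meta, bin_width_mm, range_mm
            ),
            total_edges=len(edges),
        )
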