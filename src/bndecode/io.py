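"""Readers and writers for the pipeline's interchange formats.

TSV is the canonical format (headers mandatory, UTF-8, "." decimal):
trial matrices, voxel metadata, event tables (FSL-style 3 columns),
CV reports, selections, edge lists.  Models and configs serialize to
JSON.  NIfTI mask reading is optional and isolated so the core runs
with no imaging dependency.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TrialMatrix, VoxelMeta
from .synth import EventTable, GenerativeModel

FLOAT_FMT = "%.17g"  # round-trip exact for float64


# ---------------------------------------------------------------------------
# voxel metadata


def write_voxel_meta(meta: list[VoxelMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "voxel_id": m.voxel_id,
                "x": m.coord[0],
                "y": m.coord[1],
                "z": m.coord[2],
                "ba": m.ba,
                "lobe": m.lobe,
            }
            for m in meta
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_voxel_meta(path: str | Path) -> list[VoxelMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"voxel_id", "x", "y", "z", "ba", "lobe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"voxel metadata missing columns: {sorted(missing)}")
    return [
        VoxelMeta(int(r.voxel_id), (float(r.x), float(r.y), float(r.z)), str(r.ba), str(r.lobe))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# trial matrices


def write_trial_matrix(tm: TrialMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    """TSV with a ``label`` column followed by one column per voxel id."""
    cols = [str(v) for v in tm.voxel_ids()]
    df = pd.DataFrame(tm.values, columns=cols)
    df.insert(0, "label", tm.labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if meta_path is not None and tm.voxel_meta:
        write_voxel_meta(tm.voxel_meta, meta_path)


def read_trial_matrix(path: str | Path, meta_path: str | Path | None = None) -> TrialMatrix:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    values = df.drop(columns="label")
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
    meta: list[VoxelMeta] = []
    if meta_path is not None:
        meta_all = {m.voxel_id: m for m in read_voxel_meta(meta_path)}
        meta = []
        for col in values.columns:
            vid = int(col)
            if vid not in meta_all:
                raise ValueError(f"{path}: voxel {vid} absent from metadata {meta_path}")
            meta.append(meta_all[vid])
    return TrialMatrix(values.to_numpy(dtype=float), df["label"].to_numpy(), meta)


# ---------------------------------------------------------------------------
# events


def write_events(events: EventTable, path: str | Path) -> None:
    """FSL-style 3-column text: onset, duration, condition."""
    with open(path, "w") as fh:
        for onset, dur, cond in zip(events.onsets, events.durations, events.conditions):
            fh.write(f"{onset:g}\t{dur:g}\t{cond}\n")


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["onset", "duration", "condition"])
    return EventTable(df["onset"].to_numpy(), df["duration"].to_numpy(), df["condition"].to_numpy())


# ---------------------------------------------------------------------------
# models


def write_generative_model(model: GenerativeModel, path: str | Path) -> None:
    payload = {
        "n_classes": model.n_classes,
        "class_means": model.class_means.tolist(),
        "edges": [list(e) for e in model.edges],
        "edge_weights": {
            f"{p}->{c}": (np.asarray(w).tolist()) for (p, c), w in model.edge_weights.items()
        },
        "noise_sd": np.asarray(model.noise_sd).tolist(),
        "locality_scale": model.locality_scale,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_generative_model(path: str | Path) -> GenerativeModel:
    payload = json.loads(Path(path).read_text())
    weights = {}
    for key, w in payload["edge_weights"].items():
        p, c = key.split("->")
        w = np.asarray(w)
        weights[(int(p), int(c))] = float(w) if w.ndim == 0 else w
    return GenerativeModel(
        n_classes=payload["n_classes"],
        class_means=np.asarray(payload["class_means"]),
        edges=tuple(tuple(e) for e in payload["edges"]),
        edge_weights=weights,
        noise_sd=np.asarray(payload["noise_sd"]) if isinstance(payload["noise_sd"], list) else payload["noise_sd"],
        locality_scale=payload["locality_scale"],
    )


def write_edge_list(edges: list[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["parent_id", "child_id"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(r.parent_id), int(r.child_id)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# NIfTI masks (optional)


def read_mask_labels(
    mask_paths: dict[str, str | Path],
    lobes: dict[str, str] | None = None,
) -> list[VoxelMeta]:
    """Build voxel metadata from NIfTI label masks.

    ``mask_paths`` maps a BA label to a mask file; nonzero voxels belong to
    the mask.  World coordinates come from the (shared) affine.  Voxels in
    several masks go to the first-listed mask, with a warning.  Requires
    nibabel.
    """
    import nibabel as nib  # optional dependency, imported lazily

    from .synth import BA_LOBE

    lobes = lobes or BA_LOBE
    affine = None
    claimed: dict[tuple[int, int, int], str] = {}
    order: list[tuple[str, tuple[int, int, int]]] = []
    for ba, p in mask_paths.items():
        img = nib.load(str(p))
        if affine is None:
            affine = img.affine
        elif not np.allclose(img.affine, affine):
            raise ValueError(f"mask {p} affine differs from the first mask's affine")
        data = np.asanyarray(img.dataobj)
        idx = np.argwhere(data != 0)
        if len(idx) == 0:
            warnings.warn(f"mask {p} for {ba} is empty", stacklevel=2)
        for ijk in idx:
            key = tuple(int(v) for v in ijk)
            if key in claimed:
                warnings.warn(
                    f"voxel {key} in both {claimed[key]} and {ba}; keeping {claimed[key]}",
                    stacklevel=2,
                )
                continue
            claimed[key] = ba
            order.append((ba, key))
    meta = []
    for vid, (ba, ijk) in enumerate(order):
        world = affine @ np.array([*ijk, 1.0])
        meta.append(VoxelMeta(vid, tuple(world[:3]), ba, lobes.get(ba, "frontal")))
    return meta
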