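"""Readers and writers for the pipeline's plain-text and TIFF formats.

Tables travel as TSV (expression, atlas) or CSV (recordings, assay counts,
scores); image stacks as TIFF; ground truth and lawn geometry as JSON
sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic_data import ImageStack, LawnGeometry, Recording


# -- expression / atlas ------------------------------------------------------

def write_expression_tsv(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "family", "condition", "replicate", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression TSV missing columns {sorted(missing)}")
    return df


def write_atlas_tsv(atlas: pd.DataFrame, path):
    """Atlas as long TSV: neuron, gene_id, expressed in {0, 1}."""
    long = atlas.stack().rename("expressed").reset_index()
    long.columns = ["neuron", "gene_id", "expressed"]
    long.to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    required = {"neuron", "gene_id", "expressed"}
    if not required <= set(long.columns):
        raise ValueError(f"atlas TSV needs columns {sorted(required)}")
    return long.pivot(index="neuron", columns="gene_id", values="expressed").astype(int)


# -- image stacks ------------------------------------------------------------

def write_stack_tiff(stack: ImageStack, path):
    tifffile.imwrite(path, stack.intensities.astype(np.float32),
                     photometric="minisblack")


def read_stack_tiff(path, pixel_size: float = 0.3, z_step: float = 0.5) -> ImageStack:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(arr.astype(float), pixel_size=pixel_size, z_step=z_step)


# -- recordings --------------------------------------------------------------

def write_recording_csv(rec: Recording, path, lawn_path=None):
    cols = {"time_s": rec.time, "f_neuron": rec.f_neuron,
            "f_background": rec.f_background}
    if rec.position is not None:
        cols["x_mm"] = rec.position[:, 0]
        cols["y_mm"] = rec.position[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)
    if lawn_path is not None and rec.lawn is not None:
        write_lawn_json(rec.lawn, lawn_path)


def read_recording_csv(path, lawn: LawnGeometry | None = None) -> Recording:
    df = pd.read_csv(path)
    required = {"time_s", "f_neuron", "f_background"}
    if not required <= set(df.columns):
        raise ValueError(f"recording CSV needs columns {sorted(required)}")
    pos = None
    if {"x_mm", "y_mm"} <= set(df.columns):
        pos = df[["x_mm", "y_mm"]].to_numpy()
    return Recording(df["time_s"].to_numpy(), df["f_neuron"].to_numpy(),
                     df["f_background"].to_numpy(), position=pos, lawn=lawn)


def write_lawn_json(lawn: LawnGeometry, path):
    with open(path, "w") as fh:
        json.dump({"center": list(lawn.center), "radius": lawn.radius}, fh)


def read_lawn_json(path) -> LawnGeometry:
    with open(path) as fh:
        d = json.load(fh)
    return LawnGeometry(center=tuple(d["center"]), radius=float(d["radius"]))


# -- assay counts / tracks ---------------------------------------------------

def write_counts_csv(counts: pd.DataFrame, path):
    counts.to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "x_mm", "y_mm"}
    if not required <= set(df.columns):
        raise ValueError(f"track CSV needs columns {sorted(required)}")
    return df


# -- truth sidecars ----------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_truth_json(truth, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2, sort_keys=True)
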