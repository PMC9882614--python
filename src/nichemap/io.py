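"""Readers and writers for the on-disk interchange formats.

Label masks are 16-bit multi-page TIFFs (one page per tissue region),
intensity stacks are multi-channel TIFFs, cell tables and count tables
are CSV, ground truth and meta-analysis results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth

__all__ = [
    "write_mask", "read_mask",
    "write_stack", "read_stack",
    "write_cells", "read_cells",
    "write_ground_truth",
]


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_stack(path, stack: np.ndarray, channel_names=None) -> None:
    meta = {"channel_names": list(channel_names)} if channel_names else None
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     metadata=meta)


def read_stack(path) -> tuple[np.ndarray, list[str] | None]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata
    names = None
    if meta and "channel_names" in meta[0]:
        names = list(meta[0]["channel_names"])
    if arr.ndim == 3:
        arr = arr[None]
    return arr, names


def write_cells(path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))
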