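"""Readers and writers for the shared file formats.

Cell tables are CSV in the shared schema (see :mod:`furrow.core`); images
and label masks are TIFF; fits, calibrations and manifests are JSON.  The
reader is tolerant: extra columns are preserved verbatim; missing required
columns or unknown cell types are errors naming the column and row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from furrow.core import CELL_TABLE_COLUMNS, DiscSample, SchemaError, validate_cell_table


def write_cell_table(sample: Union[DiscSample, pd.DataFrame], path) -> None:
    df = sample.cells if isinstance(sample, DiscSample) else sample
    validate_cell_table(df)
    ordered = [c for c in CELL_TABLE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in CELL_TABLE_COLUMNS]
    df[ordered + extra].to_csv(path, index=False)


def read_cell_table(path) -> DiscSample:
    df = pd.read_csv(path)
    validate_cell_table(df)  # raises SchemaError naming column/row
    disc_ids = df["disc_id"].unique()
    disc_id = str(disc_ids[0]) if len(disc_ids) == 1 else "multi"
    return DiscSample(disc_id=disc_id, cells=df)


def write_image(image: np.ndarray, path) -> None:
    """Multi-page TIFF, one page per channel."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
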