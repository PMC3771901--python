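"""Tab-separated table and mask I/O.

All tables are headered TSV so every stage can be run, inspected and
re-entered independently.  Boolean columns are stored as 0/1 to survive
the round trip unambiguously.  Masks are 8-bit PNG/TIFF images with label
values {0 excluded, 1 cytoplasm, 2 mitochondrion}.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

BOOL_COLUMNS = frozenset({
    "is_decoy", "is_labeled", "is_false_target", "covered",
    "is_differential_lof", "is_differential_hof",
    "criterion1_met", "criterion2_met", "excluded_as_contaminant",
    "all_filtered", "degenerate_variance", "concordant",
})


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    out = df.copy()
    for col in out.columns.intersection(BOOL_COLUMNS):
        out[col] = out[col].astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    for col in df.columns.intersection(BOOL_COLUMNS):
        df[col] = df[col].astype(int).astype(bool)
    return df


def write_mask(mask: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    mask = np.asarray(iio.imread(path))
    if mask.ndim == 3:  # collapse redundant color planes
        mask = mask[..., 0]
    return mask.astype(np.uint8)
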