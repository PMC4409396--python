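"""Localization-table CSV input/output.

Localization tables are plain UTF-8 CSV with a header row and named
columns (ThunderSTORM-style): ``frame`` (0-based integer), ``x_nm``,
``y_nm`` (decimal nm), ``photons``, and optionally ``sigma_nm``,
``track_id`` and ``emitter_id``.  Columns are identified by name, never by
position.  Rows with non-finite coordinates, negative photon counts or
negative frames are rejected on read, with the rejection count logged and
stored in ``df.attrs["n_rejected"]``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("palmquant")

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "photons")
OPTIONAL_COLUMNS = ("sigma_nm", "track_id", "emitter_id")


class LocalizationFormatError(ValueError):
    """Raised when a localization table is missing a mandatory column."""


def read_localizations(path) -> pd.DataFrame:
    """Read and validate a localization CSV.

    Returns a DataFrame with the mandatory columns plus any recognized
    optional ones; an empty file yields an empty table.  Invalid rows are
    dropped and counted in ``df.attrs["n_rejected"]``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise LocalizationFormatError(f"{path}: missing mandatory column '{col}'")
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep]
    n0 = len(df)
    valid = (
        np.isfinite(df["x_nm"].to_numpy(dtype=float))
        & np.isfinite(df["y_nm"].to_numpy(dtype=float))
        & (df["photons"].to_numpy(dtype=float) >= 0)
        & (df["frame"].to_numpy(dtype=float) >= 0)
    )
    df = df[valid].reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    n_rejected = n0 - len(df)
    if n_rejected:
        logger.warning("%s: rejected %d invalid rows", path, n_rejected)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write a localization table as CSV (header, no index)."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_ground_truth(truth, path) -> None:
    """Write an emitter ground-truth sidecar CSV (emitter_id, x_nm, y_nm, cluster_id)."""
    truth.to_frame().to_csv(path, index=False)
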