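"""Sample tables of δ³⁴S observations.

A sample table is a pandas DataFrame with one row per measurement:

====================  =======================================================
column                meaning
====================  =======================================================
``site_id``           groups replicate measurements from one location
``lat``, ``lon``      WGS84 degrees of the site
``tissue``            ``"foliar"`` or ``"moth"``
``species``           free-text taxon tag
``d34S``              δ³⁴S in ‰ on the VCDT scale
``n_replicates``      replicate count behind the row's value
====================  =======================================================

Extra columns are preserved by all operations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "TISSUES", "validate_samples", "read_samples", "write_samples"]

REQUIRED_COLUMNS = ("site_id", "lat", "lon", "tissue", "species", "d34S", "n_replicates")
TISSUES = ("foliar", "moth")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and values of a sample table; returns the table.

    Raises ``ValueError`` naming the offending column or rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing required column(s): {', '.join(missing)}")
    bad_tissue = set(df["tissue"].unique()) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue value(s): {sorted(bad_tissue)} (expected {TISSUES})")
    for col in ("lat", "lon", "d34S"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)]
        if len(bad):
            raise ValueError(f"non-finite {col} in row(s) {list(bad[:5])}")
    if (np.abs(df["lat"]) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-table CSV."""
    df = pd.read_csv(path)
    return validate_samples(df)


def write_samples(df: pd.DataFrame, path: str | Path) -> Path:
    """Validate and write a sample table as CSV."""
    validate_samples(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
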