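"""Study-table I/O.

Two strict CSV schemas are recognized (header required, UTF-8):

- g-level:      study_id, g, n1, n2
- raw-summary:  study_id, mean1, sd1, n1, mean2, sd2, n2

Column sets must match exactly — no positional guessing — because a silent
misread is the worst failure mode for meta-analytic inputs. Raw-summary
rows are converted to Hedges' g on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .effect_size import hedges_g
from .estimators import MetaSample
from .exceptions import SchemaError

__all__ = ["read_study_table", "write_study_table", "G_SCHEMA", "RAW_SCHEMA"]

G_SCHEMA = ("study_id", "g", "n1", "n2")
RAW_SCHEMA = ("study_id", "mean1", "sd1", "n1", "mean2", "sd2", "n2")


def _check_numeric(df: pd.DataFrame, col: str, integer: bool = False):
    parsed = pd.to_numeric(df[col], errors="coerce")
    bad = parsed.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise SchemaError(f"column {col!r}: unparseable value at file row {row}")
    if integer and not np.allclose(parsed, parsed.round()):
        raise SchemaError(f"column {col!r} must contain integers")
    if integer:
        return parsed.round().astype(int)
    # strtod via float(): correctly-rounded, unlike pandas' fast parser
    return pd.Series([float(v) for v in df[col]], index=df.index)


def read_study_table(path) -> MetaSample:
    """Read a study table (either schema) into a :class:`MetaSample`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = set(df.columns)
    if cols == set(G_SCHEMA):
        g = _check_numeric(df, "g")
    elif cols == set(RAW_SCHEMA):
        g = None
    else:
        missing_g = set(G_SCHEMA) - cols
        missing_raw = set(RAW_SCHEMA) - cols
        extra = cols - set(RAW_SCHEMA) - set(G_SCHEMA)
        raise SchemaError(
            f"unrecognized column set in {path.name}: "
            f"missing {sorted(missing_g)} for the g schema or "
            f"{sorted(missing_raw)} for the raw-summary schema; "
            f"unexpected columns {sorted(extra)}"
        )
    n1 = _check_numeric(df, "n1", integer=True)
    n2 = _check_numeric(df, "n2", integer=True)
    ids = df["study_id"].astype(str).tolist()
    if g is None:
        g = hedges_g(
            _check_numeric(df, "mean1").to_numpy(),
            _check_numeric(df, "mean2").to_numpy(),
            _check_numeric(df, "sd1").to_numpy(),
            _check_numeric(df, "sd2").to_numpy(),
            n1.to_numpy(),
            n2.to_numpy(),
        )
    else:
        g = g.to_numpy()
    return MetaSample(g=g, n1=n1.to_numpy(), n2=n2.to_numpy(), study_ids=ids)


def write_study_table(sample: MetaSample, path) -> None:
    """Write a :class:`MetaSample` as a g-schema CSV (full precision)."""
    # pandas' default float repr is shortest-round-trip, i.e. exact
    sample.to_dataframe().to_csv(path, index=False)
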