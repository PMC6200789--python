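"""Trial-table CSV I/O and run configuration loading.

Trial tables are written as plain CSV with a one-line header and the fixed
column order ``subject_id, session, block, trial, context, sample, correct,
produced, units, excluded_reason``.  ``excluded_reason`` is empty for
included trials.  Round-trips are lossless (full float precision).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "load_config_file"]

_NUMERIC = {"session": int, "block": int, "trial": int}
_FLOATS = ("sample", "correct", "produced")


def write_trials(table: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s): {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"subject_id": "string", "context": "string", "units": "string",
               "excluded_reason": "string"},
        keep_default_na=True,
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing required column(s): {missing}")
    for col, typ in _NUMERIC.items():
        df[col] = df[col].astype(typ)
    for col in _FLOATS:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() and not df[col].isna().any():
            raise ValueError(f"column {col!r} contains non-numeric values")
        df[col] = bad.astype(float)
    if df["units"].nunique(dropna=True) > 1:
        raise ValueError(
            f"column 'units' mixes units within one table: {sorted(df['units'].dropna().unique())}"
        )
    return df[TRIAL_COLUMNS]


def load_config_file(path) -> dict:
    """Parse a YAML run-configuration file into a plain dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return cfg
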