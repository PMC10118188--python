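"""Long-format observation tables and pooling helpers.

The canonical analysis input is a long-format table with one row per
measurement: columns ``site, group, period, year, replicate, attribute,
value``.  ``period`` is ``"pre"`` or ``"post"``.  All downstream analyses
operate either on these replicate-level records or on site-year means
(replicates averaged within a site x year x attribute cell), which is the
default analysis unit to avoid pseudo-replication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

OBSERVATION_COLUMNS = ["site", "group", "period", "year", "replicate", "attribute", "value"]

PERIODS = ("pre", "post")


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table, returning it unchanged.

    Raises ``ValueError`` on missing columns, missing group labels,
    unknown period labels, or non-finite values.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if df["group"].isna().any():
        raise ValueError("observation table has missing group labels")
    bad_period = set(df["period"].unique()) - set(PERIODS)
    if bad_period:
        raise ValueError(f"unknown period labels: {sorted(bad_period)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("observation table contains non-finite values")
    return df


def site_year_means(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicates within each site x year x attribute cell.

    Returns a table with one row per site-year-attribute and the same
    columns except ``replicate``.
    """
    keys = ["site", "group", "period", "year", "attribute"]
    out = df.groupby(keys, as_index=False, sort=False)["value"].mean()
    return out


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path) -> None:
    validate_observations(df)
    df.to_csv(path, index=False)
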