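"""Measurement-table CSV reading/writing with validation.

The long format has one record per subject x occasion x outcome:
``subject,group,age0,occasion,outcome,value`` with occasions in years
(0 = baseline, 10 = follow-up; other values are accepted with a warning
and treated as continuous time), missing values as empty fields, UTF-8,
comma separator and ``.`` decimals.  Lines starting with ``#`` are header
comments (the pipeline stamps a config hash and seed there).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lmm import GROUP_LESS, GROUP_WELL

__all__ = ["read_measurements", "write_measurements", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("subject", "group", "age0", "occasion", "outcome", "value")

_VALID_GROUPS = {GROUP_WELL, GROUP_LESS}


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Check table structure; raise with offending rows/keys named."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    bad_groups = set(table["group"].unique()) - _VALID_GROUPS
    if bad_groups:
        raise ValueError(
            f"unknown group labels {sorted(bad_groups)}; expected {sorted(_VALID_GROUPS)}"
        )
    dup = table.duplicated(["subject", "occasion", "outcome"], keep=False)
    if dup.any():
        keys = (
            table.loc[dup, ["subject", "occasion", "outcome"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"duplicate subject x occasion x outcome records: {keys[:5]}")
    n_groups = table.groupby("subject")["group"].nunique()
    varying = n_groups[n_groups > 1].index.tolist()
    if varying:
        raise ValueError(f"group changes within subject(s): {varying[:5]}")
    no_baseline = sorted(
        set(table["subject"]) - set(table.loc[table["occasion"] == 0, "subject"])
    )
    if no_baseline:
        raise ValueError(f"subject(s) without a baseline occasion: {no_baseline[:5]}")
    odd = sorted(set(np.unique(table["occasion"])) - {0, 10})
    if odd:
        warnings.warn(
            f"non-standard occasion values {odd}: treated as continuous time "
            "in years (change estimates remain per decade)",
            stacklevel=2,
        )
    return table


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV."""
    table = pd.read_csv(
        path,
        comment="#",
        dtype={"subject": str, "group": str, "outcome": str},
        float_precision="round_trip",
    )
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    table["age0"] = table["age0"].astype(float)
    table["occasion"] = table["occasion"].astype(int)
    table["value"] = table["value"].astype(float)
    return validate_measurements(table)


def _format_value(v: float) -> str:
    return "" if pd.isna(v) else repr(float(v))


def write_measurements(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a measurement table in canonical order (round-trips exactly)."""
    out = table.loc[:, list(REQUIRED_COLUMNS)].sort_values(
        ["subject", "occasion", "outcome"], kind="mergesort"
    )
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.subject},{row.group},{repr(float(row.age0))},"
                f"{int(row.occasion)},{row.outcome},{_format_value(row.value)}\n"
            )
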