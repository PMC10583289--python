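"""CSV and config I/O for field profiles.

Profile files are comma-separated UTF-8 with ``#`` comment lines and a
header row.  Offsets are reported as Omega/2pi in MHz with the convention
Omega = omega_S - omega (offset of the electronic resonance above the
microwave frequency); the sign convention of externally supplied data
should be checked against this, and the reader accepts a column mapping
for that purpose.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["ProfileIOError", "read_profile", "write_profile", "read_config"]

REQUIRED_COLUMNS = ("offset_MHz", "enhancement")


class ProfileIOError(ValueError):
    """Malformed profile file (missing columns, non-numeric cells, ...)."""


def read_profile(
    path,
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Read a field-profile CSV into a DataFrame.

    Requires columns ``offset_MHz`` and ``enhancement`` (after applying
    ``column_map``, a {file column -> canonical column} renaming).  An
    optional ``weight`` column is passed through.  Comment lines starting
    with ``#`` are preserved in ``df.attrs["comments"]``.  Non-numeric
    cells (including locale-style decimal commas) and NaN offsets are
    rejected with the 1-based file line number.
    """
    path = Path(path)
    comments: list[str] = []
    header_line = None
    rows: list[tuple[int, str]] = []  # (file line number, text)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                comments.append(line)
                continue
            if not line.strip():
                continue
            if header_line is None:
                header_line = (lineno, line)
            else:
                rows.append((lineno, line))
    if header_line is None:
        raise ProfileIOError(f"{path}: no header row found")
    columns = [c.strip() for c in header_line[1].split(",")]
    if column_map:
        columns = [column_map.get(c, c) for c in columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in columns]
    if missing:
        raise ProfileIOError(f"{path}: missing required column(s) {missing}; found {columns}")
    if not rows:
        raise ProfileIOError(f"{path}: no data rows")
    parsed = []
    for lineno, line in rows:
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(columns):
            raise ProfileIOError(
                f"{path}:{lineno}: expected {len(columns)} cells, got {len(cells)}"
            )
        rec = {}
        for col, cell in zip(columns, cells):
            try:
                rec[col] = float(cell)
            except ValueError:
                hint = " (decimal comma?)" if any("," in c for c in cells) else ""
                raise ProfileIOError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}{hint}"
                ) from None
        parsed.append((lineno, rec))
    df = pd.DataFrame([rec for _, rec in parsed], columns=columns)
    nan_off = df["offset_MHz"].isna()
    if nan_off.any():
        lineno = parsed[int(np.flatnonzero(nan_off)[0])][0]
        raise ProfileIOError(f"{path}:{lineno}: NaN offset")
    df.attrs["comments"] = comments
    return df


def write_profile(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    """Write a profile DataFrame as CSV with ``#`` comment header lines.

    Floats are written with ``repr`` precision so that
    ``read_profile(write_profile(x)) == x`` exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for c in comments:
            c = str(c)
            fh.write(c if c.startswith("#") else f"# {c}")
            fh.write("\n")
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write(",".join(repr(float(v)) for v in row.to_numpy()) + "\n")


def read_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ProfileIOError(f"{path}: top-level YAML structure must be a mapping")
    return cfg
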