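"""CSV readers/writers for plate scans, FLIM ROI tables and configs.

Dialect: comma-separated, dot decimal separator, no thousands separators,
LF line endings, locale-independent float formatting — so identical tables
always serialize to identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import FretlinError, GridMismatchError, MalformedTableError
from .spectra import GRID_STEP

__all__ = ["read_scan", "write_scan", "read_roi_table", "load_config"]

SCAN_COLUMNS = ["well", "excitation_nm", "emission_nm", "intensity"]


def _validate_scan(table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != SCAN_COLUMNS:
        raise MalformedTableError(
            f"scan header must be {','.join(SCAN_COLUMNS)}; got {','.join(map(str, table.columns))}"
        )
    try:
        table = table.astype(
            {"excitation_nm": float, "emission_nm": float, "intensity": float}
        )
    except (TypeError, ValueError) as exc:
        raise MalformedTableError(f"non-numeric values in scan table: {exc}") from exc
    off = table["emission_nm"] % GRID_STEP != 0
    if off.any():
        row = table[off].iloc[0]
        raise GridMismatchError(
            f"emission wavelength {row['emission_nm']:g} nm (well {row['well']}, "
            f"excitation {row['excitation_nm']:g} nm) is off the {GRID_STEP:g} nm grid"
        )
    if (table["intensity"] < 0).any():
        row = table[table["intensity"] < 0].iloc[0]
        raise MalformedTableError(
            f"negative intensity at well {row['well']}, emission {row['emission_nm']:g} nm"
        )
    dup = table.duplicated(subset=["well", "excitation_nm", "emission_nm"])
    if dup.any():
        row = table[dup].iloc[0]
        raise MalformedTableError(
            f"duplicate key (well {row['well']}, excitation {row['excitation_nm']:g}, "
            f"emission {row['emission_nm']:g})"
        )
    return table


def read_scan(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-scan CSV (header ``well,excitation_nm,emission_nm,intensity``)."""
    path = Path(path)
    if not path.exists():
        raise MalformedTableError(f"no such file: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise MalformedTableError(f"cannot parse {path}: {exc}") from exc
    return _validate_scan(table)


def _fmt(value: float) -> str:
    return format(float(value), ".10g")


def write_scan(table: pd.DataFrame, path: str | Path) -> None:
    """Write a scan table deterministically: rows sorted by (well, excitation,
    emission), stable float formatting, LF endings."""
    table = _validate_scan(table.reset_index(drop=True))
    ordered = table.sort_values(
        ["well", "excitation_nm", "emission_nm"], kind="mergesort"
    )
    lines = [",".join(SCAN_COLUMNS)]
    for row in ordered.itertuples(index=False):
        lines.append(
            f"{row.well},{_fmt(row.excitation_nm)},{_fmt(row.emission_nm)},{_fmt(row.intensity)}"
        )
    try:
        Path(path).write_text("\n".join(lines) + "\n", encoding="ascii", newline="\n")
    except OSError as exc:
        raise FretlinError(f"cannot write {path}: {exc}") from exc


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read a FLIM ROI table: columns ``sample, fraction, tau_ns`` and
    optionally ``phase_rad``."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise MalformedTableError(f"cannot parse {path}: {exc}") from exc
    required = {"sample", "fraction", "tau_ns"}
    missing = required - set(table.columns)
    if missing:
        raise MalformedTableError(f"ROI table missing columns: {sorted(missing)}")
    return table


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON parameter file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise MalformedTableError(f"config {path} must contain a mapping")
    return data
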