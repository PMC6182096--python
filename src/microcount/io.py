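"""Readers, writers and the packaged example dataset.

Two CSV schemas are supported.  Raw counts (the recommended reporting
form) use columns ``sample_id,count,volume_liters`` with an optional
``tntc_threshold`` column; a row is either an exact count or a TNTC
threshold, never both.  Reported concentrations (the legacy form) use
``sample_id,value`` where ``value`` is numeric for a detect or a
``"<x"`` string for a non-detect with limit x; a units flag says whether
values are per liter or per 100 liters.

One real dataset ships with the package: eight source-water Giardia cyst
samples (City of Calgary, October 2012), loadable by name with
:func:`load_fixture`.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import (
    CountObservation,
    Dataset,
    ReportedConcentration,
    ValidationError,
)

__all__ = [
    "read_counts",
    "read_reported",
    "write_counts",
    "write_reported",
    "load_fixture",
    "available_fixtures",
]

_FIXTURES = {
    "calgary_giardia_2012": (
        "calgary_giardia_2012.csv",
        "Giardia cysts, raw source water, City of Calgary, AB — October 2012",
    ),
}


def _counts_from_frame(df: pd.DataFrame, provenance: str) -> Dataset:
    required = {"sample_id", "count", "volume_liters"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    has_tntc = "tntc_threshold" in df.columns
    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            tntc = None
            if has_tntc and not pd.isna(row["tntc_threshold"]):
                tntc = int(row["tntc_threshold"])
            count = None if pd.isna(row["count"]) else int(row["count"])
            records.append(
                CountObservation(
                    sample_id=str(row["sample_id"]),
                    count=count,
                    volume=float(row["volume_liters"]),
                    tntc_threshold=tntc,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            "invalid rows in counts file:\n  " + "\n  ".join(errors)
        )
    if not records:
        raise ValidationError("counts file contains no data rows")
    return Dataset(records, kind="counts", provenance=provenance)


def read_counts(path) -> Dataset:
    """Read a raw-count CSV into a validated dataset.

    Malformed rows are reported together, each with its line number."""
    df = pd.read_csv(path)
    return _counts_from_frame(df, provenance=str(path))


def read_reported(path, units: str) -> Dataset:
    """Read a legacy reported-concentration CSV.

    ``units`` must be ``"per-L"`` or ``"per-100L"``; values (including
    "<x" limits) are converted to organisms per liter internally.
    """
    if units not in ("per-L", "per-100L"):
        raise ValidationError(f"units must be 'per-L' or 'per-100L', got {units!r}")
    scale = 1.0 if units == "per-L" else 0.01
    df = pd.read_csv(path, dtype={"value": str})
    required = {"sample_id", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2
        raw = str(row["value"]).strip()
        try:
            if raw.startswith("<"):
                limit = float(raw[1:]) * scale
                if limit <= 0:
                    raise ValidationError(f"non-positive limit in {raw!r}")
                records.append(
                    ReportedConcentration(
                        str(row["sample_id"]), nondetect=True, limit=limit
                    )
                )
            else:
                records.append(
                    ReportedConcentration(
                        str(row["sample_id"]), value=float(raw) * scale
                    )
                )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            "invalid rows in reported file:\n  " + "\n  ".join(errors)
        )
    if not records:
        raise ValidationError("reported file contains no data rows")
    return Dataset(records, kind="reported", units="per-L", provenance=str(path))


def write_counts(dataset: Dataset, path) -> None:
    """Write a counts dataset back to the raw-count CSV schema."""
    if dataset.kind != "counts":
        raise ValidationError("write_counts requires a counts dataset")
    rows = []
    for r in dataset.records:
        rows.append(
            dict(
                sample_id=r.sample_id,
                count="" if r.count is None else r.count,
                volume_liters=repr(r.volume),
                tntc_threshold="" if r.tntc_threshold is None else r.tntc_threshold,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_reported(dataset: Dataset, path, display: bool = False) -> None:
    """Write a reported dataset as per-liter CSV.

    With ``display=True`` values are rendered per 100 L at 2 significant
    figures, mimicking conventional lab reports; analysis paths should
    keep the default full precision.
    """
    if dataset.kind != "reported":
        raise ValidationError("write_reported requires a reported dataset")

    def fmt(x: float) -> str:
        if display:
            return f"{float(f'{x * 100:.2g}'):g}"
        return repr(x)

    rows = []
    for r in dataset.records:
        val = f"<{fmt(r.limit)}" if r.nondetect else fmt(r.value)
        rows.append(dict(sample_id=r.sample_id, value=val))
    pd.DataFrame(rows).to_csv(path, index=False)


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str = "calgary_giardia_2012") -> Dataset:
    """Load a packaged dataset by name.

    The default is the eight-sample Calgary Giardia monitoring set:
    counts 1, 0, 0, 0, 0, 0, 0, 2 in volumes of roughly 50-64 L.
    """
    if name not in _FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        )
    filename, provenance = _FIXTURES[name]
    ref = resources.files("microcount.data").joinpath(filename)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return _counts_from_frame(df, provenance=provenance)
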