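"""Reading and writing fluctuation-test colony tables.

The interchange format is a plain CSV with header ``colony_id,n_total,n_state2``
(one row per colony; fractions are derived on read), plus an optional sidecar
key-value text file ``<table>.meta`` echoing the simulation parameters,
assay duration, and master seed.  Writing is byte-stable: fixed column order,
LF line endings, integer formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .simulate import FluctuationDataset

__all__ = ["read_colony_table", "write_colony_table", "sidecar_path"]

_COLUMNS = ["colony_id", "n_total", "n_state2"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta")


def write_colony_table(ds: FluctuationDataset, path) -> None:
    """Write a dataset as a colony-table CSV plus a ``.meta`` sidecar.

    Requires at least 2 colonies (a single colony supports no variance
    computation).  Two writes of the same dataset are byte-identical.
    """
    if len(ds) < 2:
        raise ValidationError("refusing to write a dataset with fewer than 2 colonies")
    path = Path(path)
    lines = [",".join(_COLUMNS)]
    for i, (x, x2) in enumerate(zip(ds.n_total, ds.n_state2)):
        lines.append(f"{i},{int(x)},{int(x2)}")
    path.write_text("\n".join(lines) + "\n", newline="\n")

    meta = {"duration": ds.t, **ds.metadata}
    meta_lines = [f"{key}={meta[key]}" for key in sorted(meta)]
    sidecar_path(path).write_text("\n".join(meta_lines) + "\n", newline="\n")


def _read_sidecar(path: Path) -> dict:
    meta = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"malformed sidecar line in {path}: {line!r}")
        key, value = line.split("=", 1)
        meta[key.strip()] = value.strip()
    return meta


def read_colony_table(path, t: float | None = None) -> FluctuationDataset:
    """Read and validate a colony-table CSV.

    The assay duration comes from ``t`` or, failing that, from the
    ``duration`` key of the sidecar file.  Rejects missing/extra columns,
    non-integer counts, duplicate colony ids, and rows with
    ``n_state2 > n_total`` (naming the offending colony).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    if list(table.columns) != _COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(_COLUMNS)}, got {','.join(map(str, table.columns))}"
        )
    if len(table) < 2:
        raise ValidationError(f"{path}: a fluctuation dataset needs at least 2 colonies")
    for col in ("n_total", "n_state2"):
        values = table[col]
        numeric = pd.to_numeric(values, errors="coerce")
        if numeric.isna().any() or not np.all(numeric == numeric.astype(np.int64)):
            bad = table["colony_id"][numeric.isna() | (numeric != numeric.astype(np.int64))]
            raise ValidationError(
                f"{path}: non-integer {col} for colony_id {bad.iloc[0]}"
            )
        table[col] = numeric.astype(np.int64)
    if table["colony_id"].duplicated().any():
        dup = table["colony_id"][table["colony_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate colony_id {dup}")
    bad = table["n_state2"] > table["n_total"]
    if bad.any():
        row = table[bad].iloc[0]
        raise ValidationError(
            f"{path}: n_state2 ({row['n_state2']}) exceeds n_total ({row['n_total']}) "
            f"for colony_id {row['colony_id']}"
        )
    if (table["n_total"] < 1).any():
        row = table[table["n_total"] < 1].iloc[0]
        raise ValidationError(f"{path}: n_total < 1 for colony_id {row['colony_id']}")

    metadata: dict = {}
    meta_file = sidecar_path(path)
    if meta_file.exists():
        metadata = _read_sidecar(meta_file)
    if t is None:
        if "duration" not in metadata:
            raise ValidationError(
                f"{path}: assay duration not given and no 'duration' key in sidecar"
            )
        t = float(metadata["duration"])
    return FluctuationDataset(
        t=float(t),
        n_total=table["n_total"].to_numpy(),
        n_state2=table["n_state2"].to_numpy(),
        metadata=metadata,
    )
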