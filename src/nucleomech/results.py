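"""Result serialization: JSON summary records and flat CSV tables.

Records round-trip exactly: JSON numbers use Python's shortest repr and
pandas writes floats the same way, so ``read(write(x)) == x`` bit-for-bit.
Non-finite values are rejected before anything touches disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError


def _check_finite(obj: Any, context: str = "record") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{context}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{context}[{i}]")
    elif isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            raise ValidationError(f"non-finite value at {context}")


def _to_builtin(obj: Any) -> Any:
    """Convert numpy scalars/arrays to plain Python for exact JSON round-trips."""
    if isinstance(obj, dict):
        return {str(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_builtin(v) for v in obj.tolist()]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_record(record: dict, path: str | Path) -> None:
    """Write a summary record as JSON (sorted keys, deterministic bytes)."""
    record = _to_builtin(record)
    _check_finite(record)
    path = Path(path)
    try:
        path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_record(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a flat CSV table; floats use shortest-repr so re-reading is exact."""
    numeric = df.select_dtypes(include=[np.number])
    if not np.all(np.isfinite(numeric.to_numpy(dtype=float, na_value=np.inf))):
        raise ValidationError("table contains non-finite values")
    path = Path(path)
    try:
        df.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
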