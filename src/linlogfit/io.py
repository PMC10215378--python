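"""Reading titration tables and writing fit reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from .data import DoseResponseTable

__all__ = ["read_table", "write_report", "to_jsonable"]

logger = logging.getLogger("linlogfit")


def read_table(
    path,
    dose_col: str = "dose",
    response_col: str = "response",
    replicate_col: Optional[str] = None,
    dose_unit: str = "",
    response_unit: str = "",
) -> DoseResponseTable:
    """Read a CSV/TSV titration table (delimiter auto-detected).

    Rows with missing dose or response are dropped with a logged count;
    a missing column or an empty usable table raises with the column
    name in the message.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in filter(None, (dose_col, response_col, replicate_col)):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path} (have: {list(df.columns)})"
            )
    used = [dose_col, response_col] + ([replicate_col] if replicate_col else [])
    n_before = len(df)
    df = df.dropna(subset=[dose_col, response_col])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values from %s", n_dropped, path)
    if len(df) == 0:
        raise ValueError(f"no usable rows in {path}")
    return DoseResponseTable(
        df[dose_col].to_numpy(dtype=float),
        df[response_col].to_numpy(dtype=float),
        replicate_id=df[replicate_col].to_numpy() if replicate_col else None,
        dose_unit=dose_unit,
        response_unit=response_unit,
    )


def to_jsonable(obj: Any) -> Any:
    """Recursively convert fit dataclasses / numpy values to JSON types.

    Floats pass through unchanged; Python's float repr round-trips, so
    re-reading the JSON reproduces every number bit-for-bit.  Non-finite
    floats become the strings "nan"/"inf"/"-inf" (JSON has no literals
    for them).
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return "nan"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sig6(v: Any) -> Any:
    if isinstance(v, float):
        return float(f"{v:.6g}")
    return v


def write_report(
    fits: Mapping[str, Any],
    out_dir,
    basename: str = "report",
    extra: Optional[Mapping[str, Any]] = None,
) -> tuple[Path, Path]:
    """Write fit results as nested JSON (full precision) + flat TSV summary.

    ``fits`` maps a model name to a fit object (anything dataclass-like
    with ``rss``/``r2``/``aicc``).  The TSV has one row per fitted
    model, values rounded to 6 significant digits for display; the JSON
    keeps full precision.  Returns the two paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {name: to_jsonable(fit) for name, fit in fits.items()}
    if extra:
        payload.update(to_jsonable(dict(extra)))
    json_path = out_dir / f"{basename}.json"
    json_path.write_text(json.dumps(payload, indent=2) + "\n")

    rows = []
    for name, fit in fits.items():
        row: dict[str, Any] = {"model": name}
        for attr in ("rss", "r2", "aicc", "converged"):
            if hasattr(fit, attr):
                row[attr] = _sig6(getattr(fit, attr))
        st = getattr(fit, "stationary", None)
        if st is not None:
            row["regime"] = st.regime
            row["rmax"] = _sig6(st.rmax) if st.rmax is not None else ""
            row["rmin"] = _sig6(st.rmin) if st.rmin is not None else ""
        if hasattr(fit, "breakpoint"):
            row["breakpoint"] = _sig6(fit.breakpoint)
        rows.append(row)
    tsv_path = out_dir / f"{basename}.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path
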