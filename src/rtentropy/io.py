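"""CSV input/output of duration samples and JSON result writing."""

from __future__ import annotations

import json
from typing import List

import numpy as np
import pandas as pd

from .empirical import RTSample
from .exceptions import UsageError, ValidationError

__all__ = ["read_rt_csv", "write_samples_csv", "write_json"]


def read_rt_csv(path) -> List[RTSample]:
    """Read observed durations from a CSV with columns ``rt`` (+ optional ``condition``).

    Returns one sample per distinct condition label (a single unlabelled
    sample when no condition column is present).  Offending rows are
    reported by their zero-based data row index.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise UsageError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise UsageError(f"{path}: no data rows")
    if "rt" not in df.columns:
        raise ValidationError(f"{path}: required column 'rt' is missing "
                              f"(found: {list(df.columns)})")
    rt = pd.to_numeric(df["rt"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(rt) | (rt <= 0))
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"{path}: row {row}: 'rt' must be a finite positive number, "
            f"got {df['rt'].iloc[row]!r}")
    if "condition" in df.columns:
        cond = df["condition"].astype(str)
        return [RTSample(rt[(cond == label).to_numpy()], condition=label)
                for label in sorted(cond.unique())]
    return [RTSample(rt)]


def write_samples_csv(samples, path) -> None:
    """Write samples as CSV with columns ``rt,condition`` (full precision)."""
    frames = []
    for s in samples:
        frames.append(pd.DataFrame({"rt": s.durations,
                                    "condition": s.condition if s.condition is not None else ""}))
    df = pd.concat(frames, ignore_index=True)
    if (df["condition"] == "").all():
        df = df[["rt"]]
    # %.17g guarantees exact float64 round-tripping through text
    df.to_csv(path, index=False, float_format="%.17g")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
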