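"""Readers and writers for hyperpolarized intensity time series.

Two plain-text CSV dialects are supported:

* **wide** — one row per excitation: ``time_s,pyruvate,lactate``
* **long** — one row per (time, species): ``time_s,species,intensity``
  with species labels ``pyruvate`` and ``lactate``.

Parse failures report 1-based file line numbers (header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .kinetics import HyperpolarizedSeries

__all__ = ["read_series", "write_series"]

WIDE_COLUMNS = ("time_s", "pyruvate", "lactate")
LONG_COLUMNS = ("time_s", "species", "intensity")
SPECIES = ("pyruvate", "lactate")


def _numeric(df: pd.DataFrame, column: str) -> np.ndarray:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() & df[column].notna()
    if bad.any():
        lines = ", ".join(str(i + 2) for i in df.index[bad][:5])
        raise ParseError(f"non-numeric value in column {column!r} at line(s) {lines}")
    if vals.isna().any():
        lines = ", ".join(str(i + 2) for i in df.index[vals.isna()][:5])
        raise ParseError(f"missing value in column {column!r} at line(s) {lines}")
    # parse through Python float(): correctly rounded, so written values
    # round-trip bit-exactly
    return np.array([float(x) for x in df[column]], dtype=float)


def read_series(path, dialect: str = "auto") -> HyperpolarizedSeries:
    """Read a series table; ``dialect`` is ``"wide"``, ``"long"`` or ``"auto"``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = tuple(c.strip() for c in df.columns)
    df.columns = cols
    if dialect == "auto":
        if set(WIDE_COLUMNS) <= set(cols):
            dialect = "wide"
        elif set(LONG_COLUMNS) <= set(cols):
            dialect = "long"
        else:
            raise ParseError(
                f"{path}: header {cols} matches neither the wide "
                f"{WIDE_COLUMNS} nor the long {LONG_COLUMNS} dialect"
            )

    if dialect == "wide":
        t = _numeric(df, "time_s")
        dup = pd.Series(t).duplicated()
        if dup.any():
            lines = ", ".join(str(i + 2) for i in df.index[dup][:5])
            raise ParseError(f"{path}: duplicate timestamps at line(s) {lines}")
        order = np.argsort(t, kind="stable")
        return HyperpolarizedSeries(
            times=t[order],
            precursor=_numeric(df, "pyruvate")[order],
            product=_numeric(df, "lactate")[order],
        )

    if dialect == "long":
        species = df["species"].str.strip()
        unknown = ~species.isin(SPECIES)
        if unknown.any():
            lines = ", ".join(str(i + 2) for i in df.index[unknown][:5])
            raise ParseError(
                f"{path}: unknown species label at line(s) {lines} "
                f"(expected one of {SPECIES})"
            )
        t = _numeric(df, "time_s")
        y = _numeric(df, "intensity")
        per = {}
        for sp in SPECIES:
            m = (species == sp).to_numpy()
            ts = t[m]
            dup = pd.Series(ts).duplicated()
            if dup.any():
                lines = ", ".join(str(i + 2) for i in df.index[m][dup.to_numpy()][:5])
                raise ParseError(f"{path}: duplicate {sp} timestamps at line(s) {lines}")
            order = np.argsort(ts, kind="stable")
            per[sp] = (ts[order], y[m][order])
        t_p, y_p = per["pyruvate"]
        t_l, y_l = per["lactate"]
        if t_p.size != t_l.size or not np.array_equal(t_p, t_l):
            raise ParseError(f"{path}: pyruvate and lactate rows cover different time grids")
        return HyperpolarizedSeries(times=t_p, precursor=y_p, product=y_l)

    raise ParseError(f"unknown dialect {dialect!r}")


def write_series(series: HyperpolarizedSeries, path, dialect: str = "wide") -> None:
    """Write a series as CSV; floats round-trip exactly through ``read_series``."""
    path = Path(path)
    if dialect == "wide":
        df = pd.DataFrame(
            {
                "time_s": series.times,
                "pyruvate": series.precursor,
                "lactate": series.product,
            }
        )
    elif dialect == "long":
        df = pd.DataFrame(
            {
                "time_s": np.concatenate([series.times, series.times]),
                "species": ["pyruvate"] * len(series) + ["lactate"] * len(series),
                "intensity": np.concatenate([series.precursor, series.product]),
            }
        )
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
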