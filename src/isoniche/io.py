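"""CSV ingest with schema validation.

All exchange is plain UTF-8 CSV with '.' decimals.  Expected schemas:

- whisker_segments.csv: seal_id, sex, position_mm, d13C, d15N
- prey.csv: sample_id, species, d13C
- age_readings.csv: seal_id, reader_id, age_years
- seals.csv: seal_id, sex, group?, age_years?, mass_kg, length_cm, span_cm, girth_cm
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SchemaError, WhiskerSeries

SEGMENT_COLUMNS = ("seal_id", "sex", "position_mm", "d13C", "d15N")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = vals.isna() & out[c].notna() | out[c].isna()
        if bad.any():
            rows = [int(i) + 2 for i in out.index[bad][:10]]  # 1-based + header
            raise SchemaError(f"{path}: non-numeric {c!r} at rows {rows}")
        out[c] = vals
    return out


def read_segments(
    path,
    root_exclusion_mm: float = 5.0,
    spacing_tol: float = 1e-6,
) -> list[WhiskerSeries]:
    """Read per-segment isotope records into one WhiskerSeries per seal.

    Positions are sorted, checked for duplicates and uniform spacing, the
    proximal whisker root (default 5 mm) is dropped, and positions are
    rebased so the first retained segment sits at 0.
    """
    df = pd.read_csv(path)
    _require_columns(df, SEGMENT_COLUMNS, path)
    df = _numeric(df, ("position_mm", "d13C", "d15N"), path)

    dup = df.duplicated(subset=("seal_id", "position_mm"), keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:10]]
        raise SchemaError(f"{path}: duplicated (seal_id, position_mm) at rows {rows}")

    series = []
    for seal_id, sub in df.groupby("seal_id", sort=True):
        sub = sub.sort_values("position_mm")
        pos = sub["position_mm"].to_numpy(float)
        if len(pos) >= 3:
            steps = np.diff(pos)
            if np.ptp(steps) > spacing_tol:
                raise SchemaError(
                    f"{path}: seal {seal_id}: non-uniform segment spacing "
                    f"(steps {sorted(set(np.round(steps, 6)))} mm)"
                )
        keep = pos >= root_exclusion_mm - spacing_tol
        if not keep.any():
            raise SchemaError(
                f"{path}: seal {seal_id}: no segments beyond the whisker root"
            )
        sexes = sub["sex"].unique()
        if len(sexes) != 1:
            raise SchemaError(f"{path}: seal {seal_id}: inconsistent sex labels")
        series.append(
            WhiskerSeries(
                seal_id=str(seal_id),
                sex=str(sexes[0]),
                positions=pos[keep] - pos[keep][0],
                d13C=sub["d13C"].to_numpy(float)[keep],
                d15N=sub["d15N"].to_numpy(float)[keep],
            )
        )
    return series


def read_prey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("d13C",), path)
    return _numeric(df, ("d13C",), path)


def read_age_readings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("seal_id", "reader_id", "age_years"), path)
    df = _numeric(df, ("age_years",), path)
    if (df["age_years"] < 1).any():
        raise SchemaError(f"{path}: age readings below 1 year")
    return df


def read_seals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("seal_id",), path)
    return df
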