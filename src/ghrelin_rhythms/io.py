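"""Long-format CSV tables for Ct values and relative expression.

The dialect is deliberately strict: comma-separated, UTF-8, '.' decimal,
header required, with a fixed schema per table kind.  Silent column drift
is the main failure mode of long-format tables, so missing columns and
malformed rows are hard errors that name the offending rows (1-based file
line numbers, header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CT_SCHEMA = ["sample_id", "tissue", "gene", "is_reference", "zt_h", "replicate", "ct"]
EXPRESSION_SCHEMA = ["sample_id", "tissue", "gene", "zt_h", "rq"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class TableFormatError(ValueError):
    """Malformed input table; the message lists offending rows."""


def _read_checked(path: str | Path, schema: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    return df


def _parse_float(df: pd.DataFrame, col: str, errors: list[str]) -> pd.Series:
    parsed = pd.to_numeric(df[col], errors="coerce")
    bad = parsed.isna() | ~np.isfinite(parsed)
    for idx in df.index[bad]:
        errors.append(f"row {idx + 2}: unparseable {col} {df.at[idx, col]!r}")
    return parsed


def _check_zt(zt: pd.Series, errors: list[str]) -> None:
    bad = zt.notna() & ((zt < 0) | (zt > 24))
    for idx in zt.index[bad]:
        errors.append(f"row {idx + 2}: zt_h {zt[idx]} outside [0, 24]")


def _raise_if(errors: list[str], path: Path | str) -> None:
    if errors:
        shown = "; ".join(errors[:20]) + ("; ..." if len(errors) > 20 else "")
        raise TableFormatError(f"{path}: {shown}")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a raw Ct table.

    Columns: ``sample_id, tissue, gene, is_reference, zt_h, replicate, ct``.
    Duplicate ``(sample_id, gene, replicate)`` wells are rejected.
    """
    df = _read_checked(path, CT_SCHEMA)
    errors: list[str] = []
    zt = _parse_float(df, "zt_h", errors)
    ct = _parse_float(df, "ct", errors)
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    for idx in df.index[rep.isna()]:
        errors.append(f"row {idx + 2}: unparseable replicate {df.at[idx, 'replicate']!r}")
    _check_zt(zt, errors)
    is_ref = df["is_reference"].str.strip().str.lower()
    bad_flag = ~is_ref.isin(_TRUE | _FALSE)
    for idx in df.index[bad_flag]:
        errors.append(f"row {idx + 2}: is_reference must be true/false, got {df.at[idx, 'is_reference']!r}")
    dup = df.duplicated(subset=["sample_id", "gene", "replicate"], keep=False)
    for idx in df.index[dup]:
        errors.append(f"row {idx + 2}: duplicate (sample_id, gene, replicate) well")
    _raise_if(errors, path)
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "tissue": df["tissue"],
            "gene": df["gene"],
            "is_reference": is_ref.isin(_TRUE),
            "zt_h": zt.astype(float),
            "replicate": rep.astype(int),
            "ct": ct.astype(float),
        }
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-fish relative-expression table.

    Columns: ``sample_id, tissue, gene, zt_h, rq``.
    """
    df = _read_checked(path, EXPRESSION_SCHEMA)
    errors: list[str] = []
    zt = _parse_float(df, "zt_h", errors)
    rq = _parse_float(df, "rq", errors)
    _check_zt(zt, errors)
    dup = df.duplicated(subset=["sample_id", "gene"], keep=False)
    for idx in df.index[dup]:
        errors.append(f"row {idx + 2}: duplicate (sample_id, gene) record")
    _raise_if(errors, path)
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "tissue": df["tissue"],
            "gene": df["gene"],
            "zt_h": zt.astype(float),
            "rq": rq.astype(float),
        }
    )


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a Ct table in the canonical column order."""
    out = df.copy()
    if "replicate" not in out.columns:
        out["replicate"] = 1
    out["is_reference"] = out["is_reference"].astype(bool).map({True: "true", False: "false"})
    out[CT_SCHEMA].to_csv(path, index=False)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an expression table in the canonical column order."""
    df[EXPRESSION_SCHEMA].to_csv(path, index=False)
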