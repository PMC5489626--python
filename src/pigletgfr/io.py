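"""CSV schemas and validated table I/O for every pipeline stage.

All files are UTF-8 CSV with a header row and "." decimal separator;
units are encoded in the column names so the files are self-describing.
``read_table`` validates column presence, numeric type, positivity and
categorical membership, citing the offending row in error messages.
Extra columns are tolerated (the simulator appends latent truth columns
to subjects.csv for closure testing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import SchemaError


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str = "float"  # float | int | str
    min_value: float | None = None
    strict: bool = False  # True: value must exceed min_value
    allowed: tuple[str, ...] | None = None


SCHEMAS: dict[str, tuple[ColumnSpec, ...]] = {
    "subjects": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("age_days", "int", 0, True),
        ColumnSpec("bw_kg", min_value=0, strict=True),
        ColumnSpec("bsa_m2", min_value=0, strict=True),
        ColumnSpec("kw_g", min_value=0, strict=True),
        ColumnSpec("total_protein_g_per_l", min_value=0),
    ),
    "urine": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("interval_start_min", min_value=0),
        ColumnSpec("interval_end_min", min_value=0, strict=True),
        ColumnSpec("u_vol_ml", min_value=0),
        ColumnSpec("u_cr_mg_dl", min_value=0),
    ),
    "plasma_creatinine": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("clock_label", "str"),
        ColumnSpec("p_cr_mg_dl", min_value=0, strict=True),
        ColumnSpec("assay", "str", allowed=("jaffe", "enzymatic")),
    ),
    "iohexol": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("time_min", min_value=0),
        ColumnSpec("conc_ug_ml", min_value=0),
        ColumnSpec("dose_mg", min_value=0, strict=True),
    ),
    "clcr": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("assay", "str", allowed=("jaffe", "enzymatic")),
        ColumnSpec("clearance_ml_min", min_value=0, strict=True),
        ColumnSpec("load_mg_24h", min_value=0),
        ColumnSpec("outlier_flag", "str"),
    ),
    "nca": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("auc_0_last", min_value=0, strict=True),
        ColumnSpec("auc_0_inf", min_value=0, strict=True),
        ColumnSpec("lambda_z", min_value=0, strict=True),
        ColumnSpec("extrap_fraction", min_value=0),
        ColumnSpec("clearance_ml_min", min_value=0, strict=True),
        ColumnSpec("n_terminal_points", "int", 0, True),
    ),
    "gfr_indexed": (
        ColumnSpec("subject_id", "str"),
        ColumnSpec("age_days", "int", 0, True),
        ColumnSpec("technique", "str", allowed=("jaffe", "enzymatic", "exo_iohexol")),
        ColumnSpec("clearance_ml_min", min_value=0, strict=True),
        ColumnSpec("per_bw_ml_min_kg", min_value=0, strict=True),
        ColumnSpec("per_bsa_ml_min_m2", min_value=0, strict=True),
        ColumnSpec("per_kw_ml_min_g", min_value=0, strict=True),
    ),
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a stage CSV against its named schema."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path} does not exist")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in SCHEMAS[schema_name]:
        if col.name not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col.name!r}")
        series = df[col.name]
        if col.kind in ("float", "int"):
            numeric = pd.to_numeric(series, errors="coerce")
            bad = numeric.isna() & series.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{path.name}: non-numeric {col.name!r} at row {row}: {series[row]!r}"
                )
            if numeric.isna().any():
                row = int(numeric.isna().idxmax())
                raise SchemaError(f"{path.name}: missing {col.name!r} at row {row}")
            if col.min_value is not None:
                viol = numeric < col.min_value if not col.strict else numeric <= col.min_value
                if viol.any():
                    row = int(viol.idxmax())
                    op = ">" if col.strict else ">="
                    raise SchemaError(
                        f"{path.name}: {col.name!r} must be {op} {col.min_value} "
                        f"but is {numeric[row]} at row {row}"
                    )
            df[col.name] = numeric.astype(int if col.kind == "int" else float)
        elif col.allowed is not None:
            viol = ~series.astype(str).isin(col.allowed)
            if viol.any():
                row = int(viol.idxmax())
                raise SchemaError(
                    f"{path.name}: {col.name!r} must be one of {col.allowed} "
                    f"but is {series[row]!r} at row {row}"
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a stage CSV (full float precision, round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip exact
    return path
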