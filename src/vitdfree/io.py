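"""Cohort CSV reading/validation and deterministic report writing.

CSV (UTF-8, header row, '.' decimal) is the sole tabular interchange;
units are encoded in column names (e.g. ``total_25ohd_ng_ml``) so unit
drift is visible at the schema level.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .binding import GcDiplotype
from .cohort import COHORT_COLUMNS
from .stats import AnalysisReport

__all__ = ["read_cohort", "write_cohort", "write_report",
           "CohortValidationError"]

log = logging.getLogger("vitdfree")

# columns that must be non-negative when present
_NON_NEGATIVE = [
    "total_25ohd_ng_ml", "d24_25ohd3_ng_ml", "vdbp_ug_ml", "albumin_g_dl",
    "measured_free_pg_ml", "ipth_pg_ml", "ca_mg_dl", "p_mg_dl", "alp_iu_l",
    "vitd_intake_iu_day", "ca_intake_mg_day", "daylight_hours_week",
    "activity_days_week", "activity_min_day",
    "bmc_tb_g", "bmd_tb_g_cm2", "bmd_ls_g_cm2",
]
_REQUIRED = ["id", "sex", "age_years"]


class CohortValidationError(ValueError):
    """Raised when the cohort file is structurally unusable."""


def read_cohort(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rows failing validation (negative analyte, unparseable diplotype) are
    dropped with a logged message carrying the 1-based data line number;
    the collected messages are attached as ``df.attrs['validation_errors']``.
    With ``strict=True`` any row-level error raises instead.  Unknown
    columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing required columns {missing}")
    errors: list[str] = []
    bad = pd.Series(False, index=df.index)
    for col in _NON_NEGATIVE:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        neg = vals < 0
        for idx in df.index[neg]:
            errors.append(f"line {idx + 2}: {col} negative "
                          f"({df.loc[idx, col]}); row rejected")
        bad |= neg
        df[col] = vals
    if "diplotype" in df.columns:
        for idx in df.index[df["diplotype"].notna()]:
            try:
                GcDiplotype.parse(df.loc[idx, "diplotype"])
            except ValueError as exc:
                errors.append(f"line {idx + 2}: {exc}; row rejected")
                bad.loc[idx] = True
    if errors:
        for msg in errors:
            log.warning("%s: %s", path.name, msg)
        if strict:
            raise CohortValidationError(
                f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    out = df[~bad].reset_index(drop=True)
    out.attrs["validation_errors"] = errors
    return out


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with stable column order (byte-deterministic)."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns] + \
        [c for c in df.columns if c not in COHORT_COLUMNS]
    df.to_csv(path, index=False, columns=cols, lineterminator="\n")


def _summary_markdown(report: AnalysisReport) -> str:
    lines = ["# Cohort analysis summary", "",
             f"Subjects analyzed: {report.n_total}", ""]
    for name, table in report.tables().items():
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append("")
        if table.empty:
            lines.append("(no rows)")
        else:
            lines.append(f"{len(table)} rows; columns: "
                         + ", ".join(table.columns))
            if name == "interactions" and "p_interaction" in table:
                sig = table[table["p_interaction"] < 0.05]
                lines.append(f"significant interactions (p < 0.05): {len(sig)}")
            if name == "regressions" and "p" in table:
                sig = table[table["p"] < 0.05]
                lines.append(f"significant adjusted slopes (p < 0.05): {len(sig)}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write the report tables as CSVs plus a markdown summary.

    Output is deterministic: fixed file set, stable column order, '%.6g'
    float formatting; re-running on identical input overwrites
    byte-identically.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, table in report.tables().items():
            p = outdir / f"{name}.csv"
            table.to_csv(p, index=False, float_format="%.6g",
                         lineterminator="\n")
            written.append(p)
        summary = outdir / "summary.md"
        summary.write_text(_summary_markdown(report), encoding="utf-8")
        written.append(summary)
    except OSError as exc:
        raise OSError(f"cannot write report into {outdir}: {exc}") from exc
    for p in written:
        log.info("wrote %s", p)
    return written
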