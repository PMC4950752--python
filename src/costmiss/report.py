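"""Rendering of simulation summaries and cohort round-trip I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_report", "format_summary_table", "write_cohort", "read_cohort"]

_COLUMNS = [
    ("method", "{}"),
    ("mechanism", "{}"),
    ("true_mean", "{:.0f}"),
    ("mean_cost", "{:.0f}"),
    ("absolute_bias", "{:.0f}"),
    ("relative_bias_pct", "{:.1f}"),
    ("sse", "{:.0f}"),
    ("see", "{:.0f}"),
    ("see_sse_ratio", "{:.2f}"),
    ("coverage_probability", "{:.2f}"),
]


def format_summary_table(summaries: pd.DataFrame) -> str:
    """Plain-text table: mean cost, bias (EUR and %), SSE, SEE, ratio, CP.

    Costs are rendered to the nearest euro and coverage to two decimals.
    """
    if len(summaries) == 0:
        raise ValueError("no simulation summaries to report")
    cols = [c for c, _ in _COLUMNS if c in summaries.columns]
    fmt = dict(_COLUMNS)
    cells = [[fmt[c].format(row[c]) for c in cols] for _, row in summaries.iterrows()]
    widths = [max(len(c), *(len(r[i]) for r in cells)) for i, c in enumerate(cols)]
    def line(parts):
        return "  ".join(p.rjust(w) for p, w in zip(parts, widths))
    out = [line(cols), line(["-" * w for w in widths])]
    out += [line(r) for r in cells]
    return "\n".join(out) + "\n"


def write_report(summaries: pd.DataFrame, path: str | Path,
                 format: str = "text-table") -> Path:
    """Write the summary table as a delimited (CSV) or aligned text file."""
    path = Path(path)
    if len(summaries) == 0:
        raise ValueError("no simulation summaries to report")
    if format == "delimited":
        summaries.to_csv(path, index=False)
    elif format == "text-table":
        path.write_text(format_summary_table(summaries))
    else:
        raise ValueError("format must be 'delimited' or 'text-table'")
    return path


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Comma-separated cohort table, header row, empty cells for missing."""
    path = Path(path)
    cohort.to_csv(path, index=False, na_rep="")
    return path


_BOOL_COLS = ("caregiver_working", "baseline_complete")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table; '' , '.' and 'NA' all count as missing."""
    df = pd.read_csv(path, na_values=[".", "NA", ""], keep_default_na=True)
    for c in _BOOL_COLS:
        if c in df.columns and df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False}).astype(bool)
    return df
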