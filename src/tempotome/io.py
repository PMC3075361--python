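"""TSV dialects and containers for the time-course pipeline.

All on-disk formats are UTF-8 TSV with a header row, '.' decimal and no
thousands separators, so that every stage output re-read by the next stage is
bit-equivalent to the in-memory hand-off. Arrays are named ``d{day}{replicate}``
(e.g. ``d0A``, ``d14B``); the parsing rule is overridable where it matters.

In-memory containers are plain pandas objects:

* probe intensities — ``DataFrame`` indexed by ``probe_id`` with one float
  column per array, plus a ``Series`` mapping ``probe_id -> probeset_id``;
* expression — ``DataFrame`` indexed by feature id (probe set or gene),
  log2 scale, one column per array;
* design — ``DataFrame`` indexed by ``array_id`` with integer ``day`` and
  string ``replicate`` columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeIntensityMatrix",
    "SchemaError",
    "read_design",
    "write_design",
    "read_probes",
    "write_probes",
    "read_expression",
    "write_expression",
    "validate_design_arrays",
    "read_geo_series_matrix",
    "DEFAULT_TITLE_REGEX",
]

DEFAULT_TITLE_REGEX = r"d(?P<day>\d+)(?P<rep>[A-Za-z])"


class SchemaError(ValueError):
    """An input file violates the documented TSV schema."""


@dataclass(frozen=True)
class ProbeIntensityMatrix:
    """Raw linear-scale probe intensities plus the probe -> probe-set map."""

    intensities: pd.DataFrame  # probe_id x array_id, positive reals
    probeset: pd.Series  # probe_id -> probeset_id

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.probeset.index):
            raise SchemaError("probe ids of intensities and probeset map differ")
        if self.intensities.index.has_duplicates:
            raise SchemaError("duplicate probe ids")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise SchemaError("probe intensities must be finite and strictly positive")

    @property
    def arrays(self) -> list[str]:
        return list(self.intensities.columns)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.reset_index()
    out.columns = ["array_id", "day", "replicate"]
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "replicate": str})
    _require_columns(df, ["array_id", "day", "replicate"], path)
    df["day"] = df["day"].astype(int)
    design = df.set_index("array_id")[["day", "replicate"]]
    dup = design.reset_index().duplicated(subset=["day", "replicate"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (day, replicate) assignment")
    return design


def write_probes(probes: ProbeIntensityMatrix, path: str | Path) -> None:
    out = probes.intensities.copy()
    out.insert(0, "probeset_id", probes.probeset)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_probes(path: str | Path) -> ProbeIntensityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", float_precision="round_trip")
    _require_columns(df, ["probeset_id"], path)
    probeset = df["probeset_id"].astype(str)
    intensities = df.drop(columns="probeset_id").astype(float)
    return ProbeIntensityMatrix(intensities=intensities, probeset=probeset)


def write_expression(expr: pd.DataFrame, path: str | Path, index_name: str = "feature_id") -> None:
    out = expr.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the TSV hand-off bit-equivalent to memory
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise SchemaError(f"{path}: non-numeric expression columns {bad}")
    if not np.all(np.isfinite(df.to_numpy())):
        raise SchemaError(f"{path}: non-finite expression values")
    return df


def validate_design_arrays(expr: pd.DataFrame, design: pd.DataFrame) -> None:
    """Every design array must be an expression column (and vice versa)."""
    missing = [a for a in design.index if a not in expr.columns]
    if missing:
        raise SchemaError(f"design references arrays absent from expression: {missing}")
    extra = [a for a in expr.columns if a not in design.index]
    if extra:
        raise SchemaError(f"expression has arrays absent from design: {extra}")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _unquote(field: str) -> str:
    field = field.strip()
    if len(field) >= 2 and field[0] == '"' and field[-1] == '"':
        return field[1:-1]
    return field


def read_geo_series_matrix(
    path: str | Path,
    title_regex: str = DEFAULT_TITLE_REGEX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix text file into (expression, design).

    The series-matrix dialect is TSV with ``!``-prefixed metadata lines and the
    signal table delimited by ``!series_matrix_table_begin`` / ``_end``.
    Day and replicate are recovered from ``!Sample_title`` via ``title_regex``
    (named groups ``day`` and ``rep``); a title that does not match raises a
    ``SchemaError`` listing it.
    """
    path = Path(path)
    titles: list[str] | None = None
    table_lines: list[list[str]] = []
    in_table = False
    saw_table = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                saw_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append([_unquote(f) for f in line.split("\t")])
            elif line.startswith("!Sample_title"):
                titles = [_unquote(f) for f in line.split("\t")[1:]]
            elif not line.startswith(("!", "#")):
                raise SchemaError(f"{path}:{lineno}: malformed header line: {line[:60]!r}")
    if not saw_table or not table_lines:
        raise SchemaError(f"{path}: no series_matrix_table found")
    header, *rows = table_lines
    if not header or header[0].upper() != "ID_REF":
        raise SchemaError(f"{path}: table header must start with ID_REF, got {header[:1]}")
    sample_ids = header[1:]
    if titles is None:
        titles = sample_ids
    if len(titles) != len(sample_ids):
        raise SchemaError(f"{path}: {len(titles)} sample titles for {len(sample_ids)} samples")

    expr = pd.DataFrame(
        [[float(v) for v in r[1:]] for r in rows],
        index=[r[0] for r in rows],
        columns=sample_ids,
    )

    pattern = re.compile(title_regex)
    records = []
    for sid, title in zip(sample_ids, titles):
        m = pattern.search(title)
        if m is None:
            raise SchemaError(f"{path}: sample title {title!r} does not match {title_regex!r}")
        records.append((sid, int(m.group("day")), m.group("rep")))
    design = pd.DataFrame(records, columns=["array_id", "day", "replicate"]).set_index("array_id")
    return expr, design
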