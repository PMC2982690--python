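"""Reading, validation and normalisation of expression time-series tables.

The expected on-disk layout is the common microarray export: one header row
of time labels (hours), one identifier column, and one row of log2 expression
ratios per gene.  Tab- and comma-delimited dialects are auto-detected from
the header line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionProfile",
    "read_expression_table",
    "write_expression_table",
    "average_replicates",
]

#: relative tolerance on equal spacing of the time grid
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class ExpressionProfile:
    """A genes x time-points matrix of log2 expression ratios.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    time_points_h
        Strictly increasing, (near-)equally spaced sampling times in hours.
    values
        2-D float array of shape ``(len(gene_ids), len(time_points_h))``
        holding log2-normalised expression ratios.  No missing values.
    """

    gene_ids: tuple[str, ...]
    time_points_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        t = np.asarray(self.time_points_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_points_h", t)
        object.__setattr__(self, "values", v)

        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if v.shape != (len(self.gene_ids), t.size):
            raise ValueError(
                f"shape mismatch: {v.shape} values for {len(self.gene_ids)} genes "
                f"x {t.size} time points"
            )
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time points must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=_GRID_RTOL, atol=1e-9):
                raise ValueError("time points must be equally spaced")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_time_points(self) -> int:
        return self.time_points_h.size

    @property
    def sampling_interval_h(self) -> float:
        """Sampling interval in hours (0 for a single-point grid)."""
        if self.time_points_h.size < 2:
            return 0.0
        return float(self.time_points_h[1] - self.time_points_h[0])

    def series(self, gene: str) -> np.ndarray:
        """Expression series of one gene."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None
        return self.values[i]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.time_points_h)
        )


def _parse_time_label(label: str) -> float:
    s = label.strip().lower()
    for suffix in ("hours", "hour", "hrs", "hr", "h"):
        if s.endswith(suffix):
            s = s[: -len(suffix)].strip()
            break
    else:
        if s.endswith("min"):
            return float(s[:-3].strip()) / 60.0
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"cannot parse time label {label!r} as hours") from None


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_table(
    path: str | Path,
    delimiter: str | None = None,
    *,
    interpolate_missing: bool = False,
    log2_transform: bool = False,
) -> ExpressionProfile:
    """Read a delimited expression table into an :class:`ExpressionProfile`.

    Parameters
    ----------
    path
        Text file: header row of time labels, first column of gene ids.
    delimiter
        Field delimiter; auto-detected (tab vs comma) from the header when
        ``None``.
    interpolate_missing
        Linearly interpolate *interior* empty cells; boundary gaps and any
        gap when this flag is off are hard errors.
    log2_transform
        Apply log2 to the (positive) values.  Off by default: tables are
        assumed to be log2-normalised already.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header and at least one gene row")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])

    header = lines[0].split(delimiter)
    time_labels = header[1:]
    if not time_labels:
        raise ValueError(f"{path}: header has no time-point columns")
    times = np.array([_parse_time_label(t) for t in time_labels])

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split(delimiter)
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{r}: ragged row ({len(cells)} fields, expected {len(header)})"
            )
        gid = cells[0].strip()
        if gid in seen:
            raise ValueError(f"{path}:{r}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)

        row = np.empty(len(cells) - 1)
        for c, cell in enumerate(cells[1:], start=2):
            s = cell.strip()
            if s == "" or s.upper() in {"NA", "NAN", "NULL"}:
                row[c - 2] = np.nan
                continue
            try:
                row[c - 2] = float(s)
            except ValueError:
                raise ValueError(
                    f"{path}:{r}: non-numeric cell {cell!r} in column {c}"
                ) from None
        rows.append(row)

    values = np.vstack(rows)
    if np.any(np.isnan(values)):
        if not interpolate_missing:
            bad = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"{path}: missing value for gene {gene_ids[bad[0]]!r} at "
                f"time column {bad[1] + 1} (pass interpolate_missing=True "
                "to fill interior gaps)"
            )
        values = _interpolate_interior(values, gene_ids, path)

    if log2_transform:
        if np.any(values <= 0):
            raise ValueError(f"{path}: log2 transform requires positive values")
        values = np.log2(values)

    return ExpressionProfile(tuple(gene_ids), times, values)


def _interpolate_interior(
    values: np.ndarray, gene_ids: Sequence[str], path: Path
) -> np.ndarray:
    out = values.copy()
    for i in range(out.shape[0]):
        row = out[i]
        nan = np.isnan(row)
        if not nan.any():
            continue
        if nan[0] or nan[-1]:
            raise ValueError(
                f"{path}: gene {gene_ids[i]!r} has a missing boundary value; "
                "only interior gaps can be interpolated"
            )
        idx = np.arange(row.size)
        out[i, nan] = np.interp(idx[nan], idx[~nan], row[~nan])
    return out


def write_expression_table(
    profile: ExpressionProfile, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a profile so that a re-read round-trips bit-identically.

    Floats are rendered with ``repr``, the shortest form that parses back
    to the same IEEE double.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "gene" + delimiter + delimiter.join(repr(float(t)) for t in profile.time_points_h)
        )
        fh.write("\n")
        for gid, row in zip(profile.gene_ids, profile.values):
            fh.write(
                gid + delimiter + delimiter.join(repr(float(v)) for v in row) + "\n"
            )


def average_replicates(profiles: Sequence[ExpressionProfile]) -> ExpressionProfile:
    """Element-wise mean of replicate experiments.

    All replicates must share the same gene order and time grid; replicate
    averaging is how triplicate designs collapse to one profile before
    pairwise analysis.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.gene_ids != first.gene_ids:
            raise ValueError("replicates have mismatched gene ids/order")
        if p.time_points_h.shape != first.time_points_h.shape or not np.allclose(
            p.time_points_h, first.time_points_h, rtol=_GRID_RTOL, atol=1e-9
        ):
            raise ValueError("replicates have mismatched time grids")
    # correctly rounded summation makes the result independent of the order
    # in which replicates are passed
    stacked = np.stack([p.values for p in profiles])
    mean = np.empty_like(first.values)
    for i in range(mean.shape[0]):
        for j in range(mean.shape[1]):
            mean[i, j] = math.fsum(stacked[:, i, j]) / len(profiles)
    return ExpressionProfile(first.gene_ids, first.time_points_h, mean)
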