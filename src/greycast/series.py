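"""Annual observation series.

A :class:`RawSeries` is the package's basic container: a strictly positive
sequence of annual observations indexed by consecutive calendar years. Grey
models are small-sample methods, so the container deliberately stays tiny —
a pair of NumPy arrays plus validation — instead of wrapping a full time
series library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidSeriesError

__all__ = ["RawSeries", "read_series_csv", "write_series_csv"]

#: grey models need at least this many observations to be identifiable
#: in any meaningful way (two parameters fit to n-1 difference equations)
MIN_LENGTH = 4


@dataclass(frozen=True)
class RawSeries:
    """A positive annual sequence x(0) with its calendar years.

    Parameters
    ----------
    years
        Consecutive integer calendar years, strictly increasing by one.
    values
        Strictly positive observations, one per year.
    name
        Optional indicator label (used as a column/row header in reports).
    """

    years: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise InvalidSeriesError(
                "years and values must be one-dimensional and equally long"
            )
        if len(values) < MIN_LENGTH:
            raise InvalidSeriesError(
                f"series needs at least {MIN_LENGTH} observations, got {len(values)}"
            )
        if np.any(np.diff(years) != 1):
            raise InvalidSeriesError("years must be consecutive and ascending")
        if not np.all(np.isfinite(values)):
            raise InvalidSeriesError("values must be finite")
        bad = values <= 0
        if np.any(bad):
            year = int(years[np.argmax(bad)])
            raise InvalidSeriesError(
                f"all values must be positive; offending year {year}"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @classmethod
    def from_values(
        cls, values, first_year: int = 2000, name: str = ""
    ) -> "RawSeries":
        values = np.asarray(values, dtype=np.float64)
        years = first_year + np.arange(len(values))
        return cls(years=years, values=values, name=name)

    def with_values(self, values) -> "RawSeries":
        """Same years and name, new values (used by transforms)."""
        return RawSeries(years=self.years.copy(), values=values, name=self.name)


def read_series_csv(path: str | Path, name: str | None = None) -> RawSeries:
    """Read a two-column ``year,value`` CSV into a :class:`RawSeries`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise DataError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in frame.columns]
    if len(frame.columns) < 2 or cols[0] != "year":
        raise DataError(
            f"{path}: expected header 'year,value', got {list(frame.columns)}"
        )
    value_col = frame.columns[1]
    try:
        return RawSeries(
            years=frame["year" if "year" in frame.columns else frame.columns[0]].to_numpy(),
            values=frame[value_col].to_numpy(dtype=np.float64),
            name=name if name is not None else str(value_col),
        )
    except InvalidSeriesError:
        raise
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric data ({exc})") from exc


def write_series_csv(series: RawSeries, path: str | Path, value_header: str = "value") -> None:
    """Write ``year,value`` CSV with deterministic formatting."""
    lines = [f"year,{value_header}"]
    for year, value in zip(series.years, series.values):
        lines.append(f"{int(year)},{float(value)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
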