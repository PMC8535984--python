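"""Packaged reference datasets.

Ships the national work-safety accident-death series for China, 2000-2020
(official yearbook statistics), which is the worked example used throughout
the documentation and tests, plus a published table of grey-relational /
Pearson / composite correlation coefficients between three accident
indicators and five economic indicators computed on the same period. The
economic indicator series underlying that table were never published as
numbers, so the table is shipped as printed coefficients rather than being
recomputed from raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import FixtureNotFoundError
from .series import RawSeries

__all__ = [
    "Fixture",
    "load_fixture",
    "list_fixtures",
    "published_correlation_table",
]

_SERIES_FIXTURES = {
    "accident_deaths_2000_2020": (
        "accident_deaths_2000_2020.csv",
        "Deaths from work-safety accidents, China, 2000-2020 "
        "(national yearbook statistics)",
    ),
}


@dataclass(frozen=True)
class Fixture:
    name: str
    series: RawSeries
    provenance: str


def _data_path(filename: str):
    return resources.files("greycast.data").joinpath(filename)


def list_fixtures() -> tuple[str, ...]:
    return tuple(sorted(_SERIES_FIXTURES))


def load_fixture(name: str) -> Fixture:
    """Load a packaged annual series by name."""
    try:
        filename, provenance = _SERIES_FIXTURES[name]
    except KeyError:
        available = ", ".join(list_fixtures())
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {available}"
        ) from None
    with resources.as_file(_data_path(filename)) as path:
        frame = pd.read_csv(path)
    series = RawSeries(
        years=frame["year"].to_numpy(),
        values=frame["value"].to_numpy(dtype=float),
        name=name,
    )
    return Fixture(name=name, series=series, provenance=provenance)


def published_correlation_table() -> pd.DataFrame:
    """The published 12x5 correlation-coefficient table.

    Indexed by (block, indicator) where block is one of ``grey``,
    ``pearson``, ``composite``; columns are the five economic indicators.
    Values are the coefficients exactly as published (6 decimals).
    """
    with resources.as_file(
        _data_path("published_correlation_coefficients.csv")
    ) as path:
        frame = pd.read_csv(path)
    return frame.set_index(["block", "indicator"])
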