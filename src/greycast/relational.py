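"""Grey relational analysis and the Pearson-blended composite coefficient.

Grey relational analysis (GRA) scores how closely each comparison series
x_i tracks a reference series y, pointwise, after making the series
dimensionless. With deviations Delta_i(k) = |y(k) - x_i(k)| and global
extremes m = min over (i, k) and M = max over (i, k), the relational
coefficient at each time point is

    xi_i(k) = (m + rho * M) / (Delta_i(k) + rho * M),

with resolution coefficient rho in (0, 1) (customarily 0.5), and the grey
relational degree gamma_i is the time average of xi_i(k). The composite
coefficient blends the relational degree with the ordinary sample Pearson
correlation epsilon_i:

    rho_i = phi * gamma_i + (1 - phi) * epsilon_i,   phi in [0, 1].

GRA operates on initial-value normalized series (every series divided by
its own first element); the Pearson coefficient is invariant to that
normalization, so it is computed on the raw series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    DegeneratePanelWarning,
    InternalConsistencyError,
    InvalidSeriesError,
    InvalidSpecError,
    UndefinedCorrelationError,
)
from .series import RawSeries

__all__ = [
    "SeriesPanel",
    "RelationalConfig",
    "DeviationMatrix",
    "RelationalResult",
    "CorrelationTable",
    "normalize_panel",
    "deviations",
    "relational_coefficients",
    "grey_degree",
    "pearson",
    "composite",
    "comprehensive_index",
    "analyze_panel",
    "build_correlation_table",
    "read_panel_csv",
]

NormalizeMode = Literal["initial_value", "none", "first_series_pointwise"]

#: block labels, in published row order
BLOCKS = ("grey", "pearson", "composite")
COMPREHENSIVE_LABEL = "Comprehensive accident index"


@dataclass(frozen=True)
class RelationalConfig:
    """Tuning constants of the analysis.

    ``resolution`` is the GRA resolution coefficient rho in (0, 1);
    ``blend`` the composite weight phi in [0, 1] on the grey relational
    degree; ``normalize`` selects the dimensionless transform applied
    before GRA (``initial_value`` divides every series by its own first
    element; ``first_series_pointwise`` is a compatibility variant that
    divides all series by the first comparison series at each time point;
    ``none`` skips normalization).
    """

    resolution: float = 0.5
    blend: float = 0.5
    normalize: NormalizeMode = "initial_value"

    def __post_init__(self) -> None:
        if not (0 < self.resolution < 1):
            raise InvalidSpecError(
                f"resolution must lie in (0, 1), got {self.resolution}"
            )
        if not (0 <= self.blend <= 1):
            raise InvalidSpecError(f"blend must lie in [0, 1], got {self.blend}")
        if self.normalize not in ("initial_value", "none", "first_series_pointwise"):
            raise InvalidSpecError(f"unknown normalize mode {self.normalize!r}")


@dataclass(frozen=True)
class SeriesPanel:
    """One reference series plus m comparison series on shared years."""

    reference: RawSeries
    comparisons: tuple[RawSeries, ...]

    def __post_init__(self) -> None:
        comparisons = tuple(self.comparisons)
        object.__setattr__(self, "comparisons", comparisons)
        if len(comparisons) < 1:
            raise InvalidSeriesError("panel needs at least one comparison series")
        for comp in comparisons:
            if not np.array_equal(comp.years, self.reference.years):
                raise InvalidSeriesError(
                    f"comparison {comp.name!r} does not share the reference years"
                )

    @property
    def n(self) -> int:
        return self.reference.n

    @property
    def m(self) -> int:
        return len(self.comparisons)

    @property
    def comparison_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.comparisons)


@dataclass(frozen=True)
class DeviationMatrix:
    """Absolute deviations Delta_i(k) with their global extremes."""

    deltas: np.ndarray  # shape (m, n)
    global_min: float
    global_max: float


@dataclass(frozen=True)
class RelationalResult:
    """Per-pair GRA coefficients and the three summary vectors."""

    coefficients: np.ndarray  # xi, shape (m, n)
    grey_degree: np.ndarray  # gamma, shape (m,)
    pearson: np.ndarray  # epsilon, shape (m,)
    composite: np.ndarray  # rho, shape (m,)
    comparison_names: tuple[str, ...]


def normalize_panel(panel: SeriesPanel, config: RelationalConfig) -> SeriesPanel:
    """Make the panel dimensionless per ``config.normalize``."""
    mode = config.normalize
    if mode == "none":
        return panel

    def scale_initial(series: RawSeries) -> RawSeries:
        first = series.values[0]
        if first == 0:
            raise InvalidSeriesError(
                f"series {series.name!r} starts at zero; cannot normalize"
            )
        return series.with_values(series.values / first)

    if mode == "initial_value":
        return SeriesPanel(
            reference=scale_initial(panel.reference),
            comparisons=tuple(scale_initial(c) for c in panel.comparisons),
        )
    # first_series_pointwise: divide everything by the first comparison
    # series at each time point (order-dependent; compatibility only)
    base = panel.comparisons[0].values
    if np.any(base == 0):
        raise InvalidSeriesError("pointwise base series contains zeros")
    return SeriesPanel(
        reference=panel.reference.with_values(panel.reference.values / base),
        comparisons=tuple(
            c.with_values(c.values / base) for c in panel.comparisons
        ),
    )


def deviations(panel: SeriesPanel) -> DeviationMatrix:
    """Delta_i(k) = |y(k) - x_i(k)| with global min/max over i and k."""
    y = panel.reference.values
    deltas = np.abs(
        np.stack([c.values for c in panel.comparisons]) - y[None, :]
    )
    return DeviationMatrix(
        deltas=deltas,
        global_min=float(deltas.min()),
        global_max=float(deltas.max()),
    )


def relational_coefficients(
    dev: DeviationMatrix, config: RelationalConfig
) -> np.ndarray:
    """Grey relational coefficients xi_i(k) from a deviation matrix."""
    if dev.global_max == 0:
        warnings.warn(
            "all comparison series coincide with the reference; relational "
            "coefficients set to their limit value 1",
            DegeneratePanelWarning,
            stacklevel=2,
        )
        return np.ones_like(dev.deltas)
    rho_m = config.resolution * dev.global_max
    return (dev.global_min + rho_m) / (dev.deltas + rho_m)


def grey_degree(coefficients: np.ndarray) -> np.ndarray:
    """Grey relational degree: time average of each coefficient row."""
    xi = np.asarray(coefficients, dtype=np.float64)
    if xi.size == 0:
        raise InvalidSeriesError("empty coefficient matrix")
    return xi.mean(axis=-1)


def pearson(x: np.ndarray | RawSeries, y: np.ndarray | RawSeries) -> float:
    """Sample Pearson correlation between two equal-length series."""
    if isinstance(x, RawSeries):
        x = x.values
    if isinstance(y, RawSeries):
        y = y.values
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InternalConsistencyError("need two equal-length series of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero-variance series")
    return float((xc * yc).sum() / denom)


def composite(
    gamma: np.ndarray, epsilon: np.ndarray, config: RelationalConfig
) -> np.ndarray:
    """Composite coefficient: phi * gamma + (1 - phi) * epsilon."""
    gamma = np.asarray(gamma, dtype=np.float64)
    epsilon = np.asarray(epsilon, dtype=np.float64)
    if gamma.shape != epsilon.shape:
        raise InternalConsistencyError("gamma and epsilon differ in shape")
    phi = config.blend
    return phi * gamma + (1 - phi) * epsilon


def comprehensive_index(block: np.ndarray) -> np.ndarray:
    """Column means of the three accident-indicator rows of one block.

    The published layout averages exactly three accident indicators
    (death toll, mortality per 100 million yuan of GDP, mortality per
    100,000 workers) per economic indicator.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] != 3:
        raise InvalidSeriesError(
            f"expected exactly 3 indicator rows, got shape {block.shape}"
        )
    return block.mean(axis=0)


def analyze_panel(panel: SeriesPanel, config: RelationalConfig | None = None) -> RelationalResult:
    """Full single-reference analysis: xi, gamma, epsilon and composite.

    GRA runs on the normalized panel; Pearson on the raw series (it is
    invariant to per-series positive scaling, so the choice is immaterial
    for ``initial_value`` normalization).
    """
    config = config or RelationalConfig()
    normalized = normalize_panel(panel, config)
    xi = relational_coefficients(deviations(normalized), config)
    gamma = grey_degree(xi)
    eps = np.array(
        [pearson(c.values, panel.reference.values) for c in panel.comparisons]
    )
    rho = composite(gamma, eps, config)
    return RelationalResult(
        coefficients=xi,
        grey_degree=gamma,
        pearson=eps,
        composite=rho,
        comparison_names=panel.comparison_names,
    )


@dataclass(frozen=True)
class CorrelationTable:
    """Three stacked blocks (grey, pearson, composite) of coefficients.

    ``frame`` is indexed by (block, indicator) with one column per
    comparison series; each block carries one row per reference indicator
    plus a comprehensive-index row holding the column means.
    """

    frame: pd.DataFrame
    config: RelationalConfig

    def block(self, name: str) -> pd.DataFrame:
        return self.frame.loc[name]

    def to_csv(self, path: str | Path) -> None:
        """Deterministic 6-decimal rendering, one row per (block, indicator)."""
        lines = ["block,indicator," + ",".join(self.frame.columns)]
        for (block, indicator), row in self.frame.iterrows():
            cells = ",".join(f"{v:.6f}" for v in row.to_numpy())
            lines.append(f"{block},{indicator},{cells}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def to_dict(self) -> dict:
        out: dict = {"columns": list(self.frame.columns), "blocks": {}}
        for block in self.frame.index.get_level_values(0).unique():
            sub = self.frame.loc[block]
            out["blocks"][block] = {
                str(ind): [float(v) for v in row.to_numpy()]
                for ind, row in sub.iterrows()
            }
        return out


def build_correlation_table(
    panels: Mapping[str, SeriesPanel] | Sequence[SeriesPanel],
    config: RelationalConfig | None = None,
) -> CorrelationTable:
    """Assemble the published-style table from one panel per reference.

    Every panel must share the same comparison names and years. For each
    block a comprehensive-index row (column mean over the reference
    indicators) is appended; with three reference indicators this is the
    standard comprehensive accident index.
    """
    config = config or RelationalConfig()
    if isinstance(panels, Mapping):
        named = list(panels.items())
    else:
        named = [(p.reference.name or f"reference_{i + 1}", p) for i, p in enumerate(panels)]
    if not named:
        raise InvalidSeriesError("need at least one panel")
    first = named[0][1]
    for _, panel in named[1:]:
        if panel.comparison_names != first.comparison_names:
            raise InternalConsistencyError("panels disagree on comparison names")
        if not np.array_equal(panel.reference.years, first.reference.years):
            raise InternalConsistencyError("panels disagree on years")

    results = {name: analyze_panel(panel, config) for name, panel in named}
    columns = list(first.comparison_names)
    rows: list[tuple[str, str]] = []
    data: list[np.ndarray] = []
    for block, attr in zip(BLOCKS, ("grey_degree", "pearson", "composite")):
        stacked = np.stack([getattr(results[name], attr) for name, _ in named])
        for (name, _), vector in zip(named, stacked):
            rows.append((block, name))
            data.append(vector)
        rows.append((block, COMPREHENSIVE_LABEL))
        if stacked.shape[0] == 3:
            data.append(comprehensive_index(stacked))
        else:
            data.append(stacked.mean(axis=0))
    frame = pd.DataFrame(
        np.stack(data),
        index=pd.MultiIndex.from_tuples(rows, names=["block", "indicator"]),
        columns=columns,
    )
    return CorrelationTable(frame=frame, config=config)


def read_panel_csv(
    path: str | Path, references: Sequence[str] | None = None
) -> dict[str, SeriesPanel]:
    """Read a wide panel CSV (``year,<col>,...``) into per-reference panels.

    ``references`` names the columns treated as reference indicators
    (default: the first data column); every remaining column becomes a
    comparison series shared by all panels.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 3 or frame.columns[0].strip().lower() != "year":
        raise DataError(
            f"{path}: expected 'year,<reference>,<comparison>,...' header"
        )
    years = frame.iloc[:, 0].to_numpy()
    names = list(frame.columns[1:])
    if references is None:
        references = [names[0]]
    missing = [r for r in references if r not in names]
    if missing:
        raise DataError(f"{path}: reference columns not found: {missing}")
    comp_names = [c for c in names if c not in references]
    if not comp_names:
        raise DataError(f"{path}: no comparison columns left")

    def col(name: str) -> RawSeries:
        try:
            return RawSeries(
                years=years, values=frame[name].to_numpy(dtype=np.float64), name=name
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, InvalidSeriesError):
                raise
            raise DataError(f"{path}: non-numeric column {name!r}") from exc

    comparisons = tuple(col(c) for c in comp_names)
    return {
        ref: SeriesPanel(reference=col(ref), comparisons=comparisons)
        for ref in references
    }
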