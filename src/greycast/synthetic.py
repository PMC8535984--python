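"""Seeded synthetic annual series for testing every pipeline stage.

Three generator kinds cover the data shapes the models target:

* ``economy_like`` — smooth multiplicative growth, the shape of national
  economic indicators (consumption, wages, research spending): a geometric
  trend with lognormal year-on-year noise. Noise is multiplicative so the
  series stays positive, mirroring how such indicators never dip below
  zero.
* ``accident_like`` — rise-then-decline annual counts whose cumulative sum
  follows the Gaussian-exponential cumulative form of the GGM(1,1) model,
  with multiplicative noise on the increments. Defaults put the peak near
  the first quarter of the series, the shape of a count series that climbs
  for a few years and then falls.
* ``grey_exact`` — the noise-free increments of the standard anchored
  Gaussian grey solution with given (a, b, mu, sigma); refitting the model
  to this output must recover the development coefficient.

All randomness flows from ``spec.seed`` through a dedicated
``numpy.random.default_rng`` stream; there is no global state, and a fixed
spec yields a bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .exceptions import GenerationError, InvalidSpecError
from .grey_core import GaussianSpec, predict_cumulative, restore_increments
from .relational import SeriesPanel
from .series import RawSeries

__all__ = ["SyntheticSpec", "generate", "generate_panel"]

Kind = Literal["economy_like", "accident_like", "grey_exact"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic annual series.

    ``growth`` is the annual multiplicative drift of ``economy_like``
    series (1.08 = 8% nominal growth, typical of the modelled economies);
    ``noise_sd`` the standard deviation of the lognormal noise on the log
    scale. ``a``, ``b``, ``mu``, ``sigma`` parameterize the Gaussian grey
    cumulative form for ``accident_like`` and ``grey_exact``; the defaults
    (a=0.1, mu=0, sigma=1) put the increment peak near k = sigma/sqrt(a),
    i.e. in the first quarter of a two-decade series.
    """

    kind: Kind
    n: int = 21
    seed: int = 0
    first_year: int = 2000
    first_value: float = 1000.0
    growth: float = 1.08
    noise_sd: float = 0.02
    a: float = 0.1
    b: float | None = None
    mu: float = 0.0
    sigma: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("economy_like", "accident_like", "grey_exact"):
            raise InvalidSpecError(f"unknown kind {self.kind!r}")
        if self.n < 4:
            raise InvalidSpecError(f"n must be >= 4, got {self.n}")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        if self.kind in ("accident_like", "grey_exact") and self.a == 0:
            raise InvalidSpecError("a must be nonzero for grey-shaped series")


def _grey_increments(spec: SyntheticSpec) -> np.ndarray:
    gauss = GaussianSpec(mu=spec.mu, sigma=spec.sigma)
    # default b: saturation level b/a sits well above the first value, so
    # increments stay positive over the whole window
    b = spec.b if spec.b is not None else spec.a * spec.first_value * 15.0
    cum = predict_cumulative(
        spec.first_value, spec.a, b, spec=gauss, k_max=spec.n, anchored=True
    )
    return restore_increments(cum)


def generate(spec: SyntheticSpec) -> RawSeries:
    """Generate one series from a spec; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "economy_like":
        k = np.arange(spec.n)
        values = spec.first_value * spec.growth**k
        if spec.noise_sd > 0:
            values = values * np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n))
    elif spec.kind == "accident_like":
        values = _grey_increments(spec)
        if spec.noise_sd > 0:
            values = values * np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n))
    else:  # grey_exact
        values = _grey_increments(spec)
    if not np.all(values > 0):
        raise GenerationError(
            f"spec {spec} produced non-positive values; adjust a/b or noise_sd"
        )
    name = spec.name or spec.kind
    return RawSeries.from_values(values, first_year=spec.first_year, name=name)


def generate_panel(
    reference: SyntheticSpec, comparisons: Sequence[SyntheticSpec]
) -> SeriesPanel:
    """Generate a reference plus comparison series on shared years.

    All specs must agree on ``n``; years are taken from the reference
    spec. A comparison spec identical to the reference spec (same kind,
    parameters and seed) reproduces the reference column exactly.
    """
    comps = list(comparisons)
    if any(c.n != reference.n for c in comps):
        raise InvalidSpecError("all specs must share the same n")
    ref_series = generate(reference)
    comp_series = tuple(
        generate(replace(c, first_year=reference.first_year)) for c in comps
    )
    return SeriesPanel(reference=ref_series, comparisons=comp_series)
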