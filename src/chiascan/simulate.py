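"""Forward simulator of meiosis I crossover formation and segregation.

Each homolog pair receives crossovers from two pathways:

* Class I (interference-sensitive): when enabled, an obligate crossover per
  pair plus an under-dispersed "extra" count whose variance/mean is the
  configured dispersion.  Interference is modeled at the count level — the
  cytological evidence this package analyses is purely count-distributional —
  so no spatial crossover placement is attempted.
* Class II (interference-insensitive): an independent Poisson(class2_rate)
  count per pair.  With Class I disabled (the MLH1-null regime) the per-cell
  chiasma total is exactly Poisson(n_pairs * class2_rate).

A pair with >= 1 crossover is a bivalent; an achiasmate pair yields two
univalents that segregate independently, landing balanced (one to each pole)
with probability 1/2.  Lagging chromosomes at anaphase I are drawn
Binomial(#univalents, p_lag).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .chiasma import ChiasmaDataset, MeiocyteObservation

__all__ = [
    "MeiosisParams",
    "SimulatedMeiocyte",
    "SimulationResult",
    "underdispersed_counts",
    "simulate",
    "simulate_meiocyte",
    "simulate_dataset",
    "calibrate_class2_rate",
]


@dataclass(frozen=True)
class MeiosisParams:
    """Parameters of the two-pathway crossover model.

    Attributes
    ----------
    n_pairs
        Homologous chromosome pairs (soybean: 20).
    class1_enabled
        Whether the interference-sensitive pathway operates (False in the
        MLH1-null regime).
    obligate_co
        Guarantee one Class I crossover per pair.  Wild-type soybean shows
        20/20 bivalents in every meiocyte ("20 +/- 0.00"), which only an
        obligate crossover reproduces.
    class1_mean_extra
        Mean non-obligate Class I crossovers per pair.
    class1_dispersion
        Variance/mean of the per-pair Class I count, in (0, 1]; values < 1
        encode interference-driven under-dispersion, 1 recovers a Poisson.
    class2_rate
        Poisson rate of Class II crossovers per pair.
    p_lag
        Probability that a univalent lags at anaphase I.
    seed
        Default RNG seed for this parameter set.
    """

    n_pairs: int = 20
    class1_enabled: bool = True
    obligate_co: bool = True
    class1_mean_extra: float = 0.0
    class1_dispersion: float = 1.0
    class2_rate: float = 0.0
    p_lag: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.class1_mean_extra < 0 or self.class2_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.class1_dispersion <= 1:
            raise ValueError("class1_dispersion must be in (0, 1]")
        if not 0 <= self.p_lag <= 1:
            raise ValueError("p_lag must be a probability")

    def with_seed(self, seed: int) -> "MeiosisParams":
        return replace(self, seed=seed)


@dataclass
class SimulatedMeiocyte:
    per_pair_co_counts: np.ndarray
    n_bivalents: int
    n_chiasmata: int
    daughter_balanced: bool
    n_lagging: int


@dataclass
class SimulationResult:
    """Vectorized outcome of many independent meiocytes."""

    params: MeiosisParams
    co_counts: np.ndarray  # (n_cells, n_pairs)
    daughter_balanced: np.ndarray  # (n_cells,) bool
    n_lagging: np.ndarray  # (n_cells,)

    @property
    def n_cells(self) -> int:
        return self.co_counts.shape[0]

    @property
    def n_bivalents(self) -> np.ndarray:
        return (self.co_counts >= 1).sum(axis=1)

    @property
    def n_chiasmata(self) -> np.ndarray:
        return self.co_counts.sum(axis=1)

    def to_dataset(self) -> ChiasmaDataset:
        biv = self.n_bivalents
        chi = self.n_chiasmata
        obs = [
            MeiocyteObservation(
                cell_id=f"sim_{i:05d}",
                n_bivalents=int(biv[i]),
                n_chiasmata=int(chi[i]),
                n_lagging=int(self.n_lagging[i]),
            )
            for i in range(self.n_cells)
        ]
        return ChiasmaDataset(obs)


def underdispersed_counts(
    mean: float, variance: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Non-negative integer draws with the requested mean and variance.

    Uses a three-point distribution on {k-1, k, k+1} with k = round(mean),
    which matches both moments exactly whenever the linear system is
    feasible (small variances, k >= 1).  Otherwise falls back to a clipped
    normal with stochastic rounding: the fractional part is resolved by a
    Bernoulli draw, which preserves the mean exactly (up to clipping at 0)
    while the variance is met only approximately.
    """
    if mean < 0 or variance < 0:
        raise ValueError("mean and variance must be >= 0")
    if mean == 0 and variance == 0:
        return np.zeros(size, dtype=int)
    k = int(np.round(mean))
    delta = mean - k
    p_plus = (variance + delta * delta + delta) / 2.0
    p_minus = (variance + delta * delta - delta) / 2.0
    if k >= 1 and p_plus >= 0 and p_minus >= 0 and p_plus + p_minus <= 1:
        u = rng.random(size)
        out = np.full(size, k, dtype=int)
        out[u < p_plus] = k + 1
        out[u > 1 - p_minus] = k - 1
        return out
    # fallback: stochastic rounding adds ~E[f(1-f)] <= 1/4 of variance,
    # compensated to first order by shrinking the normal variance by 1/6
    sigma = np.sqrt(max(variance - 1.0 / 6.0, 0.0))
    x = np.clip(rng.normal(mean, sigma, size), 0.0, None)
    base = np.floor(x)
    return (base + (rng.random(size) < (x - base))).astype(int)


def _draw_co_counts(
    params: MeiosisParams, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    shape = (n_cells, params.n_pairs)
    counts = np.zeros(shape, dtype=int)
    if params.class1_enabled:
        obligate = 1 if params.obligate_co else 0
        mean_total = obligate + params.class1_mean_extra
        if params.class1_dispersion == 1.0 and not params.obligate_co:
            # exactly Poisson: the pathway becomes indistinguishable from
            # Class II, the no-interference limit
            counts += rng.poisson(params.class1_mean_extra, size=shape)
        else:
            target_var = params.class1_dispersion * mean_total
            counts += obligate + underdispersed_counts(
                params.class1_mean_extra, target_var, shape, rng
            )
    if params.class2_rate > 0:
        counts += rng.poisson(params.class2_rate, size=shape)
    return counts


def simulate(
    params: MeiosisParams,
    n_cells: int,
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Simulate ``n_cells`` independent meiocytes.

    Deterministic for a fixed seed: when ``rng`` is omitted a fresh
    generator is created from ``params.seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    counts = _draw_co_counts(params, n_cells, rng)
    univalent_pair = counts == 0
    # each achiasmate pair balanced with probability 1/2, independently
    pair_balanced = ~univalent_pair | (rng.random(counts.shape) < 0.5)
    daughter_balanced = pair_balanced.all(axis=1)
    n_univalents = 2 * univalent_pair.sum(axis=1)
    n_lagging = rng.binomial(n_univalents, params.p_lag)
    return SimulationResult(
        params=params,
        co_counts=counts,
        daughter_balanced=daughter_balanced,
        n_lagging=n_lagging,
    )


def simulate_meiocyte(
    params: MeiosisParams, rng: Optional[np.random.Generator] = None
) -> SimulatedMeiocyte:
    """Simulate a single meiocyte."""
    res = simulate(params, 1, rng=rng)
    return SimulatedMeiocyte(
        per_pair_co_counts=res.co_counts[0],
        n_bivalents=int(res.n_bivalents[0]),
        n_chiasmata=int(res.n_chiasmata[0]),
        daughter_balanced=bool(res.daughter_balanced[0]),
        n_lagging=int(res.n_lagging[0]),
    )


def simulate_dataset(
    params: MeiosisParams,
    n_cells: int,
    rng: Optional[np.random.Generator] = None,
) -> ChiasmaDataset:
    """Batch wrapper returning a cytology dataset ready for analysis."""
    return simulate(params, n_cells, rng=rng).to_dataset()


def calibrate_class2_rate(target: str, value: float, n_pairs: int = 20) -> float:
    """Invert the Class-II-only model for a per-pair Poisson rate.

    With only Class II crossovers, mean bivalents = n_pairs*(1 - e^-rate)
    and mean chiasmata = n_pairs*rate, so:

    * ``target="mean_bivalents"``: rate = -ln(1 - value/n_pairs)
    * ``target="mean_chiasmata"``: rate = value/n_pairs
    """
    if target == "mean_bivalents":
        if not 0 < value < n_pairs:
            raise ValueError("bivalent target must lie in (0, n_pairs)")
        return float(-np.log(1.0 - value / n_pairs))
    if target == "mean_chiasmata":
        if value <= 0:
            raise ValueError("chiasma target must be > 0")
        return float(value / n_pairs)
    raise ValueError(f"unknown target {target!r}")
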