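"""Fertility algebra under random univalent segregation, and segregation tests.

When a homolog pair forms no chiasma it persists as two univalents that
segregate independently at anaphase I; each pair reaches both poles
(a balanced outcome) with probability 1/2.  With u achiasmate pairs the
chance of a fully balanced daughter set is (1/2)^u, which collapses fast for
a large karyotype: soybean with a mean of 6.4 bivalents out of 20 pairs
leaves u = 13.6 and a balanced-set chance of about 0.008%.

Also here: the chi-square test of observed phenotype counts against a
Mendelian ratio (3:1 by default) and the fold-change arithmetic used for
treated/untreated aberrant-mitosis frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .chiasma import round_half_up

__all__ = [
    "KaryotypeParams",
    "SegregationCounts",
    "FertilityPrediction",
    "p_balanced",
    "p_balanced_percent",
    "expected_balanced_from_bivalents",
    "chi_square_ratio_test",
    "ChiSquareResult",
    "fold_change",
]


@dataclass
class KaryotypeParams:
    """Karyotype size in homologous pairs (soybean: 20)."""

    n_pairs: int = 20

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class SegregationCounts:
    """Observed counts of two phenotype classes with an expected ratio."""

    n_class_a: int
    n_class_b: int
    expected_ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_class_a < 0 or self.n_class_b < 0:
            raise ValueError("counts must be non-negative")
        if self.n_class_a + self.n_class_b < 1:
            raise ValueError("need at least one observation")
        if min(self.expected_ratio) <= 0:
            raise ValueError("ratio components must be > 0")

    @property
    def total(self) -> int:
        return self.n_class_a + self.n_class_b


@dataclass
class FertilityPrediction:
    """Probability of a balanced chromosome set given effective univalents."""

    u_effective: float
    p_balanced: float

    def as_percent(self, ndigits: int = 2) -> float:
        return round_half_up(100.0 * self.p_balanced, ndigits)


def p_balanced(u_pairs: float) -> float:
    """Probability that u univalent pairs all segregate in a balanced way.

    Each achiasmate pair independently sends its two univalents to opposite
    poles with probability 1/2, so the balanced-set probability is
    (1/2)^u.  ``u_pairs`` may be fractional (plug-in of a mean).
    """
    if u_pairs < 0:
        raise ValueError("u_pairs must be >= 0")
    return float(0.5 ** u_pairs)


def p_balanced_percent(u_pairs: float, ndigits: int = 2) -> float:
    """(1/2)^u as a percentage, rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * p_balanced(u_pairs), ndigits)


def expected_balanced_from_bivalents(
    karyotype: KaryotypeParams,
    mean_bivalents: float,
    mode: str = "plugin",
    bivalent_counts: Optional[Sequence[int]] = None,
) -> FertilityPrediction:
    """Balanced-daughter probability from an observed bivalent frequency.

    plugin mode (default) plugs the mean univalent-pair count
    u = n_pairs - mean_bivalents into (1/2)^u.  distributional mode averages
    2^-(n_pairs - b) over the per-cell counts b; by Jensen's inequality this
    exact expectation is >= the plug-in value, with equality only when every
    cell has the same bivalent count.
    """
    n_pairs = karyotype.n_pairs
    if not 0 <= mean_bivalents <= n_pairs:
        raise ValueError(f"mean_bivalents must lie in [0, {n_pairs}]")
    if mode == "plugin":
        u = n_pairs - mean_bivalents
        return FertilityPrediction(u_effective=u, p_balanced=p_balanced(u))
    if mode == "distributional":
        if bivalent_counts is None:
            raise ValueError("distributional mode needs per-cell bivalent counts")
        b = np.asarray(bivalent_counts, dtype=float)
        if np.any(b < 0) or np.any(b > n_pairs):
            raise ValueError("bivalent counts out of range")
        p = float(np.mean(0.5 ** (n_pairs - b)))
        return FertilityPrediction(u_effective=n_pairs - float(b.mean()), p_balanced=p)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    critical_value: float
    consistent: bool
    expected: tuple[float, float]


def chi_square_ratio_test(
    counts: SegregationCounts, alpha: float = 0.05, yates: bool = False
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of two class counts against a stated ratio.

    chi2 = sum (O_i - E_i)^2 / E_i with expected counts from the ratio;
    df = 1.  ``consistent`` is True when chi2 falls below the alpha critical
    value (3.84 at alpha = 0.05), i.e. the observed segregation does not
    contradict the hypothesised Mendelian ratio.  No continuity correction
    by default; ``yates=True`` subtracts 0.5 from each |O - E|.
    """
    a, b = counts.expected_ratio
    total = counts.total
    expected = (total * a / (a + b), total * b / (a + b))
    if min(expected) <= 0:
        raise ValueError("expected count of zero in a class")
    observed = (counts.n_class_a, counts.n_class_b)
    dev = [abs(o - e) for o, e in zip(observed, expected)]
    if yates:
        dev = [max(d - 0.5, 0.0) for d in dev]
    chi2 = float(sum(d * d / e for d, e in zip(dev, expected)))
    df = 1
    crit = float(stats.chi2.ppf(1 - alpha, df))
    p = float(stats.chi2.sf(chi2, df))
    return ChiSquareResult(
        chi2=chi2,
        df=df,
        p_value=p,
        critical_value=crit,
        consistent=bool(chi2 < crit),
        expected=expected,
    )


def fold_change(treated_freq: float, untreated_freq: float) -> float:
    """treated/untreated ratio, reported to 2 decimals (e.g. 2.67/1.19 -> 2.24)."""
    if untreated_freq <= 0:
        raise ValueError("untreated_freq must be > 0")
    return round_half_up(treated_freq / untreated_freq, 2)
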