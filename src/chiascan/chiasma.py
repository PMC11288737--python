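"""Chiasma-count statistics and crossover-interference inference.

Cytological chiasma counts per meiocyte carry a distributional signature of
crossover interference: interference-sensitive (Class I) crossovers produce
under-dispersed counts (variance/mean well below 1), whereas a residuum of
interference-insensitive (Class II) crossovers is compatible with a Poisson
distribution.  This module turns per-cell counts into that inference: summary
statistics, the predicted Poisson distribution, a one-sample
Kolmogorov-Smirnov goodness-of-fit test on the discrete support (with a
parametric-bootstrap p-value as the default, since the asymptotic KS law is
misspecified for discrete data with an estimated rate), and the
percent-reduction arithmetic used to compare mutant and wild type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov

__all__ = [
    "MeiocyteObservation",
    "ChiasmaDataset",
    "GoodnessOfFitResult",
    "chiasmata_from_morphology",
    "summarize",
    "percent_reduction",
    "predicted_poisson_counts",
    "poisson_support_max",
    "expected_observed_table",
    "ks_statistic_discrete",
    "ks_goodness_of_fit",
    "read_cytology_table",
    "round_half_up",
]

#: homologous chromosome pairs in soybean (2n = 40)
SOYBEAN_N_PAIRS = 20


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed values are rounded.

    ``round()`` uses banker's rounding (3.125 -> 3.12); reported percentages
    here follow half-up (3.125 -> 3.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def chiasmata_from_morphology(
    n_ring: int, n_rod: int, n_univalent_pairs: int = 0
) -> int:
    """Chiasma count implied by bivalent morphology.

    Ring bivalents (chiasmata in both arms) score 2, rod bivalents (one arm)
    score 1, univalent pairs score 0 — the standard cytogenetic convention.

    Parameters
    ----------
    n_ring, n_rod, n_univalent_pairs
        Non-negative counts of each pair class in one meiocyte.
    """
    for name, v in (
        ("n_ring", n_ring),
        ("n_rod", n_rod),
        ("n_univalent_pairs", n_univalent_pairs),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return 2 * int(n_ring) + int(n_rod)


@dataclass
class MeiocyteObservation:
    """One meiocyte's cytology: bivalent count, chiasma count, laggards."""

    cell_id: str
    n_bivalents: int
    n_chiasmata: int
    n_ring_bivalents: Optional[int] = None
    n_rod_bivalents: Optional[int] = None
    n_lagging: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_bivalents < 0 or self.n_chiasmata < 0:
            raise ValueError("counts must be non-negative")
        if self.n_chiasmata < self.n_bivalents:
            # every bivalent is held together by at least one chiasma
            raise ValueError(
                f"cell {self.cell_id}: n_chiasmata ({self.n_chiasmata}) < "
                f"n_bivalents ({self.n_bivalents})"
            )
        if self.n_ring_bivalents is not None and self.n_rod_bivalents is not None:
            if self.n_bivalents != self.n_ring_bivalents + self.n_rod_bivalents:
                raise ValueError(
                    f"cell {self.cell_id}: n_bivalents != n_ring + n_rod"
                )
            expected = chiasmata_from_morphology(
                self.n_ring_bivalents, self.n_rod_bivalents
            )
            if self.n_chiasmata != expected:
                raise ValueError(
                    f"cell {self.cell_id}: n_chiasmata ({self.n_chiasmata}) "
                    f"inconsistent with morphology (2*ring + rod = {expected})"
                )


@dataclass
class ChiasmaDataset:
    """A collection of per-meiocyte counts with summary statistics."""

    observations: list[MeiocyteObservation] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls, chiasma_counts: Iterable[int], bivalent_counts: Optional[Iterable[int]] = None
    ) -> "ChiasmaDataset":
        chiasma_counts = list(chiasma_counts)
        if bivalent_counts is None:
            # without morphology we only know 0 <= bivalents <= chiasmata
            bivalent_counts = [0] * len(chiasma_counts)
        obs = [
            MeiocyteObservation(cell_id=f"cell_{i:04d}", n_bivalents=int(b), n_chiasmata=int(c))
            for i, (b, c) in enumerate(zip(bivalent_counts, chiasma_counts, strict=True))
        ]
        return cls(obs)

    @property
    def n_cells(self) -> int:
        return len(self.observations)

    @property
    def chiasma_counts(self) -> np.ndarray:
        return np.array([o.n_chiasmata for o in self.observations], dtype=int)

    @property
    def bivalent_counts(self) -> np.ndarray:
        return np.array([o.n_bivalents for o in self.observations], dtype=int)

    @property
    def lagging_counts(self) -> np.ndarray:
        return np.array(
            [o.n_lagging if o.n_lagging is not None else 0 for o in self.observations],
            dtype=int,
        )

    @property
    def mean(self) -> float:
        return float(np.mean(self.chiasma_counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.chiasma_counts, ddof=1))

    @property
    def dispersion_index(self) -> float:
        m = self.mean
        return float(np.var(self.chiasma_counts, ddof=1) / m) if m > 0 else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [o.cell_id for o in self.observations],
                "n_ring": [o.n_ring_bivalents for o in self.observations],
                "n_rod": [o.n_rod_bivalents for o in self.observations],
                "n_bivalents": self.bivalent_counts,
                "n_chiasmata": self.chiasma_counts,
                "n_lagging": [o.n_lagging for o in self.observations],
            }
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def read_cytology_table(path, sep: Optional[str] = None) -> ChiasmaDataset:
    """Read a delimited cytology table into a :class:`ChiasmaDataset`.

    Expected columns: ``cell_id`` and either ``n_chiasmata`` (plus optional
    ``n_bivalents``) or the morphology pair ``n_ring``/``n_rod``, from which
    chiasma and bivalent counts are derived.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    cols = set(df.columns)
    if "cell_id" not in cols:
        raise ValueError("cytology table must have a 'cell_id' column")
    has_morph = {"n_ring", "n_rod"} <= cols
    if not has_morph and "n_chiasmata" not in cols:
        raise ValueError("need either n_chiasmata or n_ring/n_rod columns")
    obs = []
    for row in df.itertuples(index=False):
        ring = rod = None
        if has_morph and not (pd.isna(row.n_ring) or pd.isna(row.n_rod)):
            ring, rod = int(row.n_ring), int(row.n_rod)
        if "n_chiasmata" in cols and not pd.isna(getattr(row, "n_chiasmata", np.nan)):
            chi = int(row.n_chiasmata)
        elif ring is not None:
            chi = chiasmata_from_morphology(ring, rod)
        else:
            raise ValueError(f"cell {row.cell_id}: no chiasma count or morphology")
        if "n_bivalents" in cols and not pd.isna(getattr(row, "n_bivalents", np.nan)):
            biv = int(row.n_bivalents)
        elif ring is not None:
            biv = ring + rod
        else:
            biv = 0
        lag = None
        if "n_lagging" in cols and not pd.isna(getattr(row, "n_lagging", np.nan)):
            lag = int(row.n_lagging)
        obs.append(
            MeiocyteObservation(
                cell_id=str(row.cell_id),
                n_bivalents=biv,
                n_chiasmata=chi,
                n_ring_bivalents=ring,
                n_rod_bivalents=rod,
                n_lagging=lag,
            )
        )
    return ChiasmaDataset(obs)


def summarize(dataset: ChiasmaDataset) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and dispersion index of a dataset.

    The dispersion index (variance/mean) is the interference diagnostic:
    ~1 for Poisson counts, << 1 under crossover interference.
    """
    if dataset.n_cells == 0:
        raise ValueError("empty dataset")
    if dataset.n_cells < 2:
        raise ValueError("sample SD undefined for a single cell")
    return dataset.mean, dataset.sd, dataset.dispersion_index


def percent_reduction(reference_mean: float, mutant_mean: float) -> float:
    """Percent decrease of ``mutant_mean`` relative to ``reference_mean``.

    Reported to 2 decimals, e.g. means (38.50, 8.41) -> 78.16.
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    return round_half_up(100.0 * (reference_mean - mutant_mean) / reference_mean, 2)


def poisson_support_max(lam: float) -> int:
    """Default truncation point for tabulating a Poisson: lam + 10*sqrt(lam)."""
    return int(np.ceil(lam + 10.0 * np.sqrt(lam)))


def predicted_poisson_counts(
    lam: float, n_cells: int, support_max: Optional[int] = None
) -> np.ndarray:
    """Expected number of cells with k chiasmata under Poisson(lam).

    Entry k is ``n_cells * pmf(k)`` for k = 0..support_max, with the tail
    mass beyond the truncation folded into the last bin so the vector sums
    exactly to ``n_cells``.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if support_max is None:
        support_max = poisson_support_max(lam)
    k = np.arange(support_max + 1)
    pmf = stats.poisson.pmf(k, lam)
    pmf[-1] += stats.poisson.sf(support_max, lam)  # fold tail into last bin
    return n_cells * pmf


def expected_observed_table(
    counts: Sequence[int], lam: Optional[float] = None
) -> pd.DataFrame:
    """Observed vs Poisson-predicted cell counts per chiasma number.

    Suitable for plotting observed (dots) against predicted (squares)
    distributions.  ``lam`` defaults to the sample mean.
    """
    counts = np.asarray(counts, dtype=int)
    if lam is None:
        lam = float(counts.mean())
    kmax = max(int(counts.max()), poisson_support_max(lam))
    observed = np.bincount(counts, minlength=kmax + 1)
    expected = predicted_poisson_counts(lam, len(counts), support_max=kmax)
    return pd.DataFrame(
        {"n_chiasmata": np.arange(kmax + 1), "observed": observed, "expected": expected}
    )


def ks_statistic_discrete(counts: np.ndarray, lam: float) -> float:
    """Sup-norm distance between the empirical CDF of integer ``counts`` and
    the Poisson(lam) CDF, evaluated at every integer of the support.

    For integer data the supremum over the real line is attained at an
    integer <= max(counts), so evaluating at k = 0..max(counts) is exact.
    """
    counts = np.asarray(counts, dtype=int)
    kmax = int(counts.max())
    k = np.arange(kmax + 1)
    ecdf = np.searchsorted(np.sort(counts), k, side="right") / counts.size
    model = stats.poisson.cdf(k, lam)
    return float(np.abs(ecdf - model).max())


def _ks_statistics_rows(count_matrix: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Vectorized D statistic per row, each row against Poisson(lams[row])."""
    b, n = count_matrix.shape
    kmax = int(count_matrix.max())
    k = np.arange(kmax + 1)
    # row-wise empirical CDF via counting values <= k
    ecdf = (count_matrix[:, :, None] <= k).sum(axis=1) / n
    model = stats.poisson.cdf(k[None, :], lams[:, None])
    return np.abs(ecdf - model).max(axis=1)


@dataclass
class GoodnessOfFitResult:
    """Kolmogorov-Smirnov goodness-of-fit outcome against Poisson(lam_hat)."""

    statistic_D: float
    p_value: float
    method: str
    lam_hat: float
    n: int
    alpha: float
    reject_at_alpha: bool

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "statistic_D": self.statistic_D,
                "p_value": self.p_value,
                "method": self.method,
                "lam_hat": self.lam_hat,
                "n": self.n,
                "alpha": self.alpha,
                "reject_at_alpha": self.reject_at_alpha,
            }
        )


def ks_goodness_of_fit(
    counts: Sequence[int],
    lam: Optional[float] = None,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.01,
    batch: int = 500,
) -> GoodnessOfFitResult:
    """One-sample KS test of integer counts against a Poisson distribution.

    Parameters
    ----------
    counts
        Per-cell chiasma counts; at least 5 cells.
    lam
        Poisson rate; estimated by the sample mean when omitted.
    method
        ``"bootstrap"`` (default): parametric bootstrap with the rate
        re-estimated on each resample, the correct calibration for a
        discrete null with an estimated parameter.  ``"asymptotic"``: the
        continuous-case limiting distribution evaluated at sqrt(n)*D; kept
        as a compatibility mode (conservative for discrete data, and blind
        to the estimation of lam).
    n_boot, seed
        Bootstrap replicates B and RNG seed; p = (1 + #{D* >= D}) / (B + 1).
    alpha
        Rejection level; 0.01 by default, the level at which under-dispersed
        wild-type counts reject Poisson while Class-II-only residual counts
        do not.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size < 5:
        raise ValueError("need at least 5 observations for a KS test")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lam_fixed = lam is not None
    lam_hat = float(lam) if lam_fixed else float(counts.mean())
    if lam_hat <= 0:
        if method == "bootstrap":
            warnings.warn("all counts are zero: degenerate data, p = 1")
            return GoodnessOfFitResult(0.0, 1.0, method, 0.0, counts.size, alpha, False)
        raise ValueError("cannot test a zero-mean sample against Poisson")

    d_obs = ks_statistic_discrete(counts, lam_hat)
    n = counts.size
    if method == "asymptotic":
        p = float(kolmogorov(np.sqrt(n) * d_obs))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        exceed = 0
        done = 0
        while done < n_boot:
            b = min(batch, n_boot - done)
            resamples = rng.poisson(lam_hat, size=(b, n))
            lams = np.full(b, lam_hat) if lam_fixed else resamples.mean(axis=1)
            lams = np.maximum(lams, 1e-12)
            d_star = _ks_statistics_rows(resamples, lams)
            exceed += int((d_star >= d_obs).sum())
            done += b
        p = (1 + exceed) / (n_boot + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GoodnessOfFitResult(
        statistic_D=d_obs,
        p_value=p,
        method=method,
        lam_hat=lam_hat,
        n=n,
        alpha=alpha,
        reject_at_alpha=bool(p < alpha),
    )
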