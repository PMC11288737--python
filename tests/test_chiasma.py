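"""Chiasma-count statistics: morphology scoring, summaries, Poisson tables
and the discrete Kolmogorov-Smirnov goodness-of-fit test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chiascan import chiasma


class TestMorphologyScoring:
    @pytest.mark.parametrize(
        "ring,rod,univ,expected",
        [
            (0, 0, 20, 0),  # fully asynaptic cell
            (20, 0, 0, 40),  # all ring bivalents
            (18, 2, 0, 38),  # near the wild-type mean
            (0, 7, 3, 7),
        ],
    )
    def test_ring_scores_two_rod_scores_one(self, ring, rod, univ, expected):
        assert chiasma.chiasmata_from_morphology(ring, rod, univ) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            chiasma.chiasmata_from_morphology(-1, 0, 0)

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    def test_additive_in_ring_and_rod_counts(self, a, b, c, d):
        whole = chiasma.chiasmata_from_morphology(a + b, c + d)
        parts = chiasma.chiasmata_from_morphology(a, c) + chiasma.chiasmata_from_morphology(b, d)
        assert whole == parts


class TestSummaries:
    def test_constant_counts_have_zero_dispersion(self):
        ds = chiasma.ChiasmaDataset.from_counts([8, 8, 8])
        assert chiasma.summarize(ds) == (8.0, 0.0, 0.0)

    def test_two_cell_hand_arithmetic(self):
        mean, sd, disp = chiasma.summarize(chiasma.ChiasmaDataset.from_counts([7, 9]))
        assert mean == 8.0
        assert sd == pytest.approx(np.sqrt(2), abs=1e-12)
        assert disp == pytest.approx(0.25, abs=1e-12)

    def test_printed_wildtype_moments_imply_strong_underdispersion(self):
        # mean 38.50 and SD 1.41 give variance/mean = 1.41^2/38.50
        assert 1.41**2 / 38.50 == pytest.approx(0.0516, abs=5e-4)

    @pytest.mark.parametrize("counts", [[], [5]])
    def test_too_few_cells_rejected(self, counts):
        with pytest.raises(ValueError):
            chiasma.summarize(chiasma.ChiasmaDataset.from_counts(counts))


class TestPercentReduction:
    @pytest.mark.parametrize(
        "ref,mut,expected",
        [(38.50, 8.41, 78.16), (20, 6.40, 68.00), (7.3, 7.3, 0.00)],
    )
    def test_reported_to_two_decimals(self, ref, mut, expected):
        assert chiasma.percent_reduction(ref, mut) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            chiasma.percent_reduction(0, 1)


class TestPredictedPoissonCounts:
    def test_closed_form_at_lambda_one(self):
        counts = chiasma.predicted_poisson_counts(1.0, 100)
        assert counts[0] == pytest.approx(100 * np.exp(-1), abs=1e-9)

    def test_tiny_lambda_concentrates_at_zero(self):
        counts = chiasma.predicted_poisson_counts(1e-9, 50)
        assert counts[0] == pytest.approx(50, abs=1e-6)

    def test_tail_folding_preserves_total(self):
        counts = chiasma.predicted_poisson_counts(8.41, 158, support_max=30)
        assert counts.sum() == pytest.approx(158, abs=0.01)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            chiasma.predicted_poisson_counts(0.0, 10)

    @given(lam=st.floats(0.01, 60.0), n=st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_scaled_table_is_a_pmf(self, lam, n):
        counts = chiasma.predicted_poisson_counts(lam, n)
        assert np.all(counts >= 0)
        assert counts.sum() / n == pytest.approx(1.0, abs=1e-9)

    def test_expected_observed_table_aligns_supports(self):
        tab = chiasma.expected_observed_table([3, 4, 4, 5, 8], lam=4.8)
        assert tab["observed"].sum() == 5
        assert tab["expected"].sum() == pytest.approx(5, abs=1e-9)
        assert tab.loc[4, "observed"] == 2


def _brute_force_D(counts, lam):
    """Independent oracle: explicit sup over every integer of the support."""
    counts = np.asarray(counts)
    best = 0.0
    for k in range(int(counts.max()) + 1):
        ecdf = np.mean(counts <= k)
        best = max(best, abs(ecdf - stats.poisson.cdf(k, lam)))
    return best


class TestKsStatistic:
    def test_three_point_example_against_hand_cdf(self):
        # counts [0,1,2] vs Poisson(1): max of |1/3-F(0)|, |2/3-F(1)|, |1-F(2)|
        f = stats.poisson.cdf([0, 1, 2], 1.0)
        expected = max(abs(1 / 3 - f[0]), abs(2 / 3 - f[1]), abs(1 - f[2]))
        assert expected == pytest.approx(0.0803, abs=5e-5)
        d = chiasma.ks_statistic_discrete(np.array([0, 1, 2]), 1.0)
        assert d == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_small_datasets(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 51)
        lam = rng.uniform(0.2, 40.0)
        counts = rng.poisson(lam, n)
        d = chiasma.ks_statistic_discrete(counts, counts.mean() or 1.0)
        assert d == pytest.approx(_brute_force_D(counts, counts.mean() or 1.0), abs=1e-12)


class TestKsGoodnessOfFit:
    def test_poisson_data_large_sample_not_rejected(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(8.41, 5000)
        res = chiasma.ks_goodness_of_fit(counts, method="asymptotic")
        assert res.statistic_D < 0.02
        assert not res.reject_at_alpha

    def test_bootstrap_p_within_bounds_and_deterministic(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(8.41, 158)
        r1 = chiasma.ks_goodness_of_fit(counts, seed=5, n_boot=500)
        r2 = chiasma.ks_goodness_of_fit(counts, seed=5, n_boot=500)
        assert r1.p_value == r2.p_value
        assert 1 / 501 <= r1.p_value <= 1.0

    def test_fixed_lambda_is_respected(self):
        counts = np.array([0, 1, 2, 3, 4])
        res = chiasma.ks_goodness_of_fit(counts, lam=1.0, method="asymptotic")
        assert res.lam_hat == 1.0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            chiasma.ks_goodness_of_fit([1, 2, 3])

    def test_all_zero_counts_degenerate(self):
        with pytest.warns(UserWarning):
            res = chiasma.ks_goodness_of_fit([0] * 10, method="bootstrap")
        assert res.p_value == 1.0
        assert not res.reject_at_alpha


class TestCytologyTable:
    def test_round_trip_with_morphology(self, tmp_path):
        df = pd.DataFrame(
            {
                "cell_id": ["c1", "c2"],
                "n_ring": [18, 20],
                "n_rod": [2, 0],
                "n_bivalents": [20, 20],
                "n_chiasmata": [38, 40],
                "n_lagging": [0, 1],
            }
        )
        path = tmp_path / "cyt.csv"
        df.to_csv(path, index=False)
        ds = chiasma.read_cytology_table(path)
        assert list(ds.chiasma_counts) == [38, 40]
        assert list(ds.bivalent_counts) == [20, 20]
        assert ds.observations[1].n_lagging == 1

    def test_chiasmata_derived_from_morphology_when_absent(self, tmp_path):
        path = tmp_path / "cyt.tsv"
        path.write_text("cell_id\tn_ring\tn_rod\nc1\t18\t2\n")
        ds = chiasma.read_cytology_table(path)
        assert ds.observations[0].n_chiasmata == 38
        assert ds.observations[0].n_bivalents == 20

    def test_morphology_inconsistency_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cell_id,n_ring,n_rod,n_bivalents,n_chiasmata\nc1,18,2,20,37\n")
        with pytest.raises(ValueError):
            chiasma.read_cytology_table(path)

    def test_chiasmata_below_bivalents_rejected(self):
        with pytest.raises(ValueError):
            chiasma.MeiocyteObservation("c1", n_bivalents=5, n_chiasmata=4)
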