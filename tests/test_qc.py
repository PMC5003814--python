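import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_values
from oracles import cumulative_oracle
from proteoage import (
    cross_omics_correlation,
    cumulative_abundance,
    dynamic_range,
    localization_profile,
    replicate_correlation,
    replicate_pca,
)
from proteoage.qc import median_protein_intensity
from proteoage.simulate import COMPARTMENTS, simulate_fraction_table


def _matrix_with_reps(rep_vectors):
    arr = np.column_stack(rep_vectors)
    return matrix_from_values({p: arr for p in ("MH", "LM", "LH")})


class TestReplicateCorrelation:
    def test_identical_replicates_give_unit_correlation(self):
        v = np.array([0.1, -0.4, 0.8, 1.2, -0.3])
        _, median_r = replicate_correlation(_matrix_with_reps([v, v, v]))
        assert median_r == pytest.approx(1.0)

    def test_negated_replicate_gives_minus_one(self):
        v = np.array([0.1, -0.4, 0.8, 1.2])
        table, _ = replicate_correlation(_matrix_with_reps([v, -v]))
        assert table["r"].to_numpy() == pytest.approx(-1.0)

    def test_matches_hand_computed_covariance_quotient(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        table, _ = replicate_correlation(_matrix_with_reps([x, y]))
        assert table["r"].to_numpy() == pytest.approx(11.0 / np.sqrt(130.0))

    def test_fewer_than_three_shared_values_is_undefined(self):
        a = np.array([0.1, 0.2, np.nan, np.nan])
        b = np.array([0.1, np.nan, 0.3, 0.4])
        table, _ = replicate_correlation(_matrix_with_reps([a, b]))
        assert table["r"].isna().all()


class TestReplicatePCA:
    def test_identical_replicates_collapse_to_origin(self):
        v = np.array([0.5, -0.2, 0.9, 0.0])
        coords, _ = replicate_pca(_matrix_with_reps([v, v, v]))
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-12)

    def test_explained_variance_fractions_are_nonincreasing(self, small_matrix):
        _, evr = replicate_pca(small_matrix)
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-12

    def test_leading_variance_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4))
        matrix = matrix_from_values({"MH": x.T, "LM": x.T, "LH": x.T})
        coords, evr = replicate_pca(matrix, n_components=3)
        xc3 = np.hstack([x] * 3) - np.hstack([x] * 3).mean(axis=0)
        eigs = np.linalg.eigvalsh(xc3 @ xc3.T)[::-1]
        assert coords["PC1"].to_numpy().var() * 3 == pytest.approx(eigs[0])
        np.testing.assert_allclose(evr, eigs[: len(evr)] / eigs.sum(), atol=1e-10)

    def test_full_rank_coordinates_preserve_pairwise_distances(self, small_matrix):
        coords, _ = replicate_pca(small_matrix, n_components=3)
        # rebuild the centered feature matrix the same way
        blocks = []
        for pair in ("MH", "LM", "LH"):
            frame = small_matrix.pair_frame(pair).dropna(axis=0)
            blocks.append(frame.to_numpy().T)
        x = np.hstack(blocks)
        xc = x - x.mean(axis=0)
        for i in range(len(xc)):
            for j in range(i + 1, len(xc)):
                d_data = np.linalg.norm(xc[i] - xc[j])
                d_pca = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
                assert d_pca == pytest.approx(d_data, abs=1e-9)

    def test_proteins_as_observations_flag(self, small_matrix):
        coords, _ = replicate_pca(small_matrix, observations="proteins")
        assert len(coords) > small_matrix.n_replicates


class TestCumulativeAbundance:
    def test_top_fraction_and_rank_queries(self):
        curve = cumulative_abundance(
            pd.Series({"a": 75.0, "b": 15.0, "c": 10.0})
        )
        assert curve.top_n_mass_fraction(1) == pytest.approx(0.75)
        assert curve.n_for_mass_fraction(0.9) == 2
        assert curve.cumulative_fraction[-1] == pytest.approx(1.0)

    def test_matches_sort_and_cumsum_oracle(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.lognormal(7, 2, size=1000))
        curve = cumulative_abundance(vals)
        np.testing.assert_allclose(
            curve.cumulative_fraction, cumulative_oracle(vals), atol=1e-12
        )

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.lognormal(5, 1, 50), index=[f"p{i}" for i in range(50)])
        shuffled = vals.sample(frac=1, random_state=3)
        np.testing.assert_allclose(
            cumulative_abundance(vals).cumulative_fraction,
            cumulative_abundance(shuffled).cumulative_fraction,
        )

    def test_rank_query_is_monotone_in_mass_fraction(self):
        rng = np.random.default_rng(2)
        curve = cumulative_abundance(pd.Series(rng.lognormal(5, 2, 200)))
        ranks = [curve.n_for_mass_fraction(q) for q in np.linspace(0.05, 1, 20)]
        assert (np.diff(ranks) >= 0).all()

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            cumulative_abundance(pd.Series([0.0, 0.0]))


class TestDynamicRange:
    def test_decade_arithmetic(self):
        assert dynamic_range([1.0, 10.0]) == pytest.approx(1.0)
        assert dynamic_range([5.0, 5.0, 5.0]) == pytest.approx(0.0)

    def test_trimmed_span_not_larger_than_raw(self, small_dataset):
        tables, _ = small_dataset
        med = median_protein_intensity(tables)
        raw = dynamic_range(med)
        trimmed = dynamic_range(med, percentiles=(0.1, 99.9))
        assert trimmed <= raw

    def test_trimmed_estimate_tracks_generator_truth(self, small_dataset):
        tables, truth = small_dataset
        med = median_protein_intensity(tables.copy())
        trimmed = dynamic_range(med, percentiles=(1, 99.9))
        expected = np.percentile(
            truth.proteins["log10_intensity"], 99.9
        ) - np.percentile(truth.proteins["log10_intensity"], 1)
        assert trimmed == pytest.approx(expected, abs=0.35)


class TestLocalizationProfile:
    def test_proportions_and_predominant_call(self):
        table = pd.DataFrame(
            [[80.0, 10.0, 5.0, 5.0]], columns=COMPARTMENTS, index=["P1"]
        )
        prof = localization_profile(table)
        np.testing.assert_allclose(
            prof[list(COMPARTMENTS)].to_numpy(), [[0.8, 0.1, 0.05, 0.05]]
        )
        assert prof.loc["P1", "predominant"] == "cytoplasm"

    def test_even_split_is_mixed_at_half_threshold(self):
        table = pd.DataFrame([[25.0] * 4], columns=COMPARTMENTS, index=["P1"])
        assert localization_profile(table).loc["P1", "predominant"] == "mixed"

    def test_planted_nucleus_dominant_proteins_are_recovered(self, small_dataset):
        _, truth = small_dataset
        planted = truth.proteins.copy()
        planted["loc_cytoplasm"] = 0.1
        planted["loc_membrane"] = 0.1
        planted["loc_nucleus"] = 0.7
        planted["loc_cytoskeleton"] = 0.1
        truth2 = type(truth)(proteins=planted, scaling=truth.scaling, params=truth.params)
        frac = simulate_fraction_table(truth2, seed=5, noise_cv=0.2)
        prof = localization_profile(frac, threshold=0.5)
        assert (prof["predominant"] == "nucleus").mean() >= 0.95

    def test_raising_threshold_never_converts_mixed_to_labeled(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            rng.dirichlet(np.ones(4), 100) * 1000, columns=COMPARTMENTS
        )
        low = localization_profile(table, threshold=0.4)["predominant"]
        high = localization_profile(table, threshold=0.6)["predominant"]
        became_labeled = (low == "mixed") & (high != "mixed")
        assert not became_labeled.any()


class TestCrossOmicsCorrelation:
    def test_identity_gives_unit_correlation(self):
        changes = pd.Series({"a": 0.1, "b": -0.5, "c": 0.7, "d": 0.2})
        r, n = cross_omics_correlation(changes, changes)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_independent_changes_have_near_zero_correlation(self):
        rng = np.random.default_rng(10)
        ids = [f"p{i}" for i in range(2000)]
        a = pd.Series(rng.normal(size=2000), index=ids)
        b = pd.Series(rng.normal(size=2000), index=ids)
        r, _ = cross_omics_correlation(a, b)
        assert abs(r) < 3 / np.sqrt(2000)

    def test_recovers_planted_correlation_of_a_quarter(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        y = 0.25 * x + np.sqrt(1 - 0.25**2) * rng.normal(size=n)
        ids = [f"p{i}" for i in range(n)]
        r, _ = cross_omics_correlation(
            pd.Series(x, index=ids), pd.Series(y, index=ids)
        )
        assert r == pytest.approx(0.25, abs=0.07)
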