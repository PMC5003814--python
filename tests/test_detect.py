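import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import matrix_from_values
from oracles import anova_oracle, bh_oracle
from proteoage import (
    DetectionParams,
    anova_p,
    confidence_band,
    detect_age_variant,
    fdr_correct,
    sample_matched_controls,
    volcano_table,
)
from proteoage.detect import volcano_counts


def _null_matrix(n, rng, sd=0.2, ref=None):
    vals = {p: rng.normal(0, sd, size=(n, 3)) for p in ("MH", "LM")}
    vals["LH"] = vals["MH"] + vals["LM"] + rng.normal(0, sd / 4, size=(n, 3))
    if ref is None:
        ref = 10 ** rng.normal(7, 1.3, n)
    return matrix_from_values(vals, ref=ref)


class TestConfidenceBand:
    def test_unit_sd_band_spans_plus_minus_multiplier(self):
        arr = np.repeat(np.array([[-1.0], [0.0], [1.0]]), 3, axis=1)
        matrix = matrix_from_values({p: arr for p in ("MH", "LM", "LH")})
        mean, sd, lo, hi = confidence_band(matrix, "MH", multiplier=1.96)
        assert (mean, sd) == (pytest.approx(0.0), pytest.approx(1.0))
        assert (lo, hi) == (pytest.approx(-1.96), pytest.approx(1.96))

    def test_constant_values_give_zero_width_band(self):
        arr = np.full((5, 3), 0.7)
        matrix = matrix_from_values({p: arr for p in ("MH", "LM", "LH")})
        _, sd, lo, hi = confidence_band(matrix, "LM")
        assert sd == 0.0 and lo == hi == pytest.approx(0.7)

    def test_normal_tail_fraction_outside_band(self):
        rng = np.random.default_rng(12)
        vals = np.repeat(rng.normal(0, 1, size=(10000, 1)), 3, axis=1)
        matrix = matrix_from_values({p: vals for p in ("MH", "LM", "LH")})
        _, _, lo, hi = confidence_band(matrix, "MH", multiplier=1.96)
        means = matrix.mean_log2()["MH"]
        outside = ((means < lo) | (means > hi)).mean()
        assert outside == pytest.approx(0.05, abs=0.01)


class TestAnovaP:
    def test_degenerate_equal_groups_give_p_one(self):
        f, p = anova_p([0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0])
        assert (f, p) == (0.0, 1.0)

    def test_degenerate_separated_groups_give_p_zero(self):
        with pytest.warns(UserWarning):
            f, p = anova_p([1.0, 1.0], [0.0, 0.0])
        assert p == 0.0 and np.isinf(f)

    def test_matches_sums_of_squares_oracle(self):
        target = [1.0, 1.2, 0.8]
        controls = [0.0, 0.1, -0.1, 0.05, -0.05, 0.0]
        f, p = anova_p(target, controls)
        f_exp, p_exp = anova_oracle(target, controls)
        assert f == pytest.approx(f_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        # exchangeable target/control groups drawn from one null pool
        from scipy import stats

        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(1000):
            pool = rng.normal(0, 1, 23)
            pvals.append(anova_p(pool[:3], pool[3:])[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_requires_two_finite_values_per_group(self):
        with pytest.raises(ValueError):
            anova_p([1.0], [0.0, 0.1])


class TestFdrCorrect:
    def test_step_up_hand_example(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated_inputs(self):
        assert fdr_correct([0.037])[0] == pytest.approx(0.037)
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_nan_entries_are_excluded_from_the_family(self):
        q = fdr_correct([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_invariant_under_permutation_of_input_order(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = fdr_correct(pvals)
        permuted = fdr_correct([pvals[i] for i in perm])
        unpermuted = np.empty_like(base)
        unpermuted[perm] = permuted
        np.testing.assert_allclose(unpermuted, base, atol=1e-12)


class TestControlSampling:
    def test_returns_all_when_exactly_k_eligible(self):
        rng = np.random.default_rng(14)
        matrix = _null_matrix(30, rng, sd=0.05)
        params = DetectionParams(controls_per_test=29, intensity_bins=1, seed=0)
        controls = sample_matched_controls(matrix.proteins[0], matrix, params)
        assert len(controls) == 29
        assert matrix.proteins[0] not in controls

    def test_target_never_appears_among_its_own_controls(self):
        rng = np.random.default_rng(15)
        matrix = _null_matrix(60, rng, sd=0.05)
        params = DetectionParams(controls_per_test=10, intensity_bins=2)
        for seed in range(5):
            params = DetectionParams(controls_per_test=10, intensity_bins=2, seed=seed)
            controls = sample_matched_controls(matrix.proteins[3], matrix, params)
            assert matrix.proteins[3] not in controls

    def test_matched_controls_are_closer_in_intensity_than_random(self):
        rng = np.random.default_rng(16)
        matrix = _null_matrix(800, rng, sd=0.1)
        params = DetectionParams(controls_per_test=20, seed=1)
        log10 = np.log10(matrix.ref_intensity)
        gaps_matched, gaps_random = [], []
        for pid in matrix.proteins[:30]:
            controls = sample_matched_controls(pid, matrix, params)
            gaps_matched.append((log10[controls] - log10[pid]).abs().mean())
            rand = rng.choice(matrix.proteins, 20, replace=False)
            gaps_random.append((log10[rand] - log10[pid]).abs().mean())
        assert np.mean(gaps_matched) < np.mean(gaps_random)

    def test_too_few_eligible_controls_is_an_error(self):
        arr = np.full((4, 3), 3.0)  # every mean far outside tau
        matrix = matrix_from_values({p: arr for p in ("MH", "LM", "LH")})
        with pytest.raises(ValueError, match="fewer than 2"):
            sample_matched_controls(
                matrix.proteins[0], matrix, DetectionParams(control_tau=0.5)
            )


class TestDetectAgeVariant:
    def test_all_zero_ratios_yield_no_significant_proteins(self):
        arr = np.zeros((50, 3))
        matrix = matrix_from_values({p: arr for p in ("MH", "LM", "LH")})
        result = detect_age_variant(matrix, DetectionParams(seed=0))
        assert not result.proteins["significant"].any()

    def test_single_planted_protein_is_flagged_with_smallest_q(self):
        rng = np.random.default_rng(17)
        matrix = _null_matrix(201, rng, sd=0.2)
        planted = matrix.proteins[0]
        matrix.log2.loc[planted, "MH"] = [2.0, 2.1, 1.9]
        matrix.log2.loc[planted, "LH"] = (
            matrix.log2.loc[planted, "MH"].to_numpy()
            + matrix.log2.loc[planted, "LM"].to_numpy()
        )
        result = detect_age_variant(matrix, DetectionParams(seed=5))
        assert result.proteins.loc[planted, "significant"]
        assert result.proteins["q_combined"].idxmin() == planted
        assert result.proteins.loc[planted, "direction"] == "up"

    def test_identical_seed_reproduces_identical_significant_set(self):
        rng = np.random.default_rng(18)
        matrix = _null_matrix(300, rng, sd=0.25)
        for pid in matrix.proteins[:20]:
            matrix.log2.loc[pid, "MH"] = rng.normal(1.5, 0.1, 3)
        a = detect_age_variant(matrix, DetectionParams(seed=9))
        b = detect_age_variant(matrix, DetectionParams(seed=9))
        assert list(a.significant_ids) == list(b.significant_ids)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_incomplete_pairs_are_reported_as_nan_not_dropped(self):
        rng = np.random.default_rng(19)
        matrix = _null_matrix(40, rng, sd=0.1)
        pid = matrix.proteins[5]
        matrix.log2.loc[pid, ("MH", 2)] = np.nan
        result = detect_age_variant(matrix, DetectionParams(seed=0))
        row = result.table[(result.table["protein"] == pid) & (result.table["pair"] == "MH")]
        assert np.isnan(row["p"].iloc[0])
        assert pid in result.proteins.index


@pytest.fixture(scope="module")
def volcano_result():
    rng = np.random.default_rng(20)
    matrix = _null_matrix(150, rng, sd=0.2)
    for pid in matrix.proteins[:8]:
        matrix.log2.loc[pid, "MH"] = rng.normal(2.0, 0.1, 3)
        matrix.log2.loc[pid, "LH"] = rng.normal(2.0, 0.1, 3)
    return detect_age_variant(matrix, DetectionParams(seed=3))


class TestVolcano:

    def test_tier_thresholds_bracket_q_values(self, volcano_result):
        table = volcano_table(volcano_result)
        tiers = {"": 1.1, "*": 0.05, "**": 0.01, "***": 0.001}
        finite = table.dropna(subset=["q"])
        for _, row in finite.iterrows():
            upper = tiers[row["tier"]]
            assert row["q"] < upper or (row["tier"] == "" and row["q"] >= 0.05)

    def test_zero_fold_change_has_no_direction(self):
        arr = np.zeros((30, 3))
        matrix = matrix_from_values({p: arr for p in ("MH", "LM", "LH")})
        result = detect_age_variant(matrix, DetectionParams(seed=0))
        assert (result.table["direction"] == "none").all()

    def test_up_down_counts_match_planted_directions(self, volcano_result):
        # counts match the 8 planted up-movers within the realized error
        counts = volcano_counts(volcano_result)
        assert counts.loc["MH", "up"] == 8
        assert counts.loc["MH"].get("down", 0) <= 1
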