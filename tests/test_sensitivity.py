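"""LHS stratification and PRCC correctness against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from essn import (
    DesignMatrix,
    ParameterSpace,
    lhs_sample,
    prcc,
    prcc_over_time,
    rank_transform,
)


def _space(k, lo=0.0, hi=1.0):
    return ParameterSpace(tuple((f"p{i}", lo, hi) for i in range(k)))


def prcc_matrix_inverse(X, y, j):
    """Independent oracle: partial rank correlation via inversion of the
    full rank-correlation matrix (off-diagonal cofactor formula)."""
    data = np.column_stack([X, y])
    ranks = np.column_stack([stats.rankdata(data[:, c]) for c in range(data.shape[1])])
    C = np.corrcoef(ranks, rowvar=False)
    P = np.linalg.inv(C)
    a, b = j, data.shape[1] - 1
    return -P[a, b] / np.sqrt(P[a, a] * P[b, b])


class TestLHS:
    def test_one_sample_per_stratum_per_dimension(self):
        design = lhs_sample(_space(3), 4, seed=0)
        for col in range(3):
            strata = np.floor(design.values[:, col] * 4).astype(int)
            assert sorted(strata) == [0, 1, 2, 3]

    def test_single_sample_lies_in_range(self):
        design = lhs_sample(ParameterSpace((("a", 2.0, 5.0),)), 1, seed=1)
        assert 2.0 <= design.values[0, 0] < 5.0

    def test_reproducible_for_fixed_seed(self):
        a = lhs_sample(_space(4), 20, seed=42)
        b = lhs_sample(_space(4), 20, seed=42)
        assert np.array_equal(a.values, b.values)
        c = lhs_sample(_space(4), 20, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_nonpositive_sample_size_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(_space(2), 0, seed=0)

    def test_respects_bounds(self):
        space = ParameterSpace((("a", -3.0, -1.0), ("b", 100.0, 200.0)))
        design = lhs_sample(space, 50, seed=7)
        assert design.values[:, 0].min() >= -3.0 and design.values[:, 0].max() < -1.0
        assert design.values[:, 1].min() >= 100.0 and design.values[:, 1].max() < 200.0


class TestRankTransform:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((10, 20, 30), (1, 2, 3)),
            ((5, 5, 7), (1.5, 1.5, 3)),
            ((3, 2, 1), (3, 2, 1)),
        ],
    )
    def test_examples(self, values, expected):
        assert rank_transform(values) == pytest.approx(expected)

    def test_requires_finite(self):
        with pytest.raises(ValueError):
            rank_transform([1.0, np.nan])


class TestPRCC:
    def test_single_parameter_equals_spearman(self):
        rng = np.random.default_rng(0)
        design = lhs_sample(_space(1), 50, seed=0)
        y = design.values[:, 0] ** 3 + rng.normal(0, 0.05, 50)
        r, p = prcc(design, y, 0)
        rho, p_s = stats.spearmanr(design.values[:, 0], y)
        assert r == pytest.approx(rho, abs=1e-10)

    def test_monotone_transform_gives_near_unit_prcc(self):
        design = lhs_sample(_space(4), 200, seed=5)
        y = np.exp(design.values[:, 2])
        r, p = prcc(design, y, 2)
        assert r >= 0.99
        assert p < 1e-6

    def test_matches_matrix_inverse_oracle_on_small_designs(self):
        for seed in range(5):
            design = lhs_sample(_space(3), 10, seed=seed)
            rng = np.random.default_rng(seed)
            y = design.values @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, 10)
            for j in range(3):
                r, _ = prcc(design, y, j)
                assert r == pytest.approx(prcc_matrix_inverse(design.values, y, j), abs=1e-10)

    def test_row_permutation_invariance(self):
        design = lhs_sample(_space(3), 40, seed=2)
        rng = np.random.default_rng(2)
        y = design.values[:, 0] - design.values[:, 1] + rng.normal(0, 0.1, 40)
        r0, _ = prcc(design, y, 0)
        perm = rng.permutation(40)
        shuffled = DesignMatrix(
            design.space, design.values[perm], design.strata[perm], design.seed
        )
        r1, _ = prcc(shuffled, y[perm], 0)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_output_independent_noise_column_changes_little(self):
        space = _space(3)
        design = lhs_sample(space, 200, seed=9)
        rng = np.random.default_rng(9)
        y = 2 * design.values[:, 0] + rng.normal(0, 0.2, 200)
        r_before, _ = prcc(design, y, 0)
        wide = ParameterSpace(space.ranges + (("noise", 0.0, 1.0),))
        values = np.column_stack([design.values, rng.uniform(size=200)])
        strata = np.column_stack([design.strata, np.arange(200)])
        design2 = DesignMatrix(wide, values, strata, 9)
        r_after, _ = prcc(design2, y, 0)
        assert abs(r_after - r_before) < 0.05

    def test_type_one_error_rate_is_controlled(self):
        # output independent of all inputs: the fraction of significant
        # PRCCs at level alpha stays below 2*alpha across 100 repetitions
        alpha = 0.05
        n, k = 40, 4
        hits = total = 0
        for seed in range(100):
            design = lhs_sample(_space(k), n, seed=seed)
            y = np.random.default_rng(1000 + seed).normal(size=n)
            for j in range(k):
                _, p = prcc(design, y, j)
                hits += p < alpha
                total += 1
        assert hits / total <= 2 * alpha

    def test_degenerate_constant_column_is_named(self):
        space = _space(2)
        values = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        design = DesignMatrix(space, values, np.zeros((10, 2), dtype=int), 0)
        with pytest.raises(ValueError, match="p0"):
            prcc(design, np.arange(10.0), 1)

    def test_insufficient_samples_rejected(self):
        design = lhs_sample(_space(4), 5, seed=0)
        with pytest.raises(ValueError, match="N > k"):
            prcc(design, np.arange(5.0), 0)


class _FakeTraj:
    """Stands in for a trajectory: value(place, t) driven by a callable."""

    def __init__(self, fn):
        self.fn = fn

    def value(self, place, t, color=()):
        return self.fn(t)


class TestPRCCOverTime:
    def test_rows_agree_with_pointwise_prcc(self):
        design = lhs_sample(_space(2), 30, seed=3)
        trajs = [
            _FakeTraj(lambda t, v=v: v[0] + 0.1 * t * v[1]) for v in design.values
        ]
        times = [0.0, 5.0, 10.0]
        res = prcc_over_time(design, trajs, lambda tr, t: tr.value("out", t), times)
        for i, t in enumerate(times):
            outputs = np.array([tr.value("out", t) for tr in trajs])
            r, p = prcc(design, outputs, 0)
            assert res.values[i, 0] == pytest.approx(r)
            assert res.p_values[i, 0] == pytest.approx(p)

    def test_constant_output_over_time_gives_identical_rows(self):
        design = lhs_sample(_space(2), 30, seed=4)
        trajs = [_FakeTraj(lambda t, v=v: np.sin(v[0])) for v in design.values]
        res = prcc_over_time(design, trajs, lambda tr, t: tr.value("o", t), [1.0, 2.0, 3.0])
        assert np.allclose(res.values[0], res.values[1])
        assert np.allclose(res.values[1], res.values[2])

    def test_decay_rate_parameter_is_negative_and_significant(self):
        # toy one-parameter decay: output x0*exp(-k t); PRCC of k must be
        # negative and significant at every positive time
        space = ParameterSpace((("k", 0.05, 1.0),))
        design = lhs_sample(space, 60, seed=6)
        trajs = [_FakeTraj(lambda t, k=v[0]: 100 * np.exp(-k * t)) for v in design.values]
        res = prcc_over_time(design, trajs, lambda tr, t: tr.value("x", t), [1.0, 5.0, 20.0])
        assert (res.values[:, 0] < -0.99).all()
        assert res.significant().all()

    def test_trajectory_count_mismatch_rejected(self):
        design = lhs_sample(_space(2), 10, seed=0)
        with pytest.raises(ValueError, match="one trajectory per design row"):
            prcc_over_time(design, [], lambda tr, t: 0.0, [1.0])

    def test_long_format_export_columns(self):
        design = lhs_sample(_space(2), 30, seed=8)
        trajs = [_FakeTraj(lambda t, v=v: v[1]) for v in design.values]
        res = prcc_over_time(design, trajs, lambda tr, t: tr.value("o", t), [1.0])
        df = res.to_dataframe()
        assert list(df.columns) == ["time", "parameter", "prcc", "p_value", "significant"]
        assert len(df) == 2
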