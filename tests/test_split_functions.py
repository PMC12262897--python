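"""Split functions: literal definitions, flip directions, grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bimm import (
    BimmError,
    SplitFunctionSpec,
    apply_h1,
    apply_h2,
    apply_h3,
    candidate_specs,
    default_k1_grid,
    default_k2_grid,
    grid_search_split,
)
from bimm.split_functions import apply_spec

# literal transcriptions of the printed piecewise definitions, kept separate
# from the vectorised implementation they check
def _h1_scalar(s, k1):
    return 0 if s <= k1 else 1


def _h2_scalar(s, k2):
    return 0 if s < k2 else 1


K1_GRID = default_k1_grid()
K2_GRID = default_k2_grid()


class TestPointwiseDefinitions:
    @pytest.mark.parametrize(
        "s, k1, expected",
        [(0.30, 0.25, 1), (0.25, 0.25, 0), (1.0, 0.05, 1), (1.0, 0.95, 1)],
    )
    def test_h1_examples(self, s, k1, expected):
        assert apply_h1(s, k1) == expected

    @pytest.mark.parametrize(
        "s, k2, expected",
        [(1.5, 1.5, 1), (1.2, 1.5, 0), (0.99, 1.05, 0), (0.99, 1.95, 0)],
    )
    def test_h2_examples(self, s, k2, expected):
        assert apply_h2(s, k2) == expected

    def test_h3_deterministic_branches(self):
        rng = np.random.default_rng(0)
        assert apply_h3(0, 0.4, rng) == 0  # s = 0.4 < 0.5
        assert apply_h3(1, 0.8, rng) == 1  # s = 1.8 > 1.5

    def test_h3_stochastic_branch_rate(self):
        # y=0, q=0.7 -> s=0.7 in the middle band; output ~ Bernoulli(0.7)
        rng = np.random.default_rng(123)
        draws = apply_h3(np.zeros(10_000, dtype=int), np.full(10_000, 0.7), rng)
        assert abs(draws.mean() - 0.7) < 0.02

    @pytest.mark.parametrize(
        "fn, bad",
        [(apply_h1, 0.0), (apply_h1, 1.0), (apply_h2, 1.0), (apply_h2, 2.0)],
    )
    def test_constant_range_enforced(self, fn, bad):
        with pytest.raises(BimmError):
            fn(0.5, bad)

    def test_h3_rejects_degenerate_q(self):
        with pytest.raises(BimmError):
            apply_h3(0, 0.0, np.random.default_rng(0))


class TestOracleEquivalence:
    def test_vectorized_matches_scalar_on_random_triples(self):
        # 10^4 random (y, q, k) triples, exact agreement with the printed rules
        rng = np.random.default_rng(2024)
        y = rng.integers(0, 2, 10_000)
        q = rng.uniform(0.001, 0.999, 10_000)
        s = y + q
        k1 = rng.uniform(0.01, 0.99, 10_000)
        k2 = rng.uniform(1.01, 1.99, 10_000)
        for i in range(0, 10_000, 997):  # scalar spot-checks along the array
            assert apply_h1(float(s[i]), float(k1[i])) == _h1_scalar(s[i], k1[i])
            assert apply_h2(float(s[i]), float(k2[i])) == _h2_scalar(s[i], k2[i])
        h1_vec = np.array([_h1_scalar(si, ki) for si, ki in zip(s, 0.5 * np.ones(10_000))])
        assert np.array_equal(apply_h1(s, 0.5), h1_vec)
        h2_vec = np.array([_h2_scalar(si, ki) for si, ki in zip(s, 1.5 * np.ones(10_000))])
        assert np.array_equal(apply_h2(s, 1.5), h2_vec)

    def test_h3_outside_band_matches_definition(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 5000)
        q = rng.uniform(0.001, 0.999, 5000)
        out = apply_h3(y, q, np.random.default_rng(9))
        s = y + q
        assert np.all(out[s < 0.5] == 0)
        assert np.all(out[s > 1.5] == 1)
        assert np.isin(out, [0, 1]).all()


class TestFlipDirections:
    """h1 never flips an original 1 to 0; h2 never flips a 0 to 1 —
    exhaustively over the full printed constant grids."""

    @pytest.mark.parametrize("k1", K1_GRID)
    def test_h1_preserves_ones(self, k1):
        q = np.arange(0.001, 1.0, 0.01)
        assert np.all(apply_h1(1 + q, k1) == 1)

    @pytest.mark.parametrize("k2", K2_GRID)
    def test_h2_preserves_zeros(self, k2):
        q = np.arange(0.001, 1.0, 0.01)
        assert np.all(apply_h2(0 + q, k2) == 0)

    @given(
        s=st.floats(min_value=0.0, max_value=2.0),
        k1=st.floats(min_value=0.01, max_value=0.99),
        k2=st.floats(min_value=1.01, max_value=1.99),
    )
    def test_monotone_in_constant(self, s, k1, k2):
        # raising the threshold can only turn 1s into 0s
        assert apply_h1(s, k1) >= apply_h1(s, min(k1 + 0.005, 0.995))
        assert apply_h2(s, k2) >= apply_h2(s, min(k2 + 0.005, 1.995))


class TestSpecAndGrids:
    def test_spec_validation(self):
        with pytest.raises(BimmError):
            SplitFunctionSpec("h1")  # k1 required
        with pytest.raises(BimmError):
            SplitFunctionSpec("h2", k2=2.5)
        with pytest.raises(BimmError):
            SplitFunctionSpec("h3", k1=0.5)
        assert SplitFunctionSpec("h1", k1=0.25).constant == 0.25
        assert SplitFunctionSpec("h3").constant is None

    def test_default_grids_span_printed_ranges(self):
        assert K1_GRID[0] == 0.05 and K1_GRID[-1] == 0.95 and len(K1_GRID) == 19
        assert K2_GRID[0] == 1.05 and K2_GRID[-1] == 1.95 and len(K2_GRID) == 19
        specs = candidate_specs()
        assert len(specs) == 39  # 19 + 19 + h3

    def test_apply_spec_dispatch(self):
        y = np.array([0, 0, 1])
        q = np.array([0.3, 0.2, 0.1])
        out = apply_spec(y, q, SplitFunctionSpec("h1", k1=0.25))
        assert out.tolist() == [1, 0, 1]


class TestGridSearch:
    def test_singleton_grid_returns_that_spec(self, small_cohort, fast_rf):
        from bimm import partition_by_individual

        train, val = partition_by_individual(small_cohort, 0.7, seed=3)
        spec, auc, trace = grid_search_split(
            train, val, fast_rf, k1_grid=[0.5], k2_grid=[], include_h3=False,
            max_iter=3, seed=5,
        )
        assert spec == SplitFunctionSpec("h1", k1=0.5)
        assert len(trace) == 1
        assert trace["auc"].iloc[0] == auc

    def test_best_auc_is_max_of_trace(self, small_cohort, fast_rf):
        from bimm import partition_by_individual

        train, val = partition_by_individual(small_cohort, 0.7, seed=3)
        spec, auc, trace = grid_search_split(
            train, val, fast_rf, k1_grid=[0.25, 0.75], k2_grid=[1.5],
            include_h3=True, max_iter=3, seed=5,
        )
        assert len(trace) == 4
        assert auc == trace["auc"].max()
        best_rows = trace[trace["auc"] == auc]
        assert spec.kind == best_rows["kind"].iloc[0]  # tie-break: first wins

    def test_leakage_warning(self, small_cohort, fast_rf):
        from bimm import partition_by_individual

        train, test = partition_by_individual(small_cohort, 0.7, seed=3)
        with pytest.warns(UserWarning, match="final test set"):
            grid_search_split(
                train, test, fast_rf, k1_grid=[0.5], k2_grid=[],
                include_h3=False, max_iter=2, seed=5, eval_is_final_test=True,
            )

    def test_empty_grids_rejected(self, small_cohort, fast_rf):
        with pytest.raises(BimmError):
            grid_search_split(
                small_cohort, small_cohort, fast_rf,
                k1_grid=[], k2_grid=[], include_h3=False, seed=0,
            )
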