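"""Paired bootstrap engine and the three comparison-probability estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdcp import (
    DataSet,
    ModelSpec,
    PairedBootstrapReplicates,
    bdcp,
    bdcp_b,
    bdcp_k,
    compare,
    fit_mle,
    paired_bootstrap,
    plug_in_bd,
)

from conftest import make_table


def _replicates(d1, d2, k1=2, k2=3, k1b=0.0, k2b=0.0):
    d1 = np.asarray(d1, dtype=float)
    return PairedBootstrapReplicates(
        d1_star=d1,
        d2_star=np.asarray(d2, dtype=float),
        k1=k1,
        k2=k2,
        k1b=k1b,
        k2b=k2b,
        neg2ll_1=0.0,
        neg2ll_2=0.0,
        indices=np.zeros((len(d1), 1), dtype=np.intp),
    )


class TestEstimatorsOnFixedReplicates:
    def test_bdcp_one_win_each(self):
        assert bdcp(_replicates([1.0, 3.0], [2.0, 2.0])) == pytest.approx(0.5)

    def test_all_ties_count_zero(self):
        r = _replicates([2.0, 2.0], [2.0, 2.0])
        assert bdcp(r) == 0.0
        assert bdcp_k(_replicates([2.0, 2.0], [2.0, 2.0], k1=3, k2=3)) == 0.0

    def test_bdcp_k_equal_sizes_reduces_to_bdcp(self, rng):
        d1, d2 = rng.normal(size=40), rng.normal(size=40)
        r = _replicates(d1, d2, k1=4, k2=4)
        assert bdcp_k(r) == bdcp(r)

    def test_bdcp_k_shift_arithmetic(self):
        # 10 + 4 < 11 + 8 for every replicate
        r = _replicates([10.0, 10.0], [11.0, 11.0], k1=4, k2=8)
        assert bdcp_k(r) == 1.0

    def test_bdcp_b_equal_shifts_cancel(self, rng):
        d1, d2 = rng.normal(size=30), rng.normal(size=30)
        r = _replicates(d1, d2, k1b=1.7, k2b=1.7)
        assert bdcp_b(r) == bdcp(r)

    def test_bdcp_b_dominating_shift(self, rng):
        d1, d2 = rng.normal(size=30), rng.normal(size=30)
        r = _replicates(d1, d2, k1b=0.0, k2b=1e12)
        assert bdcp_b(r) == 1.0

    def test_pairing_matters(self):
        # shuffling one margin changes the proportion: alignment is load-bearing
        d1 = np.array([1.0, 3.0, 5.0, 7.0])
        d2 = np.array([2.0, 4.0, 6.0, 8.0])
        aligned = bdcp(_replicates(d1, d2))
        shuffled = bdcp(_replicates(d1, d2[::-1]))
        assert aligned != shuffled


@st.composite
def replicate_pairs(draw):
    J = draw(st.integers(min_value=2, max_value=30))
    vals = st.floats(
        min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
    )
    d1 = draw(st.lists(vals, min_size=J, max_size=J))
    d2 = draw(st.lists(vals, min_size=J, max_size=J))
    return np.array(d1), np.array(d2)


class TestEstimatorProperties:
    @given(replicate_pairs())
    @settings(derandomize=True, max_examples=60)
    def test_complement_identity(self, pair):
        d1, d2 = pair
        r = _replicates(d1, d2, k1=3, k2=5, k1b=1.0, k2b=2.5)
        s = r.swapped()
        n_ties = int(np.sum(d1 == d2))
        if n_ties == 0:
            assert bdcp(r) + bdcp(s) == pytest.approx(1.0)
        if int(np.sum(d1 + r.k1 == d2 + r.k2)) == 0:
            assert bdcp_k(r) + bdcp_k(s) == pytest.approx(1.0)
        if int(np.sum(d1 + r.k1b == d2 + r.k2b)) == 0:
            assert bdcp_b(r) + bdcp_b(s) == pytest.approx(1.0)

    @given(replicate_pairs(), st.floats(min_value=-1e5, max_value=1e5, allow_nan=False))
    @settings(derandomize=True, max_examples=60)
    def test_shift_invariance(self, pair, c):
        # adding the same constant to both candidates' replicates changes
        # nothing (gaps below the float resolution of the shift excepted)
        d1, d2 = pair
        scale = np.abs([d1, d2]).max() + abs(c) + 1.0
        if (np.abs(d1 - d2) < 1e-9 * scale).any():
            return
        r = _replicates(d1, d2, k1=3, k2=5, k1b=0.4, k2b=2.2)
        shifted = _replicates(d1 + c, d2 + c, k1=3, k2=5, k1b=0.4, k2b=2.2)
        assert bdcp(shifted) == bdcp(r)
        assert bdcp_k(shifted) == bdcp_k(r)
        assert bdcp_b(shifted) == bdcp_b(r)

    @given(replicate_pairs(), st.integers(min_value=0, max_value=50))
    @settings(derandomize=True, max_examples=60)
    def test_bdcp_k_monotone_in_penalty_gap(self, pair, gap):
        # penalising the bigger model more can only favour the null
        d1, d2 = pair
        base = _replicates(d1, d2, k1=3, k2=3)
        widened = _replicates(d1, d2, k1=3, k2=3 + gap)
        assert bdcp_k(widened) >= bdcp_k(base)


class TestPairedBootstrapEngine:
    def test_deterministic_given_seed(self, nested_specs):
        data = DataSet.from_frame(make_table(10, 3, seed=5), response="y")
        null_spec, alt_spec = nested_specs
        r1 = paired_bootstrap(data, null_spec, alt_spec, J=5, seed=77)
        r2 = paired_bootstrap(data, null_spec, alt_spec, J=5, seed=77)
        np.testing.assert_array_equal(r1.d1_star, r2.d1_star)
        np.testing.assert_array_equal(r1.d2_star, r2.d2_star)
        np.testing.assert_array_equal(r1.indices, r2.indices)

    def test_extending_j_preserves_earlier_replicates(self, nested_specs):
        data = DataSet.from_frame(make_table(20, 3, seed=5), response="y")
        null_spec, alt_spec = nested_specs
        r_small = paired_bootstrap(data, null_spec, alt_spec, J=10, seed=77)
        r_big = paired_bootstrap(data, null_spec, alt_spec, J=25, seed=77)
        np.testing.assert_array_equal(r_big.d1_star[:10], r_small.d1_star)
        np.testing.assert_array_equal(r_big.d2_star[:10], r_small.d2_star)

    def test_identical_specs_give_identical_margins(self):
        data = DataSet.from_frame(make_table(15, 2, seed=9), response="y")
        spec = ModelSpec(("x2", "x3"))
        r = paired_bootstrap(data, spec, spec, J=8, seed=3)
        np.testing.assert_array_equal(r.d1_star, r.d2_star)
        assert bdcp(r) == 0.0  # strict inequality: all ties

    def test_replay_oracle_from_stored_indices(self, nested_specs):
        # every replicate is reproducible from its logged index vector by a
        # from-scratch two-fit recomputation
        data = DataSet.from_frame(make_table(25, 3, seed=11), response="y")
        null_spec, alt_spec = nested_specs
        r = paired_bootstrap(data, null_spec, alt_spec, J=20, seed=13)
        for spec, d_star in [(null_spec, r.d1_star), (alt_spec, r.d2_star)]:
            sub = data.select(spec)
            for j in range(r.J):
                idx = r.indices[j]
                refit = fit_mle(DataSet(y=sub.y[idx], X=sub.X[idx], columns=sub.columns))
                replayed = plug_in_bd((refit.beta_hat, refit.sigma2_hat), sub)
                assert replayed == pytest.approx(d_star[j], rel=1e-9)

    def test_kb_fields_match_definition(self, nested_specs):
        data = DataSet.from_frame(make_table(30, 3, seed=2), response="y")
        null_spec, alt_spec = nested_specs
        r = paired_bootstrap(data, null_spec, alt_spec, J=50, seed=1)
        fit1 = fit_mle(data.select(null_spec))
        fit2 = fit_mle(data.select(alt_spec))
        assert r.k1b == pytest.approx(r.d1_star.mean() - fit1.neg2ll_at_fit)
        assert r.k2b == pytest.approx(r.d2_star.mean() - fit2.neg2ll_at_fit)
        assert (r.k1, r.k2) == (null_spec.k, alt_spec.k)

    def test_missing_seed_is_an_error(self, nested_specs):
        data = DataSet.from_frame(make_table(10, 3, seed=5), response="y")
        with pytest.raises(ValueError, match="seed"):
            paired_bootstrap(data, *nested_specs, J=5, seed=None)


class TestCompare:
    def test_bit_identical_across_runs(self, nested_specs):
        data = DataSet.from_frame(make_table(30, 3, seed=21), response="y")
        res1 = compare(data, *nested_specs, J=30, seed=5)
        res2 = compare(data, *nested_specs, J=30, seed=5)
        assert res1 == res2

    def test_identical_specs(self):
        data = DataSet.from_frame(make_table(20, 2, seed=4), response="y")
        spec = ModelSpec(("x2",))
        res = compare(data, spec, spec, J=10, seed=8)
        assert res.bdcp == 0.0
        assert (res.bd1, res.bd1_k, res.bd1_b) == (res.bd2, res.bd2_k, res.bd2_b)

    def test_probabilities_in_unit_interval(self, nested_specs):
        data = DataSet.from_frame(make_table(40, 3, seed=6), response="y")
        res = compare(data, *nested_specs, J=60, seed=2)
        for p in (res.bdcp, res.bdcp_k, res.bdcp_b):
            assert 0.0 <= p <= 1.0
        assert res.bd1_b == pytest.approx(2 * res.bd1 - fit_mle(
            data.select(nested_specs[0])).neg2ll_at_fit)
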