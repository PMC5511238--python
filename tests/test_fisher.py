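"""GMM dictionary fitting and Fisher-vector encoding against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dlradiomics import (
    GmmModel,
    descriptor_index,
    descriptor_unindex,
    encode_case,
    fit_gmm,
    posterior,
)
from dlradiomics.features import FilterResponseSet


def brute_force_fisher(responses, gmm):
    """Literal per-element implementation of the first/second-order statistics."""
    F, T = responses.shape
    K = gmm.K
    out = np.zeros(2 * K * F)
    for f in range(F):
        for k in range(K):
            g = h = 0.0
            for t in range(T):
                x = responses[f, t]
                dens = np.array(
                    [
                        gmm.weights[j] * norm.pdf(x, gmm.means[j], np.sqrt(gmm.variances[j]))
                        for j in range(K)
                    ]
                )
                gamma = dens[k] / dens.sum()
                u = (x - gmm.means[k]) / np.sqrt(gmm.variances[k])
                g += gamma * u
                h += gamma * (u**2 - 1.0)
            out[f * 2 * K + k] = g / (T * np.sqrt(gmm.weights[k]))
            out[f * 2 * K + K + k] = h / (T * np.sqrt(2.0 * gmm.weights[k]))
    return out


def random_gmm(K, rng):
    w = rng.dirichlet(np.ones(K) * 5)
    return GmmModel(
        weights=w,
        means=rng.normal(0, 2, K),
        variances=rng.uniform(0.2, 2.0, K),
    )


class TestFitGmm:
    def test_single_component_closed_form(self):
        pool = np.random.default_rng(0).normal(3.0, 2.0, 5000)
        gmm = fit_gmm(pool, K=1, seed=0)
        assert gmm.means[0] == pytest.approx(pool.mean(), abs=1e-6)
        assert gmm.variances[0] == pytest.approx(pool.var(), rel=1e-3)
        assert gmm.weights[0] == pytest.approx(1.0)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        pool = np.concatenate(
            [rng.normal(-5, 0.5, 5000), rng.normal(5, 0.5, 5000)]
        )
        gmm = fit_gmm(pool, K=2, seed=0)
        order = np.argsort(gmm.means)
        np.testing.assert_allclose(gmm.means[order], [-5, 5], atol=0.1)
        np.testing.assert_allclose(gmm.weights[order], [0.5, 0.5], atol=0.05)

    def test_insufficient_distinct_values_rejected(self):
        pool = np.tile(np.arange(100.0), 50)  # 100 distinct values only
        with pytest.raises(ValueError):
            fit_gmm(pool, K=64, seed=0)

    def test_json_roundtrip(self):
        gmm = fit_gmm(np.random.default_rng(2).normal(size=2000), K=3, seed=1)
        back = GmmModel.from_json(gmm.to_json())
        np.testing.assert_array_equal(back.means, gmm.means)
        np.testing.assert_array_equal(back.weights, gmm.weights)


class TestPosterior:
    def test_single_component_is_certain(self):
        gmm = GmmModel(weights=[1.0], means=[0.0], variances=[1.0])
        np.testing.assert_allclose(posterior(gmm, 3.7), [1.0])

    def test_symmetric_mixture_splits_evenly_at_zero(self):
        gmm = GmmModel(weights=[0.5, 0.5], means=[-2.0, 2.0], variances=[1.0, 1.0])
        np.testing.assert_allclose(posterior(gmm, 0.0), [0.5, 0.5], atol=1e-12)

    def test_responsibilities_normalized(self):
        rng = np.random.default_rng(3)
        gmm = random_gmm(5, rng)
        gamma = posterior(gmm, rng.normal(size=50))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestDescriptorLayout:
    @pytest.mark.parametrize(
        "f,k,order,expected",
        [(0, 0, 0, 0), (127, 63, 1, 16383), (106, 35, 0, 13603)],
    )
    def test_index_formula(self, f, k, order, expected):
        assert descriptor_index(f, k, order, K=64, F=128) == expected

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 16383))
    def test_bijective(self, idx):
        f, k, order = descriptor_unindex(idx, K=64, F=128)
        assert descriptor_index(f, k, order, K=64, F=128) == idx

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            descriptor_index(128, 0, 0, K=64, F=128)
        with pytest.raises(IndexError):
            descriptor_unindex(16384, K=64, F=128)


class TestEncodeCase:
    def test_hand_computed_single_point(self):
        gmm = GmmModel(weights=[1.0], means=[0.0], variances=[1.0])
        rset = FilterResponseSet(case_id="h", responses=np.zeros((1, 1)))
        raw = encode_case(rset, gmm, signed_sqrt=False, l2_normalize=False)
        np.testing.assert_allclose(raw.values, [0.0, -1 / np.sqrt(2)], atol=1e-12)
        improved = encode_case(rset, gmm)
        np.testing.assert_allclose(improved.values, [0.0, -1.0], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            F = int(rng.integers(1, 5))
            K = int(rng.integers(1, 6))
            T = int(rng.integers(1, 101))
            gmm = random_gmm(K, rng)
            responses = rng.normal(0, 2, size=(F, T))
            rset = FilterResponseSet(case_id=f"r{trial}", responses=responses)
            mine = encode_case(rset, gmm, signed_sqrt=False, l2_normalize=False)
            oracle = brute_force_fisher(responses, gmm)
            np.testing.assert_allclose(mine.values, oracle, atol=1e-8)

    def test_fisher_consistency_at_the_model(self):
        """Responses drawn from the GMM itself give vanishing raw statistics."""
        rng = np.random.default_rng(4)
        gmm = random_gmm(3, rng)
        x = gmm.sample(100_000, seed=5)
        rset = FilterResponseSet(case_id="c", responses=x[None, :])
        raw = encode_case(rset, gmm, signed_sqrt=False, l2_normalize=False)
        assert np.abs(raw.values[: gmm.K]).mean() < 0.02

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        gmm = random_gmm(4, rng)
        responses = rng.normal(size=(3, 80))
        a = encode_case(FilterResponseSet("a", responses), gmm)
        perm = rng.permutation(80)
        b = encode_case(FilterResponseSet("b", responses[:, perm]), gmm)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_l2_normalized(self):
        rng = np.random.default_rng(7)
        gmm = random_gmm(4, rng)
        d = encode_case(FilterResponseSet("n", rng.normal(size=(2, 30))), gmm)
        assert np.linalg.norm(d.values) == pytest.approx(1.0)

    def test_empty_responses_rejected(self):
        gmm = GmmModel(weights=[1.0], means=[0.0], variances=[1.0])
        with pytest.raises(ValueError):
            encode_case(FilterResponseSet("e", np.empty((2, 0))), gmm)
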