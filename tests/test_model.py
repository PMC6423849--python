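"""Forward-backward correctness against closed forms and the enumeration
oracle, plus the structural invariants of the posterior computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import replis as rl
from replis.model import emission_matrix
from conftest import random_chmm_params, random_zmatrix


def _params(pi, A, mu, sd):
    return rl.ChmmParams(np.asarray(pi), np.asarray(A), np.asarray(mu), np.asarray(sd))


def uniform_params(mu=(2.0, 2.0), sd=(1.0, 1.0)):
    return _params(np.full(4, 0.25), np.full((4, 4), 0.25), mu, sd)


def sticky_params(mu=(3.0, 2.0), sd=(1.0, 1.0), diag=0.7):
    A = np.full((4, 4), (1 - diag) / 3)
    np.fill_diagonal(A, diag)
    return _params(np.full(4, 0.25), A, mu, sd)


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

class TestJointStateSpace:
    def test_canonical_two_study_order(self):
        space = rl.JointStateSpace(2)
        assert space.states == ((0, 0), (1, 0), (0, 1), (1, 1))
        assert space.null_states == {(0, 0), (1, 0), (0, 1)}
        assert space.full_index == 3
        assert list(space.null_indices) == [0, 1, 2]

    def test_three_studies_default_null_is_complement_of_full(self):
        space = rl.JointStateSpace(3)
        assert space.n_states == 8
        assert (1, 1, 1) not in space.null_states
        assert len(space.null_states) == 7

    def test_rejects_null_containing_all_ones(self):
        with pytest.raises(ValueError):
            rl.JointStateSpace(2, null_states=frozenset({(0, 0), (1, 1)}))

    def test_rejects_single_study(self):
        with pytest.raises(ValueError):
            rl.JointStateSpace(1)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

class TestEmissions:
    def test_reference_densities(self):
        params = uniform_params(mu=(2.0, 3.0), sd=(1.0, 1.5))
        # standard normal at its mode
        assert rl.emission_density(0.0, 0, 0, params) == pytest.approx(
            0.3989422804014327, abs=1e-12
        )
        # alternative density at its own mean, unit sd
        assert rl.emission_density(2.0, 0, 1, params) == pytest.approx(
            0.3989422804014327, abs=1e-12
        )
        # phi(-2), cross-checked against scipy's normal pdf
        assert rl.emission_density(0.0, 0, 1, params) == pytest.approx(
            0.05399096651318806, abs=1e-12
        )
        assert rl.emission_density(0.0, 0, 1, params) == pytest.approx(
            norm.pdf(0.0, loc=2.0), abs=1e-14
        )

    def test_invalid_study_or_bit(self):
        params = uniform_params()
        with pytest.raises(ValueError):
            rl.emission_density(0.0, 5, 0, params)
        with pytest.raises(ValueError):
            rl.emission_density(0.0, 0, 2, params)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            uniform_params(sd=(1.0, 0.0))

    def test_invalid_probability_parameters_rejected(self):
        with pytest.raises(ValueError):
            _params([0.5, 0.5, 0.2, -0.2], np.full((4, 4), 0.25), (2, 2), (1, 1))
        A = np.full((4, 4), 0.25)
        A[2, 2] = 0.3
        with pytest.raises(ValueError):
            _params(np.full(4, 0.25), A, (2, 2), (1, 1))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

class TestForwardBackward:
    def test_single_site_base_case(self, rng):
        params = random_chmm_params(rng)
        zmat = random_zmatrix(rng, 1)
        fwd, scale, ll = rl.forward_pass(zmat, params)
        B = emission_matrix(zmat, params)
        expected = params.pi * B[0]
        assert scale[0] == pytest.approx(expected.sum(), rel=1e-12)
        np.testing.assert_allclose(fwd[0], expected / expected.sum(), atol=1e-14)
        assert ll == pytest.approx(np.log(expected.sum()), rel=1e-12)

    def test_terminal_backward_row_is_constant(self, rng):
        params = random_chmm_params(rng)
        zmat = random_zmatrix(rng, 4)
        beta = rl.backward_pass(zmat, params)
        np.testing.assert_allclose(beta[-1], 1.0, atol=0)

    def test_backward_equals_suffix_enumeration(self, rng):
        """Unscaled beta_j(u) = P(z_{j+1:m} | state_j = u), enumerated over
        all state suffixes without the recursion."""
        import itertools

        params = random_chmm_params(rng)
        m = 3
        zmat = random_zmatrix(rng, m)
        B = emission_matrix(zmat, params)
        _, scale, _ = rl.forward_pass(zmat, params)
        beta = rl.backward_pass(zmat, params)
        for j in range(m):
            # undo the shared scaling: unscaled = scaled * prod(scale[j+1:])
            unscaled = beta[j] * np.prod(scale[j + 1 :])
            for u in range(4):
                total = 0.0
                for suffix in itertools.product(range(4), repeat=m - 1 - j):
                    prob, prev = 1.0, u
                    for k, v in enumerate(suffix):
                        prob *= params.A[prev, v] * B[j + 1 + k, v]
                        prev = v
                    total += prob
                assert unscaled[u] == pytest.approx(total, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_posteriors_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        params = random_chmm_params(rng)
        zmat = random_zmatrix(rng, m)
        post = rl.posteriors(zmat, params)
        gamma, loglik, xi = rl.brute_force_posteriors(zmat, params, return_pairwise=True)
        np.testing.assert_allclose(post.gamma, gamma, atol=1e-10)
        np.testing.assert_allclose(post.xi, xi, atol=1e-10)
        np.testing.assert_allclose(post.replis, gamma[:, :3].sum(axis=1), atol=1e-10)
        assert post.loglik == pytest.approx(loglik, abs=1e-10)

    def test_scaled_equals_unscaled_recursion(self, rng):
        """Per-site normalisation must not change the posteriors: compare
        with a plain unscaled forward-backward run in the test."""
        params = random_chmm_params(rng)
        m = 8
        zmat = random_zmatrix(rng, m)
        B = emission_matrix(zmat, params)
        a = np.zeros((m, 4))
        a[0] = params.pi * B[0]
        for j in range(1, m):
            a[j] = (a[j - 1] @ params.A) * B[j]
        b = np.zeros((m, 4))
        b[-1] = 1.0
        for j in range(m - 2, -1, -1):
            b[j] = params.A @ (B[j + 1] * b[j + 1])
        gamma_unscaled = a * b
        gamma_unscaled /= gamma_unscaled.sum(axis=1, keepdims=True)
        post = rl.posteriors(zmat, params)
        np.testing.assert_allclose(post.gamma, gamma_unscaled, atol=1e-10)
        assert post.loglik == pytest.approx(np.log(a[-1].sum()), rel=1e-10)

    def test_exp_loglik_is_a_normalised_density(self, rng):
        """For m=1 the likelihood must integrate to 1 over (z1, z2).
        Step 1: exp(loglik) agrees with the direct mixture density at
        random points; step 2: that density integrates to 1 by quadrature."""
        params = random_chmm_params(rng)
        for _ in range(25):
            z = rng.normal(scale=3.0, size=(1, 2))
            _, _, ll = rl.forward_pass(rl.ZMatrix(z), params)
            B = emission_matrix(rl.ZMatrix(z), params)
            assert np.exp(ll) == pytest.approx(float(B[0] @ params.pi), rel=1e-12)
        lo = -9.0
        hi = 9.0 + params.alt_means.max() * params.alt_sds.max() + 6
        nodes, weights = np.polynomial.legendre.leggauss(120)
        x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * weights
        zz = np.column_stack(
            [np.repeat(x, x.size), np.tile(x, x.size)]
        )
        B = emission_matrix(rl.ZMatrix(zz), params)
        dens = B @ params.pi
        integral = float((np.outer(w, w).ravel() * dens).sum())
        assert integral == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# degenerate and structural cases
# ---------------------------------------------------------------------------

class TestDegenerateChains:
    def test_independence_chain_reduces_to_sitewise_posterior(self, rng):
        """Rows of A equal to pi make states i.i.d.; repLIS then equals the
        closed-form two-group posterior null probability site by site."""
        pi = rng.dirichlet(np.ones(4))
        params = _params(pi, np.tile(pi, (4, 1)), (2.5, 3.0), (1.0, 1.3))
        zmat = random_zmatrix(rng, 50)
        post = rl.posteriors(zmat, params)
        B = emission_matrix(zmat, params)
        sitewise = pi[None, :] * B
        sitewise /= sitewise.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post.gamma, sitewise, atol=1e-12)
        np.testing.assert_allclose(post.replis, 1 - sitewise[:, 3], atol=1e-12)
        beta = post.backward
        np.testing.assert_allclose(beta - beta[:, :1], 0.0, atol=1e-12)  # constant rows

    def test_permutation_sensitivity(self, rng):
        """A sticky chain uses neighbourhood information, so site order
        matters; under the independence chain it cannot."""
        zmat = random_zmatrix(rng, 40)
        perm = rng.permutation(40)
        sticky = sticky_params()
        r = rl.posteriors(zmat, sticky).replis
        r_perm = rl.posteriors(rl.ZMatrix(zmat.z[perm]), sticky).replis
        assert np.abs(r[perm] - r_perm).max() > 1e-6
        pi = np.full(4, 0.25)
        indep = _params(pi, np.tile(pi, (4, 1)), (3.0, 2.0), (1.0, 1.0))
        r = rl.posteriors(zmat, indep).replis
        r_perm = rl.posteriors(rl.ZMatrix(zmat.z[perm]), indep).replis
        np.testing.assert_allclose(r[perm], r_perm, atol=1e-12)

    def test_point_mass_deterministic_chain(self, rng):
        pi = np.zeros(4)
        pi[2] = 1.0
        params = _params(pi, np.eye(4), (2.0, 2.0), (1.0, 1.0))
        zmat = random_zmatrix(rng, 2)
        gamma, _ = rl.brute_force_posteriors(zmat, params)
        expected = np.zeros((2, 4))
        expected[:, 2] = 1.0
        np.testing.assert_allclose(gamma, expected, atol=1e-14)
        np.testing.assert_allclose(rl.posteriors(zmat, params).gamma, expected, atol=1e-14)

    def test_single_site_closed_form(self):
        """m=1: the chain contributes only pi; repLIS has the hand-derived
        closed form 1 - phi(-2)^2 / (phi(0)+phi(-2))^2 at z=(0,0)."""
        params = uniform_params(mu=(2.0, 2.0))
        post = rl.posteriors(params=params, zmat=rl.ZMatrix([[0.0, 0.0]]))
        phi0, phi2 = norm.pdf(0.0), norm.pdf(-2.0)
        expected = 1 - phi2 ** 2 / (phi0 ** 2 + 2 * phi0 * phi2 + phi2 ** 2)
        assert post.replis[0] == pytest.approx(expected, abs=1e-12)
        assert post.replis[0] == pytest.approx(0.9858, abs=5e-5)

    def test_enumeration_cap_enforced(self, rng):
        params = random_chmm_params(rng)
        zmat = random_zmatrix(rng, 11)
        with pytest.raises(ValueError, match="enumeration"):
            rl.brute_force_posteriors(zmat, params)
        # configurable cap
        rl.brute_force_posteriors(random_zmatrix(rng, 3), params, max_sites=3)


# ---------------------------------------------------------------------------
# invariants (property-based)
# ---------------------------------------------------------------------------

@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1), m=st.integers(1, 30))
def test_posterior_invariants(seed, m):
    """gamma rows and xi slices are distributions; xi marginals recover
    gamma; repLIS is the null-state posterior mass, inside [0, 1]."""
    rng = np.random.default_rng(seed)
    params = random_chmm_params(rng)
    post = rl.posteriors(random_zmatrix(rng, m), params)
    np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)
    assert post.gamma.min() >= 0 and post.gamma.max() <= 1 + 1e-12
    assert post.replis.min() >= 0 and post.replis.max() <= 1
    np.testing.assert_allclose(post.replis, 1 - post.gamma[:, 3], atol=1e-10)
    if m > 1:
        np.testing.assert_allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)
        np.testing.assert_allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-8)
        np.testing.assert_allclose(post.xi.sum(axis=1), post.gamma[1:], atol=1e-8)
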