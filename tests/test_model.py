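"""Model-implied covariance structure of the MR-DoC twin model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrdoc import (
    ParameterVector,
    expected_covariance,
    implied_moments_unrelated,
    make_candidate_spec,
)
from mrdoc.model import MZ_KEEP, PARAM_NAMES, StructuralModelError

from conftest import random_admissible_theta


def test_independent_standardized_variables():
    """With all paths zero and unit E loadings every within-person moment is
    the identity; only the genetically shared polygenic score correlates
    across co-twins (fully for MZ, half for DZ)."""
    theta = ParameterVector(e_x=1.0, e_y=1.0, x=1.0)
    for zyg, m in (("MZ", 1.0), ("DZ", 0.5)):
        expected = np.eye(6)
        expected[0, 3] = expected[3, 0] = m
        np.testing.assert_allclose(expected_covariance(theta, zyg), expected, atol=1e-14)
    np.testing.assert_allclose(implied_moments_unrelated(theta), np.eye(3), atol=1e-14)


@pytest.mark.parametrize("zyg,factor", [("MZ", 1.0), ("DZ", 0.5)])
def test_cross_twin_pgs_covariance_tracks_zygosity(zyg, factor, rng):
    """Co-twins share all (MZ) or on average half (DZ) of the additive score,
    so cov(PGS1, PGS2) is x^2 or x^2/2."""
    theta = random_admissible_theta(rng)
    sigma = expected_covariance(theta, zyg)
    assert sigma[0, 3] == pytest.approx(factor * theta.x**2, rel=1e-12)
    assert sigma[0, 0] == pytest.approx(theta.x**2, rel=1e-12)


def test_unrelated_moments_equal_within_twin_block(rng):
    for _ in range(5):
        theta = random_admissible_theta(rng)
        np.testing.assert_allclose(
            implied_moments_unrelated(theta),
            expected_covariance(theta, "MZ")[:3, :3],
            atol=1e-12,
        )


def test_iv_ratio_identity_on_population_moments(rng):
    """cov(Y, PGS)/cov(X, PGS) = g1 + b2/b1 — the standard-MR estimand."""
    for _ in range(10):
        theta = random_admissible_theta(rng, g2=0.0)
        m = implied_moments_unrelated(theta)
        assert m[0, 2] / m[0, 1] == pytest.approx(theta.g1 + theta.b2 / theta.b1, rel=1e-10)


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.sampled_from(["MZ", "DZ"]))
def test_covariance_symmetric_psd(seed, zyg):
    theta = random_admissible_theta(np.random.default_rng(seed))
    sigma = expected_covariance(theta, zyg)
    np.testing.assert_allclose(sigma, sigma.T, atol=1e-14)
    assert np.linalg.eigvalsh(sigma).min() >= -1e-10


def test_mz_dz_differ_only_in_a_and_pgs_cross_blocks(rng):
    """C-factor and E-factor cross-twin structure is zygosity-independent,
    so the MZ and DZ matrices agree except where A-factors or the polygenic
    score enter the cross-twin covariance."""
    theta = random_admissible_theta(rng)
    mz = expected_covariance(theta, "MZ")
    dz = expected_covariance(theta, "DZ")
    np.testing.assert_allclose(mz[:3, :3], dz[:3, :3], atol=1e-12)
    np.testing.assert_allclose(mz[3:, 3:], dz[3:, 3:], atol=1e-12)
    # Removing all additive-genetic routes (background A and the score)
    # makes the cross-twin blocks zygosity-independent.
    theta_no_a = theta.replace(a_x=0.0, a_y=0.0, b1=0.0, b2=0.0, x=1e-6)
    np.testing.assert_allclose(
        expected_covariance(theta_no_a, "MZ")[:3, 3:],
        expected_covariance(theta_no_a, "DZ")[:3, 3:],
        atol=1e-12,
    )


def test_mz_matrix_singular_pgs_duplicated(rng):
    """MZ co-twins carry identical polygenic scores: the 6x6 MZ matrix has
    the PGS rows duplicated and is singular, while the reduced 5-variate
    system is full rank."""
    theta = random_admissible_theta(rng)
    mz = expected_covariance(theta, "MZ")
    np.testing.assert_allclose(mz[0], mz[3], atol=1e-12)
    reduced = mz[np.ix_(MZ_KEEP, MZ_KEEP)]
    assert np.linalg.eigvalsh(reduced).min() > 1e-8


def test_pgs_marginalization_reproduces_bivariate_doc(rng):
    """With b1 = b2 = 0 the (X, Y) block is the classical bivariate DoC
    structure, checked against independent path-tracing algebra."""
    theta = random_admissible_theta(rng, b1=0.0, b2=0.0, g2=0.0)
    g1 = theta.g1
    # Path tracing for Y = ACE_Y + g1 X, X = ACE_X:
    vx = theta.a_x**2 + theta.c_x**2 + theta.e_x**2
    cxy_resid = (theta.ra * theta.a_x * theta.a_y + theta.rc * theta.c_x * theta.c_y
                 + theta.re * theta.e_x * theta.e_y)
    vy = theta.a_y**2 + theta.c_y**2 + theta.e_y**2 + g1**2 * vx + 2 * g1 * cxy_resid
    for zyg, m in (("MZ", 1.0), ("DZ", 0.5)):
        sigma = expected_covariance(theta, zyg)
        assert sigma[1, 1] == pytest.approx(vx, rel=1e-12)
        assert sigma[2, 2] == pytest.approx(vy, rel=1e-12)
        assert sigma[1, 2] == pytest.approx(g1 * vx + cxy_resid, rel=1e-12)
        # cross-twin within-trait X
        ct_x = m * theta.a_x**2 + theta.c_x**2
        assert sigma[1, 4] == pytest.approx(ct_x, rel=1e-12)
        # cross-twin cross-trait X1-Y2
        ct_xy = m * theta.ra * theta.a_x * theta.a_y + theta.rc * theta.c_x * theta.c_y
        assert sigma[1, 5] == pytest.approx(ct_xy + g1 * ct_x, rel=1e-12)


def test_monte_carlo_latent_oracle(rng):
    """Sampling the latent A/C/E factors and polygenic score explicitly and
    applying the structural equations reproduces the covariance algebra."""
    n = 200_000
    for _ in range(3):
        theta = random_admissible_theta(rng, g2=0.0)
        for zyg, m in (("MZ", 1.0), ("DZ", 0.5)):
            sim = _simulate_from_latents(theta, m, n, rng)
            emp = np.cov(sim.T, ddof=1)
            target = expected_covariance(theta, zyg)
            # 3 Monte-Carlo standard errors, elementwise
            se = 3 * np.sqrt(
                (np.outer(np.diag(target), np.diag(target)) + target**2) / n
            )
            assert np.all(np.abs(emp - target) < se + 1e-12)


def _simulate_from_latents(theta, m, n, rng):
    def corr4(r_within, r_cross_within, r_cross_between):
        return np.array([
            [1.0, r_within, r_cross_within, r_cross_between],
            [r_within, 1.0, r_cross_between, r_cross_within],
            [r_cross_within, r_cross_between, 1.0, r_within],
            [r_cross_between, r_cross_within, r_within, 1.0],
        ])

    def draw(c):
        vals, vecs = np.linalg.eigh(c)
        root = vecs * np.sqrt(np.clip(vals, 0, None))
        return rng.standard_normal((n, c.shape[0])) @ root.T

    A = draw(corr4(theta.ra, m, m * theta.ra))          # AX1 AY1 AX2 AY2
    C = draw(corr4(theta.rc, 1.0, theta.rc))
    E = draw(corr4(theta.re, 0.0, 0.0))
    P = draw(np.array([[1.0, m], [m, 1.0]]))
    out = np.empty((n, 6))
    for j in range(2):
        X = (theta.a_x * A[:, 2 * j] + theta.c_x * C[:, 2 * j]
             + theta.e_x * E[:, 2 * j] + theta.b1 * P[:, j])
        Y = (theta.a_y * A[:, 2 * j + 1] + theta.c_y * C[:, 2 * j + 1]
             + theta.e_y * E[:, 2 * j + 1] + theta.g1 * X + theta.b2 * P[:, j])
        out[:, 3 * j] = theta.x * P[:, j]
        out[:, 3 * j + 1] = X
        out[:, 3 * j + 2] = Y
    return out


def test_reciprocal_variant_reduced_form():
    """With both causal paths active the covariance follows the
    simultaneous-equations reduced form, and g1*g2 = 1 is rejected."""
    theta = ParameterVector(e_x=1.0, e_y=1.0, g1=0.5, g2=0.4, x=1.0)
    sigma = expected_covariance(theta, "DZ")
    det = 1 - 0.5 * 0.4
    # X = (e_x E_X + g2 e_y E_Y)/det -> Var(X) = (1 + g2^2)/det^2
    assert sigma[1, 1] == pytest.approx((1 + 0.4**2) / det**2, rel=1e-12)
    with pytest.raises(StructuralModelError):
        ParameterVector(g1=2.0, g2=0.5)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        ParameterVector(x=0.0)
    with pytest.raises(ValueError):
        ParameterVector(ra=1.5)
    with pytest.raises(ValueError):
        expected_covariance(ParameterVector(), "XY")


class TestCandidateSpecs:
    def test_patterns(self):
        s1 = make_candidate_spec(1)
        assert s1.n_free == 13 and not s1.is_free("g2")
        assert make_candidate_spec(2).fixed == {"g2": 0.0, "re": 0.0}
        assert make_candidate_spec(3).fixed == {"g2": 0.0, "b2": 0.0}
        assert make_candidate_spec(5).fixed == {"g2": 0.0, "c_x": 0.0, "c_y": 0.0, "rc": 0.0}
        assert make_candidate_spec(6).fixed == {"g2": 0.0, "c_y": 0.0, "rc": 0.0}

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            make_candidate_spec(8)

    def test_nesting_and_counts(self):
        full = make_candidate_spec(2)
        nested = full.constrain(g1=0.0)
        assert nested.is_nested_in(full)
        assert not full.is_nested_in(nested)
        assert nested.n_free == full.n_free - 1
        assert set(nested.free_names) | {"g1"} == set(full.free_names)
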