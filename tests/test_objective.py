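import numpy as np
import pytest

from patjrec.forward import Medium, simulate_forward
from patjrec.grid import make_grid, place_sensors
from patjrec.objective import (
    JointProblem,
    UnknownVector,
    evaluate_objective,
    gradient_c,
    gradient_p0,
    stack_gradient,
)
from patjrec.priors import NoiseModel, build_ou_prior, prior_gradient



def make_priors(grid, p0_mean=5.0, c_mean=1505.0):
    xi = grid.interior_coords()
    xx, yy = np.meshgrid(xi, xi, indexing="ij")
    coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
    return (
        build_ou_prior(coords, 2.5, 1.5e-3, p0_mean),
        build_ou_prior(coords, 37.5, 1.5e-3, c_mean),
    )


@pytest.fixture
def tiny_setup(rng):
    g = make_grid(16, 3e-4, 2, 5, 5.5e-8, 40)
    sensors = place_sensors(g, 16, 4e-4)
    p0_prior, c_prior = make_priors(g)
    c_true = 1430.0 + 150.0 * (rng.random((16, 16)) > 0.7)
    med = Medium(np.pad(c_true, 7, constant_values=1430.0), c_ref=1800.0)
    p0s = [10.0 * rng.random((16, 16)) for _ in range(2)]
    data = [
        simulate_forward(med, p, g, sensors, dataset_index=i)[0]
        for i, p in enumerate(p0s)
    ]
    noise = [NoiseModel(0.01 * (d.y.max() - d.y.min())) for d in data]
    problem = JointProblem(
        g, sensors, data, p0_prior, c_prior, noise, c_background=1430.0, c_ref=1800.0
    )
    return g, sensors, problem, p0s, c_true, data, noise, p0_prior, c_prior


class TestUnknownVector:
    def test_pack_unpack_roundtrip(self, rng):
        p0s = [rng.random((8, 8)) for _ in range(4)]
        c = rng.random((8, 8))
        x = UnknownVector.pack(p0s, c)
        back_p, back_c = x.unpack()
        for a, b in zip(p0s, back_p):
            assert np.array_equal(a, b)
        assert np.array_equal(c, back_c)
        assert x.vector.size == 5 * 64

    def test_stacked_norm_is_block_norm(self, rng):
        blocks = [rng.random((6, 6)) for _ in range(3)]
        c = rng.random((6, 6))
        g = stack_gradient(blocks, c)
        expect = np.sqrt(sum(np.sum(b**2) for b in blocks) + np.sum(c**2))
        assert np.linalg.norm(g.vector) == pytest.approx(expect)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            UnknownVector(np.zeros(10), 2, 4)


class TestEvaluateObjective:
    def test_truth_with_centred_priors_is_zero(self, tiny_setup):
        g, sensors, _, p0s, c_true, data, noise, _, _ = tiny_setup
        xi = g.interior_coords()
        xx, yy = np.meshgrid(xi, xi, indexing="ij")
        coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
        # priors centred exactly at the truth
        p0_prior = build_ou_prior(coords, 2.5, 1.5e-3, p0s[0].ravel())
        # can't centre one prior at two different p0 truths; use I=1 here
        c_prior = build_ou_prior(coords, 37.5, 1.5e-3, c_true.ravel())
        x = UnknownVector.pack([p0s[0]], c_true)
        rep = evaluate_objective(
            x, data[:1], p0_prior, c_prior, noise[:1], g, sensors,
            c_background=1430.0, c_ref=1800.0,
        )
        assert rep.total == pytest.approx(0.0, abs=1e-10)

    def test_doubling_noise_std_quarters_data_term(self, tiny_setup, rng):
        g, sensors, problem, p0s, c_true, data, noise, p0_prior, c_prior = tiny_setup
        x = UnknownVector.pack([5 + rng.random((16, 16)) for _ in range(2)], np.full((16, 16), 1480.0))
        rep1 = problem.objective_report(x)
        noise2 = [NoiseModel(2 * n.sigma) for n in noise]
        problem2 = JointProblem(
            g, sensors, data, p0_prior, c_prior, noise2, c_background=1430.0, c_ref=1800.0
        )
        rep2 = problem2.objective_report(x)
        for a, b in zip(rep1.data_terms, rep2.data_terms):
            assert b == pytest.approx(a / 4.0)
        assert rep1.prior_c_term == pytest.approx(rep2.prior_c_term)

    def test_matches_bruteforce_composition(self, tiny_setup, rng):
        """End-to-end oracle: independently scripted forward + norms."""
        g, sensors, _, _, _, data, noise, p0_prior, c_prior = tiny_setup
        p0 = 5 + rng.random((16, 16))
        c = 1480 + 20 * rng.random((16, 16))
        x = UnknownVector.pack([p0], c)
        rep = evaluate_objective(
            x, data[:1], p0_prior, c_prior, noise[:1], g, sensors,
            c_background=1430.0, c_ref=1800.0,
        )
        # brute force
        c_full = np.full((g.n_total,) * 2, 1430.0)
        c_full[g.interior_slice, g.interior_slice] = c
        y, _ = simulate_forward(Medium(c_full, c_ref=1800.0), p0, g, sensors)
        r = (y.y - data[0].y) / noise[0].sigma
        expect = 0.5 * np.sum(r**2)
        rp = p0.ravel() - p0_prior.mean
        expect += 0.5 * rp @ np.linalg.solve(p0_prior.gamma, rp)
        rc = c.ravel() - c_prior.mean
        expect += 0.5 * rc @ np.linalg.solve(c_prior.gamma, rc)
        assert rep.total == pytest.approx(expect, rel=1e-10)


class TestGradients:
    def test_gradient_p0_reduces_to_prior_without_residual(self, tiny_setup, rng):
        _, _, _, _, _, _, _, p0_prior, _ = tiny_setup
        p0 = rng.random((16, 16))
        zero_term = np.zeros((16, 16))
        g1 = gradient_p0(zero_term, p0, p0_prior)
        assert np.allclose(g1, prior_gradient(p0, p0_prior))
        assert not gradient_p0(zero_term, np.full((16, 16), 5.0), p0_prior).any()

    def test_gradient_c_requires_pairing_or_movie(self, tiny_setup):
        from patjrec.adjoint import AdjointField

        g, _, _, _, _, _, _, _, c_prior = tiny_setup
        bare = AdjointField(terminal=np.zeros((g.n_total,) * 2))
        with pytest.raises(ValueError, match="record_full"):
            gradient_c([bare], np.full((16, 16), 1505.0), c_prior, g)

    def test_stacked_gradient_matches_finite_differences(self, tiny_setup, rng):
        g, _, problem, _, _, _, _, _, _ = tiny_setup
        x = UnknownVector.pack(
            [5 + 2 * rng.random((16, 16)) for _ in range(2)],
            1480 + 30 * rng.random((16, 16)),
        )
        f0, grad = problem.objective_and_gradient(x.vector)
        n_pix = 16 * 16
        for _ in range(5):
            d = rng.standard_normal(x.vector.size)
            d[-n_pix:] *= 30.0  # comparable physical scales per block
            h = 1e-4
            fp = problem.objective(x.vector + h * d)
            fm = problem.objective(x.vector - h * d)
            fd = (fp - fm) / (2 * h)
            assert abs(fd - grad @ d) / abs(fd) < 1e-6

    def test_gradient_c_data_term_scales_inversely_with_frozen_fields(self, tiny_setup, rng):
        """With frozen forward/adjoint pairings the misfit part of the
        speed gradient carries the explicit 2/c factor."""
        from patjrec.adjoint import AdjointField

        g, _, _, _, _, _, _, _, c_prior = tiny_setup
        n_tot = g.n_total
        adj = AdjointField(
            terminal=rng.standard_normal((n_tot, n_tot)),
            pair_sum=rng.standard_normal((n_tot, n_tot)),
            pair_init=rng.standard_normal((n_tot, n_tot)),
        )
        c1 = np.full((16, 16), 1500.0)
        g1 = gradient_c([adj], c1, c_prior, g) - prior_gradient(c1, c_prior)
        g2 = gradient_c([adj], 2 * c1, c_prior, g) - prior_gradient(2 * c1, c_prior)
        assert np.allclose(g2, g1 / 2.0, rtol=1e-12)

    def test_data_gradient_for_c_sums_over_datasets(self, tiny_setup, rng):
        """With identical datasets the misfit c-gradient doubles for I=2."""
        g, sensors, _, p0s, c_true, data, noise, p0_prior, c_prior = tiny_setup
        dup = [data[0], data[0]]
        noise2 = [noise[0], noise[0]]
        x1 = UnknownVector.pack([p0s[0]], np.full((16, 16), 1505.0))
        x2 = UnknownVector.pack([p0s[0], p0s[0]], np.full((16, 16), 1505.0))
        prob1 = JointProblem(g, sensors, dup[:1], p0_prior, c_prior, noise2[:1],
                             c_background=1430.0, c_ref=1800.0)
        prob2 = JointProblem(g, sensors, dup, p0_prior, c_prior, noise2,
                             c_background=1430.0, c_ref=1800.0)
        _, g1 = prob1.objective_and_gradient(x1.vector)
        _, g2 = prob2.objective_and_gradient(x2.vector)
        n_pix = 16 * 16
        prior_c = prior_gradient(np.full((16, 16), 1505.0), c_prior).ravel()
        data1 = g1[-n_pix:] - prior_c
        data2 = g2[-n_pix:] - prior_c
        assert np.allclose(data2, 2.0 * data1, rtol=1e-10)
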