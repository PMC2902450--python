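"""Forward algorithm, posteriors, and ancestral/conditional sampling
against brute-force enumeration and quadrature oracles."""

import numpy as np
import pytest
from scipy import stats

from conftest import enumerate_loglik, enumerate_posterior
from sidechaindbn.inference import (chi_density_grid, forward, loglik_chi,
                                    posterior_hidden, sample_ancestral,
                                    sample_conditional)
from sidechaindbn.model import ModelParams, ResidueAngles, default_spec
from sidechaindbn.synthetic import make_ground_truth


def uniform_emission_model(H, K):
    rng = np.random.default_rng(8)
    return ModelParams(initial=rng.dirichlet(np.ones(H), size=K),
                       transition=rng.dirichlet(np.ones(H), size=(K, H)),
                       emission_mu=np.zeros(H), emission_kappa=np.zeros(H))


class TestForward:
    def test_matches_enumeration(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        idx = spec.slice_sequence("HIS")
        for ev in ([0.3, -1.2, 2.0, -2.5],
                   [0.3, None, None, -2.5],
                   [None, -1.2, 2.0, None]):
            assert forward(params, idx, ev).loglik == pytest.approx(
                enumerate_loglik(params, idx, ev), abs=1e-10)

    def test_six_slice_chain(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        idx = spec.slice_sequence("LYS")  # 6 slices
        ev = [0.1, 0.2, -0.3, 1.0, -1.5, 2.2]
        assert forward(params, idx, ev).loglik == pytest.approx(
            enumerate_loglik(params, idx, ev), abs=1e-9)

    def test_uniform_emissions_give_exact_constant(self):
        params = uniform_emission_model(3, 4)
        ll = forward(params, [0, 1, 2, 3], [0.5, -0.5, 1.0, 2.0]).loglik
        assert ll == pytest.approx(-4 * np.log(2 * np.pi), abs=1e-12)

    def test_full_marginalization_is_zero(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        idx = spec.slice_sequence("LYS")
        assert forward(params, idx, [None] * 6).loglik == pytest.approx(0.0, abs=1e-12)

    def test_index_out_of_range(self, toy_truth):
        with pytest.raises(ValueError):
            forward(toy_truth.params, [9999], [0.1])


class TestLoglikChi:
    def test_conditional_matches_enumeration_ratio(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        rec = ResidueAngles("HIS", 0.4, -0.9, (1.2, -2.0))
        idx = spec.slice_sequence("HIS")
        expect = (enumerate_loglik(params, idx, [0.4, -0.9, 1.2, -2.0])
                  - enumerate_loglik(params, idx, [0.4, -0.9, None, None]))
        got = loglik_chi(params, spec, rec, "conditional")
        assert got == pytest.approx(expect, abs=1e-10)

    def test_marginal_matches_enumeration(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        rec = ResidueAngles("HIS", None, None, (1.2, -2.0))
        idx = spec.slice_sequence("HIS")
        assert loglik_chi(params, spec, rec, "marginal") == pytest.approx(
            enumerate_loglik(params, idx, [None, None, 1.2, -2.0]), abs=1e-10)

    def test_h1_conditional_equals_marginal(self):
        truth = make_ground_truth(3, hidden_size=1,
                                  require_backbone_coupling=False)
        rec = ResidueAngles("SER", 0.5, -0.5, (1.0,))
        c = loglik_chi(truth.params, truth.spec, rec, "conditional")
        m = loglik_chi(truth.params, truth.spec, rec, "marginal")
        assert c == pytest.approx(m, abs=1e-10)

    def test_conditional_requires_backbone(self, toy_truth):
        rec = ResidueAngles("SER", None, None, (1.0,))
        with pytest.raises(ValueError):
            loglik_chi(toy_truth.params, toy_truth.spec, rec, "conditional")

    def test_conditional_density_normalizes(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        grid = np.linspace(-np.pi, np.pi, 2001)
        dens = chi_density_grid(params, spec, "SER", grid, backbone=(0.5, -1.0))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_marginal_density_normalizes(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        grid = np.linspace(-np.pi, np.pi, 2001)
        dens = chi_density_grid(params, spec, "SER", grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestPosterior:
    def test_matches_enumeration(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        idx = spec.slice_sequence("HIS")
        ev = [0.3, None, 2.0, -2.5]
        got = posterior_hidden(params, idx, ev)
        assert np.allclose(got, enumerate_posterior(params, idx, ev), atol=1e-10)
        assert np.allclose(got.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_model_no_evidence(self):
        H, K = 3, 4
        params = ModelParams(initial=np.full((K, H), 1 / H),
                             transition=np.full((K, H, H), 1 / H),
                             emission_mu=np.zeros(H), emission_kappa=np.ones(H))
        post = posterior_hidden(params, [0, 1, 2], [None, None, None])
        assert np.allclose(post, 1 / H, atol=1e-12)

    def test_sharp_emission_kills_far_component(self):
        params = ModelParams(initial=np.array([[0.5, 0.5]]),
                             transition=np.full((1, 2, 2), 0.5),
                             emission_mu=np.array([0.0, np.pi * 0.9]),
                             emission_kappa=np.array([300.0, 300.0]))
        post = posterior_hidden(params, [0], [0.0])
        assert post[0, 1] < 1e-10


class TestSampling:
    def test_seed_determinism(self, toy_truth):
        a = sample_ancestral(toy_truth.params, toy_truth.spec, "HIS", 100, 5)
        b = sample_ancestral(toy_truth.params, toy_truth.spec, "HIS", 100, 5)
        assert all(x.chi == y.chi and x.phi == y.phi for x, y in zip(a, b))
        ca = sample_conditional(toy_truth.params, toy_truth.spec, "SER",
                                0.5, -1.0, 100, 5)
        cb = sample_conditional(toy_truth.params, toy_truth.spec, "SER",
                                0.5, -1.0, 100, 5)
        assert np.array_equal(ca, cb)

    def test_h1_model_angles_iid_vonmises(self):
        truth = make_ground_truth(3, hidden_size=1,
                                  require_backbone_coupling=False)
        recs = sample_ancestral(truth.params, truth.spec, "SER", 50_000, 9)
        angles = np.array([r.chi[0] for r in recs])
        mu = float(truth.params.emission_mu[0])
        mean = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
        assert abs(mean - mu) < 0.05

    def _hist_pvalue(self, samples, density_fn):
        from conftest import hist_chisq_pvalue
        return hist_chisq_pvalue(samples, density_fn)

    def test_ancestral_histogram_matches_marginal(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        recs = sample_ancestral(params, spec, "SER", 100_000, 13)
        chi = np.array([r.chi[0] for r in recs])
        p = self._hist_pvalue(chi, lambda g: chi_density_grid(params, spec,
                                                              "SER", g))
        assert p > 0.001

    def test_conditional_histogram_matches_conditional_density(self, toy_truth):
        params, spec = toy_truth.params, toy_truth.spec
        chi = sample_conditional(params, spec, "SER", 0.5, -1.0, 100_000, 11)
        p = self._hist_pvalue(chi[:, 0],
                              lambda g: chi_density_grid(params, spec, "SER", g,
                                                         backbone=(0.5, -1.0)))
        assert p > 0.001

    def test_memoryless_transitions_decouple_backbone(self):
        # transition rows identical across inputs AND previous states ->
        # hidden states are independent between slices, so backbone
        # observations cannot inform the chi slices
        truth = make_ground_truth(2, hidden_size=2,
                                  require_backbone_coupling=False)
        params = truth.params
        params.initial[:] = params.initial[0]
        params.transition[:, :, :] = params.transition[0, 0, :]
        spec = truth.spec
        cond = sample_conditional(params, spec, "SER", 0.5, -1.0, 30_000, 3)[:, 0]
        recs = sample_ancestral(params, spec, "SER", 30_000, 4)
        marg = np.array([r.chi[0] for r in recs])
        assert stats.ks_2samp(cond, marg).pvalue > 0.001

    def test_conditional_samples_score_higher_than_ancestral(self, toy_truth):
        # Gibbs inequality: E_q[log q] >= E_p[log q] for the conditional q
        params, spec = toy_truth.params, toy_truth.spec
        phi, psi = 0.5, -1.0
        cond = sample_conditional(params, spec, "SER", phi, psi, 10_000, 21)
        recs = sample_ancestral(params, spec, "SER", 10_000, 22)

        def mean_cond_ll(chis):
            return np.mean([loglik_chi(params, spec,
                                       ResidueAngles("SER", phi, psi, (c,)),
                                       "conditional") for c in chis])

        assert mean_cond_ll(cond[:, 0]) >= mean_cond_ll(
            [r.chi[0] for r in recs]) - 0.02
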