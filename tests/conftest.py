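"""Shared fixtures and independent oracles.

The enumeration oracle computes chain likelihoods by explicit summation over
all hidden-state sequences, independently of the forward implementation, and
is the reference for every likelihood/posterior test on toy models.
"""

import itertools

import numpy as np
import pytest

from sidechaindbn.circular import VonMisesParams, vm_logpdf
from sidechaindbn.synthetic import make_ground_truth


def enumerate_loglik(params, indices, evidence):
    """Brute-force log-likelihood: sum over all H^T hidden sequences."""
    H = params.hidden_size
    total = 0.0
    for hs in itertools.product(range(H), repeat=len(indices)):
        p = params.initial[indices[0]][hs[0]]
        for t in range(1, len(indices)):
            p *= params.transition[indices[t]][hs[t - 1], hs[t]]
        for t, x in enumerate(evidence):
            if x is not None:
                p *= np.exp(vm_logpdf(x, VonMisesParams(
                    float(params.emission_mu[hs[t]]),
                    float(params.emission_kappa[hs[t]]))))
        total += p
    return np.log(total)


def enumerate_posterior(params, indices, evidence):
    """Brute-force per-slice hidden-state posteriors."""
    H = params.hidden_size
    T = len(indices)
    post = np.zeros((T, H))
    for hs in itertools.product(range(H), repeat=T):
        p = params.initial[indices[0]][hs[0]]
        for t in range(1, T):
            p *= params.transition[indices[t]][hs[t - 1], hs[t]]
        for t, x in enumerate(evidence):
            if x is not None:
                p *= np.exp(vm_logpdf(x, VonMisesParams(
                    float(params.emission_mu[hs[t]]),
                    float(params.emission_kappa[hs[t]]))))
        for t in range(T):
            post[t, hs[t]] += p
    return post / post.sum(axis=1, keepdims=True)


def hist_chisq_pvalue(samples, density_fn, n_bins=40, min_expected=10.0):
    """Chi-square goodness-of-fit of samples against a circular density.

    Expected bin probabilities are integrated over each bin on a fine
    sub-grid (sharp densities make the bin-center approximation fail), and
    low-expectation bins are merged into their neighbours so the chi-square
    approximation is valid.
    """
    from scipy import stats

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    obs, _ = np.histogram(samples, bins=edges)
    fine = np.linspace(-np.pi, np.pi, n_bins * 32 + 1)
    dens = density_fn(fine)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                           * np.diff(fine))])
    cdf /= cdf[-1]
    probs = np.diff(np.interp(edges, fine, cdf))
    expected = probs * obs.sum()
    # merge adjacent bins until every expected count is adequate
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if exp_m:
        obs_m[-1] += o_acc
        exp_m[-1] += e_acc
    obs_m, exp_m = np.array(obs_m), np.array(exp_m)
    exp_m *= obs_m.sum() / exp_m.sum()
    return stats.chisquare(obs_m, exp_m).pvalue


@pytest.fixture(scope="session")
def toy_truth():
    """Small ground-truth model (H=2) over the SER/HIS/LYS menu."""
    return make_ground_truth(1, hidden_size=2)


@pytest.fixture(scope="session")
def toy_truth_h3():
    return make_ground_truth(11, hidden_size=3)
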