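"""Exact inference and sampling in the side-chain DBN.

The chain over slices t = 1..T (phi, psi, chi1..chin) with discrete hidden
nodes is a small input-driven hidden Markov model, so likelihoods use the
scaled forward algorithm: each forward vector is normalized to sum to one and
the log scaling factors accumulate the log-likelihood.  Unobserved slices
contribute an emission factor of 1, which marginalizes those angles exactly.
All likelihood values are log *densities* in nats (per radian of observed
angle), not probabilities.

Batched variants operate on all residues of one amino-acid type at once
(same slice sequence), which is what makes EM training fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circular import TWO_PI, as_rng, log_i0, wrap_angle
from .model import ModelParams, ModelSpec, ResidueAngles

UNOBSERVED = None


@dataclass
class ForwardLattice:
    """Scaled forward vectors, per-slice log scaling factors, and their sum."""

    alphas: np.ndarray      # (T, H), each row sums to 1
    log_scale: np.ndarray   # (T,)

    @property
    def loglik(self) -> float:
        return float(self.log_scale.sum())


def _emission_matrix(params: ModelParams, values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-slice emission densities e[n, t, h]; 1.0 where the slice is unobserved."""
    mu = params.emission_mu
    kappa = params.emission_kappa
    x = np.where(mask, values, 0.0)[..., None]
    log_e = kappa * np.cos(x - mu) - np.log(TWO_PI) - log_i0(kappa)
    e = np.exp(log_e)
    return np.where(mask[..., None], e, 1.0)


def forward_batch(params: ModelParams, indices: np.ndarray,
                  values: np.ndarray, mask: np.ndarray):
    """Scaled forward pass for a batch of residues sharing one slice sequence.

    Returns (alphas (n,T,H), log_scale (n,T)).
    """
    indices = np.asarray(indices, dtype=int)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    n, T = values.shape
    if T != len(indices):
        raise ValueError("evidence length does not match slice sequence")
    if indices.min() < 0 or indices.max() >= params.num_indices:
        raise ValueError("input index out of range for model")
    if np.any(mask & ~np.isfinite(values)):
        raise ValueError("observed evidence values must be finite")
    H = params.hidden_size
    e = _emission_matrix(params, values, mask)
    alphas = np.empty((n, T, H))
    log_scale = np.empty((n, T))
    a = params.initial[indices[0]][None, :] * e[:, 0, :]
    for t in range(T):
        if t > 0:
            a = (a @ params.transition[indices[t]]) * e[:, t, :]
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise FloatingPointError("forward pass underflowed to zero probability")
        a = a / c[:, None]
        alphas[:, t, :] = a
        log_scale[:, t] = np.log(c)
    return alphas, log_scale, e


def forward(params: ModelParams, indices, evidence) -> ForwardLattice:
    """Single-residue forward pass.

    ``evidence`` is a sequence with one entry per slice: an angle in radians,
    or None for an unobserved slice.
    """
    values, mask = _evidence_arrays(evidence)
    alphas, log_scale, _ = forward_batch(params, indices, values[None, :], mask[None, :])
    return ForwardLattice(alphas=alphas[0], log_scale=log_scale[0])


def _evidence_arrays(evidence):
    values = np.array([0.0 if v is None else float(v) for v in evidence])
    mask = np.array([v is not None for v in evidence], dtype=bool)
    return values, mask


def backward_batch(params: ModelParams, indices: np.ndarray,
                   e: np.ndarray, log_scale: np.ndarray) -> np.ndarray:
    """Scaled backward vectors matching forward_batch's scaling."""
    n, T, H = e.shape
    betas = np.empty((n, T, H))
    betas[:, T - 1, :] = 1.0
    scale = np.exp(log_scale)
    for t in range(T - 2, -1, -1):
        nxt = betas[:, t + 1, :] * e[:, t + 1, :]
        betas[:, t, :] = (nxt @ params.transition[indices[t + 1]].T) / scale[:, t + 1][:, None]
    return betas


def posterior_hidden(params: ModelParams, indices, evidence) -> np.ndarray:
    """Exact per-slice posteriors P(H_t | evidence), shape (T, H)."""
    values, mask = _evidence_arrays(evidence)
    alphas, log_scale, e = forward_batch(params, indices, values[None, :], mask[None, :])
    betas = backward_batch(params, np.asarray(indices, dtype=int), e, log_scale)
    post = alphas * betas
    post /= post.sum(axis=2, keepdims=True)
    return post[0]


# ---------------------------------------------------------------------------
# Residue-level likelihoods
# ---------------------------------------------------------------------------

def _residue_evidence(spec: ModelSpec, residue: ResidueAngles,
                      observe_backbone: bool, observe_chi: bool = True):
    indices = spec.slice_sequence(residue.amino_acid)
    n_chi = spec.chi_counts[residue.amino_acid.upper()]
    if len(residue.chi) != n_chi and observe_chi:
        raise ValueError(
            f"{residue.amino_acid}: expected {n_chi} chi angles, got {len(residue.chi)}")
    evidence = [None, None] + [None] * n_chi
    if observe_backbone:
        if residue.phi is None or residue.psi is None:
            raise ValueError("backbone-conditional likelihood requires phi and psi")
        evidence[0], evidence[1] = residue.phi, residue.psi
    if observe_chi:
        for k, c in enumerate(residue.chi):
            evidence[2 + k] = c
    return indices, evidence


def loglik_chi(params: ModelParams, spec: ModelSpec, residue: ResidueAngles,
               backbone_mode: str = "marginal") -> float:
    """Log-density of a residue's chi vector, in nats.

    ``conditional``: log p(chi | phi, psi) = log p(chi, phi, psi) - log p(phi, psi).
    ``marginal``: backbone slices unobserved, i.e. log p(chi) with phi/psi
    integrated out.
    """
    if backbone_mode == "conditional":
        idx, ev_all = _residue_evidence(spec, residue, observe_backbone=True)
        _, ev_bb = _residue_evidence(spec, residue, observe_backbone=True, observe_chi=False)
        return forward(params, idx, ev_all).loglik - forward(params, idx, ev_bb).loglik
    if backbone_mode == "marginal":
        idx, ev = _residue_evidence(spec, residue, observe_backbone=False)
        return forward(params, idx, ev).loglik
    raise ValueError(f"unknown backbone_mode {backbone_mode!r}")


def loglik_joint(params: ModelParams, spec: ModelSpec, residue: ResidueAngles) -> float:
    """Joint log-density of all of a residue's observed angles (phi, psi, chi)."""
    idx, ev = _residue_evidence(spec, residue,
                                observe_backbone=residue.has_backbone)
    return forward(params, idx, ev).loglik


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_emissions(params: ModelParams, hidden: np.ndarray, rng) -> np.ndarray:
    mu = params.emission_mu[hidden]
    kappa = params.emission_kappa[hidden]
    out = np.where(kappa > 0,
                   rng.vonmises(mu, np.maximum(kappa, 1e-12)),
                   rng.uniform(-np.pi, np.pi, size=hidden.shape))
    return wrap_angle(out)


def _sample_rows(prob_rows: np.ndarray, rng) -> np.ndarray:
    """Draw one category per row of a row-stochastic matrix (n, H)."""
    cdf = np.cumsum(prob_rows, axis=1)
    u = rng.uniform(size=(prob_rows.shape[0], 1)) * cdf[:, -1:]
    return (u > cdf).sum(axis=1)


def sample_ancestral(params: ModelParams, spec: ModelSpec, amino_acid: str,
                     n: int, rng):
    """Draw n residues (phi, psi, chi all sampled) by root-to-leaf sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    indices = spec.slice_sequence(amino_acid)
    T = len(indices)
    hidden = np.empty((n, T), dtype=int)
    hidden[:, 0] = _sample_rows(np.broadcast_to(params.initial[indices[0]],
                                                (n, params.hidden_size)), rng)
    for t in range(1, T):
        hidden[:, t] = _sample_rows(params.transition[indices[t]][hidden[:, t - 1]], rng)
    angles = _sample_emissions(params, hidden, rng)
    return [ResidueAngles(amino_acid=amino_acid, phi=angles[i, 0], psi=angles[i, 1],
                          chi=tuple(angles[i, 2:])) for i in range(n)]


def backtrack_hidden(params: ModelParams, indices: np.ndarray,
                     alphas: np.ndarray, rng) -> np.ndarray:
    """Sample hidden sequences backwards from a batched forward lattice.

    H_T ~ normalized final forward vector; then
    H_t proportional to forward_t(h) * P(H_{t+1} | h, I_{t+1}).
    """
    n, T, H = alphas.shape
    hidden = np.empty((n, T), dtype=int)
    hidden[:, T - 1] = _sample_rows(alphas[:, T - 1, :], rng)
    for t in range(T - 2, -1, -1):
        w = alphas[:, t, :] * params.transition[indices[t + 1]][:, hidden[:, t + 1]].T
        hidden[:, t] = _sample_rows(w / w.sum(axis=1, keepdims=True), rng)
    return hidden


def sample_conditional(params: ModelParams, spec: ModelSpec, amino_acid: str,
                       phi: float, psi: float, n: int, rng) -> np.ndarray:
    """Exact draws of chi vectors from p(chi | phi, psi) by forward-backtrack.

    Forward pass with phi/psi observed and chi unobserved; hidden states are
    sampled backwards through the lattice; chi angles are then drawn from the
    emissions of the sampled hidden states.  Returns an (n, n_chi) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("phi and psi must be finite")
    rng = as_rng(rng)
    indices = spec.slice_sequence(amino_acid)
    T = len(indices)
    values = np.zeros((n, T))
    values[:, 0], values[:, 1] = phi, psi
    mask = np.zeros((n, T), dtype=bool)
    mask[:, :2] = True
    alphas, _, _ = forward_batch(params, indices, values, mask)
    hidden = backtrack_hidden(params, indices, alphas, rng)
    chi = _sample_emissions(params, hidden[:, 2:], rng)
    return chi


# ---------------------------------------------------------------------------
# Density grids (used by tests, plots and the quadrature-style checks)
# ---------------------------------------------------------------------------

def chi_density_grid(params: ModelParams, spec: ModelSpec, amino_acid: str,
                     grid: np.ndarray, backbone: Optional[tuple] = None,
                     chi_index: int = 0, fixed_chi: Optional[dict] = None) -> np.ndarray:
    """Density of one chi angle over ``grid``, other chi slices unobserved.

    With ``backbone=(phi, psi)`` the density is conditional on the backbone;
    otherwise marginal.  ``fixed_chi`` may clamp other chi slices.
    """
    aa = amino_acid.upper()
    n_chi = spec.chi_counts[aa]
    indices = spec.slice_sequence(aa)
    out = np.empty(len(grid))
    base = [None] * (2 + n_chi)
    if backbone is not None:
        base[0], base[1] = backbone
    if fixed_chi:
        for k, v in fixed_chi.items():
            base[2 + k] = v
    denom = 0.0
    if backbone is not None:
        denom = forward(params, indices, base[:2] + [None] * n_chi).loglik
        if fixed_chi:
            denom = forward(params, indices, base).loglik
    elif fixed_chi:
        denom = forward(params, indices, base).loglik
    for i, x in enumerate(grid):
        ev = list(base)
        ev[2 + chi_index] = float(x)
        out[i] = forward(params, indices, ev).loglik - denom
    return np.exp(out)
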