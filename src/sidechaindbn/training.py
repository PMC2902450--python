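"""Parameter estimation by EM and hidden-size selection by AIC.

Two EM variants are provided.  ``exact_em`` computes expected hidden-state
and transition counts with the forward-backward recursions and refits the
shared von Mises emission table from posterior-weighted angles; its
log-likelihood trace is non-decreasing.  ``stochastic_em`` replaces the
expectations with a single hidden-state sequence sampled exactly from the
posterior of each residue (forward-backtrack over hidden nodes given all
observed angles) and uses the resulting hard counts.  Both treat missing
backbone angles as unobserved slices.

Records are grouped by amino-acid type so each E-step is a handful of
vectorized batch passes rather than a Python loop over residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circular import as_rng, vm_fit_from_stats
from .inference import backtrack_hidden, backward_batch, forward_batch
from .model import ModelParams, ModelSpec, ResidueAngles


@dataclass
class TrainingConfig:
    variant: str = "exact_em"          # or "stochastic_em"
    max_iterations: int = 300
    tolerance: float = 1e-6            # nats per residue
    restarts: int = 1
    seed: int = 0
    pseudocount: float = 1e-3          # per CPD cell

    def __post_init__(self):
        if self.variant not in ("exact_em", "stochastic_em"):
            raise ValueError(f"unknown EM variant {self.variant!r}")
        if self.tolerance <= 0 or self.restarts < 1 or self.pseudocount < 0:
            raise ValueError("invalid training configuration")


@dataclass
class FitResult:
    params: ModelParams
    loglik_trace: list
    aic: float
    k_used: int
    hidden_size: int = 0
    restart: int = 0

    @property
    def final_loglik(self) -> float:
        return self.loglik_trace[-1]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 log L (lower is better)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * loglik


def _group_dataset(dataset: Sequence[ResidueAngles], spec: ModelSpec):
    """Group records by amino acid into (indices, values, mask) batches."""
    groups = {}
    for r in dataset:
        aa = r.amino_acid.upper()
        if aa not in spec.chi_counts:
            raise ValueError(f"amino acid {aa!r} not covered by the model spec")
        n_chi = spec.chi_counts[aa]
        if len(r.chi) != n_chi:
            raise ValueError(f"{aa}: expected {n_chi} chi angles, got {len(r.chi)}")
        groups.setdefault(aa, []).append(r)
    batches = {}
    for aa, records in groups.items():
        T = 2 + spec.chi_counts[aa]
        values = np.zeros((len(records), T))
        mask = np.zeros((len(records), T), dtype=bool)
        for i, r in enumerate(records):
            if r.has_backbone:
                values[i, 0], values[i, 1] = r.phi, r.psi
                mask[i, :2] = True
            values[i, 2:] = r.chi
            mask[i, 2:] = True
        batches[aa] = (spec.slice_sequence(aa), values, mask)
    return batches


def _init_params(spec: ModelSpec, rng) -> ModelParams:
    """Random restart: Dirichlet(1) CPD rows; emission means spread over the
    circle with small jitter, kappa = 1."""
    K, H = spec.num_indices, spec.hidden_size
    initial = rng.dirichlet(np.ones(H), size=K)
    transition = rng.dirichlet(np.ones(H), size=(K, H))
    mu = -np.pi + 2 * np.pi * (np.arange(H) + 0.5) / H + rng.uniform(-0.3, 0.3, size=H)
    return ModelParams(initial=initial, transition=transition,
                       emission_mu=np.mod(mu + np.pi, 2 * np.pi) - np.pi,
                       emission_kappa=np.ones(H))


class _Accumulator:
    """Expected (or sampled) sufficient statistics for one M-step."""

    def __init__(self, K: int, H: int):
        self.initial = np.zeros((K, H))
        self.transition = np.zeros((K, H, H))
        self.em_sin = np.zeros(H)
        self.em_cos = np.zeros(H)
        self.em_w = np.zeros(H)

    def add_emission(self, weights: np.ndarray, values: np.ndarray, mask: np.ndarray):
        # weights: (n, T, H) posterior (or one-hot) weights; only observed slices count
        w = weights * mask[..., None]
        self.em_sin += np.einsum("nth,nt->h", w, np.sin(values))
        self.em_cos += np.einsum("nth,nt->h", w, np.cos(values))
        self.em_w += w.sum(axis=(0, 1))


def _e_step_exact(params, batches, acc: _Accumulator) -> float:
    total = 0.0
    for indices, values, mask in batches.values():
        alphas, log_scale, e = forward_batch(params, indices, values, mask)
        total += float(log_scale.sum())
        betas = backward_batch(params, indices, e, log_scale)
        gamma = alphas * betas
        gamma /= gamma.sum(axis=2, keepdims=True)
        acc.initial[indices[0]] += gamma[:, 0, :].sum(axis=0)
        scale = np.exp(log_scale)
        for t in range(1, len(indices)):
            # xi_t(g, h) = alpha_{t-1}(g) A[i_t](g,h) e_t(h) beta_t(h) / c_t
            xi = np.einsum("ng,gh,nh->gh", alphas[:, t - 1, :],
                           params.transition[indices[t]],
                           e[:, t, :] * betas[:, t, :] / scale[:, t][:, None])
            acc.transition[indices[t]] += xi
        acc.add_emission(gamma, values, mask)
    return total


def _e_step_stochastic(params, batches, acc: _Accumulator, rng) -> float:
    total = 0.0
    for indices, values, mask in batches.values():
        alphas, log_scale, _ = forward_batch(params, indices, values, mask)
        total += float(log_scale.sum())
        hidden = backtrack_hidden(params, indices, alphas, rng)
        H = params.hidden_size
        onehot = np.eye(H)[hidden]                      # (n, T, H)
        acc.initial[indices[0]] += onehot[:, 0, :].sum(axis=0)
        for t in range(1, len(indices)):
            counts = np.zeros((H, H))
            np.add.at(counts, (hidden[:, t - 1], hidden[:, t]), 1.0)
            acc.transition[indices[t]] += counts
        acc.add_emission(onehot, values, mask)
    return total


def _m_step(params: ModelParams, acc: _Accumulator, pseudocount: float) -> ModelParams:
    def renorm(counts, old):
        counts = counts + pseudocount
        row_sum = counts.sum(axis=-1, keepdims=True)
        # rows never visited (and pseudocount 0) keep their previous values
        safe = row_sum > 0
        out = np.where(safe, counts / np.where(safe, row_sum, 1.0), old)
        return out

    mu = params.emission_mu.copy()
    kappa = params.emission_kappa.copy()
    for h in range(params.hidden_size):
        if acc.em_w[h] > 1e-12:
            vm = vm_fit_from_stats(acc.em_sin[h], acc.em_cos[h], acc.em_w[h])
            mu[h], kappa[h] = vm.mu, vm.kappa
    return ModelParams(initial=renorm(acc.initial, params.initial),
                       transition=renorm(acc.transition, params.transition),
                       emission_mu=mu, emission_kappa=kappa)


def _run_em(dataset, spec, config: TrainingConfig, rng) -> FitResult:
    batches = _group_dataset(dataset, spec)
    params = _init_params(spec, rng)
    n = len(dataset)
    trace = []
    for _ in range(config.max_iterations):
        acc = _Accumulator(spec.num_indices, spec.hidden_size)
        if config.variant == "exact_em":
            loglik = _e_step_exact(params, batches, acc)
        else:
            loglik = _e_step_stochastic(params, batches, acc, rng)
        trace.append(loglik)
        new_params = _m_step(params, acc, config.pseudocount)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) / n < config.tolerance:
            params = new_params
            break
        params = new_params
    from .model import count_parameters
    k = count_parameters(spec, params)
    return FitResult(params=params, loglik_trace=trace,
                     aic=aic(trace[-1], k), k_used=k,
                     hidden_size=spec.hidden_size)


def em_train(dataset: Sequence[ResidueAngles], spec: ModelSpec,
             config: Optional[TrainingConfig] = None) -> FitResult:
    """Fit ModelParams to a dataset; with restarts, keep the best final
    log-likelihood.  Per-restart seeds are derived from ``config.seed``."""
    if not dataset:
        raise ValueError("dataset is empty")
    config = config or TrainingConfig()
    master = as_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=config.restarts)
    best = None
    for r, s in enumerate(seeds):
        fit = _run_em(dataset, spec, config, as_rng(int(s)))
        fit.restart = r
        if best is None or fit.final_loglik > best.final_loglik:
            best = fit
    return best


def model_selection_scan(dataset, hidden_sizes: Sequence[int],
                         restarts_per_size: int = 5,
                         config: Optional[TrainingConfig] = None,
                         chi_counts: Optional[dict] = None):
    """Train ``restarts_per_size`` models per hidden size and keep the
    minimum-AIC model.  Returns (best FitResult, score table)."""
    from .model import default_spec
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be non-empty")
    config = config or TrainingConfig()
    master = as_rng(config.seed)
    table = []
    best = None
    for H in hidden_sizes:
        spec = default_spec(H, chi_counts)
        for r in range(restarts_per_size):
            sub = TrainingConfig(variant=config.variant,
                                 max_iterations=config.max_iterations,
                                 tolerance=config.tolerance, restarts=1,
                                 seed=int(master.integers(0, 2**31 - 1)),
                                 pseudocount=config.pseudocount)
            fit = _run_em(dataset, spec, sub, as_rng(sub.seed))
            fit.restart = r
            table.append({"hidden_size": H, "restart": r,
                          "loglik": fit.final_loglik, "k": fit.k_used,
                          "aic": fit.aic})
            if best is None or fit.aic < best.aic:
                best = fit
    return best, table


def mean_loglik(params: ModelParams, spec: ModelSpec,
                dataset: Sequence[ResidueAngles]) -> float:
    """Mean joint log-density (nats per residue) of a dataset under a model."""
    batches = _group_dataset(dataset, spec)
    total = 0.0
    for indices, values, mask in batches.values():
        _, log_scale, _ = forward_batch(params, indices, values, mask)
        total += float(log_scale.sum())
    return total / len(dataset)
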