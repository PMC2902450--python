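"""Lennard-Jones energy, MH acceptance, the packing loop, and the
+-20 degree accuracy evaluator."""

import copy

import numpy as np
import pytest
from scipy import stats

from sidechaindbn.geometry import (AtomRecord, Residue, StructureModel,
                                   apply_side_chain, build_backbone)
from sidechaindbn.model import CHI_COUNTS
from sidechaindbn.packing import (EnergyModel, PackingConfig, PackingState,
                                  boltzmann_logweight, evaluate_accuracy,
                                  lj_energy, mh_accept, mh_log_alpha,
                                  mh_log_alpha_full, run_packing)
from sidechaindbn.synthetic import (make_ground_truth, make_toy_protein,
                                    min_heavy_atom_distance)


def two_atom_structure(d):
    s = StructureModel()
    r1 = Residue("ALA", "A", 1)
    r1.atoms["CA"] = AtomRecord("CA", "C", [0.0, 0.0, 0.0])
    r2 = Residue("ALA", "A", 9)
    r2.atoms["CA"] = AtomRecord("CA", "C", [d, 0.0, 0.0])
    s.residues = [r1, r2]
    return s


def strip_side_chains(s):
    bb = copy.deepcopy(s)
    for r in bb.residues:
        for n in list(r.atoms):
            if n not in ("N", "CA", "C", "O"):
                del r.atoms[n]
    return bb


class TestLJEnergy:
    def test_minimum_is_minus_epsilon(self):
        em = EnergyModel()
        t = em.atom_type("ALA", "CA")
        e = lj_energy(two_atom_structure(2 ** (1 / 6) * t.sigma), em)
        assert e == pytest.approx(-t.epsilon, rel=1e-9)

    def test_zero_crossing_at_sigma(self):
        em = EnergyModel()
        t = em.atom_type("ALA", "CA")
        assert lj_energy(two_atom_structure(t.sigma), em) == pytest.approx(0.0,
                                                                           abs=1e-12)

    def test_tail_decay(self):
        em = EnergyModel()
        t = em.atom_type("ALA", "CA")
        assert abs(lj_energy(two_atom_structure(10 * t.sigma), em)) < 1e-5 * t.epsilon

    def test_incremental_equals_full(self):
        s = build_backbone(["LYS", "SER", "HIS"],
                           [(np.radians(-60), np.radians(-45))] * 3)
        rng = np.random.default_rng(0)
        for r in s.residues:
            apply_side_chain(r, rng.uniform(-np.pi, np.pi, CHI_COUNTS[r.name]))
        em = EnergyModel()
        full = lj_energy(s, em)
        all_res = lj_energy(s, em, moved_residues={0, 1, 2})
        assert all_res == pytest.approx(full, abs=1e-6)

    def test_bonded_pairs_excluded(self):
        # a 2-residue backbone has no non-bonded pair closer than ~2.8 A,
        # so the energy must stay modest rather than exploding from 1-2/1-3
        s = build_backbone(["GLY", "GLY"], [(np.radians(-60), np.radians(-45))] * 2)
        assert lj_energy(s, EnergyModel()) < 100.0


class TestBoltzmann:
    def test_zero_energy(self):
        assert boltzmann_logweight(0.0, EnergyModel()) == 0.0

    def test_rt_scaling(self):
        em = EnergyModel(temperature=298.15)
        assert em.rt == pytest.approx(0.5925, abs=1e-3)
        assert boltzmann_logweight(em.rt, em) == pytest.approx(-1.0, abs=1e-12)

    def test_monotone(self):
        em = EnergyModel()
        assert boltzmann_logweight(1.0, em) > boltzmann_logweight(2.0, em)


class TestMHAcceptance:
    def _state(self, e, lq):
        return PackingState(chi={}, e_lj=e, model_logprob=lq)

    def test_identity_move_always_accepted(self):
        em = EnergyModel()
        s = self._state(3.0, -2.0)
        for mode in ("proposal_only", "pseudo_energy"):
            assert mh_accept(s, self._state(3.0, -2.0), mode, em, 0)

    def test_full_expression_matches_reduced_form(self):
        em = EnergyModel()
        rng = np.random.default_rng(7)
        for _ in range(50):
            cur = self._state(rng.normal() * 5, rng.normal() * 3)
            prop = self._state(rng.normal() * 5, rng.normal() * 3)
            full = mh_log_alpha_full(cur, prop, "pseudo_energy", em)
            reduced = mh_log_alpha(prop.e_lj - cur.e_lj, cur.model_logprob,
                                   prop.model_logprob, "pseudo_energy", em)
            assert full == pytest.approx(reduced, abs=1e-12)

    def test_hard_clash_never_accepted(self):
        em = EnergyModel()
        cur = self._state(0.0, 0.0)
        prop = self._state(1e6, 0.0)
        rng = np.random.default_rng(0)
        assert not any(mh_accept(cur, prop, "pseudo_energy", em, rng)
                       for _ in range(100))

    def test_nonfinite_terms_rejected(self):
        em = EnergyModel()
        assert not mh_accept(self._state(0.0, 0.0),
                             self._state(np.nan, 0.0), "pseudo_energy", em, 0)

    def test_stationary_distribution_proposal_only(self):
        # 2-residue, 3-state enumerable toy: MH visit frequencies must match
        # exhaustive Boltzmann probabilities
        em = EnergyModel()
        st = build_backbone(["SER", "SER"],
                            [(np.radians(-120), np.radians(130))] * 2)
        states = [np.radians(v) for v in (-60.0, 60.0, 180.0)]
        E = np.zeros((3, 3))
        for i, a in enumerate(states):
            for j, b in enumerate(states):
                apply_side_chain(st.residues[0], [a])
                apply_side_chain(st.residues[1], [b])
                E[i, j] = lj_energy(st, em)
        logB = -E / em.rt
        target = np.exp(logB - logB.max())
        target /= target.sum()
        q = np.array([0.5, 0.2, 0.3])
        logq = np.log(q)
        rng = np.random.default_rng(0)
        props = rng.choice(3, size=(200_000, 2), p=q)
        cur = (0, 0)
        visits = np.zeros((3, 3))
        for prop in map(tuple, props):
            a = mh_accept(
                PackingState(chi={}, e_lj=E[cur],
                             model_logprob=logq[cur[0]] + logq[cur[1]]),
                PackingState(chi={}, e_lj=E[prop],
                             model_logprob=logq[prop[0]] + logq[prop[1]]),
                "proposal_only", em, rng)
            if a:
                cur = prop
            visits[cur] += 1
        visits /= visits.sum()
        assert np.abs(visits - target).max() < 0.02


class TestRunPacking:
    def test_seed_determinism(self, toy_truth_h3):
        s, _, _ = make_toy_protein("helix_clash", seed=0, truth=toy_truth_h3)
        bb = strip_side_chains(s)
        cfg = PackingConfig(iterations=300, seed=5)
        r1 = run_packing(copy.deepcopy(bb), toy_truth_h3.params,
                         toy_truth_h3.spec, config=cfg)
        r2 = run_packing(copy.deepcopy(bb), toy_truth_h3.params,
                         toy_truth_h3.spec, config=cfg)
        assert r1.trace == r2.trace
        assert r1.best.chi == r2.best.chi

    def test_energy_bookkeeping_consistent(self, toy_truth_h3):
        s, _, _ = make_toy_protein("helix_clash", seed=1, truth=toy_truth_h3)
        res = run_packing(strip_side_chains(s), toy_truth_h3.params,
                          toy_truth_h3.spec,
                          config=PackingConfig(iterations=400, seed=2))
        assert res.best.e_lj == pytest.approx(
            lj_energy(res.structure, EnergyModel()), abs=1e-6)

    def _flat_energy_run(self, mode, truth, seed):
        from sidechaindbn.packing import LJAtomType
        s = build_backbone(["SER"], [(np.radians(-60), np.radians(-45))])
        em = EnergyModel(overrides={("SER", n): LJAtomType(0.0, 3.0)
                                    for n in ("N", "CA", "C", "O", "CB", "OG")})
        return run_packing(s, truth.params, truth.spec, em,
                           PackingConfig(iterations=4000, seed=seed, mode=mode,
                                         residues_per_move=1,
                                         report_interval=1))

    def test_flat_energy_pseudo_mode_samples_the_model(self):
        # with a flat LJ term the pseudo-energy target equals the proposal,
        # so every move is accepted and the visited states are exact model
        # samples; compare the visited log-density trace against the
        # log-density of direct ancestral samples
        from sidechaindbn.inference import loglik_chi, sample_ancestral
        from sidechaindbn.model import ResidueAngles
        truth = make_ground_truth(4, hidden_size=2)
        res = self._flat_energy_run("pseudo_energy", truth, 3)
        assert res.acceptance_rate == 1.0
        visited = np.array([lq for _, _, lq, _ in res.trace])
        direct = np.array([
            loglik_chi(truth.params, truth.spec,
                       ResidueAngles("SER", None, None, r.chi), "marginal")
            for r in sample_ancestral(truth.params, truth.spec, "SER", 4000, 99)])
        assert stats.ks_2samp(visited, direct).pvalue > 0.001

    def test_flat_energy_proposal_only_targets_uniform(self):
        # in proposal_only mode the flat-energy Boltzmann target is uniform,
        # so the proposal correction must *reject* some moves (the chain
        # unbiases itself against the model's preferences)
        truth = make_ground_truth(4, hidden_size=2)
        res = self._flat_energy_run("proposal_only", truth, 3)
        assert 0.05 < res.acceptance_rate < 1.0

    def test_clashed_start_resolves(self, toy_truth_h3):
        s, native, keys = make_toy_protein("helix_clash", seed=2,
                                           truth=toy_truth_h3)
        res = run_packing(strip_side_chains(s), toy_truth_h3.params,
                          toy_truth_h3.spec,
                          config=PackingConfig(iterations=4000, seed=0))
        assert res.best.e_lj < 1000.0
        assert min_heavy_atom_distance(res.structure, *keys) > 2.5


class TestEvaluateAccuracy:
    def _structures_with_deviations(self, devs):
        """Four SER residues; predicted chi1 deviates from reference by the
        given degrees."""
        ref = build_backbone(["SER"] * len(devs),
                             [(np.radians(-60), np.radians(-45))] * len(devs))
        for r in ref.residues:
            apply_side_chain(r, [np.radians(-65.0)])
        pred = copy.deepcopy(ref)
        for r, d in zip(pred.residues, devs):
            apply_side_chain(r, [np.radians(-65.0 + d)])
        return pred, ref

    def test_cutoff_boundary(self):
        pred, ref = self._structures_with_deviations([19.9, 20.1])
        rep = evaluate_accuracy(pred, ref)
        assert rep.overall_chi1 == pytest.approx(50.0)

    def test_wraparound(self):
        ref = build_backbone(["SER"], [(np.radians(-60), np.radians(-45))])
        apply_side_chain(ref.residues[0], [np.radians(-179.0)])
        pred = copy.deepcopy(ref)
        apply_side_chain(pred.residues[0], [np.radians(175.0)])
        rep = evaluate_accuracy(pred, ref)
        assert rep.overall_chi1 == pytest.approx(100.0)

    def test_chi2_conditional_counting(self):
        # 4 residues; chi1 correct for 3, and of those chi2 correct for 2
        ref = build_backbone(["HIS"] * 4, [(np.radians(-60), np.radians(-45))] * 4)
        for r in ref.residues:
            apply_side_chain(r, np.radians([-65.0, 90.0]))
        pred = copy.deepcopy(ref)
        devs = [(5.0, 5.0), (5.0, 10.0), (10.0, 40.0), (45.0, 0.0)]
        for r, (d1, d2) in zip(pred.residues, devs):
            apply_side_chain(r, np.radians([-65.0 + d1, 90.0 + d2]))
        rep = evaluate_accuracy(pred, ref)
        assert rep.overall_chi1 == pytest.approx(75.0)
        assert rep.overall_chi2_given_chi1 == pytest.approx(100.0 * 2 / 3)

    def test_burial_mask_restricts(self):
        pred, ref = self._structures_with_deviations([5.0, 45.0])
        mask = {("A", 1, " "): True, ("A", 2, " "): False}
        rep = evaluate_accuracy(pred, ref, burial_mask=mask)
        assert rep.overall_chi1 == pytest.approx(100.0)

    def test_symmetry_folding_opt_in(self):
        ref = build_backbone(["PHE"], [(np.radians(-60), np.radians(-45))])
        apply_side_chain(ref.residues[0], np.radians([-65.0, 60.0]))
        pred = copy.deepcopy(ref)
        apply_side_chain(pred.residues[0], np.radians([-65.0, 60.0 + 180.0]))
        assert evaluate_accuracy(pred, ref).overall_chi2_given_chi1 == \
            pytest.approx(0.0)
        assert evaluate_accuracy(pred, ref,
                                 fold_symmetric=True).overall_chi2_given_chi1 == \
            pytest.approx(100.0)

    def test_orphans_reported(self):
        pred, ref = self._structures_with_deviations([5.0, 5.0])
        del pred.residues[1]
        rep = evaluate_accuracy(pred, ref)
        assert rep.orphans == [("A", 2, " ")]
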