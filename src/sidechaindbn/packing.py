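"""Fixed-backbone side-chain packing by Metropolis–Hastings.

The energy is an unmodified Lennard-Jones 6-12 potential over heavy-atom
pairs,

    E_LJ = sum_ij 4 eps_ij [ (sigma_ij / d)^12 - (sigma_ij / d)^6 ],

with OPLS-convention geometric-mean combination rules (sigma is the
zero-crossing distance, so the minimum -eps sits at d = 2^(1/6) sigma) and a
small packaged atom-type table.  1-2 and 1-3 bonded pairs are excluded; 1-4
pairs count at full weight.  Energies become probabilities through
Boltzmann's law at room temperature, p proportional to exp(-E / RT).

The side-chain model drives the sampler in three modes:

* ``proposal_only``    — the model is only the proposal; the MH ratio
  includes the proposal correction q(x)/q(x'), so the chain samples the
  Boltzmann distribution of the LJ energy without bias.
* ``pseudo_energy``    — the model density also multiplies the target; used
  both as proposal and pseudo-energy the MH expression reduces to the plain
  LJ ratio min(1, p_LJ(x')/p_LJ(x)).
* ``pseudo_energy_bbdep`` — as pseudo_energy but proposals (and the
  pseudo-energy) condition on the residue's fixed backbone angles.

Each iteration resamples three randomly chosen residues jointly with one
accept/reject, which lets neighbouring side chains swap positions.  After a
fixed number of iterations the lowest-energy state visited is the
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circular import angular_difference, as_rng
from .geometry import (SIDE_CHAIN_TOPOLOGY, StructureModel, apply_side_chain,
                       compute_dihedral, extract_residue_angles)
from .inference import loglik_chi, sample_ancestral, sample_conditional
from .model import ModelParams, ModelSpec, ResidueAngles

logger = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.987204258640832e-3   # kcal / (mol K)
ENERGY_CAP = 1e6                           # numerical overflow guard only

MODES = ("proposal_only", "pseudo_energy", "pseudo_energy_bbdep")


@dataclass(frozen=True)
class LJAtomType:
    epsilon: float   # kcal/mol, well depth
    sigma: float     # Angstrom, zero-crossing distance

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0:
            raise ValueError("epsilon must be >= 0 and sigma > 0")


# OPLS-like heavy-atom parameters keyed by atom class.
_LJ_CLASSES = {
    "C_aliphatic": LJAtomType(0.066, 3.50),
    "C_aromatic": LJAtomType(0.070, 3.55),
    "C_carbonyl": LJAtomType(0.105, 3.75),
    "N": LJAtomType(0.170, 3.25),
    "O_carbonyl": LJAtomType(0.210, 2.96),
    "O_hydroxyl": LJAtomType(0.170, 3.12),
    "S": LJAtomType(0.250, 3.55),
}

_AROMATIC_ATOMS = {
    ("PHE", "TYR", "TRP", "HIS"):
        {"CG", "CD1", "CD2", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2"},
}


_SP2_CARBONS = {("ASP", "CG"), ("ASN", "CG"), ("GLU", "CD"), ("GLN", "CD"),
                ("ARG", "CZ")}


def _atom_class(res_name: str, atom_name: str) -> str:
    if atom_name.startswith("N"):
        return "N"
    if atom_name.startswith("S"):
        return "S"
    if atom_name.startswith("O"):
        return "O_hydroxyl" if atom_name in ("OG", "OG1", "OH") else "O_carbonyl"
    if atom_name == "C" or (res_name, atom_name) in _SP2_CARBONS:
        return "C_carbonyl"
    for residues, names in _AROMATIC_ATOMS.items():
        if res_name in residues and atom_name in names:
            return "C_aromatic"
    return "C_aliphatic"


@dataclass
class EnergyModel:
    temperature: float = 298.15          # Kelvin
    gas_constant: float = GAS_CONSTANT_KCAL
    overrides: dict = field(default_factory=dict)   # (res, atom) -> LJAtomType

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def atom_type(self, res_name: str, atom_name: str) -> LJAtomType:
        key = (res_name, atom_name)
        if key in self.overrides:
            return self.overrides[key]
        cls = _atom_class(res_name, atom_name)
        if cls not in _LJ_CLASSES:
            raise KeyError(f"no LJ parameters for atom {res_name}/{atom_name}")
        return _LJ_CLASSES[cls]


def lj_pair_energy(eps: float, sigma: float, d: float) -> float:
    if d <= 0:
        return ENERGY_CAP
    s6 = (sigma / d) ** 6
    return min(4.0 * eps * (s6 * s6 - s6), ENERGY_CAP)


def boltzmann_logweight(energy: float, energy_model: EnergyModel) -> float:
    """log of the Boltzmann factor, -E/(RT), up to the partition constant."""
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    return -energy / energy_model.rt


# ---------------------------------------------------------------------------
# Bond graph and pairwise exclusions (1-2 and 1-3 excluded, 1-4 kept)
# ---------------------------------------------------------------------------

_RING_CLOSURE_BONDS = {
    "HIS": [("CE1", "NE2")],
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "PRO": [("CD", "N")],
}


def _residue_bonds(res_name: str):
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    topo = SIDE_CHAIN_TOPOLOGY.get(res_name, [])
    for name, refs, *_ in topo:
        bonds.append((refs[2], name))
    bonds.extend(_RING_CLOSURE_BONDS.get(res_name, []))
    return bonds


def _build_atom_table(structure: StructureModel, energy_model: EnergyModel):
    """Flatten the structure into arrays plus the set of excluded pairs."""
    names, residue_of, eps, sig, coords = [], [], [], [], []
    index = {}
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms.values():
            index[(ri, atom.name)] = len(names)
            names.append(atom.name)
            residue_of.append(ri)
            t = energy_model.atom_type(res.name, atom.name)
            eps.append(t.epsilon)
            sig.append(t.sigma)
            coords.append(atom.coord)
    adjacency = {i: set() for i in range(len(names))}
    for ri, res in enumerate(structure.residues):
        for a, b in _residue_bonds(res.name):
            if (ri, a) in index and (ri, b) in index:
                i, j = index[(ri, a)], index[(ri, b)]
                adjacency[i].add(j)
                adjacency[j].add(i)
        if (ri, "C") in index and (ri + 1, "N") in index:
            i, j = index[(ri, "C")], index[(ri + 1, "N")]
            adjacency[i].add(j)
            adjacency[j].add(i)
    excluded = set()
    for i, nbrs in adjacency.items():
        for j in nbrs:
            excluded.add((min(i, j), max(i, j)))          # 1-2
            for k in adjacency[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))  # 1-3
    return (np.array(residue_of), np.array(eps), np.array(sig),
            np.array(coords), excluded, index)


def lj_energy(structure: StructureModel, energy_model: EnergyModel,
              moved_residues: Optional[set] = None,
              _context=None) -> float:
    """Total LJ energy (kcal/mol); with ``moved_residues``, only pairs with
    at least one atom in those residues are summed (incremental evaluation)."""
    residue_of, eps, sig, coords, excluded, _ = (
        _build_atom_table(structure, energy_model) if _context is None else _context)
    n = len(eps)
    total = 0.0
    eps_comb = np.sqrt(np.outer(eps, eps))
    sig_comb = np.sqrt(np.outer(sig, sig))
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        s6 = (sig_comb / np.where(d > 0, d, np.inf)) ** 6
    e = np.minimum(4.0 * eps_comb * (s6 * s6 - s6), ENERGY_CAP)
    include = np.triu(np.ones((n, n), dtype=bool), k=1)
    for i, j in excluded:
        include[i, j] = False
    if moved_residues is not None:
        moved = np.isin(residue_of, list(moved_residues))
        include &= moved[:, None] | moved[None, :]
    return float(e[include].sum())


class _PairEnergyCache:
    """Residue-pair decomposition of the LJ energy.

    ``pair[ri, rj]`` holds the summed LJ energy of atom pairs spanning
    residues ri and rj (diagonal: intra-residue pairs); acceptance
    bookkeeping then only touches the rows of moved residues.
    """

    def __init__(self, structure: StructureModel, energy_model: EnergyModel):
        self.structure = structure
        self.energy_model = energy_model
        self.n_res = len(structure.residues)
        self.refresh()

    def _rebuild_atoms(self):
        (self.residue_of, self.eps, self.sig, self.coords,
         excluded, self.index) = _build_atom_table(self.structure, self.energy_model)
        n = len(self.eps)
        self.include = np.triu(np.ones((n, n), dtype=bool), k=1)
        for i, j in excluded:
            self.include[i, j] = False

    def refresh(self, moved=None):
        self._rebuild_atoms()
        eps_comb = np.sqrt(np.outer(self.eps, self.eps))
        sig_comb = np.sqrt(np.outer(self.sig, self.sig))
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            s6 = (sig_comb / np.where(d > 0, d, np.inf)) ** 6
        e = np.where(self.include,
                     np.minimum(4.0 * eps_comb * (s6 * s6 - s6), ENERGY_CAP), 0.0)
        r = self.residue_of
        flat = np.bincount(r[:, None].repeat(len(r), 1).ravel() * self.n_res
                           + r[None, :].repeat(len(r), 0).ravel(),
                           weights=e.ravel(),
                           minlength=self.n_res * self.n_res
                           ).reshape(self.n_res, self.n_res)
        self.pair = flat + flat.T - np.diag(np.diag(flat))

    @property
    def total(self) -> float:
        return float(np.triu(self.pair, k=1).sum() + np.diag(self.pair).sum())


@dataclass
class PackingState:
    chi: dict                  # residue position -> chi tuple
    e_lj: float
    model_logprob: float


@dataclass
class PackingConfig:
    iterations: int = 500_000
    residues_per_move: int = 3
    mode: str = "pseudo_energy"
    seed: int = 0
    report_interval: int = 1000

    def __post_init__(self):
        if self.iterations < 1 or self.residues_per_move < 1:
            raise ValueError("iterations and residues_per_move must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def mh_log_alpha(delta_e: float, logq_current: float, logq_proposed: float,
                 mode: str, energy_model: EnergyModel) -> float:
    """Log MH acceptance ratio (before the min with 0).

    ``proposal_only``: the target is the LJ Boltzmann distribution and the
    model only proposes, so log alpha = -dE/RT + log q(x) - log q(x').
    ``pseudo_energy*``: the model density multiplies the target *and* is the
    proposal, so it cancels and log alpha = -dE/RT.
    """
    log_p_ratio = -delta_e / energy_model.rt
    if mode == "proposal_only":
        return log_p_ratio + logq_current - logq_proposed
    return log_p_ratio


def mh_log_alpha_full(current: "PackingState", proposed: "PackingState",
                      mode: str, energy_model: EnergyModel) -> float:
    """The un-reduced MH log ratio: log of
    [pi(x') q(x' -> x)] / [pi(x) q(x -> x')] with every term evaluated.

    For the pseudo-energy modes pi = p_LJ * q_B and the proposal is q_B, so
    algebraically this equals the plain LJ ratio; this function keeps all
    four terms so the reduction can be verified numerically.
    """
    log_target_prop = boltzmann_logweight(proposed.e_lj, energy_model)
    log_target_cur = boltzmann_logweight(current.e_lj, energy_model)
    if mode != "proposal_only":
        log_target_prop = log_target_prop + proposed.model_logprob
        log_target_cur = log_target_cur + current.model_logprob
    log_q_fwd = proposed.model_logprob   # q(x -> x') draws the proposed chis
    log_q_rev = current.model_logprob
    return (log_target_prop + log_q_rev) - (log_target_cur + log_q_fwd)


def mh_accept(current: PackingState, proposed: PackingState, mode: str,
              energy_model: EnergyModel, rng,
              full_expression: bool = False) -> bool:
    """Metropolis–Hastings accept/reject for a proposed packing state."""
    rng = as_rng(rng)
    terms = (proposed.e_lj, current.e_lj, proposed.model_logprob,
             current.model_logprob)
    if not all(np.isfinite(t) for t in terms):
        logger.warning("non-finite MH term %r; rejecting move", terms)
        return False
    if full_expression:
        log_alpha = mh_log_alpha_full(current, proposed, mode, energy_model)
    else:
        log_alpha = mh_log_alpha(proposed.e_lj - current.e_lj,
                                 current.model_logprob, proposed.model_logprob,
                                 mode, energy_model)
    return log_alpha >= 0 or np.log(rng.uniform()) < log_alpha


@dataclass
class PackingResult:
    best: PackingState
    structure: StructureModel       # rebuilt at the best state
    trace: list                     # (iteration, e_lj, model_logprob, accepted)
    acceptance_rate: float


def _sample_residue_chi(params, spec, res, angles: ResidueAngles, mode, rng):
    if mode == "pseudo_energy_bbdep" and angles.has_backbone:
        chi = sample_conditional(params, spec, res.name, angles.phi, angles.psi,
                                 1, rng)[0]
    else:
        chi = np.array(sample_ancestral(params, spec, res.name, 1, rng)[0].chi)
    return tuple(float(c) for c in chi)


def _residue_logq(params, spec, res, angles: ResidueAngles, chi, mode) -> float:
    rec = ResidueAngles(amino_acid=res.name, phi=angles.phi, psi=angles.psi, chi=chi)
    if mode == "pseudo_energy_bbdep" and rec.has_backbone:
        return loglik_chi(params, spec, rec, backbone_mode="conditional")
    return loglik_chi(params, spec, rec, backbone_mode="marginal")


def run_packing(backbone: StructureModel, params: ModelParams, spec: ModelSpec,
                energy_model: Optional[EnergyModel] = None,
                config: Optional[PackingConfig] = None) -> PackingResult:
    """Pack side chains onto a fixed backbone and return the best state found.

    All side-chain-bearing residues are initialized by model sampling; each
    iteration jointly resamples ``residues_per_move`` randomly chosen
    residues and accepts or rejects the joint move.  The best state
    minimizes E_LJ in ``proposal_only`` mode and E_LJ - RT log q in the
    pseudo-energy modes.
    """
    energy_model = energy_model or EnergyModel()
    config = config or PackingConfig()
    rng = as_rng(config.seed)
    structure = backbone
    modeled = [i for i, r in enumerate(structure.residues)
               if r.name in spec.chi_counts and r.backbone_complete]
    if not modeled:
        raise ValueError("no side-chain-bearing residues to pack")
    # backbone angles straight from the backbone atoms (side chains not needed)
    angles_of = {}
    for i in modeled:
        res = structure.residues[i]
        prev_res = structure.residues[i - 1] if i > 0 else None
        next_res = structure.residues[i + 1] if i + 1 < len(structure.residues) else None
        phi = psi = None
        if prev_res is not None and prev_res.backbone_complete:
            phi = compute_dihedral(prev_res.coord("C"), res.coord("N"),
                                   res.coord("CA"), res.coord("C"))
        if next_res is not None and "N" in next_res.atoms:
            psi = compute_dihedral(res.coord("N"), res.coord("CA"),
                                   res.coord("C"), next_res.coord("N"))
        angles_of[i] = ResidueAngles(amino_acid=res.name, phi=phi, psi=psi,
                                     chi=(0.0,) * spec.chi_counts[res.name])

    chi = {}
    logq = {}
    for i in modeled:
        res = structure.residues[i]
        chi[i] = _sample_residue_chi(params, spec, res, angles_of[i], config.mode, rng)
        logq[i] = _residue_logq(params, spec, res, angles_of[i], chi[i], config.mode)
        apply_side_chain(res, chi[i])

    cache = _PairEnergyCache(structure, energy_model)
    e_current = cache.total
    logq_total = sum(logq.values())

    def score(e, lq):
        if config.mode == "proposal_only":
            return e
        return e - energy_model.rt * lq

    best = PackingState(chi=dict(chi), e_lj=e_current, model_logprob=logq_total)
    best_score = score(e_current, logq_total)
    trace = []
    n_accept = 0
    k = min(config.residues_per_move, len(modeled))
    for it in range(config.iterations):
        # positions drawn with replacement: occasionally fewer distinct
        # residues move, which mixes cheap single-residue moves in with the
        # joint swap-enabling ones
        move = rng.choice(len(modeled), size=k, replace=True)
        move_res = sorted({modeled[m] for m in move})
        old_chi = {i: chi[i] for i in move_res}
        old_logq = {i: logq[i] for i in move_res}
        old_pair_rows = cache.pair.copy()
        old_coords = {i: {n: a.coord.copy()
                          for n, a in structure.residues[i].atoms.items()}
                      for i in move_res}
        e_old_contrib = _moved_energy(cache, move_res)
        new_logq_sum = 0.0
        for i in move_res:
            res = structure.residues[i]
            chi[i] = _sample_residue_chi(params, spec, res, angles_of[i],
                                         config.mode, rng)
            logq[i] = _residue_logq(params, spec, res, angles_of[i], chi[i],
                                    config.mode)
            new_logq_sum += logq[i]
            apply_side_chain(res, chi[i])
        cache.refresh(move_res)
        e_new_contrib = _moved_energy(cache, move_res)
        delta_e = e_new_contrib - e_old_contrib
        logq_old_sum = sum(old_logq.values())
        log_alpha = mh_log_alpha(delta_e, logq_old_sum, new_logq_sum,
                                 config.mode, energy_model)
        accept = (np.isfinite(log_alpha)
                  and (log_alpha >= 0 or np.log(rng.uniform()) < log_alpha))
        if accept:
            e_current += delta_e
            logq_total += new_logq_sum - logq_old_sum
            n_accept += 1
            s = score(e_current, logq_total)
            if s < best_score:
                best_score = s
                best = PackingState(chi=dict(chi), e_lj=e_current,
                                    model_logprob=logq_total)
        else:
            for i in move_res:
                chi[i] = old_chi[i]
                logq[i] = old_logq[i]
                res = structure.residues[i]
                for name in list(res.atoms):
                    if name not in old_coords[i]:
                        del res.atoms[name]
                for name, coord in old_coords[i].items():
                    res.atoms[name].coord = coord
            cache.pair = old_pair_rows
            cache._rebuild_atoms()
        if (it + 1) % config.report_interval == 0 or it == config.iterations - 1:
            trace.append((it + 1, e_current, logq_total, accept))
    for i in modeled:
        apply_side_chain(structure.residues[i], best.chi[i])
    return PackingResult(best=best, structure=structure, trace=trace,
                         acceptance_rate=n_accept / config.iterations)


def _moved_energy(cache: _PairEnergyCache, moved) -> float:
    """Energy of all pairs involving at least one moved residue.

    Each moved row counts its intra-residue energy once and every partner
    once; pairs between two moved residues are then counted twice, so each
    such pair is subtracted once.
    """
    moved = sorted(set(moved))
    total = 0.0
    for idx, ri in enumerate(moved):
        total += cache.pair[ri].sum()
        total -= sum(cache.pair[ri, rj] for rj in moved[:idx])
    return float(total)


# ---------------------------------------------------------------------------
# +-20 degree accuracy evaluation
# ---------------------------------------------------------------------------

#: chi angles with two-fold terminal symmetry (180 deg flip equivalent)
_SYMMETRIC_CHI = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}


@dataclass
class AccuracyReport:
    per_amino_acid: dict      # aa -> {"n", "chi1", "chi2_given_chi1"}
    overall_chi1: float       # percent
    overall_chi2_given_chi1: float
    orphans: list


def evaluate_accuracy(predicted: StructureModel, reference: StructureModel,
                      cutoff_deg: float = 20.0,
                      burial_mask: Optional[dict] = None,
                      fold_symmetric: bool = False) -> AccuracyReport:
    """Fraction of chi1 (and chi2 among chi1-correct) within ``cutoff_deg``
    of the reference, per amino acid and overall, as percentages.

    ``burial_mask`` maps residue keys (chain, resseq, icode) -> bool; absent
    mask evaluates every residue.  ``fold_symmetric`` folds the two-fold
    terminal symmetry of Asp chi2, Glu chi3 and Phe/Tyr chi2.
    """
    pred = {key: rec for key, rec in extract_residue_angles(predicted)[0]}
    ref = {key: rec for key, rec in extract_residue_angles(reference)[0]}
    cutoff = np.radians(cutoff_deg)
    orphans = sorted(set(pred) ^ set(ref))
    stats = {}
    n1_tot = c1_tot = n2_tot = c2_tot = 0
    for key in sorted(set(pred) & set(ref)):
        if burial_mask is not None and not burial_mask.get(key, False):
            continue
        p, r = pred[key], ref[key]
        if p.amino_acid != r.amino_acid or not r.chi:
            continue

        def within(k):
            d = abs(angular_difference(p.chi[k], r.chi[k]))
            if fold_symmetric and (p.amino_acid, k + 1) in _SYMMETRIC_CHI:
                d = min(d, abs(angular_difference(p.chi[k], r.chi[k] + np.pi)))
            return d <= cutoff

        st = stats.setdefault(p.amino_acid, {"n": 0, "c1": 0, "n2": 0, "c2": 0})
        st["n"] += 1
        n1_tot += 1
        if within(0):
            st["c1"] += 1
            c1_tot += 1
            if len(r.chi) >= 2 and len(p.chi) >= 2:
                st["n2"] += 1
                n2_tot += 1
                if within(1):
                    st["c2"] += 1
                    c2_tot += 1
    per_aa = {}
    for aa, st in sorted(stats.items()):
        per_aa[aa] = {
            "n": st["n"],
            "chi1": 100.0 * st["c1"] / st["n"] if st["n"] else float("nan"),
            "chi2_given_chi1": 100.0 * st["c2"] / st["n2"] if st["n2"] else float("nan"),
        }
    return AccuracyReport(
        per_amino_acid=per_aa,
        overall_chi1=100.0 * c1_tot / n1_tot if n1_tot else float("nan"),
        overall_chi2_given_chi1=100.0 * c2_tot / n2_tot if n2_tot else float("nan"),
        orphans=orphans)


def compute_burial_mask(structure: StructureModel, threshold: float = 1.0) -> dict:
    """Shrake–Rupley accessible surface per residue (via Bio.PDB); residues
    with total SASA below ``threshold`` (A^2) are marked buried."""
    import tempfile

    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley
    from .geometry import write_pdb

    with tempfile.NamedTemporaryFile(suffix=".pdb", mode="w", delete=False) as fh:
        path = fh.name
    write_pdb(structure, path)
    parser = PDBParser(QUIET=True)
    s = parser.get_structure("s", path)
    ShrakeRupley().compute(s, level="R")
    mask = {}
    for chain in next(iter(s)):
        for res in chain:
            het, resseq, icode = res.id
            mask[(chain.id, resseq, icode)] = res.sasa < threshold
    return mask
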