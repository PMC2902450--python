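"""Ground-truth models, synthetic angle datasets and toy protein fixtures.

Everything downstream (training recovery, conditional-sampling checks, the
packing pipeline) is exercised against data generated here, so no external
structure downloads are needed.  The default toy amino-acid menu spans the
chi-count range with real residue geometries — SER (1 chi), HIS (2), LYS (4)
— so the model layer and the geometry layer share fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import angular_difference, as_rng, wrap_angle
from .geometry import StructureModel, apply_side_chain, build_backbone
from .inference import chi_density_grid, sample_ancestral
from .model import ModelParams, ModelSpec, ResidueAngles, default_spec

TOY_AA_MENU = ("SER", "HIS", "LYS")


@dataclass
class GroundTruth:
    """A known model (spec + params) used as the data-generating truth."""

    spec: ModelSpec
    params: ModelParams
    seed: int


def make_ground_truth(seed: int, hidden_size: int = 3,
                      aa_menu=TOY_AA_MENU, kappa_range=(2.0, 20.0),
                      require_backbone_coupling: bool = True) -> GroundTruth:
    """Random but reproducible ground-truth model.

    Emission means are spread over the circle with concentrations in
    ``kappa_range``; initial/transition CPDs are Dirichlet draws, so the
    hidden chain is input-dependent and the backbone genuinely informs the
    chi distribution.  If the conditional and marginal chi1 densities of the
    first 1-chi amino acid are closer than total variation 0.05, the draw is
    rejected and the seed advanced, so backbone-coupling tests are never
    vacuous.
    """
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    from .model import CHI_COUNTS
    chi_counts = {aa: CHI_COUNTS[aa] for aa in aa_menu}
    for attempt in range(20):
        trial_seed = seed + 1_000_003 * attempt
        rng = as_rng(trial_seed)
        spec = default_spec(hidden_size, chi_counts)
        K, H = spec.num_indices, hidden_size
        params = ModelParams(
            initial=rng.dirichlet(np.ones(H), size=K),
            transition=rng.dirichlet(np.ones(H), size=(K, H)),
            emission_mu=wrap_angle(
                -np.pi + 2 * np.pi * (np.arange(H) + 0.5) / H
                + rng.uniform(-0.5, 0.5, size=H)),
            emission_kappa=rng.uniform(*kappa_range, size=H),
        )
        params.validate()
        if not require_backbone_coupling or hidden_size == 1:
            return GroundTruth(spec=spec, params=params, seed=trial_seed)
        if _backbone_coupling_tv(params, spec) > 0.05:
            return GroundTruth(spec=spec, params=params, seed=trial_seed)
    raise RuntimeError("could not draw a backbone-coupled ground truth")


def _backbone_coupling_tv(params: ModelParams, spec: ModelSpec) -> float:
    """Max total-variation distance between conditional and marginal chi1
    densities over a few (phi, psi) probes, by trapezoid quadrature."""
    one_chi = [aa for aa, n in spec.chi_counts.items() if n == 1]
    aa = one_chi[0] if one_chi else min(spec.chi_counts)
    grid = np.linspace(-np.pi, np.pi, 241)
    marginal = chi_density_grid(params, spec, aa, grid)
    tv_max = 0.0
    for phi, psi in ((-1.2, 2.4), (1.0, -0.5), (-2.8, -0.9)):
        cond = chi_density_grid(params, spec, aa, grid, backbone=(phi, psi))
        tv = 0.5 * np.trapezoid(np.abs(cond - marginal), grid)
        tv_max = max(tv_max, float(tv))
    return tv_max


def sample_dataset(truth: GroundTruth, n_residues: int, seed: int,
                   missing_backbone_fraction: float = 0.0):
    """Draw ``n_residues`` i.i.d. residues (uniform over the truth's amino
    acids) by ancestral sampling; a fraction get phi/psi masked missing."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if not 0.0 <= missing_backbone_fraction <= 1.0:
        raise ValueError("missing_backbone_fraction must be in [0, 1]")
    rng = as_rng(seed)
    menu = sorted(truth.spec.chi_counts)
    counts = rng.multinomial(n_residues, np.ones(len(menu)) / len(menu))
    records = []
    for aa, n_aa in zip(menu, counts):
        if n_aa == 0:
            continue
        records.extend(sample_ancestral(truth.params, truth.spec, aa, int(n_aa), rng))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    if missing_backbone_fraction > 0:
        drop = rng.uniform(size=len(records)) < missing_backbone_fraction
        records = [ResidueAngles(r.amino_acid, None, None, r.chi) if d else r
                   for r, d in zip(records, drop)]
    return records


# ---------------------------------------------------------------------------
# Toy protein fixtures
# ---------------------------------------------------------------------------

HELIX_PHI_PSI = (np.radians(-57.0), np.radians(-47.0))


def make_toy_protein(layout: str = "dipeptide", seed: int = 0,
                     truth: GroundTruth | None = None):
    """Geometrically valid toy structures with recorded native chi angles.

    ``dipeptide``: two residues (SER, HIS) in an extended conformation with
    fixed native chi.

    ``helix_clash``: a compact 5-mer with a tight turn that points the CB
    vectors of the two terminal LYS residues at each other (CB-CB under
    4 A), so their side chains must coordinate.  Native chi vectors are
    chosen by scanning candidate rotamer combinations for the pair with the
    lowest steric energy; placing both side chains at their *individually*
    optimal rotamer instead produces a heavy-atom clash (< 2.5 A) which the
    native combination avoids — the scenario that forces coordinated
    (swap-like) multi-residue moves during packing.  When ``truth`` is
    given, candidate chi vectors are drawn from the truth model so the
    native state has appreciable density under it.

    Returns (structure with side chains at native chi, native ResidueAngles
    keyed by residue, clash_pair keys).
    """
    rng = as_rng(seed)
    if layout == "dipeptide":
        structure = build_backbone(["SER", "HIS"],
                                   [(np.radians(-120), np.radians(130))] * 2)
        native = {1: (np.radians(-65.0),),
                  2: (np.radians(-60.0), np.radians(90.0))}
        for res in structure.residues:
            apply_side_chain(res, native[res.resseq])
        return structure, _native_records(structure), []
    if layout != "helix_clash":
        raise ValueError(f"unknown layout {layout!r}")

    structure, native, keys, _ = _clash_fixture(truth, rng)
    return structure, native, keys


def _clash_fixture(truth, rng):
    sequence = ["LYS", "ALA", "ALA", "ALA", "LYS"]
    phi_psi = [(-120.0, 130.0), (-120.0, 130.0), (60.0, 30.0),
               (-140.0, -60.0), (-120.0, 130.0)]
    structure = build_backbone(sequence,
                               [tuple(np.radians(a) for a in pp) for pp in phi_psi])
    pair = [0, 4]   # 0-based positions of the two LYS
    candidates = _lys_candidates(truth, rng)
    logq = None
    if truth is not None:
        from .inference import loglik_chi
        logq = [loglik_chi(truth.params, truth.spec,
                           ResidueAngles("LYS", None, None, c), "marginal")
                for c in candidates]
    combos, score = _search_native(structure, pair, candidates, logq=logq)
    best = combos[0]
    margin = np.inf
    if truth is not None:
        # refine one representative per distinct chi1 basin, then rank the
        # refined optima; the native is the global one and the margin is its
        # lead over the best genuinely different basin
        reps = _distinct_combos(score, candidates, n_basins=14)
        refined = [_refine_native(structure, pair, c, truth) for c in reps]
        scores = [_packing_score(structure, pair, c, truth) for c in refined]
        order = np.argsort(scores)
        best = refined[order[0]]
        thr = np.radians(30.0)
        for o in order[1:]:
            c = refined[o]
            if (abs(angular_difference(c[0][0], best[0][0])) > thr
                    or abs(angular_difference(c[1][0], best[1][0])) > thr):
                margin = scores[o] - scores[order[0]]
                break
        # a finite chain only reaches basins through crude proposals, so the
        # native basin must also win on the crude candidate score table and
        # carry enough proposal mass to be hit jointly
        margin = min(margin, _crude_margin(score, candidates, best, thr))
        chi1 = np.array([c[0] for c in candidates])
        reach = min(
            float(np.mean(np.abs(angular_difference(chi1, best[0][0])) <= thr)),
            float(np.mean(np.abs(angular_difference(chi1, best[1][0])) <= thr)))
        if reach < 0.08:
            margin = -np.inf
    for pos, chi in zip(pair, best):
        apply_side_chain(structure.residues[pos], chi)
    keys = [structure.residues[p].key for p in pair]
    return structure, _native_records(structure), keys, margin


def _crude_margin(score, candidates, native, thr) -> float:
    """Gap between the best crude candidate pair inside the native chi1
    basin and the best one outside it (positive: native basin wins even
    without local refinement)."""
    chi1 = np.array([c[0] for c in candidates])
    near_a = np.abs(angular_difference(chi1, native[0][0])) <= thr
    near_b = np.abs(angular_difference(chi1, native[1][0])) <= thr
    inside = near_a[:, None] & near_b[None, :]
    if not inside.any() or inside.all():
        return -np.inf if not inside.any() else np.inf
    return float(score[~inside].min() - score[inside].min())


def _distinct_combos(score, candidates, n_basins: int = 10,
                     thr_deg: float = 30.0):
    """Greedily pick low-score candidate pairs whose chi1 signatures differ
    pairwise by more than ``thr_deg`` — one crude representative per basin."""
    thr = np.radians(thr_deg)
    order = np.argsort(score, axis=None)
    chosen = []
    sigs = []
    for f in order:
        ia, ib = np.unravel_index(f, score.shape)
        sig = (candidates[ia][0], candidates[ib][0])
        if any(abs(angular_difference(sig[0], s[0])) <= thr
               and abs(angular_difference(sig[1], s[1])) <= thr for s in sigs):
            continue
        chosen.append((candidates[ia], candidates[ib]))
        sigs.append(sig)
        if len(chosen) >= n_basins:
            break
    return chosen


def make_clash_scenario(seed: int, hidden_size: int = 3,
                        min_margin: float = 1.5, max_tries: int = 12):
    """Ground truth plus a well-posed clash fixture.

    Draws ground-truth models (advancing the seed) until the fixture's
    planted native basin beats every distinct alternative by at least
    ``min_margin`` kcal/mol of packing score, so recovering the native is a
    well-defined task.  Returns (truth, structure, native records, clash
    residue keys).
    """
    for attempt in range(max_tries):
        truth_seed = seed + 7_919 * attempt
        truth = make_ground_truth(truth_seed, hidden_size=hidden_size)
        structure, native, keys, margin = _clash_fixture(
            truth, as_rng(truth_seed + 1))
        if margin >= min_margin:
            return truth, structure, native, keys
    raise RuntimeError("no identifiable clash scenario found; widen max_tries")


def _native_records(structure: StructureModel):
    from .geometry import extract_residue_angles
    return {key: rec for key, rec in extract_residue_angles(structure)[0]}


def _lys_candidates(truth, rng, n_draws: int = 100):
    """Candidate LYS chi vectors: truth-model draws if a truth is supplied,
    else the classic staggered-rotamer grid."""
    if truth is not None and "LYS" in truth.spec.chi_counts:
        recs = sample_ancestral(truth.params, truth.spec, "LYS", n_draws, rng)
        return [tuple(r.chi) for r in recs]
    vals = [np.radians(v) for v in (-60.0, 60.0, 180.0)]
    cands = []
    for c1 in vals:
        for c2 in vals:
            for c3 in vals:
                cands.append((c1, c2, np.radians(180.0), c3))
    return cands


def min_heavy_atom_distance(structure: StructureModel, key_a, key_b) -> float:
    """Smallest heavy-atom distance between the side chains (incl. CB) of
    two residues."""
    ra = structure.residue_by_key(key_a)
    rb = structure.residue_by_key(key_b)
    xa = [a.coord for n, a in ra.atoms.items() if n not in ("N", "CA", "C", "O")]
    xb = [a.coord for n, a in rb.atoms.items() if n not in ("N", "CA", "C", "O")]
    if not xa or not xb:
        return np.inf
    xa, xb = np.array(xa), np.array(xb)
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
    return float(d.min())


def _steric_score(structure, pair, chis) -> float:
    """Clash-oriented score: summed 12-6 repulsion of the two side chains
    against everything else and each other."""
    from .packing import EnergyModel, lj_energy
    for pos, chi in zip(pair, chis):
        apply_side_chain(structure.residues[pos], chi)
    return lj_energy(structure, EnergyModel(), moved_residues=set(pair))


def _search_native(structure, pair, candidates, logq=None):
    """Pick the best candidate combination over the product set.

    With ``logq`` (per-candidate model log-density) the score is the same
    one the pseudo-energy packing mode minimizes, E_LJ - RT (logq_a +
    logq_b), so the native state is the one an ideal run of the pipeline
    should land on; without it, plain steric energy.

    The pair score decomposes into per-candidate environment terms (each
    side chain against the backbone with the other side chain absent) plus
    a cross term between the two side chains, so the product set is scored
    with O(candidates) energy evaluations and one vectorized cross table.
    """
    from .packing import EnergyModel, lj_energy
    from .geometry import build_side_chain
    em = EnergyModel()
    rt = em.rt
    n_cand = len(candidates)
    pos_a, pos_b = pair
    res_a, res_b = structure.residues[pos_a], structure.residues[pos_b]

    def strip(res):
        saved = dict(res.atoms)
        for n in list(res.atoms):
            if n not in ("N", "CA", "C", "O"):
                del res.atoms[n]
        return saved

    def env_energies(pos, other):
        saved = strip(structure.residues[other])
        out = np.empty(n_cand)
        for i, c in enumerate(candidates):
            apply_side_chain(structure.residues[pos], c)
            out[i] = lj_energy(structure, em, moved_residues={pos})
        structure.residues[other].atoms = saved
        return out

    env_a = env_energies(pos_a, pos_b)
    env_b = env_energies(pos_b, pos_a)

    def side_coords(res, c):
        atoms = build_side_chain({n: res.coord(n) for n in ("N", "CA", "C")},
                                 res.name, c)
        names = list(atoms)
        return names, np.array([atoms[n].coord for n in names])

    names_a, _ = side_coords(res_a, candidates[0])
    names_b, _ = side_coords(res_b, candidates[0])
    coords_a = np.array([side_coords(res_a, c)[1] for c in candidates])
    coords_b = np.array([side_coords(res_b, c)[1] for c in candidates])
    eps_a = np.array([em.atom_type(res_a.name, n).epsilon for n in names_a])
    sig_a = np.array([em.atom_type(res_a.name, n).sigma for n in names_a])
    eps_b = np.array([em.atom_type(res_b.name, n).epsilon for n in names_b])
    sig_b = np.array([em.atom_type(res_b.name, n).sigma for n in names_b])
    eps_c = np.sqrt(np.outer(eps_a, eps_b))
    sig_c = np.sqrt(np.outer(sig_a, sig_b))
    # cross[i, j]: candidate i at pos_a against candidate j at pos_b
    d = np.linalg.norm(coords_a[:, None, :, None, :] - coords_b[None, :, None, :, :],
                       axis=-1)
    s6 = (sig_c[None, None] / d) ** 6
    cross = np.minimum(4.0 * eps_c[None, None] * (s6 * s6 - s6), 1e6).sum(axis=(2, 3))

    score = env_a[:, None] + env_b[None, :] + cross
    if logq is not None:
        lq = np.asarray(logq)
        score = score - rt * (lq[:, None] + lq[None, :])
    flat = np.argsort(score, axis=None)
    combos = []
    for f in flat[:8]:
        ia, ib = np.unravel_index(f, score.shape)
        combos.append((candidates[ia], candidates[ib]))
    return combos, score


def _packing_score(structure, pair, combo, truth):
    """E_LJ - RT log q of a candidate chi pair, the pseudo-energy packing
    objective restricted to the two movable residues."""
    from .inference import loglik_chi
    from .packing import EnergyModel
    rt = EnergyModel().rt
    e = _steric_score(structure, pair, combo)
    lq = sum(loglik_chi(truth.params, truth.spec,
                        ResidueAngles("LYS", None, None, c), "marginal")
             for c in combo)
    return e - rt * lq


def _refine_native(structure, pair, combo, truth):
    """Polish the native chi pair to a local optimum of the pseudo-energy
    packing score (E_LJ - RT log q), so the native state sits at the bottom
    of its basin rather than at the nearest sampled point."""
    from scipy.optimize import minimize
    from .inference import loglik_chi
    from .packing import EnergyModel
    rt = EnergyModel().rt
    n_a = len(combo[0])

    def objective(x):
        ca, cb = tuple(x[:n_a]), tuple(x[n_a:])
        e = _steric_score(structure, pair, (ca, cb))
        lq = sum(loglik_chi(truth.params, truth.spec,
                            ResidueAngles("LYS", None, None, c), "marginal")
                 for c in (ca, cb))
        return e - rt * lq

    x0 = np.concatenate([combo[0], combo[1]])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 600, "xatol": 1e-3, "fatol": 1e-4})
    x = wrap_angle(res.x)
    return tuple(x[:n_a]), tuple(x[n_a:])


def independent_optimum(structure, pair, candidates):
    """Each residue's best candidate with the other side chain absent."""
    out = []
    keys = [structure.residues[p].key for p in pair]
    for idx, pos in enumerate(pair):
        other = pair[1 - idx]
        saved = {n: a for n, a in structure.residues[other].atoms.items()}
        for n in list(structure.residues[other].atoms):
            if n not in ("N", "CA", "C", "O"):
                del structure.residues[other].atoms[n]
        best, best_score = None, np.inf
        from .packing import EnergyModel, lj_energy
        for c in candidates:
            apply_side_chain(structure.residues[pos], c)
            s = lj_energy(structure, EnergyModel(), moved_residues={pos})
            if s < best_score:
                best_score, best = s, c
        structure.residues[other].atoms = dict(saved)
        out.append(best)
    return out
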