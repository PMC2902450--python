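"""Model structure: input-index scheme, parameter containers, (de)serialization.

The model is a dynamic Bayesian network over a short chain of "slices", one
per dihedral angle of a residue: two backbone slices (phi, psi) followed by
one slice per chi angle.  Each slice carries a discrete *input* node holding a
bookkeeping index that identifies the amino-acid type and the angle label, a
discrete *hidden* node of size H, and a von Mises output node whose
parameters are selected by the hidden value.  A single shared emission table
and per-index initial/transition CPDs model all amino acids and all angles
jointly, so statistical strength is shared across residue types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circular import VonMisesParams, wrap_angle

FORMAT_VERSION = 1

ANGLE_LABELS = ("phi", "psi", "chi1", "chi2", "chi3", "chi4")

#: Number of rotatable chi dihedrals per modeled amino acid.  Ala and Gly
#: have no chi angle and are not modeled; Pro is included with 2 chi angles.
CHI_COUNTS = {
    "ARG": 4, "ASN": 2, "ASP": 2, "CYS": 1, "GLN": 3, "GLU": 3,
    "HIS": 2, "ILE": 2, "LEU": 2, "LYS": 4, "MET": 3, "PHE": 2,
    "PRO": 2, "SER": 1, "THR": 1, "TRP": 2, "TYR": 2, "VAL": 1,
}


@dataclass(frozen=True)
class AngleIndexMap:
    """Bijective map (amino acid, angle label) -> contiguous integer index.

    Amino acids are sorted by 3-letter code; within each, slices are ordered
    (phi, psi, chi1..chin).  Each amino acid therefore owns its own backbone
    indices, so backbone-angle CPDs may differ between residue types.
    """

    entries: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.entries)

    def index(self, amino_acid: str, label: str) -> int:
        key = (amino_acid.upper(), label)
        if key not in self.entries:
            raise KeyError(f"no index for {key}")
        return self.entries[key]


def build_index_map(chi_counts: Optional[dict] = None) -> AngleIndexMap:
    """Deterministic index assignment from a chi-count table (default: the 18
    standard side-chain-bearing amino acids)."""
    chi_counts = dict(CHI_COUNTS if chi_counts is None else chi_counts)
    for aa, n in chi_counts.items():
        if not 1 <= n <= 4:
            raise ValueError(f"{aa}: chi count {n} outside 1..4")
    entries = {}
    idx = 0
    for aa in sorted(chi_counts):
        for label in ("phi", "psi") + tuple(f"chi{k}" for k in range(1, chi_counts[aa] + 1)):
            entries[(aa, label)] = idx
            idx += 1
    return AngleIndexMap(entries=entries)


@dataclass(frozen=True)
class ModelSpec:
    """Hidden-node size plus the index scheme and chi-count table."""

    hidden_size: int
    index_map: AngleIndexMap
    chi_counts: dict

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")

    @property
    def num_indices(self) -> int:
        return self.index_map.size

    def slice_sequence(self, amino_acid: str) -> np.ndarray:
        """Ordered input indices for one residue: phi, psi, chi1..chin.

        The backbone slices are always present; backbone-independent use
        marks them unobserved via the evidence mask rather than shortening
        the chain.
        """
        aa = amino_acid.upper()
        if aa not in self.chi_counts:
            raise KeyError(f"amino acid {amino_acid!r} is not modeled (no chi angles?)")
        labels = ("phi", "psi") + tuple(f"chi{k}" for k in range(1, self.chi_counts[aa] + 1))
        return np.array([self.index_map.index(aa, lab) for lab in labels], dtype=int)


def default_spec(hidden_size: int, chi_counts: Optional[dict] = None) -> ModelSpec:
    chi_counts = dict(CHI_COUNTS if chi_counts is None else chi_counts)
    return ModelSpec(hidden_size=hidden_size, index_map=build_index_map(chi_counts),
                     chi_counts=chi_counts)


@dataclass
class ModelParams:
    """CPDs of the network.

    initial[i]      -- P(H_1 | I_1 = i), shape (K, H), rows sum to 1
    transition[i]   -- P(H_t | H_{t-1}, I_t = i), shape (K, H, H), row-stochastic
    emission_mu/kappa -- shared von Mises table over hidden values, shape (H,)
    """

    initial: np.ndarray
    transition: np.ndarray
    emission_mu: np.ndarray
    emission_kappa: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.initial.shape[1]

    @property
    def num_indices(self) -> int:
        return self.initial.shape[0]

    def emission(self, h: int) -> VonMisesParams:
        return VonMisesParams(mu=float(self.emission_mu[h]),
                              kappa=float(self.emission_kappa[h]))

    def validate(self, atol: float = 1e-9) -> None:
        K, H = self.initial.shape
        if self.transition.shape != (K, H, H):
            raise ValueError("transition shape inconsistent with initial")
        if self.emission_mu.shape != (H,) or self.emission_kappa.shape != (H,):
            raise ValueError("emission table length must equal hidden size")
        for name, arr, axis in (("initial", self.initial, 1),
                                ("transition", self.transition, 2)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=axis), 1.0, atol=atol):
                raise ValueError(f"{name} rows do not sum to 1")
        if np.any(self.emission_kappa < 0):
            raise ValueError("kappa must be >= 0")


def count_parameters(spec: ModelSpec, params: ModelParams,
                     nonzero_only: bool = False, threshold: float = 1e-8) -> int:
    """Free-parameter count used by AIC.

    Dense count: K(H-1) initial + K*H*(H-1) transition + 2H emission.  With
    ``nonzero_only``, probability entries above ``threshold`` are counted
    instead (plus 2H), matching how sparse trained CPDs are usually reported.
    """
    if params.initial.shape[0] != spec.num_indices or params.hidden_size != spec.hidden_size:
        raise ValueError("params inconsistent with spec")
    H, K = spec.hidden_size, spec.num_indices
    if nonzero_only:
        return int((params.initial > threshold).sum()
                   + (params.transition > threshold).sum() + 2 * H)
    return K * (H - 1) + K * H * (H - 1) + 2 * H


# ---------------------------------------------------------------------------
# Model file format: self-describing JSON with a format-version field.
# JSON floats round-trip IEEE doubles exactly, so save/load is bit-exact.
# ---------------------------------------------------------------------------

def save_model(params: ModelParams, spec: ModelSpec, path) -> None:
    params.validate()
    doc = {
        "format_version": FORMAT_VERSION,
        "hidden_size": spec.hidden_size,
        "chi_counts": dict(sorted(spec.chi_counts.items())),
        "index_map": [[aa, label, idx] for (aa, label), idx in
                      sorted(spec.index_map.entries.items(), key=lambda kv: kv[1])],
        "initial": params.initial.tolist(),
        "transition": params.transition.tolist(),
        "emission_mu": params.emission_mu.tolist(),
        "emission_kappa": params.emission_kappa.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


class ModelFormatError(ValueError):
    pass


def load_model(path):
    """Load (params, spec) from a model file; raises ModelFormatError on
    version mismatch or corruption."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"corrupt model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {doc.get('format_version')!r}"
            if isinstance(doc, dict) else "corrupt model file")
    try:
        entries = {(aa, label): idx for aa, label, idx in doc["index_map"]}
        spec = ModelSpec(hidden_size=int(doc["hidden_size"]),
                         index_map=AngleIndexMap(entries=entries),
                         chi_counts={k: int(v) for k, v in doc["chi_counts"].items()})
        params = ModelParams(
            initial=np.asarray(doc["initial"], dtype=float),
            transition=np.asarray(doc["transition"], dtype=float),
            emission_mu=np.asarray(doc["emission_mu"], dtype=float),
            emission_kappa=np.asarray(doc["emission_kappa"], dtype=float),
        )
        params.validate(atol=1e-6)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupt model file {path}: {exc}") from exc
    return params, spec


# ---------------------------------------------------------------------------
# Residue angle records and the angle-table TSV (degrees on disk).
# ---------------------------------------------------------------------------

@dataclass
class ResidueAngles:
    """One residue's dihedral angles in radians; None marks a missing angle."""

    amino_acid: str
    phi: Optional[float]
    psi: Optional[float]
    chi: tuple

    def __post_init__(self):
        self.amino_acid = self.amino_acid.upper()
        for v in (self.phi, self.psi) + tuple(self.chi):
            if v is not None and not np.isfinite(v):
                raise ValueError("present angles must be finite")
        self.chi = tuple(float(wrap_angle(c)) for c in self.chi)
        self.phi = None if self.phi is None else float(wrap_angle(self.phi))
        self.psi = None if self.psi is None else float(wrap_angle(self.psi))

    @property
    def has_backbone(self) -> bool:
        return self.phi is not None and self.psi is not None


def write_angle_tsv(records, path) -> None:
    """Write a list of ResidueAngles as TSV (aa, phi, psi, chi1..chi4; degrees;
    empty cell = missing)."""
    rows = []
    for r in records:
        row = {"aa": r.amino_acid,
               "phi": np.nan if r.phi is None else np.degrees(r.phi),
               "psi": np.nan if r.psi is None else np.degrees(r.psi)}
        for k in range(4):
            row[f"chi{k + 1}"] = np.degrees(r.chi[k]) if k < len(r.chi) else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=["aa", "phi", "psi", "chi1", "chi2", "chi3", "chi4"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_angle_tsv(path):
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        chi = []
        for k in range(1, 5):
            v = getattr(row, f"chi{k}", np.nan)
            if pd.notna(v):
                chi.append(np.radians(float(v)))
        records.append(ResidueAngles(
            amino_acid=str(row.aa),
            phi=None if pd.isna(row.phi) else np.radians(float(row.phi)),
            psi=None if pd.isna(row.psi) else np.radians(float(row.psi)),
            chi=tuple(chi)))
    return records
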