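"""Backbone-independent rotamer libraries and the relative KL estimator.

A rotamer library describes each amino acid's side-chain conformational
space as a weighted list of rotamers; each rotamer places every chi angle
with a Gaussian (mean, sd).  The mixture density

    q_R(chi) = sum_R  P(R_A) * prod_n N(chi_n ; mu_{R,n}, sd_{R,n})

is evaluated with each Gaussian applied to the *wrapped* difference between
the angle and the rotamer mean, so means near +-180 deg are handled
correctly.  Model-vs-library comparison uses the relative KL divergence

    D(p||q_R) - D(p||q_B) = E_p[log q_B(x) - log q_R(x)]
                          ~ (1/n) sum_i [log q_B(x_i) - log q_R(x_i)],

estimated as an average over test observations x_i drawn from p.  Positive
values mean the model q_B fits the data better than the library q_R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .circular import angular_difference
from .model import ResidueAngles

logger = logging.getLogger(__name__)

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class Rotamer:
    probability: float
    means: np.ndarray   # radians, one per chi
    sds: np.ndarray     # radians, strictly positive

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have equal length")
        if np.any(self.sds <= 0):
            raise ValueError("rotamer standard deviations must be > 0")


@dataclass
class RotamerLibrary:
    rotamers: dict = field(default_factory=dict)  # aa -> list[Rotamer]

    def amino_acids(self):
        return sorted(self.rotamers)


class RotamerParseError(ValueError):
    pass


@dataclass(frozen=True)
class ColumnMap:
    """Column layout of a whitespace-separated rotamer-library file.

    The packaged fixture dialect is ``residue probability mean1 sd1 [mean2
    sd2 ...]`` with angles in degrees; real-world files (e.g. the Dunbrack
    backbone-independent dialect with its rotamer-class and count columns)
    are read by giving explicit column indices.
    """

    residue: int = 0
    probability: int = 1
    mean_columns: Optional[Sequence[int]] = None  # None: alternating from col 2
    sd_columns: Optional[Sequence[int]] = None


def read_rotamer_library(path, column_map: Optional[ColumnMap] = None,
                         known_residues: Optional[set] = None) -> RotamerLibrary:
    """Parse a rotamer library; angles converted to radians, per-amino-acid
    weights renormalized (with a logged warning if they were off by > 1e-6)."""
    cmap = column_map or ColumnMap()
    lib = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            try:
                aa = cols[cmap.residue].upper()
                prob = float(cols[cmap.probability])
                if cmap.mean_columns is not None:
                    means = [float(cols[i]) for i in cmap.mean_columns]
                    sds = [float(cols[i]) for i in cmap.sd_columns]
                else:
                    rest = [float(v) for v in cols[2:]]
                    if not rest or len(rest) % 2:
                        raise ValueError("expected alternating mean/sd columns")
                    means, sds = rest[0::2], rest[1::2]
            except (IndexError, ValueError) as exc:
                raise RotamerParseError(f"{path}:{lineno}: {exc}") from exc
            if known_residues is not None and aa not in known_residues:
                logger.warning("%s:%d: skipping unknown residue %s", path, lineno, aa)
                continue
            lib.setdefault(aa, []).append(
                Rotamer(probability=prob, means=np.radians(means), sds=np.radians(sds)))
    for aa, rots in lib.items():
        total = sum(r.probability for r in rots)
        if total <= 0:
            raise RotamerParseError(f"{aa}: rotamer probabilities sum to {total}")
        if abs(total - 1.0) > 1e-6:
            if abs(total - 1.0) > 0.02:
                logger.warning("%s: rotamer weights sum to %.4f; renormalizing", aa, total)
            else:
                logger.info("%s: rotamer weights sum to %.4f; renormalizing", aa, total)
        for r in rots:
            r.probability /= total
    return RotamerLibrary(rotamers=lib)


def rotlib_logpdf(chi, amino_acid: str, library: RotamerLibrary) -> float:
    """Log-density (nats) of a chi vector under the library's Gaussian mixture."""
    aa = amino_acid.upper()
    if aa not in library.rotamers:
        raise KeyError(f"amino acid {aa!r} absent from rotamer library")
    chi = np.asarray(chi, dtype=float)
    rots = library.rotamers[aa]
    terms = np.empty(len(rots))
    for i, r in enumerate(rots):
        if chi.shape != r.means.shape:
            raise ValueError(f"{aa}: chi length {len(chi)} does not match "
                             f"library chi count {len(r.means)}")
        z = angular_difference(chi, r.means) / r.sds
        log_norm = -0.5 * z * z - np.log(r.sds) - LOG_SQRT_2PI
        terms[i] = (np.log(r.probability) if r.probability > 0 else -np.inf) + log_norm.sum()
    return float(logsumexp(terms))


@dataclass
class DeltaKLReport:
    per_amino_acid: dict          # aa -> (n, estimate in nats)
    overall: float                # mean over all records, nats
    flagged: list                 # records with non-finite log-density


def delta_kl(test_data: Sequence[ResidueAngles],
             logpdf_b: Callable[[ResidueAngles], float],
             logpdf_r: Callable[[ResidueAngles], float]) -> DeltaKLReport:
    """Monte-Carlo estimate of D(p||q_R) - D(p||q_B) per amino acid.

    ``logpdf_b`` and ``logpdf_r`` map a residue record to a log-density in
    nats.  Records where either functional is non-finite are excluded from
    the averages and returned in ``flagged``.
    """
    sums, counts, flagged = {}, {}, []
    total, n_tot = 0.0, 0
    for rec in test_data:
        lb, lr = float(logpdf_b(rec)), float(logpdf_r(rec))
        if not (np.isfinite(lb) and np.isfinite(lr)):
            flagged.append(rec)
            continue
        d = lb - lr
        sums[rec.amino_acid] = sums.get(rec.amino_acid, 0.0) + d
        counts[rec.amino_acid] = counts.get(rec.amino_acid, 0) + 1
        total += d
        n_tot += 1
    per_aa = {aa: (counts[aa], sums[aa] / counts[aa]) for aa in sorted(sums)}
    return DeltaKLReport(per_amino_acid=per_aa,
                         overall=total / n_tot if n_tot else float("nan"),
                         flagged=flagged)


def write_delta_kl_tsv(report: DeltaKLReport, path) -> None:
    """TSV report (amino_acid, n, delta_kl_nats) plus an average row."""
    with open(path, "w") as fh:
        fh.write("amino_acid\tn\tdelta_kl_nats\n")
        for aa, (n, est) in report.per_amino_acid.items():
            fh.write(f"{aa}\t{n}\t{est:.6f}\n")
        n_all = sum(n for n, _ in report.per_amino_acid.values())
        fh.write(f"ALL\t{n_all}\t{report.overall:.6f}\n")
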