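"""Virtual peptide library generators.

Three rule-based design principles for candidate membranolytic peptides —
helical (position-dependent residue distributions with an 18-residue period,
i.e. five helical turns), amphipathic arc (hydrophobic face of a chosen
angular width on the helical wheel, cationic polar face), and gradient
(amphipathic scaffold with a hydrophobic C-terminal third) — plus a uniform
random control library, and a CD-HIT-style greedy redundancy filter.

Lengths default to the 11-30 residue range typical of helix-forming
peptides. Cysteine and methionine are excluded from the design pools for
synthesis friendliness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .peptide import AMINO_ACIDS, Peptide, as_peptide

# Residue pools for the arc/gradient generators. The polar pool is enriched
# in K (weight 2) and R (weight 1) relative to the uncharged polar residues,
# giving the cationic polar face.
HYDROPHOBIC_POOL = tuple("AFILVW")
POLAR_POOL = tuple("GSTNQHEDKR")
POLAR_WEIGHTS = (1, 1, 1, 1, 1, 1, 1, 1, 2, 1)

PERIOD = 18  # positions per repeat: five helical turns at 100 deg/residue


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one virtual library.

    arc_range is inclusive in degrees and only multiples of 20 inside
    [100, 260] are drawn; identity_threshold is the redundancy-filter
    cutoff in (0.5, 1].
    """

    kind: str = "amphipathic_arc"
    count: int = 1000
    length_range: tuple = (11, 30)
    arc_range: tuple = (100, 260)
    seed: int = 42
    identity_threshold: float = 0.8

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must be in (0.5, 1]")


def _check_arcs(arc_range: tuple) -> list[int]:
    lo, hi = arc_range
    if lo > hi or lo < 100 or hi > 260 or lo % 20 or hi % 20:
        raise ValueError(
            "arc range must be multiples of 20 degrees within [100, 260]"
        )
    return list(range(int(lo), int(hi) + 1, 20))


def _lengths(spec: LibrarySpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.length_range
    return rng.integers(lo, hi + 1, size=spec.count)


def default_helical_distribution() -> pd.DataFrame:
    """Surrogate 18-position residue distribution for the helical library.

    A synthetic stand-in for position statistics of natural alpha-helical
    anticancer peptides: positions whose wheel angle falls on the hydrophobic
    half draw from the hydrophobic pool, the rest from the cationic polar
    pool. Rows are the 20 residues, columns positions 0-17; each column sums
    to 1. Users may substitute any matrix with this shape.
    """
    mat = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=range(PERIOD)
    )
    hyd_p = 1.0 / len(HYDROPHOBIC_POOL)
    pol_w = np.array(POLAR_WEIGHTS, float)
    pol_p = pol_w / pol_w.sum()
    for pos in range(PERIOD):
        angle = (100 * pos) % 360
        if angle < 180:
            for aa in HYDROPHOBIC_POOL:
                mat.loc[aa, pos] = hyd_p
        else:
            for aa, p in zip(POLAR_POOL, pol_p):
                mat.loc[aa, pos] = p
    return mat


def _validate_distribution(distribution: pd.DataFrame) -> pd.DataFrame:
    if distribution.shape[1] != PERIOD:
        raise ValueError(f"distribution must have {PERIOD} position columns")
    sums = distribution.to_numpy(float).sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"distribution column {bad} sums to {sums[bad]:.6f}, not 1")
    return distribution


def generate_helical(
    spec: LibrarySpec, distribution: pd.DataFrame | None = None
) -> list[Peptide]:
    """Sample peptides from an 18-periodic position-residue distribution.

    Residue at position i is drawn from column (i mod 18); the pattern
    repeats for peptides longer than one period.
    """
    if distribution is None:
        distribution = default_helical_distribution()
    distribution = _validate_distribution(distribution)
    rng = np.random.default_rng(spec.seed)
    letters = list(distribution.index)
    cols = [distribution[c].to_numpy(float) for c in distribution.columns]
    peptides = []
    for k, L in enumerate(_lengths(spec, rng)):
        seq = "".join(
            letters[rng.choice(len(letters), p=cols[i % PERIOD])]
            for i in range(L)
        )
        peptides.append(Peptide(f"helical{k}", seq))
    return peptides


def _arc_sequence(L: int, arc: int, rng: np.random.Generator) -> str:
    pol_w = np.array(POLAR_WEIGHTS, float)
    pol_p = pol_w / pol_w.sum()
    out = []
    for i in range(L):
        angle = (100 * i) % 360
        if angle < arc:
            out.append(HYDROPHOBIC_POOL[rng.integers(len(HYDROPHOBIC_POOL))])
        else:
            out.append(POLAR_POOL[rng.choice(len(POLAR_POOL), p=pol_p)])
    return "".join(out)


def generate_amphipathic_arc(spec: LibrarySpec) -> list[Peptide]:
    """Amphipathic peptides with a hydrophobic helical-wheel face.

    Each peptide draws an arc width from spec.arc_range (multiples of 20 in
    [100, 260]); wheel sectors inside the arc take hydrophobic residues,
    sectors outside take polar residues enriched in K/R. For lengths >= 18
    every sector is occupied and the measured hydrophobic arc equals the
    requested width exactly.
    """
    arcs = _check_arcs(spec.arc_range)
    rng = np.random.default_rng(spec.seed)
    peptides = []
    for k, L in enumerate(_lengths(spec, rng)):
        arc = arcs[rng.integers(len(arcs))]
        pep = Peptide(f"arc{k}", _arc_sequence(int(L), arc, rng))
        pep.metadata["arc"] = arc
        peptides.append(pep)
    return peptides


def generate_gradient(spec: LibrarySpec) -> list[Peptide]:
    """Amphipathic-arc scaffold with a hydrophobic C-terminal third.

    The C-terminal ceil(L/3) residues are replaced with draws from the
    hydrophobic pool, creating an N-to-C hydrophobicity gradient.
    """
    arcs = _check_arcs(spec.arc_range)
    rng = np.random.default_rng(spec.seed)
    peptides = []
    for k, L in enumerate(_lengths(spec, rng)):
        L = int(L)
        arc = arcs[rng.integers(len(arcs))]
        seq = list(_arc_sequence(L, arc, rng))
        n_tail = math.ceil(L / 3)
        for i in range(L - n_tail, L):
            seq[i] = HYDROPHOBIC_POOL[rng.integers(len(HYDROPHOBIC_POOL))]
        pep = Peptide(f"gradient{k}", "".join(seq))
        pep.metadata["arc"] = arc
        peptides.append(pep)
    return peptides


def generate_random(spec: LibrarySpec) -> list[Peptide]:
    """Control library: i.i.d. uniform residues over the 20-letter alphabet."""
    rng = np.random.default_rng(spec.seed)
    peptides = []
    for k, L in enumerate(_lengths(spec, rng)):
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=int(L)))
        peptides.append(Peptide(f"random{k}", seq))
    return peptides


GENERATORS = {
    "helical": generate_helical,
    "amphipathic_arc": generate_amphipathic_arc,
    "gradient": generate_gradient,
    "random": generate_random,
}


def generate(spec: LibrarySpec, distribution: pd.DataFrame | None = None) -> list[Peptide]:
    """Dispatch to the generator named by spec.kind."""
    if spec.kind not in GENERATORS:
        raise ValueError(f"unknown library kind {spec.kind!r}")
    if spec.kind == "helical":
        return generate_helical(spec, distribution)
    return GENERATORS[spec.kind](spec)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues at equal positions, normalized by the
    shorter sequence (alignment-free)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(a[i] == b[i] for i in range(n)) / n


def dedupe_and_cluster(
    peptides: Sequence, identity_threshold: float = 0.8
) -> list[Peptide]:
    """Remove exact duplicates, then greedily cluster by sequence identity.

    Sequences are visited longest-first (CD-HIT-style); a sequence joins the
    first existing cluster whose representative shares >= threshold identity,
    otherwise it founds a new cluster. Cluster representatives are returned
    in order of their first appearance in the input.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0.5, 1]")
    peps = [as_peptide(p, id=f"pep{k}") for k, p in enumerate(peptides)]
    seen: set[str] = set()
    unique: list[tuple[int, Peptide]] = []
    for pos, pep in enumerate(peps):
        if pep.sequence not in seen:
            seen.add(pep.sequence)
            unique.append((pos, pep))
    # longest first; stable on input order for equal lengths
    by_length = sorted(unique, key=lambda t: -len(t[1]))
    reps: list[tuple[int, Peptide]] = []
    for pos, pep in by_length:
        if all(
            pairwise_identity(pep.sequence, rep.sequence) < identity_threshold
            for _, rep in reps
        ):
            reps.append((pos, pep))
    reps.sort(key=lambda t: t[0])
    return [pep for _, pep in reps]
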