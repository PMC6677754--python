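"""Sequence descriptors for membranolytic peptide design.

Encodes a peptide as a 151-component vector: 147 pharmacophore
cross-correlation frequencies (21 unordered feature pairs x sequence
separations 0..6, a seven-residue sliding window) followed by four global
physicochemical properties — Eisenberg hydrophobicity (H), Eisenberg
hydrophobic moment (uH), charge density, and length. Also provides
helical-wheel geometry: residue angles at 100 deg/residue and the
hydrophobic-arc width in 20 deg sectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .peptide import Peptide, as_peptide
from .scales import DEFAULT_PHARMACOPHORE, EISENBERG_CONSENSUS, FEATURES

MAX_DISTANCE = 6  # pair separations 0..6: the seven-residue window

# Mass difference of C-terminal amidation: -OH replaced by -NH2 (average masses).
_AMIDATION_DELTA = -0.98476

#: Names of the 21 unordered feature pairs, canonical order (L,R,A,D,P,N).
PAIR_NAMES = tuple(
    FEATURES[i] + FEATURES[j]
    for i in range(len(FEATURES))
    for j in range(i, len(FEATURES))
)

#: The 151 canonical descriptor names: "LLd0" ... "NNd6", then the globals.
GLOBAL_NAMES = ("H", "uH", "charge_density", "Len")
PEPCATS_NAMES = tuple(
    f"{pair}d{d}" for pair in PAIR_NAMES for d in range(MAX_DISTANCE + 1)
)
DESCRIPTOR_NAMES = PEPCATS_NAMES + GLOBAL_NAMES


def assign_pharmacophore(
    peptide: Peptide | str,
    table: Mapping[str, frozenset] = DEFAULT_PHARMACOPHORE,
) -> np.ndarray:
    """Binary L x 6 pharmacophore profile of a peptide.

    Columns follow the canonical feature order: hydrophobic (L), aromatic (R),
    hydrogen-bond acceptor (A), hydrogen-bond donor (D), positively
    ionizable (P), negatively ionizable (N). Assignment is a pure function of
    residue identity given ``table``.
    """
    pep = as_peptide(peptide)
    prof = np.zeros((len(pep), len(FEATURES)), dtype=np.int8)
    for i, aa in enumerate(pep.sequence):
        for k, feat in enumerate(FEATURES):
            if aa in table[feat]:
                prof[i, k] = 1
    return prof


def pepcats(
    peptide: Peptide | str,
    table: Mapping[str, frozenset] = DEFAULT_PHARMACOPHORE,
) -> np.ndarray:
    """147-component pharmacophore cross-correlation vector.

    For each unordered feature pair (f, g) and separation d in 0..6, counts
    residue index pairs (i, i+d) carrying f at one end and g at the other
    (each index pair counted once; at d = 0 a residue carrying both features
    counts once), normalized by the number of index pairs max(L - d, 1).
    Components with d >= L are zero.
    """
    prof = assign_pharmacophore(peptide, table).astype(bool)
    L = prof.shape[0]
    out = np.zeros(len(PEPCATS_NAMES))
    idx = 0
    nf = len(FEATURES)
    for fi in range(nf):
        for gi in range(fi, nf):
            for d in range(MAX_DISTANCE + 1):
                if d < L:
                    a, b = prof[: L - d], prof[d:]
                    hits = (a[:, fi] & b[:, gi]) | (a[:, gi] & b[:, fi])
                    out[idx] = hits.sum() / max(L - d, 1)
                idx += 1
    return out


def global_hydrophobicity(
    peptide: Peptide | str,
    scale: Mapping[str, float] = EISENBERG_CONSENSUS,
) -> float:
    """Mean per-residue hydrophobicity on the given scale (default Eisenberg)."""
    pep = as_peptide(peptide)
    return sum(scale[aa] for aa in pep.sequence) / len(pep)


def hydrophobic_moment(
    peptide: Peptide | str,
    angle: float = 100.0,
    scale: Mapping[str, float] = EISENBERG_CONSENSUS,
) -> float:
    """Eisenberg hydrophobic moment uH for an idealized helix.

    uH = (1/L) * || sum_i h_i (cos(angle*i), sin(angle*i)) || with residue i
    (0-based) at ``angle`` degrees per residue (100 deg for an alpha-helix).
    """
    pep = as_peptide(peptide)
    rad = math.radians(angle)
    x = y = 0.0
    for i, aa in enumerate(pep.sequence):
        h = scale[aa]
        x += h * math.cos(rad * i)
        y += h * math.sin(rad * i)
    return math.hypot(x, y) / len(pep)


def positive_residue_count(peptide: Peptide | str) -> int:
    """Count of positively charged residues (K and R)."""
    pep = as_peptide(peptide)
    return sum(aa in "KR" for aa in pep.sequence)


def net_charge(peptide: Peptide | str, ph: float = 7.0, his_pka: float = 6.0) -> float:
    """Side-chain net charge: +1 per K/R, -1 per D/E, histidine fractional
    charge from Henderson-Hasselbalch at the given pH (about +0.1 at pH 7).

    Termini are excluded (the design context is C-terminally amidated
    synthetic peptides).
    """
    pep = as_peptide(peptide)
    his = 1.0 / (1.0 + 10.0 ** (ph - his_pka))
    charge = 0.0
    for aa in pep.sequence:
        if aa in "KR":
            charge += 1.0
        elif aa in "DE":
            charge -= 1.0
        elif aa == "H":
            charge += his
    return charge


def peptide_mw(peptide: Peptide | str, amidated: bool = True) -> float:
    """Average molecular weight in Da; C-terminal amide by default."""
    pep = as_peptide(peptide)
    mw = molecular_weight(pep.sequence, seq_type="protein")
    if amidated:
        mw += _AMIDATION_DELTA
    return mw


def charge_and_density(
    peptide: Peptide | str, ph: float = 7.0, amidated: bool = True
) -> tuple[float, float]:
    """(net charge, charge density in e/Da) of the peptide."""
    q = net_charge(peptide, ph=ph)
    return q, q / peptide_mw(peptide, amidated=amidated)


def combined_descriptor(
    peptide: Peptide | str,
    table: Mapping[str, frozenset] = DEFAULT_PHARMACOPHORE,
    scale: Mapping[str, float] = EISENBERG_CONSENSUS,
    ph: float = 7.0,
) -> pd.Series:
    """Full 151-component descriptor: 147 cross-correlations then H, uH,
    charge_density, Len, indexed by the canonical feature names."""
    pep = as_peptide(peptide)
    _, density = charge_and_density(pep, ph=ph)
    values = np.concatenate([
        pepcats(pep, table),
        [
            global_hydrophobicity(pep, scale),
            hydrophobic_moment(pep, scale=scale),
            density,
            float(len(pep)),
        ],
    ])
    return pd.Series(values, index=list(DESCRIPTOR_NAMES), name=pep.id)


def describe(
    peptides: Iterable[Peptide | str],
    table: Mapping[str, frozenset] = DEFAULT_PHARMACOPHORE,
    scale: Mapping[str, float] = EISENBERG_CONSENSUS,
    ph: float = 7.0,
) -> pd.DataFrame:
    """Descriptor table (one row per peptide) for a batch of sequences."""
    rows = []
    for k, p in enumerate(peptides):
        pep = as_peptide(p, id=f"pep{k}")
        rows.append(combined_descriptor(pep, table, scale, ph))
    if not rows:
        return pd.DataFrame(columns=list(DESCRIPTOR_NAMES))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HelicalWheel:
    """Idealized helical-wheel layout: residue i at (100 * i) mod 360 degrees."""

    angles: tuple
    hydrophobic_arc: int


def residue_angles(peptide: Peptide | str, angle: float = 100.0) -> np.ndarray:
    """Wheel angle (degrees in [0, 360)) of each residue, 0-based indexing."""
    pep = as_peptide(peptide)
    return np.array([(angle * i) % 360.0 for i in range(len(pep))])


def hydrophobic_arc(
    peptide: Peptide | str,
    table: Mapping[str, frozenset] = DEFAULT_PHARMACOPHORE,
    sector_width: int = 20,
) -> int:
    """Angular width (degrees) of the hydrophobic face on the helical wheel.

    Each residue sits at (100 * i) mod 360. Every ``sector_width``-degree
    sector (anchored at 0) containing at least one hydrophobic residue is
    marked; the arc is sector_width times the longest circularly contiguous
    run of marked sectors (360 if all marked, 0 if none).
    """
    pep = as_peptide(peptide)
    hydrophobic = table["L"]
    n_sectors = 360 // sector_width
    marked = [False] * n_sectors
    for i, aa in enumerate(pep.sequence):
        if aa in hydrophobic:
            marked[int((100 * i) % 360) // sector_width] = True
    if all(marked):
        return 360
    if not any(marked):
        return 0
    best = run = 0
    # doubled scan handles circular wrap; runs never exceed n_sectors here
    for m in marked + marked:
        run = run + 1 if m else 0
        best = max(best, run)
    return sector_width * min(best, n_sectors)


def helical_wheel(peptide: Peptide | str) -> HelicalWheel:
    """Helical-wheel summary: per-residue angles and hydrophobic-arc width."""
    return HelicalWheel(
        angles=tuple(residue_angles(peptide)),
        hydrophobic_arc=hydrophobic_arc(peptide),
    )
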