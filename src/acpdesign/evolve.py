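"""Simulated molecular evolution (SME): a (1, lambda) evolution strategy
with a Grantham-distance mutation kernel.

From one parent peptide, lambda offspring are generated by mutating each
position independently according to

    P(i -> j) = exp(-d_ij^2 / 2 sigma^2) / sum_j exp(-d_ij^2 / 2 sigma^2)

where d_ij is the Grantham dissimilarity between residues i and j,
row-normalized to [0, 1], and sigma is a strategy parameter: small sigma
keeps offspring close to the parent (conservative substitutions), larger
sigma increases cohort diversity. Cysteine and methionine are excluded from
the mutation alphabet (cyclization risk, synthesis difficulty). Fitness is
always external — an experimental readout table or a user-supplied score —
and the fittest offspring becomes the next parent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .peptide import AMINO_ACIDS, Peptide, as_peptide
from .scales import grantham_matrix

#: Mutation alphabet: the canonical residues minus cysteine and methionine.
KERNEL_ALPHABET = "".join(a for a in AMINO_ACIDS if a not in "CM")

_ENTROPY_NORM = math.log2(20)


@dataclass(frozen=True)
class MutationKernel:
    """Row-stochastic residue transition table at a given sigma.

    ``distances`` holds the row-normalized dissimilarities in [0, 1]
    (zero diagonal), ``P`` the Gaussian transition probabilities; rows of
    ``P`` sum to one and the diagonal entry is each row's maximum.
    """

    alphabet: str
    distances: pd.DataFrame
    sigma: float
    P: pd.DataFrame

    def row(self, residue: str, forbidden: Sequence[str] = ()) -> pd.Series:
        """Transition distribution from ``residue``, with any forbidden
        residues removed and the row renormalized."""
        if residue not in self.alphabet:
            raise KeyError(f"residue {residue!r} is not in the kernel alphabet")
        row = self.P.loc[residue].copy()
        for f in forbidden:
            if f in row.index:
                row[f] = 0.0
        total = row.sum()
        if total <= 0:
            raise ValueError("all transitions forbidden for residue " + residue)
        return row / total


def build_kernel(
    sigma: float,
    matrix: pd.DataFrame | None = None,
    alphabet: str = KERNEL_ALPHABET,
) -> MutationKernel:
    """Construct the mutation kernel from a symmetric dissimilarity matrix.

    The raw matrix (default: Grantham distances over the 18-residue
    alphabet) must be symmetric with a zero diagonal and no negative
    entries. Each row is divided by its own maximum, mapping
    dissimilarities to [0, 1], before the Gaussian transition rule is
    applied.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if matrix is None:
        matrix = grantham_matrix(alphabet)
    else:
        matrix = matrix.loc[list(alphabet), list(alphabet)]
    raw = matrix.to_numpy(float)
    if (raw < 0).any():
        raise ValueError("dissimilarity matrix has negative entries")
    if not np.allclose(raw, raw.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(raw), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    row_max = raw.max(axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0
    d = raw / row_max
    logits = -(d ** 2) / (2.0 * sigma ** 2)
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    P = w / w.sum(axis=1, keepdims=True)
    letters = list(alphabet)
    return MutationKernel(
        alphabet=alphabet,
        distances=pd.DataFrame(d, index=letters, columns=letters),
        sigma=float(sigma),
        P=pd.DataFrame(P, index=letters, columns=letters),
    )


def mutate(
    parent: Peptide | str,
    kernel: MutationKernel,
    n_offspring: int = 10,
    seed: int = 42,
    forbidden: Sequence[str] = (),
    max_retries: int = 100,
) -> list[Peptide]:
    """Generate lambda offspring of a parent by positionwise kernel draws.

    Every position mutates independently according to the kernel row of the
    parent residue (self-transitions dominate at small sigma, so most
    positions stay unchanged). Residues listed in ``forbidden`` are removed
    from every row before sampling. Offspring identical to an already-drawn
    sibling are re-drawn up to ``max_retries`` times, then accepted with a
    warning, keeping the cohort size fixed.

    Parents containing residues outside the kernel alphabet (C or M by
    default) are refused with the offending position reported.
    """
    pep = as_peptide(parent)
    for i, aa in enumerate(pep.sequence):
        if aa not in kernel.alphabet:
            raise ValueError(
                f"parent residue {aa!r} at position {i} is outside the "
                f"mutation alphabet {kernel.alphabet!r}"
            )
    if n_offspring < 1:
        raise ValueError("need at least one offspring")
    rng = np.random.default_rng(seed)
    rows = {
        aa: kernel.row(aa, forbidden) for aa in set(pep.sequence)
    }
    letters = {aa: list(r.index) for aa, r in rows.items()}
    probs = {aa: r.to_numpy(float) for aa, r in rows.items()}

    def draw() -> str:
        return "".join(
            letters[aa][rng.choice(len(letters[aa]), p=probs[aa])]
            for aa in pep.sequence
        )

    offspring: list[Peptide] = []
    seen: set[str] = set()
    for k in range(n_offspring):
        seq = draw()
        retries = 0
        while seq in seen and retries < max_retries:
            seq = draw()
            retries += 1
        if seq in seen:
            warnings.warn("duplicate offspring accepted after retry cap")
        seen.add(seq)
        offspring.append(Peptide(f"{pep.id}.off{k + 1}", seq))
    return offspring


def position_entropy(offspring: Sequence[Peptide | str]) -> np.ndarray:
    """Normalized per-position Shannon entropy of an offspring cohort.

    H_pos = -sum_i p_i log2 p_i over the observed residue frequencies at
    that position, divided by log2(20), giving values in [0, 1]: 0 for a
    conserved column, 1 for a 20-way uniform one.
    """
    seqs = [as_peptide(p).sequence for p in offspring]
    if not seqs:
        raise ValueError("need at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal lengths")
    n = len(seqs)
    out = np.zeros(L)
    for pos in range(L):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[pos]] = counts.get(s[pos], 0) + 1
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        out[pos] = h / _ENTROPY_NORM
    return out


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectivityRule:
    """Default parent-selection comparator for fitness tables.

    Offspring are ranked by (activity retained, selectivity ratio): an
    offspring is "active" if its best (lowest) EC50 over the target columns
    is at or below ``activity_ceiling``; among actives the selectivity
    ratio nontarget_EC50 / min(target EC50s) is maximized (larger = more
    margin between killing target cells and harming nontarget cells). Ties
    break lexicographically on sequence.
    """

    target_columns: tuple
    nontarget_column: str
    activity_ceiling: float = 50.0

    def key(self, row: pd.Series, sequence: str):
        target = min(float(row[c]) for c in self.target_columns)
        active = target <= self.activity_ceiling
        ratio = float(row[self.nontarget_column]) / target if target > 0 else 0.0
        return (active, ratio)


@dataclass
class GenerationRecord:
    """One SME iteration: parent, offspring cohort, diversity diagnostics,
    external fitness table, and the selected child (if any)."""

    parent: Peptide
    offspring: list
    sigma: float
    entropy: np.ndarray
    fitness: pd.DataFrame | None = None
    selected: Peptide | None = None


def select_parent(
    offspring: Sequence[Peptide],
    fitness: pd.DataFrame,
    rule: SelectivityRule | Callable | None = None,
) -> Peptide:
    """Pick the comparator-maximal offspring from an external fitness table.

    ``fitness`` is indexed by offspring id (or carries an ``id`` column) with
    numeric readout columns. ``rule`` is a :class:`SelectivityRule` or any
    callable ``(row, sequence) -> sortable key``; the offspring with the
    largest key wins, ties broken by lexicographic sequence order.
    """
    if fitness is None or len(fitness) == 0:
        raise ValueError("fitness table is empty")
    table = fitness.set_index("id") if "id" in fitness.columns else fitness
    missing = [p.id for p in offspring if p.id not in table.index]
    if missing:
        raise ValueError(f"fitness table lacks offspring: {missing}")
    if rule is None:
        numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        targets, nontarget = tuple(numeric[:-1]), numeric[-1]
        rule = SelectivityRule(targets, nontarget)
    key = rule.key if isinstance(rule, SelectivityRule) else rule
    ranked = sorted(
        offspring,
        key=lambda p: (key(table.loc[p.id], p.sequence), _lex_key(p.sequence)),
        reverse=True,
    )
    return ranked[0]


def _lex_key(seq: str):
    # reverse=True overall; invert characters so ties resolve to the
    # lexicographically smallest sequence
    return tuple(-ord(c) for c in seq)


def evolve_generation(
    parent: Peptide | str,
    sigma: float = 0.1,
    n_offspring: int = 10,
    seed: int = 42,
    forbidden: Sequence[str] = (),
    fitness: pd.DataFrame | None = None,
    rule: SelectivityRule | Callable | None = None,
) -> GenerationRecord:
    """Run one SME iteration: mutate, measure diversity, optionally select.

    If a fitness table is provided the selected child is recorded; otherwise
    selection is deferred (experiment-in-the-loop usage: write the offspring
    out, assay them, then call :func:`select_parent`).
    """
    pep = as_peptide(parent)
    kernel = build_kernel(sigma)
    offspring = mutate(pep, kernel, n_offspring=n_offspring, seed=seed,
                       forbidden=forbidden)
    record = GenerationRecord(
        parent=pep,
        offspring=offspring,
        sigma=sigma,
        entropy=position_entropy(offspring),
        fitness=fitness,
    )
    if fitness is not None:
        record.selected = select_parent(offspring, fitness, rule)
    return record
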