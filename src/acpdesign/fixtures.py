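"""Synthetic labeled datasets and packaged example peptides.

The training corpus behind the classifier (curated active peptides from a
database, helical fragments from solved protein structures as negatives) is
not redistributable, so testing and examples run on a synthetic stand-in:
"active-like" peptides are built with the amphipathic-arc generator (wide
hydrophobic face, cationic polar face, hence high hydrophobic moment and
net positive charge), "inactive-like" peptides are near-uniform random
sequences with no amphipathic structure. A separation knob interpolates
between this fully structured contrast and a label-free null.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .libgen import LibrarySpec, _arc_sequence, generate_random
from .model import LabeledDataset
from .peptide import AMINO_ACIDS, Peptide


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic labeled dataset.

    separation in [0, 1]: the probability that each peptide is drawn from
    its class-specific construction rule rather than the shared random
    background. 1 gives the full active/inactive contrast, 0 makes the
    labels carry no signal.
    """

    n_pos: int = 200
    n_neg: int = 200
    seed: int = 42
    separation: float = 1.0
    length_range: tuple = (11, 30)
    arc_range: tuple = (140, 260)

    def __post_init__(self):
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each class needs at least 2 members")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")


def _random_sequence(L: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=L))


def make_fixture(spec: FixtureSpec) -> LabeledDataset:
    """Generate the synthetic labeled peptide dataset.

    Positives draw an arc width from spec.arc_range (>= 140 degrees by
    default) and are laid out on the helical wheel with a cationic polar
    face; negatives are uniform random sequences. With probability
    1 - separation a peptide of either class falls back to the random
    background. Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    arcs = list(range(spec.arc_range[0], spec.arc_range[1] + 1, 20))
    peptides: list[Peptide] = []
    labels: list[int] = []
    for k in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.separation:
            seq = _arc_sequence(L, arcs[rng.integers(len(arcs))], rng)
        else:
            seq = _random_sequence(L, rng)
        peptides.append(Peptide(f"pos{k}", seq))
        labels.append(1)
    for k in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        peptides.append(Peptide(f"neg{k}", _random_sequence(L, rng)))
        labels.append(0)
    return LabeledDataset.from_peptides(peptides, labels)


def fixture_table(spec: FixtureSpec) -> pd.DataFrame:
    """The fixture as an (id, sequence, label) table, e.g. for CSV export."""
    ds = make_fixture(spec)
    return pd.DataFrame({
        "id": [p.id for p in ds.peptides],
        "sequence": [p.sequence for p in ds.peptides],
        "label": ds.labels,
    })


# ---------------------------------------------------------------------------
# packaged example data


def _data_path(name: str):
    return resources.files("acpdesign.data") / name


def load_validation_peptides() -> list[Peptide]:
    """The 12 designed peptides that were synthesized and assayed (two per
    library scored each way), shipped as a packaged FASTA."""
    from .io import read_fasta

    return read_fasta(_data_path("validation_peptides.fasta"))


def load_validation_outcomes() -> pd.DataFrame:
    """Prediction/outcome table for the 12 validation peptides: columns id,
    sequence, predicted (model call) and active (assay result)."""
    return pd.read_csv(_data_path("validation_outcomes.csv"))
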