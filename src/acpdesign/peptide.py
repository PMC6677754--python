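"""Peptide sequence container and validation.

Sequences are one-letter amino-acid strings over the 20 canonical residues,
normalized to upper case on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the canonical 20-letter alphabet."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.residue = sequence[position]
        super().__init__(
            f"invalid residue {self.residue!r} at position {position} "
            f"in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class Peptide:
    """A named peptide sequence.

    Parameters
    ----------
    id : str
        Short text label.
    sequence : str
        One-letter amino-acid sequence; case is normalized to upper on
        construction and every character must be one of the 20 canonical
        codes.
    metadata : dict
        Optional free-form annotations (activity label, fitness readouts).
    """

    id: str
    sequence: str
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(seq):
            if aa not in _AA_SET:
                raise InvalidResidueError(seq, i)
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def as_peptide(obj, id: str = "pep") -> Peptide:
    """Coerce a raw sequence string (or pass through a Peptide) to a Peptide."""
    if isinstance(obj, Peptide):
        return obj
    return Peptide(id=id, sequence=str(obj))
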