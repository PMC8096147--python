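"""RNA sequences with deazapurine residues.

Deazapurines replace a ring nitrogen of A or G by CH: 3-deazaadenosine
(c3A) and 3-deazaguanosine (c3G) alter the minor-groove face, the
7-deaza isomers (c7A, c7G) the major-groove face.  All four keep the
Watson-Crick edge intact, so for complementarity they pair exactly like
their parent purine.  This module provides the token alphabet, parsing,
reverse complementation under the pairing-parent rule, and a heuristic
molecularity classification used by the melting analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Closed residue alphabet.  Multi-character tokens first: parsing is greedy.
MODIFIED_TOKENS = ("c3A", "c3G", "c7A", "c7G")
PLAIN_TOKENS = ("A", "C", "G", "U")
ALPHABET = MODIFIED_TOKENS + PLAIN_TOKENS

#: Parent purine on the Watson-Crick edge; identity for plain residues.
PAIRING_PARENT = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "c3A": "A", "c7A": "A", "c3G": "G", "c7G": "G",
}

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SequenceParseError(ValueError):
    """Raised when a sequence string contains an unrecognisable token."""

    def __init__(self, text: str, position: int):
        self.position = position
        super().__init__(
            f"unrecognised residue token at position {position + 1} "
            f"in {text!r}"
        )


class Molecularity(enum.Enum):
    """How a strand reaches its folded state in the two-state model."""

    UNIMOLECULAR_HAIRPIN = "unimolecular_hairpin"
    BIMOLECULAR_SELF_COMPLEMENTARY = "bimolecular_self_complementary"
    BIMOLECULAR_NONSELF = "bimolecular_nonself"

    @property
    def bimolecular(self) -> bool:
        return self is not Molecularity.UNIMOLECULAR_HAIRPIN


@dataclass(frozen=True)
class ModifiedRNASequence:
    """An RNA sequence over {A, C, G, U, c3A, c3G, c7A, c7G}.

    Parameters
    ----------
    residues : tuple of str
        Ordered residue tokens, 5' to 3'.
    name : str, optional
        Free-text label, e.g. a table row id like ``"IIIa"``.
    """

    residues: tuple
    name: str = ""

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError("sequence must contain at least one residue")
        bad = [r for r in self.residues if r not in PAIRING_PARENT]
        if bad:
            raise ValueError(f"unknown residue token(s): {bad}")
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return "".join(self.residues)

    @property
    def is_modified(self) -> bool:
        return any(r in MODIFIED_TOKENS for r in self.residues)

    def pairing_parent(self) -> "ModifiedRNASequence":
        """The sequence with every deaza residue replaced by its parent."""
        return ModifiedRNASequence(
            tuple(PAIRING_PARENT[r] for r in self.residues), name=self.name
        )

    def is_self_complementary(self, strip_dangling_3prime: bool = False) -> bool:
        """True if the pairing-parent string equals its reverse complement.

        ``strip_dangling_3prime`` drops the final residue first, for designs
        that append a dangling nucleotide to reduce end fraying.
        """
        parents = [PAIRING_PARENT[r] for r in self.residues]
        if strip_dangling_3prime and len(parents) > 1:
            parents = parents[:-1]
        rc = [_WC_PARTNER[p] for p in reversed(parents)]
        return parents == rc


def parse_sequence(text: str, name: str = "") -> ModifiedRNASequence:
    """Parse a plain-text sequence with inline deaza tokens.

    Tokens are matched greedily, so ``"c3G"`` is one residue, never
    ``c``-``3``-``G``.  Matching is case-insensitive; whitespace is ignored.

    >>> str(parse_sequence("GGUCc3GACC"))
    'GGUCc3GACC'
    """
    text = "".join(text.split())
    if not text:
        raise ValueError("empty sequence string")
    residues = []
    i = 0
    lowered = text.lower()
    while i < len(text):
        for tok in MODIFIED_TOKENS:
            if lowered.startswith(tok.lower(), i):
                residues.append(tok)
                i += len(tok)
                break
        else:
            ch = text[i].upper()
            if ch in PLAIN_TOKENS:
                residues.append(ch)
                i += 1
            else:
                raise SequenceParseError(text, i)
    return ModifiedRNASequence(tuple(residues), name=name)


def format_sequence(seq: ModifiedRNASequence) -> str:
    """Inverse of :func:`parse_sequence`; round-trips exactly."""
    return str(seq)


def complement(seq: ModifiedRNASequence) -> ModifiedRNASequence:
    """Reverse complement under Watson-Crick rules.

    Deaza residues pair through their parent purine (c3G/c7G pair with C,
    c3A/c7A with U), so the output contains only unmodified residues.
    """
    comp = [_WC_PARTNER[PAIRING_PARENT[r]] for r in reversed(seq.residues)]
    name = f"rc({seq.name})" if seq.name else ""
    return ModifiedRNASequence(tuple(comp), name=name)


def classify_molecularity(
    seq: ModifiedRNASequence,
    partner: Optional[ModifiedRNASequence] = None,
    strip_dangling_3prime: bool = False,
) -> Molecularity:
    """Heuristic molecularity from sequence alone.

    With a partner strand the system is a non-self-complementary duplex.
    A single palindromic strand is classified as a self-complementary
    dimer; anything else defaults to a hairpin.  This is a design-time
    convenience — hairpin versus self-dimer cannot be decided from
    sequence alone, and the melting models take molecularity explicitly.
    """
    if partner is not None:
        return Molecularity.BIMOLECULAR_NONSELF
    if seq.is_self_complementary(strip_dangling_3prime=strip_dangling_3prime):
        return Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY
    return Molecularity.UNIMOLECULAR_HAIRPIN


def read_fasta(path) -> list:
    """Read unmodified sequences from a FASTA file.

    Deaza tokens are not legal FASTA; any non-ACGU letter raises.
    T is accepted and read as U (DNA-convention files).
    """
    records = []
    name = None
    chunks: list = []

    def _flush():
        if name is not None:
            seq = "".join(chunks).upper().replace("T", "U")
            records.append(parse_sequence(seq, name=name))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA file does not start with '>'")
                chunks.append(line)
    _flush()
    return records
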