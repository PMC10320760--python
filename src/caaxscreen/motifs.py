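"""CXXX motif space: enumeration, codon translation, and C-terminal scanning.

The CaaX box generalizes to the full CXXX space: a C-terminal cysteine
followed by three freely varying residues (positions a1, a2, X), giving
20**3 = 8,000 motifs.  Everything downstream (counting, enrichment,
heatmaps, trees) is keyed on the 4-character motif string, always starting
with 'C'.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio.Seq import Seq
from Bio import SeqIO

#: The canonical 20-letter amino-acid alphabet in fixed lexicographic order.
#: No ambiguity codes, no stop symbol.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Variable positions of a CXXX motif mapped to string offsets.
POSITIONS: dict[str, int] = {"a1": 1, "a2": 2, "x": 3}

#: One fixed codon per amino acid, mirroring a trimer-phosphoramidite
#: ("Trimer 20") library in which each residue is encoded by a single codon
#: and no stop codons occur.  A=GCA, S=TCT, Q=CAA match the parent-reporter
#: insert context; the rest are common yeast codons, fixed once.
CODON_OF_AA: dict[str, str] = {
    "A": "GCA", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

N_MOTIFS: int = 20 ** 3


class TranslationError(ValueError):
    """A 9-nt insert could not be translated to an XXX triplet.

    ``reason`` is one of ``bad_length``, ``invalid_base``, ``stop_codon``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True, order=True)
class CXXXMotif:
    """A 4-residue C-terminal motif with the cysteine fixed at position 0."""

    a1: str
    a2: str
    x: str

    def __post_init__(self) -> None:
        for res in (self.a1, self.a2, self.x):
            if res not in AMINO_ACIDS:
                raise ValueError(f"not a canonical amino acid: {res!r}")

    def __str__(self) -> str:
        return "C" + self.a1 + self.a2 + self.x

    @classmethod
    def from_string(cls, s: str) -> "CXXXMotif":
        if len(s) != 4 or s[0] != "C":
            raise ValueError(f"not a CXXX motif string: {s!r}")
        return cls(s[1], s[2], s[3])

    def residue(self, position: str) -> str:
        """Residue at ``a1``, ``a2`` or ``x``."""
        return str(self)[POSITIONS[position]]


def enumerate_cxxx() -> list[str]:
    """All 8,000 CXXX motifs in lexicographic order of the XXX part.

    Returned as plain 4-character strings (the package-wide motif key);
    the first element is ``CAAA``.
    """
    return ["C" + a1 + a2 + x
            for a1, a2, x in itertools.product(AMINO_ACIDS, repeat=3)]


def motif_index(motif: str) -> int:
    """Position of ``motif`` in :func:`enumerate_cxxx` order."""
    i1 = AMINO_ACIDS.index(motif[1])
    i2 = AMINO_ACIDS.index(motif[2])
    i3 = AMINO_ACIDS.index(motif[3])
    if motif[0] != "C":
        raise ValueError(f"not a CXXX motif: {motif!r}")
    return (i1 * 20 + i2) * 20 + i3


def translate_insert(nt9: str) -> tuple[str, str, str]:
    """Translate the 9-nt library insert into the (a1, a2, X) triplet.

    Standard genetic code; raises :class:`TranslationError` for wrong
    length, non-ACGT characters, or any stop codon (the trimer library
    design excludes stops, so a stop implies a sequencing artifact).
    """
    if len(nt9) != 9:
        raise TranslationError("bad_length", f"expected 9 nt, got {len(nt9)}")
    if any(b not in "ACGT" for b in nt9):
        raise TranslationError("invalid_base", nt9)
    aa = str(Seq(nt9).translate())
    if "*" in aa:
        raise TranslationError("stop_codon", nt9)
    return (aa[0], aa[1], aa[2])


def motif_to_insert(motif: str) -> str:
    """The 9-nt insert encoding ``motif``'s XXX part, one codon per residue."""
    return "".join(CODON_OF_AA[r] for r in motif[1:])


def _matches_pattern(motif: str, pattern: str) -> bool:
    """Match a 4-character motif against a pattern where X is a wildcard
    at positions 1-3 (e.g. ``CKQX``)."""
    if len(pattern) != 4:
        raise ValueError("pattern must be 4 characters, e.g. 'CKQX'")
    for got, want in zip(motif, pattern):
        if want != "X" and got != want:
            return False
    # position 0 of the pattern is never a wildcard
    return True


def scan_cterminal(
    fasta: str | Iterable,
    pattern: Optional[str] = None,
) -> Iterator[tuple[str, Optional[str]]]:
    """Scan protein FASTA records for a C-terminal CXXX motif.

    Yields ``(record_id, motif_or_None)`` per record.  A motif is reported
    iff the final four residues are Cys followed by three canonical amino
    acids; records shorter than 4 residues or with non-standard residues in
    the tail yield ``None``.  ``pattern`` (e.g. ``"CKQX"``, X = wildcard)
    additionally filters reported motifs.
    """
    if isinstance(fasta, str):
        records = SeqIO.parse(fasta, "fasta")
    else:
        records = fasta
    for rec in records:
        seq = str(rec.seq).upper().rstrip("*")
        motif: Optional[str] = None
        if len(seq) >= 4:
            tail = seq[-4:]
            if tail[0] == "C" and all(r in AMINO_ACIDS for r in tail[1:]):
                motif = tail
        if motif is not None and pattern is not None:
            if not _matches_pattern(motif, pattern):
                motif = None
        yield rec.id, motif
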