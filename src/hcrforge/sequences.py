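"""Validated nucleotide sequences and elementary strand operations.

Orientation is always 5'->3'. Case is preserved for display (the toolkit
renders functional single-stranded domains upper-case and stems lower-case,
following common HCR display style) but is never semantic: all comparisons
are case-insensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import AlphabetError, EmptySequenceError

_DNA = set("ACGT")
_RNA = set("ACGU")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def detect_alphabet(residues: str) -> str:
    """Classify a residue string as ``DNA`` or ``RNA``.

    A sequence containing U (and no T) is RNA; anything over {A,C,G,T} is
    DNA. Mixing T and U, or any other character, is an alphabet error.
    """
    if not residues:
        raise EmptySequenceError("empty sequence")
    upper = set(residues.upper())
    if upper <= _DNA:
        return "DNA"
    if upper <= _RNA:
        return "RNA"
    bad = sorted(upper - (_DNA | _RNA)) or sorted(upper)
    raise AlphabetError(f"invalid nucleotide characters: {''.join(bad)}")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named, validated DNA or RNA string, recorded 5'->3'."""

    residues: str
    name: str = ""
    alphabet: str = field(default="")

    def __post_init__(self):
        detected = detect_alphabet(self.residues)
        if not self.alphabet:
            object.__setattr__(self, "alphabet", detected)
        elif self.alphabet != detected and not (
            self.alphabet == "DNA" and set(self.residues.upper()) <= _DNA
        ):
            raise AlphabetError(
                f"declared alphabet {self.alphabet} does not match residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_rna(self) -> bool:
        return self.alphabet == "RNA"

    def upper(self) -> str:
        return self.residues.upper()


def rna_to_dna(seq: NucleotideSequence) -> NucleotideSequence:
    """Back-transcribe an RNA sequence (U->T), preserving case.

    A DNA input is returned unchanged with a warning — the paper's targets
    are miRNAs but the hairpins themselves are DNA, so DNA input is usually
    a sign the conversion already happened.
    """
    if not seq.is_rna:
        warnings.warn(
            f"rna_to_dna: sequence {seq.name or '<unnamed>'} is already DNA; no-op",
            stacklevel=2,
        )
        return seq
    dna = seq.residues.replace("U", "T").replace("u", "t")
    return NucleotideSequence(dna, name=seq.name, alphabet="DNA")


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single DNA base (case preserved)."""
    if base.upper() not in _DNA:
        raise AlphabetError(f"cannot complement non-DNA base {base!r}")
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string, 5'->3'.

    Ambiguity codes are rejected; only A/C/G/T (either case) are accepted.
    """
    if not seq:
        raise EmptySequenceError("cannot reverse-complement an empty sequence")
    if not set(seq.upper()) <= _DNA:
        bad = sorted(set(seq.upper()) - _DNA)
        raise AlphabetError(f"non-DNA characters in reverse_complement: {''.join(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def pairs(a: str, b: str) -> bool:
    """True if two DNA bases form a Watson-Crick pair (case-insensitive)."""
    return complement_base(a).upper() == b.upper()


def is_self_reverse_complementary(seq: str) -> bool:
    """True if a DNA string equals its own reverse complement."""
    return seq.upper() == reverse_complement(seq).upper()
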