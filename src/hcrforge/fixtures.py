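"""Built-in sequence panels and the synthetic family generator.

``LET7_PANEL`` carries the canonical human let-7 family 5p mature
sequences (public miRNA registry) plus ``let-7d-prime``, a *synthetic*
analog of hsa-let-7d-5p constructed with a single difference in region a
(position 2, A->C); it stands in for the analog probe such panels use and
is not a natural miRNA.

:func:`generate_family` emulates miRNA-like homolog families: a random
target of realistic composition (GC fraction within [0.3, 0.7], length
19-25 nt typical) and homologs differing at a controlled number of
positions confined to a requested region. It reproduces byte-identically
under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import DesignError, PartitionError
from .sequences import NucleotideSequence

_LET7_RNA = {
    "hsa-let-7a-5p": "UGAGGUAGUAGGUUGUAUAGUU",
    "hsa-let-7b-5p": "UGAGGUAGUAGGUUGUGUGGUU",
    "hsa-let-7c-5p": "UGAGGUAGUAGGUUGUAUGGUU",
    "hsa-let-7d-5p": "AGAGGUAGUAGGUUGCAUAGUU",
    "hsa-let-7e-5p": "UGAGGUAGGAGGUUGUAUAGUU",
    "hsa-let-7f-5p": "UGAGGUAGUAGAUUGUAUAGUU",
    # synthetic analog: hsa-let-7d-5p with one region-a difference (pos 2)
    "let-7d-prime": "AGCGGUAGUAGGUUGCAUAGUU",
}

LET7_PANEL = {
    name: NucleotideSequence(seq, name=name) for name, seq in _LET7_RNA.items()
}

MIR21 = NucleotideSequence("uagcuuaucagacugauguuga", name="hsa-miR-21-5p")


@dataclass(frozen=True)
class FixtureFamily:
    """A synthetic target plus homologs with controlled differences."""

    target: NucleotideSequence
    homologs: tuple
    seed: int
    region: str
    metadata: dict


def _random_target(rng: random.Random, length: int) -> str:
    for _ in range(1000):
        seq = "".join(rng.choice("ACGU") for _ in range(length))
        gc = (seq.count("G") + seq.count("C")) / length
        if 0.3 <= gc <= 0.7:
            return seq
    raise DesignError("could not draw a target with GC fraction in [0.3, 0.7]")


def generate_family(
    length: int,
    n_homologs: int,
    diffs_per_homolog: int,
    region: str = "mixed",
    seed: int = 0,
    end_region_len: int = 6,
) -> FixtureFamily:
    """Generate a reproducible synthetic homolog family.

    ``region`` places every difference inside region a, b or c (or
    anywhere, ``mixed``). Each homolog differs from the target at exactly
    ``diffs_per_homolog`` positions drawn uniformly within that region.
    """
    if length <= 2 * end_region_len:
        raise PartitionError(
            f"family length {length} cannot hold two {end_region_len}-nt end regions"
        )
    windows = {
        "a": range(0, end_region_len),
        "b": range(end_region_len, length - end_region_len),
        "c": range(length - end_region_len, length),
        "mixed": range(0, length),
    }
    if region not in windows:
        raise DesignError(f"region must be one of a/b/c/mixed, got {region!r}")
    window = list(windows[region])
    if diffs_per_homolog > len(window):
        raise DesignError(
            f"requested {diffs_per_homolog} differences in a {len(window)}-nt region"
        )
    rng = random.Random(seed)
    target = _random_target(rng, length)
    homologs = []
    for i in range(n_homologs):
        positions = sorted(rng.sample(window, diffs_per_homolog))
        residues = list(target)
        for p in positions:
            residues[p] = rng.choice([b for b in "ACGU" if b != target[p]])
        homologs.append(
            NucleotideSequence("".join(residues), name=f"synthetic_homolog_{i + 1}")
        )
    return FixtureFamily(
        target=NucleotideSequence(target, name="synthetic_target"),
        homologs=tuple(homologs),
        seed=seed,
        region=region,
        metadata={
            "length": length,
            "n_homologs": n_homologs,
            "diffs_per_homolog": diffs_per_homolog,
            "end_region_len": end_region_len,
        },
    )
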