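"""Construction of H1/H2 HCR hairpin pairs and leak-risk classification.

The basic framework builds two metastable hairpins from a target sequence:
H1 carries an exposed toehold complementary to one end of the target and a
stem complementary to the remainder; H2 sequesters the target's toehold
region in its loop so that opened H1 can open H2 and regenerate an
initiator-equivalent strand, propagating the chain.

A hairpin whose designed-structure free energy lies above the
-16.0 kcal/mol benchmark is classified leak-prone: its stem can transiently
melt and start the chain reaction without any initiator. Leak-prone designs
are repaired by appending G-C pairs at the loop-proximal stem end until the
benchmark is met; the target then leaves a short residual duplex it cannot
displace, which transiently melts (the same mechanism the trigger rules
encode), so the repaired pair stays functional.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    AlphabetError,
    ConfigError,
    DesignError,
    ExtensionFailureError,
    MalformedHairpinError,
    TargetTooShortError,
)
from .nn_thermo import FoldEvaluation, NNParameterSet, hairpin_dG, load_default_params
from .sequences import (
    NucleotideSequence,
    is_self_reverse_complementary,
    reverse_complement,
    rna_to_dna,
)

LEAK_PRONE = "leak_prone"
LEAK_RESISTANT = "leak_resistant"


@dataclass(frozen=True)
class Segment:
    """0-based half-open coordinates on a hairpin's full sequence."""

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, full: str) -> str:
        return full[self.start : self.end]


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design parameters (lengths in nt/bp, energies in kcal/mol)."""

    toehold_len: int = 6
    loop_len: int = 6
    end_region_len: int = 6
    leak_threshold: float = -16.0
    threshold_interval: tuple = (-16.0, -15.5)
    max_stem_extension: int = 6
    melt_window_max: int = 5

    def __post_init__(self):
        lengths = (
            self.toehold_len,
            self.loop_len,
            self.end_region_len,
            self.max_stem_extension,
            self.melt_window_max,
        )
        if any(v <= 0 for v in lengths):
            raise ConfigError("all configured lengths must be positive")
        if self.leak_threshold > self.threshold_interval[1]:
            raise ConfigError(
                "leak_threshold must not exceed the transition interval's upper edge"
            )


@dataclass(frozen=True)
class HairpinDesign:
    """A hairpin decomposed into exposed toehold, stem arms and loop.

    Segments are contiguous, non-overlapping, 0-based half-open on
    ``full``, and concatenate to it; ``stem_arm_5p`` is the reverse
    complement of ``stem_arm_3p``. The loop always lies between the two
    arms; the toehold overhang sits at whichever terminus the design
    register dictates. Case encodes display roles only (single-stranded
    functional domains upper, stems lower) and is never compared.
    """

    full: str
    role: str
    name: str
    toehold: Segment
    stem_arm_5p: Segment
    loop: Segment
    stem_arm_3p: Segment
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        segs = sorted(
            (self.toehold, self.stem_arm_5p, self.loop, self.stem_arm_3p),
            key=lambda s: s.start,
        )
        if segs[0].start != 0 or segs[-1].end != len(self.full):
            raise MalformedHairpinError("segments do not cover the full sequence")
        for left, right in zip(segs, segs[1:]):
            if left.end != right.start:
                raise MalformedHairpinError("segments are not contiguous")
        if self.arm5p_seq.upper() != reverse_complement(self.arm3p_seq).upper():
            raise MalformedHairpinError("stem arms are not mutually reverse-complementary")
        if len(self.loop) < 3:
            raise MalformedHairpinError("loop must be at least 3 nt")
        if len(self.toehold) < 1:
            raise MalformedHairpinError("toehold must be at least 1 nt")
        if not (self.stem_arm_5p.end == self.loop.start and self.loop.end == self.stem_arm_3p.start):
            raise MalformedHairpinError("loop must connect the two stem arms")

    # -- segment sequences ------------------------------------------------
    @property
    def toehold_seq(self) -> str:
        return self.toehold.extract(self.full)

    @property
    def arm5p_seq(self) -> str:
        return self.stem_arm_5p.extract(self.full)

    @property
    def arm3p_seq(self) -> str:
        return self.stem_arm_3p.extract(self.full)

    @property
    def loop_seq(self) -> str:
        return self.loop.extract(self.full)

    @property
    def stem_len(self) -> int:
        return len(self.stem_arm_5p)

    @property
    def toehold_side(self) -> str:
        """'5p' if the exposed toehold is the 5' overhang, else '3p'."""
        return "5p" if self.toehold.start == 0 else "3p"


@dataclass(frozen=True)
class LeakVerdict:
    """Leak classification of a hairpin against the free-energy benchmark."""

    verdict: str
    transition_zone: bool
    evaluation: FoldEvaluation
    threshold: float
    interval: tuple


@dataclass(frozen=True)
class ExtensionResult:
    design: HairpinDesign
    partner: HairpinDesign | None
    pairs_added: int


def _assemble(role, name, ordered, provenance):
    """Build a HairpinDesign from (segment_role, sequence) in 5'->3' order."""
    full = "".join(seq for _, seq in ordered)
    coords, pos = {}, 0
    for seg_role, seq in ordered:
        coords[seg_role] = Segment(pos, pos + len(seq))
        pos += len(seq)
    return HairpinDesign(
        full=full,
        role=role,
        name=name,
        toehold=coords["toehold"],
        stem_arm_5p=coords["arm5p"],
        loop=coords["loop"],
        stem_arm_3p=coords["arm3p"],
        provenance=dict(provenance),
    )


def _auto_loop(target_dna: str, arms: list, loop_len: int, max_attempts: int = 4096):
    """Deterministically pick a loop with no >=4-nt cross-complementarity."""
    screened = [target_dna.upper()] + [a.upper() for a in arms]

    def clashes(candidate: str) -> bool:
        for i in range(len(candidate) - 3):
            w = reverse_complement(candidate[i : i + 4])
            if any(w in s for s in screened):
                return True
        return False

    for n, letters in enumerate(itertools.product("ACGT", repeat=loop_len)):
        if n >= max_attempts:
            break
        candidate = "".join(letters)
        if not clashes(candidate):
            return candidate
    raise DesignError(
        "auto loop generation failed the cross-complementarity screen "
        f"after {max_attempts} attempts"
    )


def build_basic_pair(
    target: NucleotideSequence,
    cfg: DesignConfig | None = None,
    loop_choice: str = "CAAAGT",
    toehold_end: str = "3p",
):
    """Construct the H1/H2 hairpin pair for a target by the basic framework.

    ``toehold_end`` selects which end of the target the exposed toehold
    complements: ``"3p"`` (the basic recipe; H1's toehold binds the
    target's 3' terminal ``toehold_len`` bases) or ``"5p"`` (the mirrored
    register used when homolog differences forbid the 3' end).
    ``loop_choice`` is a DNA string of ``loop_len`` nt or ``"auto"``.

    Returns ``(H1, H2)``.
    """
    cfg = cfg or DesignConfig()
    if toehold_end not in ("3p", "5p"):
        raise ConfigError(f"toehold_end must be '3p' or '5p', got {toehold_end!r}")
    dna = rna_to_dna(target) if target.is_rna else target
    d = dna.residues
    L, T = len(d), cfg.toehold_len
    if L < T + 3:
        raise TargetTooShortError(
            f"target {target.name or '<unnamed>'} has {L} nt; needs at least {T + 3}"
        )
    stem_len = L - T
    if toehold_end == "3p":
        remainder, toehold_region = d[:stem_len], d[stem_len:]
    else:
        toehold_region, remainder = d[:T], d[T:]

    if is_self_reverse_complementary(remainder):
        warnings.warn(
            "design failure risk: the target remainder is self-reverse-"
            "complementary, so the stem arm would fold internally",
            stacklevel=2,
        )

    rc_rem = reverse_complement(remainder)
    if loop_choice == "auto":
        loop = _auto_loop(d, [remainder, rc_rem], cfg.loop_len)
    else:
        if len(loop_choice) != cfg.loop_len:
            raise DesignError(
                f"loop_choice must have loop_len={cfg.loop_len} nt, got {len(loop_choice)}"
            )
        if not set(loop_choice.upper()) <= set("ACGT"):
            raise AlphabetError(f"loop_choice {loop_choice!r} is not DNA")
        loop = loop_choice

    prov = {
        "target": target.name,
        "target_dna": d,
        "register": toehold_end,
        "loop_choice": loop,
        "extension_bp": 0,
        "protective_bp": 0,
    }
    base = target.name or "target"
    if toehold_end == "3p":
        h1 = _assemble(
            "H1",
            f"{base}_H1",
            [
                ("toehold", reverse_complement(toehold_region).upper()),
                ("arm5p", rc_rem.lower()),
                ("loop", loop.upper()),
                ("arm3p", remainder.lower()),
            ],
            prov,
        )
        h2 = _assemble(
            "H2",
            f"{base}_H2",
            [
                ("arm5p", remainder.lower()),
                ("loop", toehold_region.upper()),
                ("arm3p", rc_rem.lower()),
                ("toehold", reverse_complement(loop).upper()),
            ],
            prov,
        )
    else:
        h1 = _assemble(
            "H1",
            f"{base}_H1",
            [
                ("arm5p", remainder.lower()),
                ("loop", loop.upper()),
                ("arm3p", rc_rem.lower()),
                ("toehold", reverse_complement(toehold_region).upper()),
            ],
            prov,
        )
        h2 = _assemble(
            "H2",
            f"{base}_H2",
            [
                ("toehold", reverse_complement(loop).upper()),
                ("arm5p", rc_rem.lower()),
                ("loop", toehold_region.upper()),
                ("arm3p", remainder.lower()),
            ],
            prov,
        )
    return h1, h2


def classify_leak(
    design: HairpinDesign,
    cfg: DesignConfig | None = None,
    params: NNParameterSet | None = None,
) -> LeakVerdict:
    """Classify a hairpin against the leak-resistance benchmark.

    ``leak_resistant`` iff the designed-structure free energy is at or
    below the threshold (-16.0 kcal/mol by default; the boundary counts as
    resistant). Energies falling inside the reported transition interval
    (-16.0, -15.5) are additionally flagged.
    """
    cfg = cfg or DesignConfig()
    params = params or load_default_params()
    ev = hairpin_dG(design, params)
    resistant = ev.total_dg <= cfg.leak_threshold
    lo, hi = cfg.threshold_interval
    return LeakVerdict(
        verdict=LEAK_RESISTANT if resistant else LEAK_PRONE,
        transition_zone=lo < ev.total_dg < hi,
        evaluation=ev,
        threshold=cfg.leak_threshold,
        interval=cfg.threshold_interval,
    )


def _bump(design, role_changes, provenance_update):
    """Rebuild a design with modified segment sequences, preserving order."""
    parts = {
        "toehold": design.toehold_seq,
        "arm5p": design.arm5p_seq,
        "loop": design.loop_seq,
        "arm3p": design.arm3p_seq,
    }
    parts.update(role_changes)
    coords = {
        "toehold": design.toehold,
        "arm5p": design.stem_arm_5p,
        "loop": design.loop,
        "arm3p": design.stem_arm_3p,
    }
    order = sorted(coords, key=lambda r: coords[r].start)
    prov = dict(design.provenance)
    prov.update(provenance_update)
    return _assemble(design.role, design.name, [(r, parts[r]) for r in order], prov)


def extend_attacked_distal(design: HairpinDesign, added: str) -> HairpinDesign:
    """Insert base pairs at the loop-proximal stem end of the hairpin the
    initiator attacks (``added`` is the arm5p-side content, 5'->3')."""
    return _bump(
        design,
        {
            "arm5p": design.arm5p_seq + added.upper(),
            "arm3p": reverse_complement(added).upper() + design.arm3p_seq,
        },
        {"extension_bp": design.provenance.get("extension_bp", 0) + len(added)},
    )


def extend_partner_open_end(design: HairpinDesign, added: str) -> HairpinDesign:
    """Mirror an attacked-hairpin extension onto the partner hairpin.

    The partner grows at its open (toehold-adjacent) stem end so the output
    strand released by the extended attacked hairpin — which carries the
    complement of the added bases right after its loop domain — can still
    branch-migrate through it without a stall.
    """
    if design.toehold_side == "3p":
        changes = {
            "arm3p": design.arm3p_seq + added.upper(),
            "arm5p": reverse_complement(added).upper() + design.arm5p_seq,
        }
    else:
        changes = {
            "arm5p": reverse_complement(added).upper() + design.arm5p_seq,
            "arm3p": design.arm3p_seq + added.upper(),
        }
    return _bump(
        design,
        changes,
        {"extension_bp": design.provenance.get("extension_bp", 0) + len(added)},
    )


def extend_stem(
    design: HairpinDesign,
    cfg: DesignConfig | None = None,
    params: NNParameterSet | None = None,
    partner: HairpinDesign | None = None,
) -> ExtensionResult:
    """Append G-C pairs until the hairpin meets the leak benchmark.

    Pairs are added one at a time at the loop-proximal stem end (C on the
    arm5p side), re-evaluating after each addition, and mirrored onto
    ``partner`` (at its open end) so the pair stays co-functional. An
    already-resistant design is returned unchanged with count 0; exceeding
    ``max_stem_extension`` raises :class:`ExtensionFailureError`.
    """
    cfg = cfg or DesignConfig()
    params = params or load_default_params()
    current, mate = design, partner
    for added in range(cfg.max_stem_extension + 1):
        if classify_leak(current, cfg, params).verdict == LEAK_RESISTANT:
            return ExtensionResult(current, mate, added)
        if added == cfg.max_stem_extension:
            break
        current = extend_attacked_distal(current, "C")
        if mate is not None:
            mate = extend_partner_open_end(mate, "C")
    raise ExtensionFailureError(
        f"{design.name or 'design'} still leak-prone after "
        f"{cfg.max_stem_extension} added G-C pairs"
    )


def stem_length_scan(
    target: NucleotideSequence,
    cfg: DesignConfig | None = None,
    stem_range=None,
    params: NNParameterSet | None = None,
    loop_choice: str = "CAAAGT",
) -> pd.DataFrame:
    """Free energy and leak verdict of H1 across a range of stem lengths.

    Stems shorter than the recipe's natural length truncate the
    loop-proximal end; longer stems append G-C pairs there. Returns a
    DataFrame with columns ``stem_length``, ``total_dg``, ``verdict``.
    """
    cfg = cfg or DesignConfig()
    params = params or load_default_params()
    h1, _ = build_basic_pair(target, cfg, loop_choice=loop_choice)
    natural = h1.stem_len
    if stem_range is None:
        stem_range = range(max(4, natural - 5), natural + cfg.max_stem_extension + 1)
    lengths = list(stem_range)
    if not lengths:
        raise DesignError("stem_length_scan requires a non-empty range")
    if min(lengths) < 4 or max(lengths) > natural + cfg.max_stem_extension:
        raise DesignError(
            f"stem lengths must lie in [4, {natural + cfg.max_stem_extension}]"
        )
    rows = []
    for length in lengths:
        if length <= natural:
            variant = _bump(
                h1,
                {
                    "arm5p": h1.arm5p_seq[:length],
                    "arm3p": h1.arm3p_seq[natural - length :],
                },
                {"stem_variant": length},
            )
        else:
            variant = extend_attacked_distal(h1, "C" * (length - natural))
        verdict = classify_leak(variant, cfg, params)
        rows.append(
            {
                "stem_length": length,
                "total_dg": verdict.evaluation.total_dg,
                "verdict": verdict.verdict,
            }
        )
    return pd.DataFrame(rows)
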