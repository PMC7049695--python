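"""Nearest-neighbor free-energy engine for DNA stems and hairpins.

The model predicts duplex stability as a sum of Watson-Crick dinucleotide
stacking free energies plus initiation, terminal and loop penalty terms,
evaluated at the toolkit's reference condition: 37 degC, 1 M Na+. The stack
and penalty tables are the published unified DNA parameter set (see
``data/nn_dg37.tsv`` for values and sources); all energies are dG37 in
kcal/mol, more negative = more stable.

Two evaluation modes exist for hairpins:

* default (``dangles=False``): the strict additive decomposition —
  one duplex-initiation event, at most one terminal A.T penalty at the open
  helix end, stem stacks, and the hairpin loop penalty.
* calibrated (``dangles=True``, :func:`nupack_calibrated`): the hairpin is
  treated as a unimolecular fold (no bimolecular initiation term) and
  single-stranded neighbors stack onto the helix ends — a dangle at the open
  end where a toehold overhang continues the strand, and the published
  terminal-mismatch term of the first/last loop bases on the loop-closing
  pair, as reference folding tools apply. This mode
  tracks imposed-structure evaluations by NUPACK-family tools to within
  a few tenths of a kcal/mol and is the configuration under which the
  -16.0 kcal/mol leak benchmark is interpreted.

Only the energy of the *designed* secondary structure is computed; this is
not a minimum-free-energy search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import (
    AlphabetError,
    DegenerateHelixError,
    ImpossibleLoopError,
    MalformedHairpinError,
)
from .sequences import reverse_complement

GAS_CONSTANT = 0.0019872  # kcal / (mol K)


@dataclass(frozen=True)
class NNParameterSet:
    """Embedded nearest-neighbor dG37 parameters (1 M Na+).

    ``stack_table`` maps every 5'->3' top-strand dinucleotide of a
    Watson-Crick paired stack to its dG37; a stack and its
    reverse-complement reading share one value. ``hairpin_loop_table`` is
    defined for every integer loop size 3..30; larger loops use the
    Jacobson-Stockmayer logarithmic extrapolation with coefficient
    1.75*R*T. ``dangles`` selects the calibrated unimolecular hairpin mode.
    """

    stack_table: dict
    initiation: float
    terminal_at_penalty: float
    hairpin_loop_table: dict
    dangle5_table: dict = field(default_factory=dict)
    dangle3_table: dict = field(default_factory=dict)
    mismatch_hairpin_table: dict = field(default_factory=dict)
    loop_extrapolation_coefficient: float = 1.75 * GAS_CONSTANT * 310.15
    temperature_c: float = 37.0
    reference_salt: float = 1.0
    dangles: bool = False
    version: str = "nn_dg37/1"

    def __post_init__(self):
        missing = {
            d for d in ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG")
        } - set(self.stack_table)
        if missing:
            raise ValueError(f"stack table incomplete: missing {sorted(missing)}")
        if any(v >= 0 for v in self.stack_table.values()):
            raise ValueError("every Watson-Crick stack dG37 must be negative")
        if set(range(3, 31)) - set(self.hairpin_loop_table):
            raise ValueError("hairpin loop table must cover sizes 3..30")
        if any(v <= 0 for v in self.hairpin_loop_table.values()):
            raise ValueError("hairpin loop penalties must be positive")


@dataclass(frozen=True)
class FoldEvaluation:
    """Additive free-energy breakdown of a stem or hairpin structure.

    ``total_dg`` is exactly ``stack_sum + loop_penalty + initiation_terms``
    (the latter bundles initiation, terminal A.T penalties and any dangle
    contributions; ``terms`` itemizes them).
    """

    stack_sum: float
    loop_penalty: float
    initiation_terms: float
    total_dg: float
    per_stack_breakdown: tuple
    terms: dict = field(default_factory=dict)


def _parse_param_tsv(text: str):
    stacks, loops, d5, d3, mmh = {}, {}, {}, {}, {}
    scalars = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        context, value, _source = line.split("\t")
        value = float(value)
        parts = context.split("/")
        if parts[0] == "stack":
            stacks[parts[1]] = value
        elif parts[0] == "hairpin_loop":
            loops[int(parts[1])] = value
        elif parts[0] == "dangle5":
            d5[(parts[1][0], parts[1][1], parts[2])] = value
        elif parts[0] == "dangle3":
            d3[(parts[1][0], parts[1][1], parts[2])] = value
        elif parts[0] == "mismatch_hairpin":
            mmh[(parts[1][0], parts[1][1], parts[2], parts[3])] = value
        else:
            scalars[parts[0]] = value
    return stacks, loops, d5, d3, mmh, scalars


def _fill_loop_table(anchors: dict, coefficient: float) -> dict:
    """Fill sizes 3..30 from tabulated anchors by logarithmic interpolation."""
    table = {}
    sizes = sorted(anchors)
    for n in range(3, 31):
        if n in anchors:
            table[n] = anchors[n]
        else:
            below = max(s for s in sizes if s < n)
            table[n] = round(anchors[below] + coefficient * math.log(n / below), 3)
    return table


@lru_cache(maxsize=2)
def load_default_params(dangles: bool = False) -> NNParameterSet:
    """Load the embedded parameter TSV shipped with the package."""
    text = resources.files("hcrforge.data").joinpath("nn_dg37.tsv").read_text()
    stacks, anchors, d5, d3, mmh, scalars = _parse_param_tsv(text)
    full_stacks = {}
    for dinuc, v in stacks.items():
        full_stacks[dinuc] = v
        full_stacks[reverse_complement(dinuc)] = v
    coefficient = 1.75 * GAS_CONSTANT * 310.15
    return NNParameterSet(
        stack_table=full_stacks,
        initiation=scalars["initiation"],
        terminal_at_penalty=scalars["terminal_at_penalty"],
        hairpin_loop_table=_fill_loop_table(anchors, coefficient),
        dangle5_table=d5,
        dangle3_table=d3,
        mismatch_hairpin_table=mmh,
        loop_extrapolation_coefficient=coefficient,
        dangles=dangles,
    )


def nupack_calibrated() -> NNParameterSet:
    """Parameter set in the calibrated (unimolecular, dangles-on) mode."""
    return load_default_params(dangles=True)


def stack_energy(top_dinucleotide: str, params: NNParameterSet | None = None) -> float:
    """dG37 of one Watson-Crick paired stack, looked up by its top strand.

    The implied bottom strand is the Watson-Crick complement; a stack and
    its reverse-complement reading return the same value.
    """
    params = params or load_default_params()
    key = top_dinucleotide.upper()
    if len(key) != 2 or not set(key) <= set("ACGT"):
        raise AlphabetError(f"stack must be a 2-letter DNA string, got {top_dinucleotide!r}")
    return params.stack_table[key]


def _is_at(top: str, bottom: str) -> bool:
    return {top.upper(), bottom.upper()} == {"A", "T"}


def _dangle(table: dict, pair_top: str, pair_bottom: str, base: str) -> float:
    return table.get((pair_top.upper(), pair_bottom.upper(), base.upper()), 0.0)


def duplex_dG(top_strand: str, params: NNParameterSet | None = None) -> FoldEvaluation:
    """NN free energy of a fully Watson-Crick paired duplex.

    ``total_dg`` = initiation + per-end terminal A.T penalties + the sum of
    all n-1 stack energies. Invariant under replacing the top strand with
    its reverse complement.
    """
    params = params or load_default_params()
    seq = top_strand.upper()
    if len(seq) < 2:
        raise DegenerateHelixError("a duplex needs at least 2 bp to have a stack")
    if not set(seq) <= set("ACGT"):
        raise AlphabetError(f"non-DNA characters in duplex strand {top_strand!r}")
    breakdown = tuple(
        (seq[i : i + 2], stack_energy(seq[i : i + 2], params))
        for i in range(len(seq) - 1)
    )
    stack_sum = sum(v for _, v in breakdown)
    at_ends = sum(
        params.terminal_at_penalty
        for end in (seq[0], seq[-1])
        if end in ("A", "T")
    )
    init = params.initiation + at_ends
    terms = {"initiation": params.initiation, "terminal_at": at_ends}
    return FoldEvaluation(
        stack_sum=stack_sum,
        loop_penalty=0.0,
        initiation_terms=init,
        total_dg=stack_sum + 0.0 + init,
        per_stack_breakdown=breakdown,
        terms=terms,
    )


def hairpin_loop_penalty(loop_size: int, params: NNParameterSet | None = None) -> float:
    """Destabilizing dG37 of a hairpin loop of ``loop_size`` unpaired nt."""
    params = params or load_default_params()
    if loop_size < 3:
        raise ImpossibleLoopError(f"hairpin loops below 3 nt are impossible (got {loop_size})")
    if loop_size <= 30:
        return params.hairpin_loop_table[loop_size]
    return params.hairpin_loop_table[30] + params.loop_extrapolation_coefficient * math.log(
        loop_size / 30
    )


def hairpin_dG(design, params: NNParameterSet | None = None) -> FoldEvaluation:
    """Free energy of a designed hairpin structure.

    ``design`` is any object exposing ``full``, ``arm5p_seq``, ``arm3p_seq``,
    ``loop_seq`` and segment coordinates (see
    :class:`hcrforge.hairpins.HairpinDesign`). The stem is evaluated on its
    imposed structure; single-stranded toehold overhangs contribute no
    base-pairing energy (in calibrated mode they contribute one dangle term
    at the open helix end).
    """
    params = params or load_default_params()
    arm5, arm3, loop = design.arm5p_seq, design.arm3p_seq, design.loop_seq
    if arm5.upper() != reverse_complement(arm3).upper():
        raise MalformedHairpinError("stem arms are not mutually reverse-complementary")
    if len(loop) < 3:
        raise ImpossibleLoopError(f"loop of {len(loop)} nt is sterically impossible")
    if len(arm5) < 2:
        raise DegenerateHelixError("hairpin stem needs at least 2 bp")

    seq5 = arm5.upper()
    breakdown = tuple(
        (seq5[i : i + 2], stack_energy(seq5[i : i + 2], params))
        for i in range(len(seq5) - 1)
    )
    stack_sum = sum(v for _, v in breakdown)
    loop_pen = hairpin_loop_penalty(len(loop), params)

    open_top, open_bottom = arm5[0], arm3[-1]
    at_pen = params.terminal_at_penalty if _is_at(open_top, open_bottom) else 0.0
    terms = {"terminal_at": at_pen}
    if not params.dangles:
        init = params.initiation + at_pen
        terms["initiation"] = params.initiation
    else:
        # Unimolecular fold: no strand-association penalty. Dangles stack
        # single-stranded neighbors onto both helix ends.
        dangle = 0.0
        start5 = design.stem_arm_5p.start
        end3 = design.stem_arm_3p.end
        if start5 > 0:  # toehold continues 5' of the open end (H1-style)
            dangle += _dangle(
                params.dangle5_table, open_top, open_bottom, design.full[start5 - 1]
            )
        if end3 < len(design.full):  # toehold continues 3' (H2-style)
            dangle += _dangle(
                params.dangle3_table, open_bottom, open_top, design.full[end3]
            )
        close_top, close_bottom = arm5[-1], arm3[0]
        mismatch = params.mismatch_hairpin_table.get(
            (close_top.upper(), close_bottom.upper(), loop[0].upper(), loop[-1].upper()),
            0.0,
        )
        terms["dangles"] = dangle
        terms["loop_terminal_mismatch"] = mismatch
        init = at_pen + dangle + mismatch
    return FoldEvaluation(
        stack_sum=stack_sum,
        loop_penalty=loop_pen,
        initiation_terms=init,
        total_dg=stack_sum + loop_pen + init,
        per_stack_breakdown=breakdown,
        terms=terms,
    )
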