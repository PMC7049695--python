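"""Free-energy engine tests.

The oracle used throughout is an independent re-summation over the raw
parameter TSV (stacks looked up directly, penalties applied per the
documented decomposition), written here without reference to the engine's
internals.
"""

import math
from importlib import resources

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcrforge import (
    build_basic_pair,
    duplex_dG,
    hairpin_dG,
    hairpin_loop_penalty,
    stack_energy,
)
from hcrforge.errors import (
    AlphabetError,
    DegenerateHelixError,
    ImpossibleLoopError,
    MalformedHairpinError,
)
from hcrforge.hairpins import HairpinDesign, Segment, extend_attacked_distal
from hcrforge.sequences import NucleotideSequence, reverse_complement

dna = st.text(alphabet="ACGT", min_size=2, max_size=40)

HR1_ARM = "tcagtctgataagcta"  # the printed H1 stem arm (16 nt)


def _raw_tables():
    """Read the shipped TSV directly — independent of the loader."""
    text = resources.files("hcrforge.data").joinpath("nn_dg37.tsv").read_text()
    stacks, loops, scalars = {}, {}, {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        context, value, _ = line.split("\t")
        parts = context.split("/")
        if parts[0] == "stack":
            stacks[parts[1]] = float(value)
        elif parts[0] == "hairpin_loop":
            loops[int(parts[1])] = float(value)
        elif parts[0] in ("initiation", "terminal_at_penalty"):
            scalars[parts[0]] = float(value)
    return stacks, loops, scalars


def oracle_duplex(top: str) -> float:
    """Brute-force hand summation of the duplex decomposition."""
    stacks, _, scalars = _raw_tables()
    seq = top.upper()
    total = scalars["initiation"]
    for end in (seq[0], seq[-1]):
        if end in "AT":
            total += scalars["terminal_at_penalty"]
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        total += stacks.get(dinuc, stacks.get(reverse_complement(dinuc), 0.0))
    return total


def make_hairpin(arm5: str, loop: str, toehold: str = "") -> HairpinDesign:
    """Assemble an H1-style hairpin (optional 5' toehold) by hand."""
    arm3 = reverse_complement(arm5)
    full = toehold + arm5 + loop + arm3
    t = len(toehold)
    return HairpinDesign(
        full=full,
        role="H1",
        name="fixture",
        toehold=Segment(0, t) if t else Segment(0, 1),
        stem_arm_5p=Segment(t, t + len(arm5)),
        loop=Segment(t + len(arm5), t + len(arm5) + len(loop)),
        stem_arm_3p=Segment(t + len(arm5) + len(loop), len(full)),
    ) if t else _bare_hairpin(arm5, loop)


def _bare_hairpin(arm5, loop):
    # toehold >= 1 nt is a design invariant; give a minimal 1-nt overhang
    return make_hairpin(arm5, loop, toehold="A")


class TestStackEnergy:
    def test_aa_matches_published_table(self):
        assert stack_energy("AA") == -1.00

    def test_reverse_complement_reading_identical(self):
        for a in "ACGT":
            for b in "ACGT":
                dinuc = a + b
                assert stack_energy(dinuc) == stack_energy(reverse_complement(dinuc))

    def test_every_stack_negative(self):
        assert all(stack_energy(a + b) < 0 for a in "ACGT" for b in "ACGT")

    def test_invalid_character(self):
        with pytest.raises(AlphabetError):
            stack_energy("AX")


class TestDuplex:
    def test_two_nt_forced_decomposition(self):
        ev = duplex_dG("AT")
        assert len(ev.per_stack_breakdown) == 1
        assert ev.total_dg == pytest.approx(oracle_duplex("AT"))

    def test_printed_stem_arm_oracle_sum(self):
        ev = duplex_dG(HR1_ARM)
        assert len(ev.per_stack_breakdown) == 15
        assert ev.total_dg == pytest.approx(oracle_duplex(HR1_ARM))
        assert ev.total_dg == pytest.approx(-16.58)

    def test_degenerate_helix(self):
        with pytest.raises(DegenerateHelixError):
            duplex_dG("A")

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_strand_symmetry(self, s):
        assert duplex_dG(s).total_dg == pytest.approx(
            duplex_dG(reverse_complement(s)).total_dg
        )


class TestLoopPenalty:
    def test_size_six_matches_published_table(self):
        assert hairpin_loop_penalty(6) == 4.0

    def test_impossible_loop(self):
        with pytest.raises(ImpossibleLoopError):
            hairpin_loop_penalty(2)

    def test_extrapolation_monotone(self):
        assert hairpin_loop_penalty(31) > hairpin_loop_penalty(30)
        # Jacobson-Stockmayer logarithmic form beyond the table
        expected = hairpin_loop_penalty(30) + 1.75 * 0.0019872 * 310.15 * math.log(45 / 30)
        assert hairpin_loop_penalty(45) == pytest.approx(expected)

    def test_all_tabulated_sizes_positive(self, params):
        assert all(params.hairpin_loop_table[n] > 0 for n in range(3, 31))


class TestHairpin:
    def test_additivity_identity(self, params):
        hp = make_hairpin("GCGCATTGCA", "CAAAGT", "TCAACA")
        ev = hairpin_dG(hp, params)
        assert ev.total_dg == ev.stack_sum + ev.loop_penalty + ev.initiation_terms
        assert len(ev.per_stack_breakdown) == hp.stem_len - 1

    def test_breakdown_resums_to_total(self, params, calibrated):
        hp = make_hairpin("GGATCCTTAGCAC", "TTTCGT", "ACGTAC")
        for p in (params, calibrated):
            ev = hairpin_dG(hp, p)
            resum = sum(v for _, v in ev.per_stack_breakdown)
            assert ev.stack_sum == pytest.approx(resum)
            assert ev.total_dg == pytest.approx(
                resum + ev.loop_penalty + ev.initiation_terms
            )

    def test_printed_h1_leak_prone_energy(self, printed_pair, params, calibrated):
        h1, _ = printed_pair
        # the basic-framework hairpin lies above the -16.0 benchmark in
        # both evaluation modes
        assert hairpin_dG(h1, params).total_dg > -16.0
        assert hairpin_dG(h1, calibrated).total_dg > -16.0

    def test_appended_pair_adds_exactly_its_stack(self, printed_pair, params):
        h1, _ = printed_pair
        extended = extend_attacked_distal(h1, "C")
        new_stack = stack_energy(h1.arm5p_seq[-1] + "C")
        delta = hairpin_dG(extended, params).total_dg - hairpin_dG(h1, params).total_dg
        # loop-proximal extension: no terminal-penalty change in default mode
        assert delta == pytest.approx(new_stack)

    def test_monotone_extension(self, params):
        hp = make_hairpin("ATGCATGCAT", "CAAAGT", "GG")
        base = hairpin_dG(hp, params).total_dg
        for b in "ACGT":
            bigger = extend_attacked_distal(hp, b)
            assert hairpin_dG(bigger, params).total_dg < base

    def test_malformed_arms_rejected(self):
        with pytest.raises(MalformedHairpinError):
            HairpinDesign(
                full="AACCCTTTGGA",
                role="H1",
                name="bad",
                toehold=Segment(0, 2),
                stem_arm_5p=Segment(2, 5),
                loop=Segment(5, 8),
                stem_arm_3p=Segment(8, 11),
            )

    def test_impossible_loop_rejected(self):
        arm = "GCGC"
        with pytest.raises(MalformedHairpinError):
            HairpinDesign(
                full="A" + arm + "TT" + reverse_complement(arm),
                role="H1",
                name="bad",
                toehold=Segment(0, 1),
                stem_arm_5p=Segment(1, 5),
                loop=Segment(5, 7),
                stem_arm_3p=Segment(7, 11),
            )


class TestReferenceAgreement:
    def test_designed_hairpins_within_1_kcal_of_reference_fold(self, calibrated, let7):
        """Cross-validation harness: imposed-structure evaluation at 37 degC,
        1 M Na+, against an external reference implementation."""
        RNA = pytest.importorskip("RNA")
        RNA.params_load_DNA_Mathews2004()

        def reference(design):
            md = RNA.md()
            md.temperature = 37.0
            md.dangles = 2
            order = sorted(
                [
                    (".", design.toehold),
                    ("(", design.stem_arm_5p),
                    (".", design.loop),
                    (")", design.stem_arm_3p),
                ],
                key=lambda x: x[1].start,
            )
            db = "".join(ch * len(seg) for ch, seg in order)
            return RNA.fold_compound(design.full.upper(), md).eval_structure(db)

        designs = []
        panel = ["hsa-let-7a-5p", "hsa-let-7b-5p", "hsa-let-7d-5p", "hsa-let-7e-5p"]
        for name in panel:
            designs.extend(build_basic_pair(let7[name], loop_choice="auto"))
        designs.extend(
            build_basic_pair(NucleotideSequence("uagcuuaucagacugauguuga", name="miR21"))
        )
        designs.append(make_hairpin("GCGCGCGCGCGCGCGCGCGC", "CAAAGT", "TCAACA"))
        designs.append(make_hairpin("ATTATAATTATA", "AAAAAA", "TTTTTT"))
        assert len(designs) >= 10
        for d in designs:
            mine = hairpin_dG(d, calibrated).total_dg
            assert mine == pytest.approx(reference(d), abs=1.0)
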