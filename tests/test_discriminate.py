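import dataclasses

import pytest

from hcrforge import (
    DesignConfig,
    build_basic_pair,
    design_discriminating_pair,
    diff_profile,
    partition_regions,
    select_toehold_end,
)
from hcrforge.discriminate import (
    A_COMPLEMENTARY,
    C_COMPLEMENTARY,
    add_protective_bases,
)
from hcrforge.errors import (
    IndelError,
    IndistinguishableHomologError,
    InfeasiblePlanError,
    PartitionError,
)
from hcrforge.sequences import NucleotideSequence
from hcrforge.trigger import NO_REACTION, TRIGGER


def seq(s, name="seq"):
    return NucleotideSequence(s, name=name)


def mutate(s, *positions):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G", "U": "G"}
    out = list(s)
    for p in positions:
        out[p] = swap[out[p].upper()]
    return "".join(out)


TARGET = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt


class TestPartition:
    def test_exact_partition_22mer(self):
        regions = partition_regions(seq(TARGET), 6)
        assert len(regions.region_a) == 6
        assert len(regions.region_b) == 10
        assert len(regions.region_c) == 6
        assert (
            regions.seq("a") + regions.seq("b") + regions.seq("c") == TARGET
        )

    def test_too_short(self):
        with pytest.raises(PartitionError):
            partition_regions(seq("ACGTACGTACGT"), 6)


class TestDiffProfile:
    def test_self_is_empty(self):
        assert len(diff_profile(seq(TARGET), seq(TARGET))) == 0

    def test_single_difference_region_a(self):
        prof = diff_profile(seq(TARGET), seq(mutate(TARGET, 2)))
        assert prof.positions == (2,)
        assert prof.regions == ("a",)

    def test_two_differences_span_regions(self):
        prof = diff_profile(seq(TARGET), seq(mutate(TARGET, 3, 18)))
        assert prof.positions == (3, 18)
        assert prof.regions == ("a", "c")
        assert prof.dist_3p == (18, 3)

    def test_indels_unsupported(self):
        with pytest.raises(IndelError):
            diff_profile(seq(TARGET), seq(TARGET[:-1]))


class TestSelectToeholdEnd:
    def _profiles(self, *position_groups):
        target = seq(TARGET)
        return [
            diff_profile(target, seq(mutate(TARGET, *ps), name=f"h{i}"))
            for i, ps in enumerate(position_groups)
        ], partition_regions(target)

    def test_rule_i_difference_in_a(self):
        profiles, regions = self._profiles((2,))
        assert select_toehold_end(profiles, regions)[0] == C_COMPLEMENTARY

    def test_rule_ii_difference_in_c(self):
        profiles, regions = self._profiles((18,))
        assert select_toehold_end(profiles, regions)[0] == A_COMPLEMENTARY

    def test_rule_iii_farther_end_wins(self):
        # differences at 8 and 11: min distance 8 from the 5' end,
        # 10 from the 3' end -> c-complementary
        profiles, regions = self._profiles((8,), (11,))
        choice, why = select_toehold_end(profiles, regions)
        assert choice == C_COMPLEMENTARY
        assert "farther" in why

    def test_rule_iii_near_3p_end(self):
        profiles, regions = self._profiles((14,))
        assert select_toehold_end(profiles, regions)[0] == A_COMPLEMENTARY

    def test_rule_iii_tie_prefers_c(self):
        # position 10 and 11 are equidistant as a set: min 10 vs min 10
        profiles, regions = self._profiles((10, 11))
        choice, why = select_toehold_end(profiles, regions)
        assert choice == C_COMPLEMENTARY
        assert "tie" in why

    def test_mixed_regions_clean_end_used(self):
        profiles, regions = self._profiles((2, 8))  # a and b dirty, c clean
        assert select_toehold_end(profiles, regions)[0] == C_COMPLEMENTARY
        profiles, regions = self._profiles((8, 18))  # b and c dirty, a clean
        assert select_toehold_end(profiles, regions)[0] == A_COMPLEMENTARY

    def test_both_ends_dirty_infeasible(self):
        profiles, regions = self._profiles((2, 18))
        with pytest.raises(InfeasiblePlanError) as err:
            select_toehold_end(profiles, regions)
        assert err.value.blocking_homolog == "h0"

    def test_identical_homolog_rejected(self):
        profiles, regions = self._profiles(())
        with pytest.raises(IndistinguishableHomologError):
            select_toehold_end(profiles, regions)


class TestProtectiveBases:
    def _pair_and_profiles(self, *positions):
        target = seq(TARGET, "target")
        homolog = seq(mutate(TARGET, *positions), "homolog")
        pair = build_basic_pair(target, loop_choice="auto")  # c-register
        return pair, [diff_profile(target, homolog)]

    @staticmethod
    def oracle_k(distances, window, existing=0):
        """Brute force over k: smallest k meeting both melt-window rules."""
        for k in range(0, window - existing + 1):
            if all(d + existing + k >= window + 1 for d in distances):
                return k
        return None

    def test_difference_one_bp_from_distal_end_needs_five(self):
        pair, profiles = self._pair_and_profiles(0)
        cfg = DesignConfig(melt_window_max=5)
        (h1, h2), k = add_protective_bases(pair, profiles, cfg)
        assert k == self.oracle_k([1], 5) == 5
        assert h1.stem_len == pair[0].stem_len + 5
        assert h1.provenance["protective_bp"] == 5

    def test_far_difference_needs_none(self):
        pair, profiles = self._pair_and_profiles(8)  # residual would be 9 bp
        (h1, h2), k = add_protective_bases(pair, profiles, DesignConfig())
        assert k == self.oracle_k([9], 5) == 0
        assert h1.full == pair[0].full

    def test_minimality_k_minus_one_violates_window(self):
        pair, profiles = self._pair_and_profiles(2)
        cfg = DesignConfig(melt_window_max=5)
        _, k = add_protective_bases(pair, profiles, cfg)
        assert k == self.oracle_k([3], 5) == 3
        assert 3 + (k - 1) < cfg.melt_window_max + 1  # k-1 leaves a meltable residual

    def test_oversized_leak_extension_makes_plan_infeasible(self):
        # a leak repair that already consumed more than the melt window
        # leaves no budget: the target's own residual could never melt
        pair, profiles = self._pair_and_profiles(0)
        pair = (
            dataclasses.replace(
                pair[0], provenance={**pair[0].provenance, "extension_bp": 6}
            ),
            pair[1],
        )
        with pytest.raises(InfeasiblePlanError) as err:
            add_protective_bases(pair, profiles, DesignConfig(melt_window_max=5))
        assert err.value.blocking_homolog == "homolog"


class TestPipeline:
    def test_region_a_family_plan(self):
        target = seq(TARGET, "target")
        homolog = seq(mutate(TARGET, 2), "homolog-a")
        plan, pair = design_discriminating_pair(target, [homolog])
        assert plan.status == "ok"
        assert plan.toehold_end == C_COMPLEMENTARY
        verdicts = dict((name, v) for name, v, _ in plan.verdicts)
        assert verdicts["target"] == TRIGGER
        assert verdicts["homolog-a"] == NO_REACTION

    def test_infeasible_panel_reports_stage(self):
        target = seq(TARGET, "target")
        homolog = seq(mutate(TARGET, 2, 18), "homolog-ac")
        plan, pair = design_discriminating_pair(target, [homolog])
        assert plan.status == "infeasible"
        assert plan.stage == "select_toehold_end"
        assert plan.blocking_homolog == "homolog-ac"
        assert pair is None

    def test_deterministic(self):
        target = seq(TARGET, "target")
        homologs = [seq(mutate(TARGET, 8), "h1"), seq(mutate(TARGET, 11), "h2")]
        a = design_discriminating_pair(target, homologs)
        b = design_discriminating_pair(target, homologs)
        assert a[0] == b[0]
        assert [d.full for d in a[1]] == [d.full for d in b[1]]
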