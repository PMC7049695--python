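"""Design of hairpin pairs that discriminate highly similar miRNA homologs.

A miRNA is partitioned into three regions: ~6 nt at the 5' end (a), ~6 nt
at the 3' end (c), and the middle (b). The exposed toehold is taken
complementary to whichever end region carries no differences to any
homolog, so every homolog still nucleates but its mismatch lies in the
displacement domain:

* differences in region a  -> c-complementary toehold;
* differences in region c  -> a-complementary toehold;
* differences only in b    -> the end farther from the nearest difference
  (ties broken toward the c-complementary toehold, logged);
* differences in both ends -> infeasible.

A homolog's branch migration stalls at its first mismatch. If the stalled
residual duplex is longer than the melt window it cannot melt and the
homolog does not trigger; if the difference sits too close to the
displacement-distal (loop-proximal) stem end, protective base pairs are
appended there to push the homolog's residual duplex past the window while
keeping the target's own residual (the protective pairs it cannot
displace) within it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import (
    ExtensionFailureError,
    IndelError,
    IndistinguishableHomologError,
    InfeasiblePlanError,
    PartitionError,
)
from .hairpins import (
    DesignConfig,
    Segment,
    build_basic_pair,
    extend_attacked_distal,
    extend_partner_open_end,
    extend_stem,
)
from .nn_thermo import NNParameterSet, nupack_calibrated
from .sequences import NucleotideSequence, rna_to_dna
from .trigger import (
    TRIGGER,
    Initiator,
    TriggerConfig,
    cross_reactivity_matrix,
)

A_COMPLEMENTARY = "a_complementary"
C_COMPLEMENTARY = "c_complementary"


@dataclass(frozen=True)
class MirnaRegions:
    """Exact partition of a target into regions a (5'), b (middle), c (3')."""

    target_dna: str
    region_a: Segment
    region_b: Segment
    region_c: Segment

    def label(self, position: int) -> str:
        if position < self.region_a.end:
            return "a"
        if position >= self.region_c.start:
            return "c"
        return "b"

    def seq(self, region: str) -> str:
        seg = getattr(self, f"region_{region}")
        return seg.extract(self.target_dna)


@dataclass(frozen=True)
class DifferenceProfile:
    """Mismatch positions of one homolog against the target.

    Positions are 0-based on the target, strictly increasing; each carries
    its region label and its distance to either sequence end.
    """

    homolog: str
    positions: tuple
    regions: tuple
    dist_5p: tuple
    dist_3p: tuple

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DiscriminationPlan:
    """Every decision taken while designing a discriminating pair."""

    target: str
    status: str  # "ok" | "infeasible"
    toehold_end: str | None = None
    stem_extension_pairs: int = 0
    protective_pairs: int = 0
    rationale: tuple = ()
    verdicts: tuple = ()  # ((name, verdict, remaining_duplex), ...)
    stage: str | None = None
    blocking_homolog: str | None = None


def partition_regions(target: NucleotideSequence, end_region_len: int = 6) -> MirnaRegions:
    """Split a target into regions a/b/c with ``end_region_len``-nt ends."""
    dna = (rna_to_dna(target) if target.is_rna else target).residues
    L = len(dna)
    if L <= 2 * end_region_len:
        raise PartitionError(
            f"target of {L} nt cannot hold two {end_region_len}-nt end regions"
        )
    return MirnaRegions(
        target_dna=dna,
        region_a=Segment(0, end_region_len),
        region_b=Segment(end_region_len, L - end_region_len),
        region_c=Segment(L - end_region_len, L),
    )


def diff_profile(
    target: NucleotideSequence,
    homolog: NucleotideSequence,
    end_region_len: int = 6,
) -> DifferenceProfile:
    """All mismatch positions between equal-length target and homolog."""
    t = (rna_to_dna(target) if target.is_rna else target).residues.upper()
    h = (rna_to_dna(homolog) if homolog.is_rna else homolog).residues.upper()
    if len(t) != len(h):
        raise IndelError(
            f"{homolog.name or 'homolog'} has {len(h)} nt vs target {len(t)} nt; "
            "indel comparisons are unsupported"
        )
    regions = partition_regions(target, end_region_len)
    positions = tuple(i for i, (x, y) in enumerate(zip(t, h)) if x != y)
    return DifferenceProfile(
        homolog=homolog.name,
        positions=positions,
        regions=tuple(regions.label(p) for p in positions),
        dist_5p=positions,
        dist_3p=tuple(len(t) - 1 - p for p in positions),
    )


def select_toehold_end(profiles, regions: MirnaRegions):
    """Choose which end's complement serves as the exposed toehold.

    Returns ``(choice, rationale)`` where choice is ``a_complementary`` or
    ``c_complementary``. The chosen toehold region must be difference-free
    for every homolog; otherwise the panel is infeasible.
    """
    if not profiles:
        raise InfeasiblePlanError("no homolog profiles given", stage="select_toehold_end")
    for prof in profiles:
        if len(prof) == 0:
            raise IndistinguishableHomologError(
                f"{prof.homolog or 'homolog'} is identical to the target"
            )
    seen = {r for prof in profiles for r in prof.regions}
    L = len(regions.target_dna)
    if seen == {"a"}:
        return C_COMPLEMENTARY, "differences confined to region a; use the c-complementary toehold"
    if seen == {"c"}:
        return A_COMPLEMENTARY, "differences confined to region c; use the a-complementary toehold"
    if seen == {"b"}:
        b_positions = [p for prof in profiles for p in prof.positions]
        d_a = min(b_positions)
        d_c = min(L - 1 - p for p in b_positions)
        if d_a > d_c:
            return A_COMPLEMENTARY, (
                f"differences in region b; 5' end is farther "
                f"(min distance {d_a} vs {d_c}); use the a-complementary toehold"
            )
        tie = " (tie broken toward c)" if d_a == d_c else ""
        return C_COMPLEMENTARY, (
            f"differences in region b; 3' end is farther "
            f"(min distance {d_c} vs {d_a}){tie}; use the c-complementary toehold"
        )
    if "a" not in seen:
        return A_COMPLEMENTARY, (
            "differences span several regions but region a is clean for all "
            "homologs; use the a-complementary toehold"
        )
    if "c" not in seen:
        return C_COMPLEMENTARY, (
            "differences span several regions but region c is clean for all "
            "homologs; use the c-complementary toehold"
        )
    blocking = next(
        prof.homolog for prof in profiles if {"a", "c"} & set(prof.regions)
    )
    raise InfeasiblePlanError(
        "differences fall in both end regions; no clean toehold end exists",
        stage="select_toehold_end",
        blocking_homolog=blocking,
    )


def _distal_distance(position: int, length: int, register: str) -> int:
    """Residual stem bp left when a homolog stalls at ``position``.

    With the c-complementary ('3p') register the displacement-distal stem
    end maps to the target's 5' end; with the a-complementary ('5p')
    register, to its 3' end. The stalled residual includes the mismatched
    pair itself.
    """
    return position + 1 if register == "3p" else length - position


def _protective_content(k: int, panel_dna) -> str:
    """Pick protective base identity for the arm5p side of the insert.

    G-C pairs are preferred (maximal stabilization); if either strand of
    the resulting insert would share a >=4-nt complementary word with a
    panel member, fall back to A-T pairs, then to fixed mixed-composition
    inserts, in a deterministic order.
    """

    def clashes(content: str) -> bool:
        if k < 4:
            return False
        from .sequences import reverse_complement

        for i in range(len(content) - 3):
            w = content[i : i + 4]
            if any(w in s or reverse_complement(w) in s for s in panel_dna):
                return True
        return False

    candidates = ["C" * k, "A" * k] + [
        (pat * k)[:k] for pat in ("CA", "AC", "CT", "TC", "GA", "AG")
    ]
    for content in candidates:
        if not clashes(content):
            return content
    raise InfeasiblePlanError(
        "no protective-pair composition passes the orthogonality screen",
        stage="add_protective_bases",
    )


def add_protective_bases(pair, profiles, cfg: DesignConfig | None = None, panel_dna=()):
    """Append the minimal protective pairs that defeat every homolog.

    Chooses the smallest k such that (a) every homolog's stalled residual
    duplex exceeds the melt window (nearest difference at least
    ``melt_window_max + 1`` bp from the displacement-distal end, counting
    pairs already added) and (b) the target's own residual — the k
    protective pairs plus any earlier stem extension — still melts.
    Returns ``(pair, pairs_added)``; 0 when the distances already suffice.
    """
    cfg = cfg or DesignConfig()
    h1, h2 = pair
    register = h1.provenance.get("register", "3p")
    existing = h1.provenance.get("extension_bp", 0)
    length = len(h1.provenance["target_dna"])
    window = cfg.melt_window_max

    residuals = {}
    for prof in profiles:
        in_stem = [
            _distal_distance(p, length, register) + existing
            for p in prof.positions
        ]
        if in_stem:
            residuals[prof.homolog] = min(in_stem)
    needed = 0
    for name, res in residuals.items():
        needed = max(needed, window + 1 - res)
    if needed < 0:
        needed = 0
    if existing + needed > window:
        blocking = min(residuals, key=residuals.get)
        raise InfeasiblePlanError(
            f"protective pairs required ({needed}) would push the target's own "
            f"residual duplex past the {window} bp melt window",
            stage="add_protective_bases",
            blocking_homolog=blocking,
        )
    if needed == 0:
        return pair, 0
    content = _protective_content(needed, panel_dna)
    new_h1 = extend_attacked_distal(h1, content)
    new_h2 = extend_partner_open_end(h2, content)
    prov = {"protective_bp": h1.provenance.get("protective_bp", 0) + needed}
    new_h1 = replace(new_h1, provenance={**new_h1.provenance, **prov})
    new_h2 = replace(new_h2, provenance={**new_h2.provenance, **prov})
    return (new_h1, new_h2), needed


def design_discriminating_pair(
    target: NucleotideSequence,
    homologs,
    cfg: DesignConfig | None = None,
    params: NNParameterSet | None = None,
    trigger_cfg: TriggerConfig | None = None,
    loop_choice: str = "auto",
):
    """Full pipeline: partition -> profiles -> toehold end -> pair ->
    leak repair -> protective bases -> trigger verification.

    Returns ``(plan, pair)``; on infeasibility the plan carries the failing
    stage and blocking homolog and ``pair`` is ``None``. The plan is only
    emitted as ``ok`` if the trigger rule engine confirms the target
    triggers and no homolog does.
    """
    cfg = cfg or DesignConfig()
    params = params or nupack_calibrated()
    trigger_cfg = trigger_cfg or TriggerConfig(melt_window_max=cfg.melt_window_max)
    rationale = []

    regions = partition_regions(target, cfg.end_region_len)
    profiles = [diff_profile(target, h, cfg.end_region_len) for h in homologs]

    def infeasible(stage, message, blocking=None):
        rationale.append(f"{stage}: {message}")
        return (
            DiscriminationPlan(
                target=target.name,
                status="infeasible",
                rationale=tuple(rationale),
                stage=stage,
                blocking_homolog=blocking,
            ),
            None,
        )

    try:
        end, why = select_toehold_end(profiles, regions)
    except InfeasiblePlanError as err:
        return infeasible(err.stage or "select_toehold_end", str(err), err.blocking_homolog)
    rationale.append(why)
    register = "3p" if end == C_COMPLEMENTARY else "5p"

    pair = build_basic_pair(target, cfg, loop_choice=loop_choice, toehold_end=register)
    try:
        ext = extend_stem(pair[0], cfg, params, partner=pair[1])
    except ExtensionFailureError as err:
        return infeasible("extend_stem", str(err))
    pair = (ext.design, ext.partner)
    if ext.pairs_added:
        rationale.append(
            f"stem extended by {ext.pairs_added} G-C pair(s) to meet the "
            f"{cfg.leak_threshold} kcal/mol leak benchmark"
        )
    else:
        rationale.append("basic pair already meets the leak benchmark; no extension")

    panel_dna = [regions.target_dna.upper()] + [
        (rna_to_dna(h) if h.is_rna else h).residues.upper() for h in homologs
    ]
    try:
        pair, protective = add_protective_bases(pair, profiles, cfg, panel_dna)
    except InfeasiblePlanError as err:
        return infeasible(err.stage or "add_protective_bases", str(err), err.blocking_homolog)
    rationale.append(
        f"{protective} protective pair(s) appended at the displacement-distal stem end"
        if protective
        else "homolog differences already clear the melt window; no protective pairs"
    )

    panel = [Initiator(regions.target_dna, name=target.name)] + [
        Initiator((rna_to_dna(h) if h.is_rna else h).residues, name=h.name)
        for h in homologs
    ]
    table = cross_reactivity_matrix(pair, panel, trigger_cfg)
    verdicts = tuple(
        (row["name"], row["verdict"], int(row["remaining_duplex"]))
        for _, row in table.iterrows()
    )
    target_ok = verdicts[0][1] == TRIGGER
    offenders = [name for name, verdict, _ in verdicts[1:] if verdict == TRIGGER]
    if not target_ok or offenders:
        blocking = offenders[0] if offenders else None
        msg = (
            f"homolog {blocking} still triggers"
            if offenders
            else "target no longer triggers its own pair"
        )
        return infeasible("verification", msg, blocking)
    rationale.append("verified: target triggers; every homolog stays silent")

    plan = DiscriminationPlan(
        target=target.name,
        status="ok",
        toehold_end=end,
        stem_extension_pairs=ext.pairs_added,
        protective_pairs=protective,
        rationale=tuple(rationale),
        verdicts=verdicts,
    )
    return plan, pair
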