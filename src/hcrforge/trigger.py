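"""Rule engine predicting whether an initiator triggers HCR.

The model follows toehold-mediated strand displacement in three steps:

1. Toehold nucleation — the initiator's terminal bases pair with the
   hairpin's exposed toehold, anchored at the stem-proximal toehold edge.
   Matches shorter than ``min_toehold_bind`` never nucleate.
2. Branch migration — the initiator exchanges stem base pairs one at a
   time from the open end toward the loop, stalling at its own end or at
   the first mismatch (no mismatch bypass; an RNA initiator is mapped U->T
   and wobble pairs count as mismatches).
3. Remaining-duplex melting — a stalled residual duplex of at most
   ``melt_window_max`` bp transiently melts, completing hairpin opening;
   anything longer holds and the reaction stops.

A full trigger verdict additionally requires the opened hairpin's released
output domain to open the partner hairpin; if it cannot, only an
initiator:H1 dimer forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, NotNucleatedError
from .hairpins import HairpinDesign
from .sequences import pairs, reverse_complement

TRIGGER = "trigger"
DIMER_ONLY = "dimer_only"
NO_REACTION = "no_reaction"


@dataclass(frozen=True)
class Initiator:
    """A single-stranded trigger candidate, 5'->3' (DNA or RNA)."""

    sequence: str
    name: str = ""
    truncation: int | None = None

    @property
    def dna(self) -> str:
        return self.sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class TriggerConfig:
    """Displacement rule thresholds.

    ``melt_window_max`` (default 5 bp): longest residual duplex treated as
    transiently melting. ``min_toehold_bind`` (default 2 nt): shortest
    toehold match that still nucleates.
    """

    melt_window_max: int = 5
    min_toehold_bind: int = 2

    def __post_init__(self):
        if self.melt_window_max < 1:
            raise ConfigError("melt_window_max must be >= 1")
        if self.min_toehold_bind < 1:
            raise ConfigError("min_toehold_bind must be >= 1")


@dataclass(frozen=True)
class TriggerVerdict:
    verdict: str
    toehold_bound: int
    stall_cause: str
    remaining_duplex: int
    explanation: str


def bind_toehold(hairpin: HairpinDesign, initiator: Initiator) -> int:
    """Nucleotides of contiguous Watson-Crick match on the exposed toehold.

    The matching toehold segment is anchored at its stem-proximal edge (the
    junction where branch migration continues), so an initiator whose
    toehold-binding region is truncated still registers its residual
    contact. Returns 0 when even the anchor base cannot pair.
    """
    seq = initiator.dna
    th = hairpin.toehold_seq.upper()
    best = 0
    for k in range(1, min(len(th), len(seq)) + 1):
        if hairpin.toehold_side == "5p":
            ok = seq[-k:] == reverse_complement(th[len(th) - k :])
        else:
            ok = seq[:k] == reverse_complement(th[:k])
        if ok:
            best = k
    return best


def branch_migration_stall(
    hairpin: HairpinDesign,
    initiator: Initiator,
    cfg: TriggerConfig | None = None,
):
    """Walk the displacement domain and report where migration stalls.

    Returns ``(stall_cause, remaining_duplex)``: ``("none", 0)`` for full
    displacement, else ``initiator_end`` or ``mismatch`` with the stem base
    pairs that could not be displaced.
    """
    cfg = cfg or TriggerConfig()
    bound = bind_toehold(hairpin, initiator)
    if bound < cfg.min_toehold_bind:
        raise NotNucleatedError(
            f"toehold match of {bound} nt is below min_toehold_bind={cfg.min_toehold_bind}"
        )
    seq = initiator.dna
    stem = hairpin.stem_len
    for i in range(stem):
        if hairpin.toehold_side == "5p":
            stem_base = hairpin.arm5p_seq[i]
            idx = len(seq) - bound - 1 - i
        else:
            stem_base = hairpin.arm3p_seq[stem - 1 - i]
            idx = bound + i
        if idx < 0 or idx >= len(seq):
            return "initiator_end", stem - i
        if not pairs(seq[idx], stem_base):
            return "mismatch", stem - i
    return "none", 0


def _released_output(hairpin: HairpinDesign) -> Initiator:
    """The single strand exposed when a hairpin is fully opened."""
    if hairpin.toehold_side == "5p":
        out = hairpin.full[hairpin.loop.start : hairpin.stem_arm_3p.end]
    else:
        out = hairpin.full[: hairpin.loop.end]
    return Initiator(out, name=f"{hairpin.name}_output")


def _opens(hairpin, initiator, cfg):
    bound = bind_toehold(hairpin, initiator)
    if bound < cfg.min_toehold_bind:
        return False, bound, "none", hairpin.stem_len
    cause, remaining = branch_migration_stall(hairpin, initiator, cfg)
    return remaining <= cfg.melt_window_max, bound, cause, remaining


def predict_trigger(
    pair,
    initiator: Initiator,
    cfg: TriggerConfig | None = None,
) -> TriggerVerdict:
    """Verdict for an initiator on an (H1, H2) hairpin pair.

    ``trigger``: H1 opens (toehold nucleates and the residual duplex is
    within the melt window) and its released output domain opens H2.
    ``dimer_only``: H1 opens but the output cannot open H2 — the chain
    stops at an initiator:H1 dimer. ``no_reaction`` otherwise.
    """
    cfg = cfg or TriggerConfig()
    h1, h2 = pair
    h1_opens, bound, cause, remaining = _opens(h1, initiator, cfg)
    if not h1_opens:
        why = (
            f"toehold match {bound} nt below nucleation minimum"
            if bound < cfg.min_toehold_bind
            else f"residual duplex of {remaining} bp exceeds the "
            f"{cfg.melt_window_max} bp melt window (stall: {cause})"
        )
        return TriggerVerdict(NO_REACTION, bound, cause, remaining, f"H1 stays closed: {why}")
    output = _released_output(h1)
    h2_opens, bound2, cause2, remaining2 = _opens(h2, output, cfg)
    if h2_opens:
        note = (
            "full displacement"
            if remaining == 0
            else f"{remaining} bp residual duplex melts transiently"
        )
        return TriggerVerdict(
            TRIGGER, bound, cause, remaining, f"H1 opens ({note}); output opens H2"
        )
    return TriggerVerdict(
        DIMER_ONLY,
        bound,
        cause,
        remaining,
        f"H1 opens but its output stalls on H2 "
        f"(toehold {bound2} nt, {remaining2} bp residual, {cause2})",
    )


def cross_reactivity_matrix(pair, panel, cfg: TriggerConfig | None = None) -> pd.DataFrame:
    """Trigger verdicts for every panel member, in input order."""
    cfg = cfg or TriggerConfig()
    rows = []
    for member in panel:
        init = member if isinstance(member, Initiator) else Initiator(
            getattr(member, "residues", str(member)), name=getattr(member, "name", "")
        )
        v = predict_trigger(pair, init, cfg)
        rows.append(
            {
                "name": init.name,
                "verdict": v.verdict,
                "toehold_bound": v.toehold_bound,
                "stall_cause": v.stall_cause,
                "remaining_duplex": v.remaining_duplex,
            }
        )
    return pd.DataFrame(rows, columns=["name", "verdict", "toehold_bound", "stall_cause", "remaining_duplex"])
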