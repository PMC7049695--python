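"""FASTA and design-bundle I/O.

A design bundle is a directory holding ``designs.fasta`` (one record per
hairpin, 80-column wrap), ``designs.json`` (segments, free-energy
breakdowns, verdicts, plans; sorted keys) and ``audit.tsv`` (one row per
hairpin). Writers are deterministic: identical inputs produce
byte-identical files, and re-reading a bundle reproduces the designs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, EmptySequenceError, FastaError
from .hairpins import HairpinDesign, LeakVerdict, Segment
from .sequences import NucleotideSequence

FASTA_WIDTH = 80


def read_fasta(path) -> list:
    """Read FASTA into validated :class:`NucleotideSequence` objects.

    Order-preserving; case preserved; RNA auto-detected by the presence of
    U. Empty files, duplicate IDs and invalid characters raise
    :class:`FastaError`.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise FastaError(f"no such file: {path}")
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(NucleotideSequence(str(rec.seq), name=rec.id))
        except (AlphabetError, EmptySequenceError) as err:
            raise FastaError(f"{path}: record {rec.id!r}: {err}")
    return out


def write_fasta(seqs, path, width: int = FASTA_WIDTH):
    """Write sequences (NucleotideSequence or HairpinDesign) as FASTA."""
    records = []
    for s in seqs:
        residues = s.full if isinstance(s, HairpinDesign) else s.residues
        records.append(SeqRecord(Seq(residues), id=s.name, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def _segment_dict(design: HairpinDesign) -> dict:
    return {
        role: [seg.start, seg.end]
        for role, seg in (
            ("toehold", design.toehold),
            ("stem_arm_5p", design.stem_arm_5p),
            ("loop", design.loop),
            ("stem_arm_3p", design.stem_arm_3p),
        )
    }


def _verdict_dict(verdict: LeakVerdict) -> dict:
    ev = verdict.evaluation
    return {
        "verdict": verdict.verdict,
        "transition_zone": verdict.transition_zone,
        "threshold": verdict.threshold,
        "interval": list(verdict.interval),
        "total_dg": round(ev.total_dg, 4),
        "stack_sum": round(ev.stack_sum, 4),
        "loop_penalty": round(ev.loop_penalty, 4),
        "initiation_terms": round(ev.initiation_terms, 4),
        "per_stack_breakdown": [[d, v] for d, v in ev.per_stack_breakdown],
    }


def write_design_bundle(designs, evaluations=None, plans=None, outdir=".", metadata=None):
    """Write FASTA + JSON sidecar + TSV audit for a set of designs.

    ``evaluations`` maps design name -> :class:`LeakVerdict`; ``plans`` is
    a list of :class:`DiscriminationPlan`. Returns the three paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    evaluations = evaluations or {}

    write_fasta(designs, outdir / "designs.fasta")

    sidecar = {"metadata": metadata or {}, "designs": {}, "plans": []}
    rows = []
    for d in designs:
        entry = {
            "role": d.role,
            "sequence": d.full,
            "segments": _segment_dict(d),
            "provenance": d.provenance,
        }
        verdict = evaluations.get(d.name)
        if verdict is not None:
            entry["leak"] = _verdict_dict(verdict)
        sidecar["designs"][d.name] = entry
        rows.append(
            {
                "name": d.name,
                "role": d.role,
                "length_nt": len(d.full),
                "stem_bp": d.stem_len,
                "toehold_side": d.toehold_side,
                "total_dg": round(verdict.evaluation.total_dg, 4) if verdict else "",
                "verdict": verdict.verdict if verdict else "",
                "transition_zone": verdict.transition_zone if verdict else "",
            }
        )
    for plan in plans or []:
        sidecar["plans"].append(dataclasses.asdict(plan))

    json_path = outdir / "designs.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    tsv_path = outdir / "audit.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "name",
            "role",
            "length_nt",
            "stem_bp",
            "toehold_side",
            "total_dg",
            "verdict",
            "transition_zone",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    return outdir / "designs.fasta", json_path, tsv_path


def read_design_bundle(outdir) -> list:
    """Reconstruct :class:`HairpinDesign` objects from a written bundle."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "designs.json").read_text())
    seqs = {s.name: s.residues for s in read_fasta(outdir / "designs.fasta")}
    designs = []
    for name, entry in sidecar["designs"].items():
        full = seqs[name]
        if full.upper() != entry["sequence"].upper():
            raise FastaError(f"bundle mismatch for {name}: FASTA and sidecar disagree")
        segs = {k: Segment(*v) for k, v in entry["segments"].items()}
        designs.append(
            HairpinDesign(
                full=entry["sequence"],
                role=entry["role"],
                name=name,
                toehold=segs["toehold"],
                stem_arm_5p=segs["stem_arm_5p"],
                loop=segs["loop"],
                stem_arm_3p=segs["stem_arm_3p"],
                provenance=entry.get("provenance", {}),
            )
        )
    designs.sort(key=lambda d: list(sidecar["designs"]).index(d.name))
    return designs
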