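"""Design hairpin pairs that tell let-7 family members apart.

For each case the pipeline partitions the target into regions a/b/c, puts
the exposed toehold on a difference-free end, repairs leakage, appends
protective base pairs where a homolog's mismatch sits too close to the
displacement-distal stem end, and verifies the plan with the trigger rule
engine.
"""

from hcrforge import LET7_PANEL, design_discriminating_pair

cases = [
    ("hsa-let-7d-5p", ["let-7d-prime"]),
    ("hsa-let-7b-5p", ["hsa-let-7c-5p"]),
    ("hsa-let-7a-5p", ["hsa-let-7e-5p", "hsa-let-7f-5p"]),
]

for target_name, homolog_names in cases:
    target = LET7_PANEL[target_name]
    homologs = [LET7_PANEL[n] for n in homolog_names]
    plan, pair = design_discriminating_pair(target, homologs)
    print(f"\n{target_name} vs {', '.join(homolog_names)}")
    print(f"  toehold end       : {plan.toehold_end}")
    print(f"  stem extension    : {plan.stem_extension_pairs} bp")
    print(f"  protective pairs  : {plan.protective_pairs} bp")
    for name, verdict, residual in plan.verdicts:
        print(f"  {name:<18} -> {verdict:<12} (residual duplex {residual} bp)")
print(
    "\nOnly the design target may read 'trigger': a homolog's mismatch stalls "
    "branch migration with a residual duplex too long to melt."
)
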