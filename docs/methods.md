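# Methods

## Scope and design target

`hcrforge` evaluates the free energy of the *designed* hairpin structure —
the stem, loop and toehold the construction recipe prescribes — not a
minimum-free-energy fold. This matches how such designs are audited in
practice (the intended structure is imposed and scored) and keeps every
quantity an exact additive sum. Sequences that could adopt competing folds
are only caught by the self-complementarity screen at design time, not by
a structure search; that is a deliberate limitation.

## Nearest-neighbor energy model

All energies are ΔG°₃₇ in kcal/mol at the reference condition 37 °C,
1 M Na⁺. Parameters are shipped in `src/hcrforge/data/nn_dg37.tsv`
(context, value, source), comprising:

* the unified DNA Watson–Crick stack set (SantaLucia 1998) — 10 unique
  entries, expanded to all 16 dinucleotides by reverse-complement
  symmetry; duplex initiation +1.96 and a +0.05 penalty per helix end
  closed by A·T;
* DNA hairpin-loop penalties (SantaLucia & Hicks 2004) at tabulated
  anchor sizes; intermediate sizes 3–30 are filled by Jacobson–Stockmayer
  logarithmic interpolation from the nearest lower anchor, and sizes
  beyond 30 extrapolate with coefficient 1.75·R·T (≈1.079 kcal/mol at
  310.15 K). Loops below 3 nt are rejected as sterically impossible;
* DNA dangling-end terms (Bommarito et al. 2000) and DNA hairpin
  terminal-mismatch terms (Peyret/SantaLucia), as distributed in the
  public Mathews-2004 DNA parameter set at 0.1 kcal/mol precision.

Two hairpin evaluation modes exist:

* **default** — the strict decomposition: one bimolecular initiation
  event, at most one terminal A·T penalty at the open helix end, stem
  stacks, loop penalty. Its additivity makes several invariants exact
  (appending a pair changes the total by exactly the new stack), which
  the property tests exploit.
* **calibrated** (`nupack_calibrated()`) — the hairpin is treated as the
  unimolecular fold it is: no strand-association term; a dangle where the
  toehold overhang continues past the open helix end; and the
  terminal-mismatch term of the first/last loop bases on the loop-closing
  pair. This is the configuration under which the −16.0 kcal/mol leak
  benchmark is interpreted, because that benchmark was defined against
  imposed-structure evaluations by NUPACK-family tools. Cross-validation
  against ViennaRNA 2.7 with DNA Mathews-2004 parameters (imposed
  structure, 37 °C, dangle model 2) agrees to ≤ 0.8 kcal/mol over a
  30-hairpin panel of designed and random hairpins (tested at a 1.0
  kcal/mol tolerance); residual differences come from 0.1-kcal parameter
  rounding in the reference file and its slightly different loop-size
  table. Temperature is fixed at 37 °C; no salt correction beyond the
  1 M Na⁺ reference is attempted, and melting temperatures are out of
  scope.

The library default for low-level calls is the strict mode; the
discrimination pipeline and the CLI default to the calibrated mode, since
that is the configuration validated against the external reference.

## Hairpin construction

For a target of length L (RNA is back-transcribed U→T first) with toehold
length T (default 6) the basic recipe uses the target's 3′ end as the
exposed-toehold complement: H1 = revcomp(3′ T-mer) + revcomp(remainder) +
loop + remainder; H2 = remainder + 3′ T-mer + revcomp(remainder) +
revcomp(loop). H2's loop sequesters the target's toehold region, so opened
H1 opens H2 and the released strand regenerates an initiator equivalent.
A mirrored register (toehold complementary to the 5′ end) exists for
homolog discrimination. The loop (default 6 nt) is user-supplied
(`CAAAGT` reproduces the worked example) or auto-generated under a screen
rejecting ≥4-nt complementarity with the target or either stem arm;
display case is cosmetic (single-stranded functional domains upper-case),
never semantic.

**Leak repair.** A pair above the benchmark gains G·C pairs one at a time
— C appended to the arm5p side — at the **loop-proximal** stem end, with
the mirrored addition placed at the partner's open end (the geometry of
branch migration forces this: the output strand released by the extended
H1 carries the complement of the added bases immediately after its loop
domain, which must pair at H2's toehold-adjacent duplex end). An
extension at H1's open end would instead stall the target's own
displacement at the first step and render the pair untriggerable. The
extended pair leaves the target a residual duplex equal to the added
pairs, which must stay within the melt window; the trigger verification
step enforces this. Extensions are capped at `max_stem_extension`
(default 6 bp).

## Leak classification

`leak_resistant` iff ΔG°₃₇ ≤ `leak_threshold` (default −16.0 kcal/mol,
boundary inclusive — the conservative reading of a benchmark). Energies
inside `threshold_interval` (default (−16.0, −15.5)) are flagged
"transition zone" in reports, reflecting that single-nucleotide changes
move ΔG by up to ~1.9 kcal/mol so the leak/no-leak boundary is an
interval, not a line. The stem-length scan truncates the loop-proximal
stem end for shorter variants and G·C-extends for longer ones; under the
default mode the total is strictly monotone in stem length, so the
verdict flips at most once.

## Trigger rule engine

Three-stage, deliberately kinetics-free:

1. **Toehold nucleation.** The maximal contiguous Watson–Crick match
   between the initiator's terminal bases and the exposed toehold,
   anchored at the stem-proximal toehold edge. Matches below
   `min_toehold_bind` (default 2 nt — the shortest residual toehold
   observed to still react) never nucleate.
2. **Branch migration.** A base-by-base walk from the open stem end
   toward the loop, stalling at the initiator's end or the first
   mismatch; no mismatch bypass, wobble pairs count as mismatches, RNA
   initiators are mapped U→T.
3. **Remaining-duplex melting.** A stalled residual duplex of at most
   `melt_window_max` bp (default 5, inclusive) melts transiently and the
   hairpin opens; anything longer holds. The default of 5 is the largest
   value consistent with both a 5–7 bp transient-melting window and the
   observation that products vanish from a ~6-nt truncation; it is
   configurable 1–7.

A verdict of `trigger` additionally requires the opened hairpin's
released output domain to open the partner (otherwise `dimer_only`). The
leak classifier (thermodynamic, ΔG-based) and the trigger engine
(length-window-based) are deliberately independent rule systems; the
tension between a 5-bp melt window and >10-bp stems leaking is a
kinetics question this toolkit does not attempt to resolve.

## Homolog discrimination

Targets are partitioned into regions a (5′ `end_region_len` nt, default
6), c (3′ likewise) and b (rest). Only equal-length homolog comparisons
are supported (the let-7 panel is same-length; indels would need
alignment semantics that the rule set does not define). Toehold-end
selection requires the chosen end region to be difference-free for every
homolog; for differences confined to b, the end whose minimum distance to
any difference is larger wins, ties broken toward the c-complementary
toehold (logged in the plan rationale). With the c-complementary register
the displacement-distal stem end corresponds to the target's 5′ end, so a
difference at target position p stalls a homolog with a residual of
p + 1 (+ any added pairs); the a-complementary register mirrors this.

Protective pairs: the minimal k such that every homolog's residual is at
least `melt_window_max + 1` bp and the target's own residual (k plus any
leak-repair extension) is at most `melt_window_max`. For a single
difference this is always satisfiable unless the leak repair alone
exceeded the melt window. Base identity prefers G·C; if either strand of
the insert would share a ≥4-nt complementary word with a panel member the
chooser falls back to A·T, then to fixed mixed-composition patterns, in a
deterministic order. Every emitted plan is re-verified with the trigger
engine (target `trigger`, homologs anything but), and the recorded
verdict table is exactly what `cross_reactivity_matrix` reproduces —
plans that fail verification are returned as `infeasible` with the
blocking stage and homolog named. The whole pipeline is deterministic:
identical inputs yield byte-identical plans.

## Synthetic data generator

`generate_family` emulates miRNA-like panels: targets drawn uniformly
over A/C/G/U at a requested length (miRNA-typical 19–25 nt; 22 in the
shipped tests) and resampled until the GC fraction lies in [0.3, 0.7];
homologs differ at exactly the requested number of positions, drawn
uniformly within region a, b, c or anywhere, substituted to a different
base. Reproducible under a seed. It emulates the *combinatorics* of
homolog families (difference count and placement), not their biology:
real miRNA families share seed-region conservation patterns, wobble-heavy
3′ ends and expression context that the generator ignores — passing tests
show the design rules behave correctly over difference geometries, not
that any particular wet-lab panel will behave likewise. The let-7 panel
is shipped as a named fixture (canonical registry sequences); `let-7d-
prime` is a constructed synthetic analog with a single region-a
difference, standing in for the analog probe such experiments use.

## Numerical and interface choices

* Exact float additivity: totals are computed as the sum of their
  reported components, so breakdown re-summation is exact to double
  precision; JSON reports round to 4 decimals.
* Coordinates are 0-based half-open everywhere; FASTA output is 80-column
  wrapped with segments in a JSON sidecar; TSV audits carry a header row;
  JSON keys are sorted — writers are byte-deterministic.
* Auto-generated loops iterate a fixed candidate order (no RNG), so
  design output is deterministic without a seed.
* Degenerate inputs fail loudly: duplexes < 2 bp, loops < 3 nt,
  non-reverse-complementary stem arms, mixed alphabets, empty FASTA,
  duplicate record IDs.

## Known limitations

* Imposed-structure evaluation only; no partition function, suboptimal
  folds, or RNA parameters.
* The melt-window rule is binary; real melting of a 5–6 bp residual is a
  stochastic, sequence-dependent event. Composition of the residual
  duplex is ignored.
* Cross-reactivity is assessed pairwise against the panel; orthogonality
  across unrelated designs and >2-hairpin systems are out of scope.
* Salt, temperature, concentration and incubation-time dependence are not
  modeled; the reference condition is fixed.
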