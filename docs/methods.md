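# Methods

## The model system

`digevo` is a digital-evolution platform in the Avida tradition: a
population of self-replicating linear programs ("digital organisms")
lives on a toroidal grid, competes for CPU cycles, and evolves under
divide-time mutation.  The package exists to compare *instruction set
architectures* — the genetic language plus the virtual hardware it runs
on — by the evolutionary potential they confer across a battery of
computational environments.

### Virtual hardware

Each organism owns a virtual CPU with:

* `n_registers` 32-bit registers (AX, BX, CX, …); arithmetic wraps
  modulo 2^32, comparisons are signed two's-complement;
* two stacks of ten slots each, one active at a time (`swap-stk`
  toggles); a push onto a full stack overwrites the oldest entry, a pop
  from an empty stack yields 0;
* four named heads into circular genome memory — instruction pointer
  (IP), READ, WRITE, FLOW — plus one unassigned head per extra nop in
  architectures with more than four nops;
* an input channel (three fixed random 32-bit words per organism,
  cycled) and an output channel evaluated by the environment.

Replication is explicit: `h-alloc` doubles memory, `h-copy` copies one
instruction from READ to WRITE and advances both, `h-divide` splits the
region between READ and WRITE off as the offspring.  A divide fails
silently (the organism keeps executing) if nothing was copied, the READ
head sits at position 0, or fewer than half the offspring sites were
actually written by `h-copy` — the 0.5 threshold blocks trivial-divide
exploits and is configurable.  A successful divide restores the parent
CPU to its initial state (registers, stacks, heads, IP = 0), so every
gestation follows an identical execution path; without this reset the
write head is never re-armed and replication would stop after one
offspring.

Every instruction is total.  Random genomes execute indefinitely
without raising; degenerate operands wrap modulo memory length.

### Nop modification and labels

No-operation instructions (`nop-A` … up to `nop-P`) do nothing when
executed but modify the preceding instruction's operands: `inc`
defaults to BX, `inc nop-A` increments AX.  Modifier nops are read
ahead but *not consumed* — the IP still steps through them — keeping
gestation time proportional to genome length.  In the single-nop
architectures one trailing nop rebases the first operand slot and
shifts same-kind slots with it; under **fully associative (FA)**
binding, multi-register instructions read one nop per slot, the first
shifting all slots and the rest overriding slots explicitly (`add
nop-A nop-C nop-B` computes AX = CX + BX).

Runs of nops also act as position labels.  Matching is either *cyclic
complementary* (nop-A ↔ nop-B ↔ … ↔ nop-A; a search following
`nop-A nop-A nop-B` looks for `nop-B nop-B nop-C`) or *direct*; in
label-prefixed architectures a run only counts when it immediately
follows the dedicated `label` instruction.  A search instruction's own
trailing run is never an admissible match site; when no match exists
the FLOW head lands just past the instruction and its nops, while a
failed `goto` is simply ignored.  An empty pattern (no trailing nops)
is treated as "not found" — behaviour is defined only for present
labels.

### The architecture family

27 named architectures chain from the 26-instruction, 3-register
default (`HEADS`): `FA` (fully associative binding), `R4`–`R16`
(register/nop expansion), the `LABEL` series (R6-based explicit-label
variants that drop `set-flow`), `SPLIT-IO` (separate `input`/`output`
instructions), the `SEARCH` series (directional searches, `goto`,
conditional gotos), the `FLOW` series (zero-comparison conditionals,
nop-built-constant `if-x` comparisons, conditional `mov-head`), and
`HEADS-EX`, the composite of the best feature from each group (FA, six
registers, direct labels, split I/O, directional search, if-x,
conditional mov-head; content-identical to `FLOW-IFX-MVH`).

The `if-x` constant starts at 1 (the default is configurable): each
`nop-B`/`nop-C`/`nop-D` in the trailing label left-shifts it by 1/2/3
and each `nop-A` toggles its sign.  `jmp-head` defaults to the IP (a
flow-head default is a known dead end) and does not suppress the fetch
advance, so `jmp-head` with CX = 0 is a no-op.  A false `if-*`
condition skips the next non-nop instruction *together with its
modifier nops* — skipping a lone nop would merely re-address the
guarded instruction instead of suppressing it.

## Environments

Seven environments reward computations with merit multipliers (all
base 2; "bonus" below means log2 of the multiplier).  Tasks are
rewarded once per lifetime; the bookkeeping clears at divide.

| Environment | Tasks (T) | Reward |
|---|---|---|
| logic-9 | 9 | five levels, ×2 … ×32, multiplicative |
| logic-77 | 77 | ×2 each, once |
| match-12 | 12 | quality × 1 bonus, additive |
| fibonacci-32 | 32 | +1 each; −0.5 per output past the 32nd |
| sort-10 | 1 | quality × 5 bonus |
| limited-9 | 9 | logic-9 scaled by resource draw |
| navigation | 1 | path-progress quality × 5 bonus |

Logic tasks are all boolean functions of 1–3 inputs that depend on all
their inputs, deduplicated under input permutation (this removes
constants and the identity "echo"): 9 at arity ≤ 2, 77 at arity ≤ 3.
An output matches a task when it equals the function applied bitwise
to an ordered tuple of *distinct* input slots (no input reuse) already
drawn by the organism.  The logic-9 difficulty grouping fixes the
printed endpoints (×2 easiest, ×32 hardest) and uses the canonical
default for the interior: NOT, NAND → 1; AND, ORNOT → 2; OR,
ANDNOT → 3; NOR, XOR → 4; EQU → 5 (Σ = 25 log2 units).

Match-12 constants are a package default: twelve distinct values
generated once from a fixed internal seed, approximately exponentially
spaced over [2^6, 2^31]; quality is 2^(−w/half-life) in wrong bits w
with at least 22 of 32 bits correct, half-life 1 bit.  Fibonacci starts
1, 1; the per-extra-output penalty is derived as 32·reward/64 so that
64 extras exactly cancel 32 rewards.  Sort-10 evaluates when the tenth
output arrives; the displacement metric is the summed absolute
positional offset from the descending order (half-life 1 move).  These
constants are explicit configuration, not literature values.

Limited-9 attaches one consumable resource per task: inflow 100
units/update, outflow 1 % of the level per update (equilibrium 10,000
units), at most 0.25 % of the current level consumed per performance;
the bonus scales linearly with the draw relative to the 25-unit
equilibrium draw, so performance at equilibrium earns the full logic-9
bonus and depletion earns proportionally less.  Consumption is deducted
at the following per-update resource step.

Navigation appends four experiment-specific instructions (`sg-sense`,
`sg-move`, `sg-rotate-l/r`) to whatever architecture is being run and
places each organism in its own copy of a hand-authored reference maze:
a 13-cell path whose cells carry cues (forward / turn-left /
turn-right / repeat-previous, 45° turns); quality is the fraction of
path cells reached in order, settled at divide.  The maze-generation
scheme behind richer mazes is deliberately out of scope; the world is a
pluggable interface.

## Population dynamics

Default grid 60 × 60 (3,600 cells), torus, 8-neighbourhood.  One
*update* = 30 CPU cycles per living organism, assigned as independent
merit-proportional draws (a multinomial over the population, sampled
once per update from the merits at its start; a round-robin scheduler
is available for debugging).  Merit after a divide is genome length ×
2^(accumulated bonus), and the offspring inherits the parent's
post-divide merit, so task rewards translate into execution speed and
persist for selection to act on.  An organism's fitness is merit ÷
gestation cycles, defined after its first divide; populations are
seeded with a single 50-instruction ancestor capable only of
self-replication (identical canonical form across architectures, only
the neutral labelling nops differ).

Mutations act at divide: substitutions per offspring site (default
0.0075) and a single insertion and/or deletion with per-divide
probability 0.05 each.  Offspring mutated to length zero are
non-viable.  Offspring replace a uniformly random torus neighbour of
the parent.

Randomness uses four independent child streams of one root seed
(scheduler, mutation, environment, placement), so identical
(configuration, seed) pairs replay bit-identically.

## Assessment

*Mean fitness* is the arithmetic mean of per-organism fitness over the
living population at run end, reported in log2.  *Task success* S_p
sums each living organism's task qualities (q ∈ [0, 1]) and divides by
the population size; its maximum equals the task count T, and
normalized task success divides by T.  Per-organism qualities are the
snapshot of the last completed gestation (current partial lifetime for
organisms that have not yet divided).  Replicate groups are compared
with the two-sided Wilcoxon rank-sum test under Holm's step-down
("sequential Bonferroni") correction at α = 0.05, with non-parametric
bootstrap 2.5 %/97.5 % quantile intervals (10,000 iterations) on
medians.  The multi-nop usage statistic is, over the instructions of a
genome that can read more than one modifier nop, the fraction actually
followed by two or more nops; it is reported for the most abundant
genome sequence (dominant genotype, ties to earliest appearance).

## Problem sizes and what the tests show

Full-scale experiments in this tradition use 200 replicates of 3,600
organisms for 100,000 updates per architecture × environment — cluster
scale.  The package's own test suite and the acceptance script instead
run scaled-down study conditions chosen to keep a desk run in minutes
while preserving the qualitative regime (population fills the grid,
hundreds of generations, task discovery possible but not saturated):

* acceptance script: 10 replicates per architecture, 20 × 20 grid,
  2,200 updates, HEADS vs FA in logic-9;
* test suite: 6 replicates per architecture, 12 × 12 grid, 800 updates.

At these sizes only the easy logic tasks are commonly discovered, and
in many replicates none fix; the HEADS-vs-FA comparison is therefore a
*directional* check (FA median normalized task success at least
HEADS's) rather than a quantitative reproduction of full-scale medians.
Deterministic replay, the metric layer, reward calibrations and
replication fidelity are exact at any scale.

The synthetic dynamics also idealise real experiments in other ways:
all instructions cost one cycle, there is no spatial resource
diffusion, no parasites or demes, and per-organism inputs are three
random words fixed at birth.  Passing tests therefore certify the
mechanics and statistics of the platform, not any particular biological
claim.

## Numerical and design notes

* "Lifetime" for once-only rewards is one gestation (cleared at
  divide); organisms re-earn their bonuses each gestation, which is
  what lets merit track current phenotype.
* Empty populations make mean fitness and task success undefined;
  callers get an error rather than a silent zero.
* Stack overflow drops the oldest entry; division by zero cannot arise
  (no division instruction); shifts are logical.
* The multinomial scheduler allocates an update's whole budget at its
  start; organisms born during an update first execute in the next one.
* Bootstrap CIs are equivariant under positive affine maps and
  degenerate correctly on constant samples.
* All 27 architecture ancestors are built, not stored; `validate_ancestor`
  confirms exact self-copy, constant gestation over three generations
  and zero task performance for every one of them.
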