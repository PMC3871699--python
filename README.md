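# digevo

Digital evolution of self-replicating programs on configurable
virtual-CPU instruction set architectures.

## What this is for

In digital evolution, populations of self-replicating computer
programs — digital organisms — evolve under mutation and natural
selection inside a simulated world.  The *instruction set architecture*
(ISA) defines both the genetic alphabet and the virtual hardware it
executes on, and its design shapes how readily complex traits evolve.
`digevo` implements a family of 27 Avida-style ISAs (the classic
26-instruction `HEADS` machine through the combined `HEADS-EX`
architecture), seven computational reward environments, a
merit-scheduled toroidal grid population with divide-time mutation, and
the statistics used to compare architectures by evolutionary potential.
It is aimed at researchers in artificial life and evolutionary
computation who want a compact, fully deterministic, pure-Python
platform for architecture-comparison experiments.

## The model in brief

Each organism is a circular genome of instructions running on a small
CPU (32-bit registers, two 10-slot stacks, movable IP/READ/WRITE/FLOW
heads).  It replicates by allocating memory, copying itself
instruction-by-instruction and dividing; offspring are mutated and
placed on a random torus neighbour.  Time advances in *updates* — 30
CPU cycles per living organism, allocated in proportion to **merit**.
Performing environment tasks (for instance bitwise logic functions of
the organism's inputs) multiplies merit, so computation buys execution
speed and hence reproductive success:

* merit after divide: `M = L · 2^Σb`, genome length `L`, earned task
  bonuses `b` (log2 units);
* fitness: `f = M / g`, gestation time `g` in CPU cycles;
* task success of population *p*: `S_p = (1/N_p) Σ_i Σ_t q_{i,t}`,
  with `q_{i,t} ∈ [0,1]` the quality of organism *i* at task *t*;
  normalized task success divides by the task count `T`.

Replicate populations of two ISAs are compared by median log2 mean
fitness and median normalized task success, with Wilcoxon rank-sum
tests, Holm (sequential Bonferroni) correction and 10,000-iteration
bootstrap confidence intervals.

See `docs/methods.md` for the full model description, parameter
defaults and design notes.

## Worked example

Every architecture ships a canonical 50-instruction ancestor that can
only self-replicate.  Validate the default one:

```sh
$ digevo validate-ancestor heads
{
 "viable": true,
 "gestation_cycles": 194,
 "offspring_identical": true,
 "copied_fraction": 1.0,
 "n_tasks_performed": 0,
 "generations_checked": 3,
 "gestation_constant": true
}
```

The ancestor copies itself perfectly in 194 CPU cycles, every
generation, and performs no tasks — all fitness gains in a run are
evolved.  Now evolve a small population of the fully associative (FA)
architecture in the two-input logic environment:

```sh
$ digevo run --architecture FA --environment logic-9 \
    --width 12 --height 12 --updates 800 --seed 5 --out-dir demo_run
{
 "alive": 144,
 "mean_fitness_log2": -1.3276644182207593,
 "task_success": 0.5625,
 "normalized_task_success": 0.0625,
 "multinop_usage": 0.3333333333333333,
 "dominant_genotype_length": 53
}
```

After 800 updates the 144-cell grid is full; task success 0.5625 means
the average organism performs about half a unit of task quality — here,
a minority of the population has discovered one of the easy logic
tasks (maximum in this environment is 9).  Mean fitness (log2 −1.33,
i.e. ≈ 0.40) has risen above the ancestor's 50/194 ≈ 0.26 through
faster replication and task bonuses.  One third of the multi-argument
instructions in the dominant genotype carry more than one nop modifier
— evolution is using the FA architecture's multi-nop argument
specification.  The run directory contains per-update statistics
(`stats.csv`), a birth/event log (`events.jsonl`), a genome snapshot of
every cell, and a `manifest.json` that echoes the full configuration;
re-running with the same seed reproduces every file exactly.

The same machinery is available as a library:

```python
from digevo import Simulation, task_success

sim = Simulation("HEADS-EX", "fibonacci-32", width=20, height=20, seed=1)
sim.inject_ancestor()
sim.run(1000)
print(task_success(sim.sample()))
```

## Command-line interface

`digevo run | analyze | validate-ancestor | list-architectures |
list-environments | export-tasks` — see `digevo <cmd> --help`.
`analyze` consumes directories of replicate runs and emits a TSV of
medians, bootstrap CIs and Holm-adjusted significance per architecture.
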