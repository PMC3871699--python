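"""Grid population dynamics.

A toroidal lattice of self-replicating organisms.  Time advances in
*updates*: each update distributes a CPU-cycle budget of 30 cycles per
living organism across the population, with each cycle assigned
independently with probability proportional to merit, so metabolic
rewards translate into execution speed.  Offspring produced by a
successful divide are mutated (divide-time substitutions, single
insertion/deletion) and replace a uniformly random organism among the
parent's eight torus neighbours.

Fitness of an organism is merit / gestation time (CPU cycles used for
its last completed replication); it is undefined before the first
divide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ancestors as _ancestors
from . import isa
from .environments import Environment, get_environment
from .isa import ArchitectureSpec, architecture_from_dict, \
    architecture_to_dict, build_architecture
from .vcpu import VirtualCPU

__all__ = [
    "MutationRates", "Organism", "Simulation", "mutate_genome", "fitness",
    "augment_architecture",
]


@dataclass(frozen=True)
class MutationRates:
    """Divide-time mutation rates.

    Substitutions are applied per offspring genome site; insertion and
    deletion are each a single-instruction event per divide.
    """

    substitution_per_site: float = 0.0075
    insertion_per_divide: float = 0.05
    deletion_per_divide: float = 0.05

    def __post_init__(self):
        for v in (self.substitution_per_site, self.insertion_per_divide,
                  self.deletion_per_divide):
            if not 0.0 <= v <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")


def mutate_genome(genome, rates: MutationRates, rng, n_opcodes: int):
    """Mutated copy of an offspring genome, or ``None`` if non-viable
    (mutated to length zero)."""
    g = list(genome)
    n = len(g)
    if n == 0:
        return None
    k = rng.binomial(n, rates.substitution_per_site)
    if k:
        sites = rng.choice(n, size=min(k, n), replace=False)
        for s in sites:
            g[s] = int(rng.integers(n_opcodes))
    if rng.random() < rates.insertion_per_divide:
        g.insert(int(rng.integers(len(g) + 1)), int(rng.integers(n_opcodes)))
    if rng.random() < rates.deletion_per_divide:
        del g[int(rng.integers(len(g)))]
    return g if g else None


class Organism:
    __slots__ = ("genome", "cpu", "env_state", "merit", "bonus_log2",
                 "gestation_cycles", "last_qualities", "age_updates",
                 "births", "oid")

    def __init__(self, genome, cpu, env_state, merit, oid):
        self.genome = genome
        self.cpu = cpu
        self.env_state = env_state
        self.merit = merit
        self.bonus_log2 = 0.0
        self.gestation_cycles = None
        self.last_qualities = None
        self.age_updates = 0
        self.births = 0
        self.oid = oid


def fitness(org: Organism):
    """merit / gestation cycles; ``None`` before the first divide."""
    if org.gestation_cycles is None or org.gestation_cycles <= 0:
        return None
    return org.merit / org.gestation_cycles


def augment_architecture(arch: ArchitectureSpec,
                         env: Environment) -> ArchitectureSpec:
    """Append environment-specific instructions (navigation sensors)."""
    extra = [m for m in env.extra_instructions if not arch.has(m)]
    if not extra:
        return arch
    d = architecture_to_dict(arch)
    d["instructions"] = d["instructions"] + extra
    return architecture_from_dict(d)


# torus 8-neighbourhood offsets
_NEIGH = [(-1, -1), (0, -1), (1, -1), (-1, 0),
          (1, 0), (-1, 1), (0, 1), (1, 1)]


class Simulation:
    """One evolving population: architecture x environment x grid.

    Randomness uses four independent child streams of the root seed
    (scheduler, mutation, environment inputs, offspring placement), so
    identical (config, seed) pairs reproduce runs exactly.
    """

    def __init__(self, architecture="HEADS", environment="logic-9",
                 width=60, height=60, seed=0,
                 rates: MutationRates = MutationRates(),
                 cycles_per_update: int = 30, scheduler: str = "merit",
                 ancestor=None):
        if isinstance(architecture, str):
            architecture = build_architecture(architecture)
        if isinstance(environment, str):
            environment = get_environment(environment)
        self.env = environment
        self.arch = augment_architecture(architecture, environment)
        self.width = width
        self.height = height
        self.rates = rates
        self.cycles_per_update = cycles_per_update
        if scheduler not in ("merit", "round_robin"):
            raise ValueError("scheduler must be 'merit' or 'round_robin'")
        self.scheduler = scheduler
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(4)
        self.rng_sched = np.random.default_rng(kids[0])
        self.rng_mut = np.random.default_rng(kids[1])
        self.rng_env = np.random.default_rng(kids[2])
        self.rng_place = np.random.default_rng(kids[3])
        self.cells = [None] * (width * height)
        self.update_no = 0
        self.stats = []
        self.events = []
        self._next_oid = 0
        self._update_task_firsts = {}
        if ancestor is None:
            ancestor = _ancestors.build_ancestor(self.arch)
        self.ancestor = list(ancestor)

    # -- population access -------------------------------------------------

    def living(self):
        return [o for o in self.cells if o is not None]

    @property
    def n_alive(self) -> int:
        return sum(1 for o in self.cells if o is not None)

    def _new_organism(self, genome, merit):
        st = self.env.new_state(self.rng_env)
        cpu = VirtualCPU(self.arch, genome, inputs=st.cpu_inputs,
                         world=st.world)
        org = Organism(genome, cpu, st, merit, self._next_oid)
        self._next_oid += 1
        return org

    def inject_ancestor(self, genome=None):
        """Seed an empty grid with a single ancestral organism."""
        if any(o is not None for o in self.cells):
            raise RuntimeError("grid already populated")
        g = list(genome) if genome is not None else list(self.ancestor)
        org = self._new_organism(g, merit=float(len(g)))
        self.cells[(self.height // 2) * self.width + self.width // 2] = org
        return org

    # -- one update --------------------------------------------------------

    def update(self):
        occ = [(i, o) for i, o in enumerate(self.cells) if o is not None]
        if not occ:
            warnings.warn("update on empty grid is a no-op")
            return None
        n = len(occ)
        budget = self.cycles_per_update * n
        if self.scheduler == "merit":
            merits = np.array([o.merit for _, o in occ], dtype=float)
            counts = self.rng_sched.multinomial(budget, merits / merits.sum())
        else:
            counts = np.full(n, self.cycles_per_update, dtype=int)
        births = 0
        self._update_task_firsts = {}
        for (idx, org), c in zip(occ, counts):
            if self.cells[idx] is not org:
                continue  # replaced by a birth earlier this update
            if c == 0:
                continue
            births += self._run_organism(idx, org, int(c))
        self.env.on_update()
        for _, o in occ:
            if o is not None:
                o.age_updates += 1
        self.update_no += 1
        row = self._stats_row(births)
        self.stats.append(row)
        return row

    def run(self, n_updates: int):
        for _ in range(n_updates):
            self.update()
        return self.stats

    def _run_organism(self, idx, org, cycles) -> int:
        births = 0
        env = self.env
        st = org.env_state
        for ev in org.cpu.run_cycles(cycles):
            kind = ev.kind
            if kind == "output":
                before = len(st.qualities)
                delta = env.on_output(st, ev.payload, org.cpu.n_draws)
                if delta:
                    org.bonus_log2 += delta
                if len(st.qualities) > before:
                    done = list(st.qualities)
                    for t in done[before:]:
                        self._update_task_firsts[t] = \
                            self._update_task_firsts.get(t, 0) + 1
            elif kind == "divide":
                births += self._handle_divide(idx, org, ev.payload)
        return births

    def _handle_divide(self, idx, org, offspring) -> int:
        env = self.env
        st = org.env_state
        org.bonus_log2 += env.on_divide(st)
        org.gestation_cycles = org.cpu.gestation_cycles
        org.last_qualities = dict(st.qualities)
        # merit: genome length scaled by the accumulated metabolic bonus
        org.merit = org.cpu.parent_len * 2.0 ** org.bonus_log2
        org.bonus_log2 = 0.0
        org.births += 1
        st.reset_lifetime()
        org.cpu.n_draws = 0
        org.cpu.input_ptr = 0
        child = mutate_genome(offspring, self.rates, self.rng_mut,
                              len(self.arch.instructions))
        if child is None:
            self.events.append({"update": self.update_no,
                                "kind": "nonviable", "parent": org.oid})
            return 0
        self._place_offspring(idx, child, org)
        return 1

    def _place_offspring(self, idx, child_genome, parent):
        x, y = idx % self.width, idx // self.width
        dx, dy = _NEIGH[int(self.rng_place.integers(8))]
        tx = (x + dx) % self.width
        ty = (y + dy) % self.height
        target = ty * self.width + tx
        org = self._new_organism(child_genome, merit=parent.merit)
        self.cells[target] = org
        self.events.append({"update": self.update_no, "kind": "birth",
                            "parent": parent.oid, "child": org.oid,
                            "cell": target})
        return org

    # -- reporting ---------------------------------------------------------

    def _stats_row(self, births):
        alive = self.living()
        merits = [o.merit for o in alive]
        fits = [f for f in (fitness(o) for o in alive) if f is not None]
        row = {
            "update": self.update_no,
            "alive": len(alive),
            "births": births,
            "mean_merit": float(np.mean(merits)) if merits else 0.0,
            "median_merit": float(np.median(merits)) if merits else 0.0,
            "mean_fitness": float(np.mean(fits)) if fits else float("nan"),
        }
        for t, c in sorted(self._update_task_firsts.items()):
            row[f"task_{t}"] = c
        return row

    def organism_qualities(self, org) -> dict:
        """Task-quality snapshot (last completed gestation, else the
        current partial lifetime)."""
        if org.last_qualities is not None:
            return org.last_qualities
        return org.env_state.qualities

    def sample(self):
        """Fitness values and the N x T task-quality matrix of the
        living population (see :mod:`digevo.metrics`)."""
        from .metrics import PopulationSample
        alive = self.living()
        names = self.env.task_names
        qm = np.zeros((len(alive), len(names)))
        for i, o in enumerate(alive):
            q = self.organism_qualities(o)
            for j, t in enumerate(names):
                qm[i, j] = q.get(t, 0.0)
        fits = [f for f in (fitness(o) for o in alive) if f is not None]
        return PopulationSample(fitness_values=fits, quality_matrix=qm)
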