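"""Reward environments for digital organisms.

Seven environments, each defining a set of tasks whose performance earns
a metabolic bonus that multiplies the organism's merit (its share weight
in the CPU-cycle scheduler):

* ``logic-9`` — all 1- and 2-input bitwise logic functions (9 after
  removing input symmetries and the identity), rewarded multiplicatively
  in five difficulty levels from x2 up to x32.
* ``logic-77`` — adds the 68 three-input logic functions; every task
  doubles execution speed once.
* ``match-12`` — output any of 12 fixed 32-bit constants; near misses
  decay by a half-life in wrong bits, with at least 22 bits correct.
* ``fibonacci-32`` — output the Fibonacci sequence in order up to the
  32nd entry; outputs beyond the target are penalized such that 64
  extras cancel the 32 rewards.
* ``sort-10`` — echo 10 supplied values in descending order; the reward
  decays by a half-life in total positional displacement.
* ``limited-9`` — logic-9 with a consumable resource per task (inflow
  100 units/update, outflow 1%/update, equilibrium 10,000 units; at
  most 0.25% of a resource consumed per performance).
* ``navigation`` — follow a cue-marked path on a separate grid using
  sensor/actuator instructions appended to the architecture.

Each task is rewarded at most once per lifetime (one gestation; the
bookkeeping clears at divide).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaskDef", "enumerate_logic_tasks", "apply_truth_table",
    "logic9_bonus", "logic77_bonus", "LOGIC9_LEVELS",
    "match12_quality", "fibonacci_sequence", "sort10_quality",
    "ResourceState", "resource_step", "limited9_consume",
    "Environment", "get_environment", "ENVIRONMENT_NAMES",
    "NavigationWorld", "reference_maze",
]

MASK32 = 0xFFFFFFFF


# ---------------------------------------------------------------------------
# Logic task enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDef:
    """A rewarded computation: a boolean function applied bitwise to
    32-bit inputs.  ``table`` is the truth-table integer (bit m gives the
    output on input assignment m, input i in bit i of m)."""

    name: str
    arity: int
    table: int
    bonus_log2: float = 1.0
    resource_id: Optional[str] = None

    def apply(self, args: Sequence[int]) -> int:
        return apply_truth_table(self.table, self.arity, args)


def apply_truth_table(table: int, arity: int, args: Sequence[int]) -> int:
    """Evaluate a truth table bitwise over 32-bit operand words."""
    out = 0
    for m in range(1 << arity):
        if not (table >> m) & 1:
            continue
        term = MASK32
        for i in range(arity):
            a = args[i]
            term &= a if (m >> i) & 1 else ~a
        out |= term
    return out & MASK32


def _depends_on_all(table: int, arity: int) -> bool:
    for i in range(arity):
        bit = 1 << i
        if all(((table >> m) & 1) == ((table >> (m ^ bit)) & 1)
               for m in range(1 << arity)):
            return False
    return True


def _canonical_table(table: int, arity: int) -> int:
    best = None
    for perm in itertools.permutations(range(arity)):
        t = 0
        for m in range(1 << arity):
            pm = 0
            for i in range(arity):
                if (m >> i) & 1:
                    pm |= 1 << perm[i]
            if (table >> pm) & 1:
                t |= 1 << m
        if best is None or t < best:
            best = t
    return best

# canonical truth tables of the classically named 1- and 2-input tasks
_CLASSIC_NAMES = {
    (1, 0b01): "NOT",
    (2, 0b1000): "AND", (2, 0b1110): "OR",
    (2, 0b0111): "NAND", (2, 0b0001): "NOR",
    (2, 0b0110): "XOR", (2, 0b1001): "EQU",
    (2, 0b0010): "ANDNOT", (2, 0b1011): "ORNOT",
}


def enumerate_logic_tasks(max_arity: int) -> list:
    """All logic tasks of arity <= ``max_arity``.

    Functions are deduplicated under permutation of their inputs;
    functions that do not depend on all their inputs are dropped (this
    removes constants and the identity 'echo').  Ordering is canonical:
    by (arity, canonical truth-table integer).
    """
    if max_arity not in (1, 2, 3):
        raise ValueError("max_arity must be 1, 2 or 3")
    tasks = []
    for k in range(1, max_arity + 1):
        seen = set()
        for table in range(1 << (1 << k)):
            if not _depends_on_all(table, k):
                continue
            canon = _canonical_table(table, k)
            if canon in seen:
                continue
            seen.add(canon)
        for canon in sorted(seen):
            name = _CLASSIC_NAMES.get((k, canon), f"LOGIC{k}-0x{canon:02X}")
            if k == 1 and canon == 0b10:
                continue  # identity (echo) — excluded explicitly
            tasks.append(TaskDef(name, k, canon))
    return tasks


# ---------------------------------------------------------------------------
# Reward calibrations
# ---------------------------------------------------------------------------

# Logic-9 difficulty grouping: level k multiplies merit by 2**k; the
# endpoints (easiest x2, hardest x32) are fixed, the interior grouping
# follows the canonical default environment and is configurable.
LOGIC9_LEVELS = {
    "NOT": 1, "NAND": 1,
    "AND": 2, "ORNOT": 2,
    "OR": 3, "ANDNOT": 3,
    "NOR": 4, "XOR": 4,
    "EQU": 5,
}


def logic9_bonus(task: TaskDef, levels=None) -> float:
    levels = LOGIC9_LEVELS if levels is None else levels
    if task.name not in levels:
        raise KeyError(f"{task.name} is not a Logic-9 task")
    return float(levels[task.name])


def logic77_bonus(task: TaskDef) -> float:
    return 1.0


def match12_quality(value: int, targets: Sequence[int],
                    half_life_bits: float = 1.0,
                    min_bits_correct: int = 22):
    """Nearest match-target and its quality.

    Quality is ``2**(-w / half_life_bits)`` for ``w`` wrong bits, zero
    when fewer than ``min_bits_correct`` of the 32 bits are right.
    """
    best_t, best_w = None, 33
    for t in targets:
        w = int(value ^ t).bit_count()
        if w < best_w:
            best_t, best_w = t, w
    if 32 - best_w < min_bits_correct:
        return best_t, 0.0
    return best_t, 2.0 ** (-best_w / half_life_bits)


def fibonacci_sequence(n: int) -> list:
    """First ``n`` Fibonacci numbers, starting 1, 1."""
    out = [1, 1]
    while len(out) < n:
        out.append(out[-1] + out[-2])
    return out[:n]


def sort10_quality(outputs: Sequence[int], inputs: Sequence[int],
                   half_life_moves: float = 1.0) -> float:
    """Quality of a descending sort attempt.

    Zero unless ``outputs`` is a permutation of ``inputs``; otherwise
    ``2**(-D / half_life_moves)`` with D the total absolute displacement
    of each value from its slot in the descending order.
    """
    if sorted(outputs) != sorted(inputs):
        return 0.0
    target = sorted(inputs, reverse=True)
    # assign duplicate values to target slots greedily in order
    slots = {}
    for pos, v in enumerate(target):
        slots.setdefault(v, []).append(pos)
    d = 0
    for pos, v in enumerate(outputs):
        d += abs(pos - slots[v].pop(0))
    return 2.0 ** (-d / half_life_moves)


# ---------------------------------------------------------------------------
# Consumable resources (Limited-9)
# ---------------------------------------------------------------------------

@dataclass
class ResourceState:
    level: float = 0.0
    inflow: float = 100.0
    outflow_fraction: float = 0.01
    consumption_cap_fraction: float = 0.0025

    @property
    def equilibrium(self) -> float:
        return self.inflow / self.outflow_fraction


def resource_step(r: ResourceState, consumed: float = 0.0) -> float:
    """Advance one update: inflow, proportional outflow, consumption."""
    r.level = max(0.0, r.level + r.inflow
                  - r.outflow_fraction * r.level - consumed)
    return r.level


def limited9_consume(base_bonus_log2: float, quality: float,
                     r: ResourceState):
    """Units consumed and bonus collected for one task performance.

    The draw is capped at ``consumption_cap_fraction`` of the current
    level; the bonus scales linearly with the draw relative to the
    equilibrium draw (cap fraction x equilibrium level), so a task
    performed at equilibrium collects its full base bonus.
    """
    consumed = quality * r.consumption_cap_fraction * r.level
    anchor = r.consumption_cap_fraction * r.equilibrium
    bonus = base_bonus_log2 * consumed / anchor if anchor > 0 else 0.0
    return consumed, bonus


# ---------------------------------------------------------------------------
# Per-organism environment state
# ---------------------------------------------------------------------------

class OrganismEnvState:
    """Per-organism environment bookkeeping; cleared at divide."""

    __slots__ = ("cpu_inputs", "value_map", "tasks_done", "qualities",
                 "fib_index", "outputs", "world", "sort_done")

    def __init__(self, cpu_inputs):
        self.cpu_inputs = list(cpu_inputs)
        self.value_map = None
        self.tasks_done = set()
        self.qualities = {}
        self.fib_index = 0
        self.outputs = []
        self.world = None
        self.sort_done = False

    def reset_lifetime(self):
        self.tasks_done.clear()
        self.qualities = {}
        self.fib_index = 0
        self.outputs = []
        self.sort_done = False
        if self.world is not None:
            self.world.reset()


# ---------------------------------------------------------------------------
# Environments
# ---------------------------------------------------------------------------

class Environment:
    """Base environment: no tasks, no rewards."""

    name = "null"
    extra_instructions = ()

    def __init__(self):
        self.task_names = []

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def new_state(self, rng) -> OrganismEnvState:
        return OrganismEnvState([int(rng.integers(0, 1 << 32))])

    def on_output(self, st: OrganismEnvState, value: int,
                  n_draws: int) -> float:
        """Evaluate one output; returns the bonus_log2 delta."""
        return 0.0

    def on_divide(self, st: OrganismEnvState) -> float:
        """Bonus settled at divide (navigation path progress)."""
        return 0.0

    def on_update(self):
        """Per-update environment dynamics (resource flows)."""


class LogicEnvironment(Environment):
    """Logic-9 / Logic-77: reward outputs equal to a logic function of
    the organism's drawn inputs.

    Each organism receives three fixed random 32-bit inputs.  A task
    matches when the output equals the task function applied bitwise to
    some ordered tuple of distinct input slots (no reuse of a slot), and
    only once the organism has drawn the inputs the tuple uses.
    """

    n_inputs = 3

    def __init__(self, tasks, name):
        self.name = name
        self.tasks = list(tasks)
        self.task_names = [t.name for t in self.tasks]
        self.bonus = [t.bonus_log2 for t in self.tasks]

    def new_state(self, rng):
        vals = [int(v) for v in rng.integers(0, 1 << 32, self.n_inputs)]
        st = OrganismEnvState(vals)
        st.value_map = self._value_map(vals)
        return st

    def _value_map(self, vals):
        vm = {}
        by_arity = {}
        for idx, t in enumerate(self.tasks):
            by_arity.setdefault(t.arity, []).append(idx)
        for k, idxs in by_arity.items():
            for tup in itertools.permutations(range(len(vals)), k):
                args = [vals[i] for i in tup]
                min_draws = max(tup) + 1
                minterms = [None] * (1 << k)
                for m in range(1 << k):
                    term = MASK32
                    for i in range(k):
                        term &= args[i] if (m >> i) & 1 else ~args[i]
                    minterms[m] = term & MASK32
                for idx in idxs:
                    table = self.tasks[idx].table
                    v = 0
                    for m in range(1 << k):
                        if (table >> m) & 1:
                            v |= minterms[m]
                    entry = vm.setdefault(v & MASK32, {})
                    if idx not in entry or entry[idx] > min_draws:
                        entry[idx] = min_draws
        return vm

    def _reward(self, st, idx, quality):
        st.tasks_done.add(idx)
        st.qualities[self.task_names[idx]] = quality
        return self.bonus[idx] * quality

    def on_output(self, st, value, n_draws):
        entry = st.value_map.get(value)
        if not entry:
            return 0.0
        delta = 0.0
        for idx, min_draws in entry.items():
            if idx in st.tasks_done or n_draws < min_draws:
                continue
            delta += self._reward(st, idx, 1.0)
        return delta


def _logic9_tasks():
    tasks = enumerate_logic_tasks(2)
    return [TaskDef(t.name, t.arity, t.table, logic9_bonus(t))
            for t in tasks]


class Limited9Environment(LogicEnvironment):
    """Logic-9 with one consumable resource per task."""

    def __init__(self):
        super().__init__(_logic9_tasks(), "limited-9")
        self.resources = [ResourceState(level=ResourceState().equilibrium)
                          for _ in self.tasks]
        self._pending = [0.0] * len(self.tasks)

    def _reward(self, st, idx, quality):
        st.tasks_done.add(idx)
        st.qualities[self.task_names[idx]] = quality
        consumed, bonus = limited9_consume(
            self.bonus[idx], quality, self.resources[idx])
        self._pending[idx] += consumed
        return bonus

    def on_update(self):
        for idx, r in enumerate(self.resources):
            resource_step(r, self._pending[idx])
            self._pending[idx] = 0.0


# Match-12 default targets: approximately exponentially spaced across
# the 32-bit range with deterministic pseudo-random offsets (the exact
# constants are a package default, configurable per run).
def _default_match_targets():
    rng = np.random.default_rng(826206)
    targets = []
    for i in range(12):
        e = 6.0 + i * (31.0 - 6.0) / 11.0
        v = int(2 ** (e + rng.uniform(-0.4, 0.4))) & MASK32
        targets.append(v or 64)
    return tuple(dict.fromkeys(targets))


MATCH12_TARGETS = _default_match_targets()


class Match12Environment(Environment):
    name = "match-12"

    def __init__(self, targets=MATCH12_TARGETS, half_life_bits=1.0,
                 reward_log2=1.0):
        self.targets = list(targets)
        self.half_life_bits = half_life_bits
        self.reward_log2 = reward_log2
        self.task_names = [f"match-{t:#010x}" for t in self.targets]

    def on_output(self, st, value, n_draws):
        target, q = match12_quality(value, self.targets,
                                    self.half_life_bits)
        if q <= 0.0 or target in st.tasks_done:
            return 0.0
        st.tasks_done.add(target)
        st.qualities[f"match-{target:#010x}"] = q
        return q * self.reward_log2


class Fibonacci32Environment(Environment):
    name = "fibonacci-32"

    def __init__(self, n_targets=32, reward_log2=1.0,
                 penalty_outputs=64):
        self.n_targets = n_targets
        self.reward_log2 = reward_log2
        # calibrated so `penalty_outputs` extras cancel all rewards
        self.penalty_log2 = n_targets * reward_log2 / penalty_outputs
        self.sequence = fibonacci_sequence(n_targets)
        self.task_names = [f"fib-{i + 1:02d}" for i in range(n_targets)]

    def on_output(self, st, value, n_draws):
        i = st.fib_index
        if i >= self.n_targets:
            return -self.penalty_log2
        if value == self.sequence[i]:
            st.fib_index = i + 1
            st.qualities[self.task_names[i]] = 1.0
            return self.reward_log2
        return 0.0


class Sort10Environment(Environment):
    name = "sort-10"
    n_values = 10

    def __init__(self, half_life_moves=1.0, reward_log2=5.0):
        self.half_life_moves = half_life_moves
        self.reward_log2 = reward_log2
        self.task_names = ["sort"]

    def new_state(self, rng):
        vals = [int(v) for v in rng.integers(0, 1 << 32, self.n_values)]
        return OrganismEnvState(vals)

    def on_output(self, st, value, n_draws):
        if st.sort_done:
            return 0.0
        st.outputs.append(value)
        if len(st.outputs) < self.n_values:
            return 0.0
        st.sort_done = True
        q = sort10_quality(st.outputs, st.cpu_inputs, self.half_life_moves)
        if q > 0.0:
            st.qualities["sort"] = q
        return q * self.reward_log2


# ---------------------------------------------------------------------------
# Navigation
# ---------------------------------------------------------------------------

# heading k points along DIRS[k]; a 45-degree rotation steps k by one
DIRS = [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)]

CUE_EMPTY, CUE_FORWARD, CUE_LEFT, CUE_RIGHT, CUE_REPEAT = 0, 1, 2, 3, 4


def reference_maze():
    """A short hand-authored cue-marked path.

    Returns ``(path, cues, start_heading)``: the ordered path cells, the
    cue at each cell (the action that leads to the next cell: forward,
    turn left/right then move, or repeat the previous action), and the
    heading the organism starts with at the first cell.
    """
    moves = [2, 2, 3, 3, 4, 4, 3, 2, 1, 1, 0, 0]  # headings per step
    path = [(0, 0)]
    for h in moves:
        dx, dy = DIRS[h]
        x, y = path[-1]
        path.append((x + dx, y + dy))
    cues = []
    heading = moves[0]
    prev_action = None
    for h in moves:
        if h == heading:
            action = "forward"
        elif (h - heading) % 8 <= 4 and (h - heading) % 8 != 0:
            action = "right" if (h - heading) % 8 < 4 else "left"
        else:
            action = "left"
        cue = CUE_REPEAT if action == prev_action and action != "forward" \
            else {"forward": CUE_FORWARD, "left": CUE_LEFT,
                  "right": CUE_RIGHT}[action]
        cues.append(cue)
        prev_action = action
        heading = h
    cues.append(CUE_EMPTY)  # terminal cell
    return path, cues, moves[0]


class NavigationWorld:
    """Grid world adapter bound to one organism.

    ``sense`` returns the cue at the current cell, ``rotate`` turns the
    heading by 45-degree steps, ``move`` advances one cell along the
    heading (clamped to the maze bounding box).  Progress counts path
    cells reached in order.
    """

    def __init__(self, path, cues, start_heading):
        self.path = path
        self.cue_at = dict(zip(path, cues))
        self.index_of = {p: i for i, p in enumerate(path)}
        xs = [p[0] for p in path]
        ys = [p[1] for p in path]
        self.bounds = (min(xs) - 2, max(xs) + 2, min(ys) - 2, max(ys) + 2)
        self.start_heading = start_heading
        self.reset()

    def reset(self):
        self.pos = self.path[0]
        self.heading = self.start_heading
        self.progress = 0

    def sense(self) -> int:
        return self.cue_at.get(self.pos, CUE_EMPTY)

    def rotate(self, step: int):
        self.heading = (self.heading + step) % 8

    def move(self):
        dx, dy = DIRS[self.heading]
        x0, x1, y0, y1 = self.bounds
        x = min(max(self.pos[0] + dx, x0), x1)
        y = min(max(self.pos[1] + dy, y0), y1)
        self.pos = (x, y)
        nxt = self.index_of.get(self.pos)
        if nxt == self.progress + 1:
            self.progress = nxt

    @property
    def quality(self) -> float:
        return self.progress / (len(self.path) - 1)


class NavigationEnvironment(Environment):
    name = "navigation"
    extra_instructions = ("sg-sense", "sg-move", "sg-rotate-l", "sg-rotate-r")

    def __init__(self, reward_log2=5.0):
        self.reward_log2 = reward_log2
        self.task_names = ["navigation"]
        self.maze = reference_maze()

    def new_state(self, rng):
        st = OrganismEnvState([int(rng.integers(0, 1 << 32))])
        st.world = NavigationWorld(*self.maze)
        return st

    def on_divide(self, st):
        q = st.world.quality
        if q > 0.0:
            st.qualities["navigation"] = q
        return q * self.reward_log2


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _logic77_tasks():
    return [TaskDef(t.name, t.arity, t.table, 1.0)
            for t in enumerate_logic_tasks(3)]


_FACTORIES = {
    "logic-9": lambda: LogicEnvironment(_logic9_tasks(), "logic-9"),
    "logic-77": lambda: LogicEnvironment(_logic77_tasks(), "logic-77"),
    "match-12": Match12Environment,
    "fibonacci-32": Fibonacci32Environment,
    "sort-10": Sort10Environment,
    "limited-9": Limited9Environment,
    "navigation": NavigationEnvironment,
}

ENVIRONMENT_NAMES = tuple(sorted(_FACTORIES))


def get_environment(name: str) -> Environment:
    key = name.strip().lower()
    if key not in _FACTORIES:
        raise KeyError(f"unknown environment {name!r}; valid choices: "
                       + ", ".join(ENVIRONMENT_NAMES))
    return _FACTORIES[key]()
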