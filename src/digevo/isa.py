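"""Instruction set architectures for Avida-style virtual CPUs.

An architecture is an ordered instruction vocabulary plus hardware
parameters (register/nop count, head count) and feature flags (fully
associative operand binding, label-prefixed matching, split I/O).
Genomes are sequences of opcodes, i.e. indices into the architecture's
instruction list.

No-operation instructions (nop-A, nop-B, ...) play three roles: executed
directly they do nothing; trailing another instruction they redirect its
register/head operands; and runs of them form position labels that search
and conditional-copy instructions match against, either verbatim (direct)
or under cyclic complementary matching (nop-A -> nop-B -> ... -> nop-A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "InstructionDef",
    "ArchitectureSpec",
    "ARCHITECTURE_NAMES",
    "build_architecture",
    "complement_label",
    "read_following_label",
    "find_label",
    "resolve_operands",
    "architecture_to_dict",
    "architecture_from_dict",
]

# ---------------------------------------------------------------------------
# Instruction families
# ---------------------------------------------------------------------------

FAMILIES = (
    "nop", "label", "arith", "conditional", "ifx", "flow",
    "search", "goto", "stack", "io", "replication", "sensor",
)

REG, HEAD = "reg", "head"

# sentinel: instruction reads an unbounded trailing nop run (a label)
READS_LABEL = -1

# head indices (nop index k selects head k on head-operand instructions)
HEAD_IP, HEAD_READ, HEAD_WRITE, HEAD_FLOW = 0, 1, 2, 3

NOP_LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class InstructionDef:
    """One instruction: mnemonic, family, default operand slots.

    ``default_operands`` is a tuple of ``(kind, index)`` pairs where kind
    is ``"reg"`` or ``"head"``; the first slot is the one a single nop
    modifier rebases.  ``max_nop_args`` is how many trailing nops the
    instruction reads as modifiers (``READS_LABEL`` for label readers).
    """

    mnemonic: str
    family: str
    default_operands: tuple = ()
    max_nop_args: int = 0

    @property
    def n_reg_slots(self) -> int:
        return sum(1 for k, _ in self.default_operands if k == REG)


def _ins(mnemonic, family, ops=(), maxnops=None):
    ops = tuple(ops)
    if maxnops is None:
        maxnops = 1 if ops else 0
    return InstructionDef(mnemonic, family, ops, maxnops)


# Master glossary: every instruction any tested architecture may contain.
# Default operands follow the ?BX?/?CX?/?IP? conventions of the glossary.
_B, _C = (REG, 1), (REG, 2)
_IP = (HEAD, HEAD_IP)

_GLOSSARY = [
    _ins("label", "label"),
    # arithmetic / logic
    _ins("add", "arith", [_B, _B, _C]),
    _ins("sub", "arith", [_B, _B, _C]),
    _ins("nand", "arith", [_B, _B, _C]),
    _ins("inc", "arith", [_B]),
    _ins("dec", "arith", [_B]),
    _ins("shift-l", "arith", [_B]),
    _ins("shift-r", "arith", [_B]),
    # conditionals
    _ins("if-n-equ", "conditional", [_B, _C]),
    _ins("if-less", "conditional", [_B, _C]),
    _ins("if-not-0", "conditional", [_B]),
    _ins("if-equ-0", "conditional", [_B]),
    _ins("if-gtr-0", "conditional", [_B]),
    _ins("if-less-0", "conditional", [_B]),
    _ins("if-copied-seq-comp", "conditional", (), READS_LABEL),
    _ins("if-copied-seq-direct", "conditional", (), READS_LABEL),
    _ins("if-copied-lbl-comp", "conditional", (), READS_LABEL),
    _ins("if-copied-lbl-direct", "conditional", (), READS_LABEL),
    _ins("if-gtr-x", "ifx", (), READS_LABEL),
    _ins("if-equ-x", "ifx", (), READS_LABEL),
    # flow control
    _ins("mov-head", "flow", [_IP]),
    _ins("jmp-head", "flow", [_IP, _C]),
    _ins("get-head", "flow", [_IP, _C]),
    _ins("set-flow", "flow", [_C]),
    _ins("mov-head-if-n-equ", "flow", [_IP]),
    _ins("mov-head-if-less", "flow", [_IP]),
    # searches
    _ins("search-seq-comp-s", "search", (), READS_LABEL),
    _ins("search-seq-direct-s", "search", (), READS_LABEL),
    _ins("search-seq-direct-f", "search", (), READS_LABEL),
    _ins("search-seq-direct-b", "search", (), READS_LABEL),
    _ins("search-lbl-comp-s", "search", (), READS_LABEL),
    _ins("search-lbl-direct-s", "search", (), READS_LABEL),
    _ins("search-lbl-direct-f", "search", (), READS_LABEL),
    _ins("search-lbl-direct-b", "search", (), READS_LABEL),
    # gotos
    _ins("goto", "goto", (), READS_LABEL),
    _ins("goto-if-n-equ", "goto", (), READS_LABEL),
    _ins("goto-if-less", "goto", (), READS_LABEL),
    # stack / data movement
    _ins("push", "stack", [_B]),
    _ins("pop", "stack", [_B]),
    _ins("swap-stk", "stack"),
    _ins("swap", "stack", [_B, _C]),
    # environment I/O
    _ins("IO", "io", [_B]),
    _ins("input", "io", [_B]),
    _ins("output", "io", [_B]),
    # self-replication
    _ins("h-alloc", "replication"),
    _ins("h-copy", "replication"),
    _ins("h-divide", "replication"),
    # navigation sensors/actuators (appended only in that environment)
    _ins("sg-sense", "sensor", [_B]),
    _ins("sg-move", "sensor"),
    _ins("sg-rotate-l", "sensor"),
    _ins("sg-rotate-r", "sensor"),
]

for _k in range(16):
    _GLOSSARY.append(_ins("nop-" + NOP_LETTERS[_k], "nop"))

GLOSSARY = {d.mnemonic: d for d in _GLOSSARY}


def nop_mnemonic(index: int) -> str:
    return "nop-" + NOP_LETTERS[index]


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    instructions: tuple  # ordered tuple of InstructionDef
    n_registers: int
    n_nops: int
    n_heads: int
    fully_associative: bool
    label_mode: str          # "sequence" | "label_prefixed" | "both"
    match_modes: frozenset   # subset of {"complement", "direct"}
    split_io: bool
    mnemonics: tuple = field(init=False, default=())

    def __post_init__(self):
        object.__setattr__(
            self, "mnemonics", tuple(d.mnemonic for d in self.instructions))
        if self.n_registers != self.n_nops:
            raise ValueError("register and nop counts must agree")

    # -- opcode helpers ----------------------------------------------------
    def opcode(self, mnemonic: str) -> int:
        return self.mnemonics.index(mnemonic)

    def has(self, mnemonic: str) -> bool:
        return mnemonic in self.mnemonics

    def nop_index_of(self, opcode: int) -> int:
        """Nop alphabet index of an opcode, or -1 if it is not a nop."""
        d = self.instructions[opcode]
        if d.family != "nop":
            return -1
        return NOP_LETTERS.index(d.mnemonic[-1])

    def nop_opcode(self, index: int) -> int:
        return self.opcode(nop_mnemonic(index))

    def effective_max_nops(self, d: InstructionDef) -> int:
        """Modifier nops an instruction reads under this architecture.

        Fully associative operand binding lets multi-register
        instructions read one nop per register slot; otherwise every
        slotted instruction reads at most one.  Label readers are
        unbounded in both cases.
        """
        if d.max_nop_args == READS_LABEL:
            return READS_LABEL
        if not d.default_operands:
            return 0
        if self.fully_associative and d.n_reg_slots >= 2 and \
                all(k == REG for k, _ in d.default_operands):
            return len(d.default_operands)
        return 1


def _spec(name, mnemonics, n_regs, fa, split_io):
    instrs = tuple(GLOSSARY[m] for m in mnemonics)
    present = set(mnemonics)
    lbl = any(m.startswith(("search-lbl", "if-copied-lbl")) for m in present)
    seq = any(m.startswith(("search-seq", "if-copied-seq")) for m in present)
    if lbl and seq:
        label_mode = "both"
    elif lbl:
        label_mode = "label_prefixed"
    else:
        label_mode = "sequence"
    modes = set()
    for m in present:
        if m.startswith(("search-", "if-copied-")):
            modes.add("complement" if "-comp" in m else "direct")
    return ArchitectureSpec(
        name=name,
        instructions=instrs,
        n_registers=n_regs,
        n_nops=n_regs,
        n_heads=max(4, n_regs),
        fully_associative=fa,
        label_mode=label_mode,
        match_modes=frozenset(modes),
        split_io=split_io,
    )


_HEADS_MNEMONICS = [
    "nop-A", "nop-B", "nop-C",
    "if-n-equ", "if-less", "if-copied-seq-comp",
    "pop", "push", "swap-stk", "swap",
    "shift-r", "shift-l", "inc", "dec", "add", "sub", "nand",
    "IO",
    "h-alloc", "h-divide", "h-copy",
    "search-seq-comp-s",
    "mov-head", "jmp-head", "get-head", "set-flow",
]

# rows of the label-set membership table: which label/sequence matching
# instructions each LABEL-series set contains
_LABEL_ROWS = {
    "LABEL": ["label", "if-copied-lbl-comp", "search-lbl-comp-s"],
    "LABEL-DIRECT": ["label", "if-copied-lbl-direct", "search-lbl-direct-s"],
    "LABEL-BOTH": ["label", "if-copied-lbl-comp", "if-copied-lbl-direct",
                   "search-lbl-comp-s", "search-lbl-direct-s"],
    "LABEL-SEQ": ["label", "if-copied-lbl-comp", "if-copied-seq-comp",
                  "search-lbl-comp-s", "search-seq-comp-s"],
    "LABEL-SEQ-DIRECT": ["label", "if-copied-lbl-direct",
                         "if-copied-seq-direct", "search-lbl-direct-s",
                         "search-seq-direct-s"],
    "LABEL-DIRECT-SEQ": ["label", "if-copied-lbl-direct",
                         "if-copied-seq-comp", "search-lbl-direct-s",
                         "search-seq-comp-s"],
    "LABEL-SEQ-BOTH": ["label",
                       "if-copied-lbl-comp", "if-copied-lbl-direct",
                       "if-copied-seq-comp", "if-copied-seq-direct",
                       "search-lbl-comp-s", "search-lbl-direct-s",
                       "search-seq-comp-s", "search-seq-direct-s"],
}

_REGISTER_COUNTS = {"R4": 4, "R5": 5, "R6": 6, "R7": 7, "R8": 8,
                    "R12": 12, "R16": 16}

_DIRECTIONAL_SEARCHES = ["search-lbl-direct-f", "search-lbl-direct-b",
                         "search-seq-direct-f", "search-seq-direct-b"]

_IF0_GROUP = ["if-not-0", "if-equ-0", "if-gtr-0", "if-less-0"]
_IFX_GROUP = ["if-gtr-x", "if-equ-x"]
_MVH_GROUP = ["mov-head-if-n-equ", "mov-head-if-less"]

_FLOW_GROUPS = {
    "FLOW-IF0": [_IF0_GROUP],
    "FLOW-IFX": [_IFX_GROUP],
    "FLOW-MVH": [_MVH_GROUP],
    "FLOW-IF0-MVH": [_IF0_GROUP, _MVH_GROUP],
    "FLOW-IFX-MVH": [_IFX_GROUP, _MVH_GROUP],
    "FLOW-IF0-IFX-MVH": [_IF0_GROUP, _IFX_GROUP, _MVH_GROUP],
}


def _with_nops(mnemonics, n_regs):
    out = list(mnemonics)
    for k in range(3, n_regs):
        out.insert(out.index("nop-C") + (k - 2), nop_mnemonic(k))
    return out


def _build_registry():
    reg = {}

    reg["HEADS"] = _spec("HEADS", _HEADS_MNEMONICS, 3, False, False)
    reg["FA"] = _spec("FA", _HEADS_MNEMONICS, 3, True, False)

    for name, n in _REGISTER_COUNTS.items():
        reg[name] = _spec(name, _with_nops(_HEADS_MNEMONICS, n), n, True, False)

    # LABEL series: built on R6, drop set-flow, swap matching instructions
    r6_m = _with_nops(_HEADS_MNEMONICS, 6)
    base = [m for m in r6_m if m not in
            ("set-flow", "if-copied-seq-comp", "search-seq-comp-s")]
    for name, extras in _LABEL_ROWS.items():
        m = list(base)
        at = m.index("if-n-equ")  # keep matching instrs near their kin
        for e in extras:
            m.insert(at, e)
            at += 1
        reg[name] = _spec(name, m, 6, True, False)

    # SPLIT-IO: LABEL-SEQ-DIRECT with IO split into input + output
    lsd = list(reg["LABEL-SEQ-DIRECT"].mnemonics)
    i = lsd.index("IO")
    splitio = lsd[:i] + ["input", "output"] + lsd[i + 1:]
    reg["SPLIT-IO"] = _spec("SPLIT-IO", splitio, 6, True, True)

    # SEARCH series chains from SPLIT-IO
    sd = splitio + _DIRECTIONAL_SEARCHES
    reg["SEARCH-DIRECTIONAL"] = _spec("SEARCH-DIRECTIONAL", sd, 6, True, True)
    sg = sd + ["goto"]
    reg["SEARCH-GOTO"] = _spec("SEARCH-GOTO", sg, 6, True, True)
    reg["SEARCH-GOTOIF"] = _spec(
        "SEARCH-GOTOIF", sg + ["goto-if-n-equ", "goto-if-less"], 6, True, True)

    # FLOW series builds on SEARCH-DIRECTIONAL
    for name, groups in _FLOW_GROUPS.items():
        m = list(sd)
        for g in groups:
            m += g
        reg[name] = _spec(name, m, 6, True, True)

    # HEADS-EX: the combined architecture (identical content to FLOW-IFX-MVH)
    ex = reg["FLOW-IFX-MVH"]
    reg["HEADS-EX"] = _spec("HEADS-EX", list(ex.mnemonics), 6, True, True)
    return reg


_REGISTRY = _build_registry()
ARCHITECTURE_NAMES = tuple(sorted(_REGISTRY))


def build_architecture(name: str) -> ArchitectureSpec:
    """Return the named architecture (case-insensitive lookup)."""
    key = name.strip().upper()
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown architecture {name!r}; valid choices: "
            + ", ".join(ARCHITECTURE_NAMES))
    return _REGISTRY[key]


# ---------------------------------------------------------------------------
# Label matching
# ---------------------------------------------------------------------------

def complement_label(label: Sequence[int], n_nops: int) -> list:
    """Cyclic complementary image of a label: each code i -> (i+1) mod n."""
    if any(c < 0 or c >= n_nops for c in label):
        raise ValueError("label code out of range for this nop alphabet")
    return [(c + 1) % n_nops for c in label]


def read_following_label(genome: Sequence[int], position: int,
                         arch: ArchitectureSpec) -> list:
    """Maximal circular run of nops starting just after ``position``.

    Returns the run as a list of nop alphabet indices; bounded by the
    genome length so an all-nop genome terminates.
    """
    L = len(genome)
    out = []
    for k in range(1, L):
        idx = arch.nop_index_of(genome[(position + k) % L])
        if idx < 0:
            break
        out.append(idx)
    return out


NOT_FOUND = None


def find_label(genome: Sequence[int], pattern: Sequence[int],
               match: str, mode: str, scan: str, origin: int,
               arch: ArchitectureSpec) -> Optional[int]:
    """Locate a label in a circular genome.

    ``pattern`` is the raw nop sequence following the searching
    instruction; the genome site searched for is its cyclic complement
    (``match="complement"``) or the pattern itself (``match="direct"``).
    In ``mode="label_prefixed"`` the matched nop run must be immediately
    preceded by the ``label`` instruction.  ``scan`` is one of
    ``from_start`` / ``forward`` / ``backward`` relative to ``origin``
    (the searching instruction's position); the instruction's own
    trailing nop run is never an admissible site.  Returns the index of
    the instruction immediately after the matched run, or ``NOT_FOUND``.
    """
    k = len(pattern)
    L = len(genome)
    if k == 0 or k >= L:
        return NOT_FOUND
    if match == "complement":
        target = complement_label(pattern, arch.n_nops)
    elif match == "direct":
        target = list(pattern)
    else:
        raise ValueError(f"unknown match mode {match!r}")
    label_op = arch.opcode("label") if mode == "label_prefixed" else -1
    if mode not in ("sequence", "label_prefixed"):
        raise ValueError(f"unknown label mode {mode!r}")

    nop_of = arch.nop_index_of
    # the searching instruction's own trailing nop run is inadmissible
    own_len = len(read_following_label(genome, origin, arch))
    own = {(origin + 1 + j) % L for j in range(own_len)}

    def matches_at(s):
        if s in own:
            return False
        if label_op >= 0 and genome[(s - 1) % L] != label_op:
            return False
        for j in range(k):
            if nop_of(genome[(s + j) % L]) != target[j]:
                return False
        return True

    if scan == "from_start":
        starts = range(L)
    elif scan == "forward":
        starts = ((origin + d) % L for d in range(1, L + 1))
    elif scan == "backward":
        starts = ((origin - d) % L for d in range(1, L + 1))
    else:
        raise ValueError(f"unknown scan mode {scan!r}")

    for s in starts:
        if matches_at(s):
            return (s + k) % L
    return NOT_FOUND


# ---------------------------------------------------------------------------
# Operand resolution
# ---------------------------------------------------------------------------

def resolve_operands(instr: InstructionDef, following: Sequence[int],
                     arch: ArchitectureSpec):
    """Bind an instruction's operand slots given its trailing nops.

    Returns ``(slots, n_consumed)`` where ``slots`` is a list of
    ``(kind, index)`` pairs.  With no nops the defaults are returned
    unchanged.  A single nop rebases the first slot to the nop's
    register (or head) and shifts every same-kind slot by the same
    amount, preserving the default offsets.  Under fully associative
    binding, multi-register instructions additionally read one nop per
    remaining slot, each overriding that slot explicitly.
    """
    if instr.family in ("nop", "label"):
        raise ValueError("nop/label instructions take no operands")
    slots = list(instr.default_operands)
    if not slots:
        return slots, 0
    cap = arch.effective_max_nops(instr)
    if cap == READS_LABEL or cap == 0:
        return slots, 0
    nops = list(following[:cap])
    if not nops:
        return slots, 0

    kind0, idx0 = slots[0]
    domain = arch.n_registers if kind0 == REG else arch.n_heads
    shift = (nops[0] % domain) - idx0
    out = []
    for kind, idx in slots:
        if kind == kind0:
            d = arch.n_registers if kind == REG else arch.n_heads
            out.append((kind, (idx + shift) % d))
        else:
            out.append((kind, idx))
    for j, code in enumerate(nops[1:], start=1):
        if j >= len(out):
            break
        kind = out[j][0]
        d = arch.n_registers if kind == REG else arch.n_heads
        out[j] = (kind, code % d)
    return out, len(nops)


# ---------------------------------------------------------------------------
# Serialization (custom architectures)
# ---------------------------------------------------------------------------

def architecture_to_dict(arch: ArchitectureSpec) -> dict:
    return {
        "name": arch.name,
        "instructions": list(arch.mnemonics),
        "n_registers": arch.n_registers,
        "fully_associative": arch.fully_associative,
        "split_io": arch.split_io,
    }


def architecture_from_dict(d: dict) -> ArchitectureSpec:
    unknown = [m for m in d["instructions"] if m not in GLOSSARY]
    if unknown:
        raise KeyError(f"unknown mnemonics: {unknown}")
    return _spec(d["name"], d["instructions"], int(d["n_registers"]),
                 bool(d.get("fully_associative", False)),
                 bool(d.get("split_io", False)))
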