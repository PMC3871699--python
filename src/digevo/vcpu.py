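"""Virtual CPU executing linear genomes in circular memory.

The hardware model: ``n_registers`` 32-bit registers, two ten-slot
stacks (one active at a time), and movable heads into genome memory —
instruction pointer (IP), READ, WRITE and FLOW, plus unassigned extras
in architectures with more than four nops.  Replication works by
allocating offspring space (``h-alloc``), copying instructions from the
READ head to the WRITE head (``h-copy``) and splitting off the copied
segment (``h-divide``).

Every instruction is total: degenerate operands wrap modulo memory
length or 2^32, an empty stack pops 0, and a failed divide is silently
ignored, so any genome executes any number of cycles without raising.

Nop modifiers are read ahead but not consumed: the IP still steps
through them (they execute as no-ops), which keeps gestation time
proportional to genome length.
"""

from __future__ import annotations

from collections import namedtuple
from functools import lru_cache
from typing import Optional, Sequence

from . import isa
from .isa import ArchitectureSpec, READS_LABEL, REG, HEAD_FLOW, HEAD_IP

__all__ = ["VirtualCPU", "ExecEvent", "compile_architecture"]

MASK32 = 0xFFFFFFFF
SIGN_BIT = 0x80000000
STACK_DEPTH = 10

ExecEvent = namedtuple("ExecEvent", ["kind", "payload"])
EVENT_NONE = ExecEvent("none", None)

# opclass codes (dispatch integers)
(OP_NOP, OP_LABEL, OP_ADD, OP_SUB, OP_NAND, OP_INC, OP_DEC, OP_SHL, OP_SHR,
 OP_IFNEQU, OP_IFLESS, OP_IFNOT0, OP_IFEQU0, OP_IFGTR0, OP_IFLESS0,
 OP_IFCOPIED, OP_IFX, OP_MOVHEAD, OP_JMPHEAD, OP_GETHEAD, OP_SETFLOW,
 OP_MOVHEADIF, OP_SEARCH, OP_GOTO, OP_PUSH, OP_POP, OP_SWAPSTK, OP_SWAP,
 OP_IO, OP_INPUT, OP_OUTPUT, OP_HALLOC, OP_HCOPY, OP_HDIVIDE,
 OP_SGSENSE, OP_SGMOVE, OP_SGROTL, OP_SGROTR) = range(38)

_OPCLASS = {
    "label": OP_LABEL, "add": OP_ADD, "sub": OP_SUB, "nand": OP_NAND,
    "inc": OP_INC, "dec": OP_DEC, "shift-l": OP_SHL, "shift-r": OP_SHR,
    "if-n-equ": OP_IFNEQU, "if-less": OP_IFLESS, "if-not-0": OP_IFNOT0,
    "if-equ-0": OP_IFEQU0, "if-gtr-0": OP_IFGTR0, "if-less-0": OP_IFLESS0,
    "if-gtr-x": OP_IFX, "if-equ-x": OP_IFX,
    "if-copied-seq-comp": OP_IFCOPIED, "if-copied-seq-direct": OP_IFCOPIED,
    "if-copied-lbl-comp": OP_IFCOPIED, "if-copied-lbl-direct": OP_IFCOPIED,
    "search-seq-comp-s": OP_SEARCH, "search-seq-direct-s": OP_SEARCH,
    "search-seq-direct-f": OP_SEARCH, "search-seq-direct-b": OP_SEARCH,
    "search-lbl-comp-s": OP_SEARCH, "search-lbl-direct-s": OP_SEARCH,
    "search-lbl-direct-f": OP_SEARCH, "search-lbl-direct-b": OP_SEARCH,
    "mov-head": OP_MOVHEAD, "jmp-head": OP_JMPHEAD, "get-head": OP_GETHEAD,
    "set-flow": OP_SETFLOW,
    "mov-head-if-n-equ": OP_MOVHEADIF, "mov-head-if-less": OP_MOVHEADIF,
    "goto": OP_GOTO, "goto-if-n-equ": OP_GOTO, "goto-if-less": OP_GOTO,
    "push": OP_PUSH, "pop": OP_POP, "swap-stk": OP_SWAPSTK, "swap": OP_SWAP,
    "IO": OP_IO, "input": OP_INPUT, "output": OP_OUTPUT,
    "h-alloc": OP_HALLOC, "h-copy": OP_HCOPY, "h-divide": OP_HDIVIDE,
    "sg-sense": OP_SGSENSE, "sg-move": OP_SGMOVE,
    "sg-rotate-l": OP_SGROTL, "sg-rotate-r": OP_SGROTR,
}


class CompiledArchitecture:
    """Per-opcode lookup tables derived from an ArchitectureSpec."""

    def __init__(self, arch: ArchitectureSpec):
        self.arch = arch
        n = len(arch.instructions)
        self.n = n
        self.opclass = [0] * n
        self.is_nop = [False] * n
        self.nop_idx = [-1] * n
        self.maxnops = [0] * n
        self.defaults = [()] * n
        self.defs = list(arch.instructions)
        self.search_params = [None] * n   # (match, mode, scan)
        self.copied_params = [None] * n   # (match, mode)
        self.goto_test = [None] * n       # None | "n-equ" | "less"
        self.ifx_op = [None] * n          # ">" | "="
        self.movheadif_test = [None] * n
        self.label_opcode = (
            arch.opcode("label") if arch.has("label") else -1)
        self.nop_opcodes = [arch.nop_opcode(k) for k in range(arch.n_nops)]
        # precomputed single-nop operand bindings: [opcode][nop index]
        self.single_mod = [None] * n

        for op, d in enumerate(arch.instructions):
            m = d.mnemonic
            if d.family == "nop":
                self.opclass[op] = OP_NOP
                self.is_nop[op] = True
                self.nop_idx[op] = isa.NOP_LETTERS.index(m[-1])
                continue
            self.opclass[op] = _OPCLASS[m]
            self.maxnops[op] = arch.effective_max_nops(d)
            self.defaults[op] = tuple(d.default_operands)
            if d.family == "search":
                # search-{lbl|seq}-{comp|direct}-{s|f|b}
                parts = m.split("-")
                mode = "label_prefixed" if parts[1] == "lbl" else "sequence"
                match = "complement" if parts[2] == "comp" else "direct"
                scan = {"s": "from_start", "f": "forward",
                        "b": "backward"}[parts[3]]
                self.search_params[op] = (match, mode, scan)
            elif m.startswith("if-copied"):
                self.opclass[op] = OP_IFCOPIED
                parts = m.split("-")
                mode = "label_prefixed" if parts[2] == "lbl" else "sequence"
                match = "complement" if parts[3] == "comp" else "direct"
                self.copied_params[op] = (match, mode)
            elif d.family == "goto":
                self.goto_test[op] = (
                    None if m == "goto"
                    else "n-equ" if m.endswith("n-equ") else "less")
            elif m in ("if-gtr-x", "if-equ-x"):
                self.ifx_op[op] = ">" if "gtr" in m else "="
            elif m.startswith("mov-head-if"):
                self.movheadif_test[op] = "n-equ" if m.endswith("n-equ") else "less"

        for op, d in enumerate(arch.instructions):
            if self.maxnops[op] >= 1:
                self.single_mod[op] = tuple(
                    tuple(isa.resolve_operands(d, [c], arch)[0])
                    for c in range(arch.n_nops))


@lru_cache(maxsize=None)
def compile_architecture(arch: ArchitectureSpec) -> CompiledArchitecture:
    return CompiledArchitecture(arch)


def _signed(v: int) -> int:
    return v - (1 << 32) if v & SIGN_BIT else v


class VirtualCPU:
    """CPU state bound to one genome; see module docstring for the model.

    Parameters
    ----------
    arch : ArchitectureSpec
    genome : sequence of opcodes (length >= 1)
    inputs : the organism's environmental input values, cycled by
        ``input``/``IO`` (default a single 0)
    world : optional navigation-world adapter exposing
        ``sense() -> int``, ``move()``, ``rotate(step)``
    copy_fraction_min : minimum fraction of offspring sites that must
        have been written by ``h-copy`` for a divide to succeed
    alloc_factor : memory growth factor of ``h-alloc`` (total memory
        becomes ``alloc_factor * parent length``)
    ifx_base : default constant of the nop-built comparison value used
        by ``if-gtr-x`` / ``if-equ-x``
    """

    __slots__ = (
        "arch", "ca", "mem", "parent_len", "regs", "heads", "stacks",
        "active_stack", "copied", "written", "inputs", "input_ptr",
        "n_draws", "cycles", "gestation_cycles", "world",
        "copy_fraction_min", "alloc_factor", "ifx_base", "n_copies",
        "last_copied_fraction")

    def __init__(self, arch: ArchitectureSpec, genome: Sequence[int],
                 inputs: Optional[Sequence[int]] = None, world=None,
                 copy_fraction_min: float = 0.5, alloc_factor: int = 2,
                 ifx_base: int = 1):
        if len(genome) < 1:
            raise ValueError("genome must contain at least one instruction")
        ca = compile_architecture(arch)
        if any(op < 0 or op >= ca.n for op in genome):
            raise ValueError("opcode out of range for architecture")
        self.arch = arch
        self.ca = ca
        self.mem = list(genome)
        self.parent_len = len(self.mem)
        self.regs = [0] * arch.n_registers
        self.heads = [0] * arch.n_heads
        self.stacks = [[], []]
        self.active_stack = 0
        self.copied = []
        self.n_copies = 0
        self.written = bytearray(len(self.mem))
        self.inputs = list(inputs) if inputs else [0]
        self.input_ptr = 0
        self.n_draws = 0
        self.cycles = 0
        self.gestation_cycles = None
        self.last_copied_fraction = None
        self.world = world
        self.copy_fraction_min = copy_fraction_min
        self.alloc_factor = alloc_factor
        self.ifx_base = ifx_base

    # -- small helpers -----------------------------------------------------

    def _next_input(self) -> int:
        v = self.inputs[self.input_ptr % len(self.inputs)]
        self.input_ptr += 1
        self.n_draws += 1
        return v

    def _read_label(self, pos: int) -> list:
        """Nop indices following ``pos`` (maximal circular run)."""
        mem, nop_idx, L = self.mem, self.ca.nop_idx, len(self.mem)
        out = []
        for k in range(1, L):
            c = nop_idx[mem[(pos + k) % L]]
            if c < 0:
                break
            out.append(c)
        return out

    def _skip_target(self, ip: int) -> int:
        """Position after the next non-nop instruction and its nops."""
        mem, is_nop, L = self.mem, self.ca.is_nop, len(self.mem)
        j, seen = ip + 1, 0
        while seen < L and is_nop[mem[j % L]]:
            j += 1
            seen += 1
        j += 1  # past the skipped instruction
        while seen < L and is_nop[mem[j % L]]:
            j += 1
            seen += 1
        return j % L

    def _resolve(self, op: int, ip: int):
        """Operand slots for the instruction at ``ip`` (fast path)."""
        ca = self.ca
        mem, L = self.mem, len(self.mem)
        first = ca.nop_idx[mem[(ip + 1) % L]]
        if first < 0:
            return ca.defaults[op]
        cap = ca.maxnops[op]
        if cap <= 0:
            return ca.defaults[op]
        if cap == 1:
            return ca.single_mod[op][first]
        second = ca.nop_idx[mem[(ip + 2) % L]]
        if second < 0:
            return ca.single_mod[op][first]
        nops = [first, second]
        k = 3
        while len(nops) < cap:
            c = ca.nop_idx[mem[(ip + k) % L]]
            if c < 0:
                break
            nops.append(c)
            k += 1
        slots, _ = isa.resolve_operands(ca.defs[op], nops, self.arch)
        return slots

    def _find_label(self, pattern, match, mode, scan, origin):
        """Same contract as :func:`digevo.isa.find_label`, on this memory."""
        ca = self.ca
        mem, L = self.mem, len(self.mem)
        k = len(pattern)
        if k == 0 or k >= L:
            return None
        if match == "complement":
            n = self.arch.n_nops
            target = [(c + 1) % n for c in pattern]
        else:
            target = pattern
        label_op = ca.label_opcode if mode == "label_prefixed" else -1
        nop_idx = ca.nop_idx
        own_lo = origin + 1
        if scan == "from_start":
            starts = range(L)
        elif scan == "forward":
            starts = ((origin + d) % L for d in range(1, L + 1))
        else:
            starts = ((origin - d) % L for d in range(1, L + 1))
        for s in starts:
            if own_lo <= s < own_lo + k or own_lo <= s + L < own_lo + k:
                continue
            if label_op >= 0 and mem[(s - 1) % L] != label_op:
                continue
            ok = True
            for j in range(k):
                if nop_idx[mem[(s + j) % L]] != target[j]:
                    ok = False
                    break
            if ok:
                return (s + k) % L
        return None

    # -- stacks ------------------------------------------------------------

    def _push(self, v: int):
        s = self.stacks[self.active_stack]
        if len(s) >= STACK_DEPTH:
            del s[0]  # ring buffer: overwrite the oldest entry
        s.append(v)

    def _pop(self) -> int:
        s = self.stacks[self.active_stack]
        return s.pop() if s else 0

    # -- replication -------------------------------------------------------

    def _divide(self):
        r, w = self.heads[1], self.heads[2]
        L = len(self.mem)
        if r == 0 or r == w or self.n_copies == 0:
            return None
        if r < w:
            off = self.mem[r:w]
            wrf = self.written[r:w]
        else:
            off = self.mem[r:] + self.mem[:w]
            wrf = self.written[r:] + self.written[:w]
        if not off:
            return None
        frac = sum(wrf) / len(off)
        if frac < self.copy_fraction_min:
            return None
        self.last_copied_fraction = frac
        # parent keeps the memory before the READ head and is restored
        # to its initial state, re-executing from the genome start so
        # each gestation follows an identical path
        self.mem = self.mem[:r]
        self.parent_len = len(self.mem)
        self.written = bytearray(self.parent_len)
        self.copied = []
        self.n_copies = 0
        self.heads = [0] * len(self.heads)
        self.regs = [0] * len(self.regs)
        self.stacks = [[], []]
        self.active_stack = 0
        self.gestation_cycles = self.cycles
        self.cycles = 0
        return off

    # -- main execution ----------------------------------------------------

    def step(self) -> ExecEvent:
        """Execute one instruction; returns the resulting event."""
        ev = self._exec_one()
        return ev if ev is not None else EVENT_NONE

    def run_cycles(self, n: int) -> list:
        """Execute ``n`` cycles, returning events in execution order."""
        out = []
        exec_one = self._exec_one
        for _ in range(n):
            ev = exec_one()
            if ev is not None:
                out.append(ev)
        return out

    def _exec_one(self):
        ca = self.ca
        mem = self.mem
        L = len(mem)
        ip = self.heads[0] % L
        op = mem[ip]
        oc = ca.opclass[op]
        regs = self.regs
        moved = False
        event = None
        self.cycles += 1

        if oc == OP_NOP or oc == OP_LABEL:
            pass
        elif oc == OP_HCOPY:
            h = self.heads
            r, w = h[1] % L, h[2] % L
            v = mem[r]
            mem[w] = v
            self.written[w] = 1
            self.copied.append(v)
            self.n_copies += 1
            h[1] = (r + 1) % L
            h[2] = (w + 1) % L
        elif oc <= OP_SHR:  # arithmetic / logic
            slots = self._resolve(op, ip)
            d = slots[0][1]
            if oc == OP_ADD:
                regs[d] = (regs[slots[1][1]] + regs[slots[2][1]]) & MASK32
            elif oc == OP_SUB:
                regs[d] = (regs[slots[1][1]] - regs[slots[2][1]]) & MASK32
            elif oc == OP_NAND:
                regs[d] = ~(regs[slots[1][1]] & regs[slots[2][1]]) & MASK32
            elif oc == OP_INC:
                regs[d] = (regs[d] + 1) & MASK32
            elif oc == OP_DEC:
                regs[d] = (regs[d] - 1) & MASK32
            elif oc == OP_SHL:
                regs[d] = (regs[d] << 1) & MASK32
            else:
                regs[d] = regs[d] >> 1
        elif oc <= OP_IFLESS0:  # skip-style register conditionals
            slots = self._resolve(op, ip)
            a = _signed(regs[slots[0][1]])
            if oc == OP_IFNEQU:
                cond = a != _signed(regs[slots[1][1]])
            elif oc == OP_IFLESS:
                cond = a < _signed(regs[slots[1][1]])
            elif oc == OP_IFNOT0:
                cond = a != 0
            elif oc == OP_IFEQU0:
                cond = a == 0
            elif oc == OP_IFGTR0:
                cond = a > 0
            else:
                cond = a < 0
            if not cond:
                self.heads[0] = self._skip_target(ip)
                moved = True
        elif oc == OP_IFCOPIED:
            pattern = self._read_label(ip)
            match, mode = ca.copied_params[op]
            cond = False
            if pattern:
                if match == "complement":
                    n = self.arch.n_nops
                    target = [(c + 1) % n for c in pattern]
                else:
                    target = pattern
                t_ops = [ca.nop_opcodes[c] for c in target]
                if mode == "label_prefixed":
                    t_ops = [ca.label_opcode] + t_ops
                k = len(t_ops)
                cp = self.copied
                cond = len(cp) >= k and cp[-k:] == t_ops
            if not cond:
                self.heads[0] = self._skip_target(ip)
                moved = True
        elif oc == OP_IFX:
            label = self._read_label(ip)
            val = self.ifx_base
            for c in label:
                if c == 1:
                    val <<= 1
                elif c == 2:
                    val <<= 2
                elif c == 3:
                    val <<= 3
                elif c == 0:
                    val = -val
            a = _signed(regs[1])
            cond = (a > val) if ca.ifx_op[op] == ">" else (a == val)
            if not cond:
                self.heads[0] = self._skip_target(ip)
                moved = True
        elif oc == OP_MOVHEAD:
            h = self._resolve(op, ip)[0][1]
            self.heads[h] = self.heads[HEAD_FLOW]
            if h == HEAD_IP:
                moved = True
        elif oc == OP_MOVHEADIF:
            a, b = _signed(regs[1]), _signed(regs[2])
            cond = (a != b) if ca.movheadif_test[op] == "n-equ" else (a < b)
            if cond:
                h = self._resolve(op, ip)[0][1]
                self.heads[h] = self.heads[HEAD_FLOW]
                if h == HEAD_IP:
                    moved = True
        elif oc == OP_JMPHEAD:
            slots = self._resolve(op, ip)
            h = slots[0][1]
            amt = _signed(regs[slots[1][1]])
            if h == HEAD_IP:
                ip = (ip + amt) % L  # shifted, then the fetch advance
            else:
                self.heads[h] = (self.heads[h] + amt) % L
        elif oc == OP_GETHEAD:
            slots = self._resolve(op, ip)
            regs[slots[1][1]] = self.heads[slots[0][1]] % L
        elif oc == OP_SETFLOW:
            slots = self._resolve(op, ip)
            self.heads[HEAD_FLOW] = regs[slots[0][1]] % L
        elif oc == OP_SEARCH:
            pattern = self._read_label(ip)
            match, mode, scan = ca.search_params[op]
            res = self._find_label(pattern, match, mode, scan, ip)
            if res is None:
                res = (ip + 1 + len(pattern)) % L
            self.heads[HEAD_FLOW] = res
        elif oc == OP_GOTO:
            test = ca.goto_test[op]
            if test is not None:
                a, b = _signed(regs[1]), _signed(regs[2])
                ok = (a != b) if test == "n-equ" else (a < b)
            else:
                ok = True
            if ok:
                pattern = self._read_label(ip)
                res = self._find_label(
                    pattern, "direct", "label_prefixed", "from_start", ip)
                if res is not None:
                    self.heads[0] = res
                    moved = True
        elif oc == OP_PUSH:
            self._push(regs[self._resolve(op, ip)[0][1]])
        elif oc == OP_POP:
            regs[self._resolve(op, ip)[0][1]] = self._pop()
        elif oc == OP_SWAPSTK:
            self.active_stack ^= 1
        elif oc == OP_SWAP:
            slots = self._resolve(op, ip)
            a, b = slots[0][1], slots[1][1]
            regs[a], regs[b] = regs[b], regs[a]
        elif oc == OP_IO:
            r = self._resolve(op, ip)[0][1]
            event = ExecEvent("output", regs[r])
            regs[r] = self._next_input()
        elif oc == OP_INPUT:
            regs[self._resolve(op, ip)[0][1]] = self._next_input()
        elif oc == OP_OUTPUT:
            event = ExecEvent("output", regs[self._resolve(op, ip)[0][1]])
        elif oc == OP_HALLOC:
            if len(mem) < self.alloc_factor * self.parent_len:
                grow = self.alloc_factor * self.parent_len - len(mem)
                fill = ca.nop_opcodes[0]
                mem.extend([fill] * grow)
                self.written.extend(b"\x00" * grow)
                L = len(mem)
                event = ExecEvent("alloc", L)
        elif oc == OP_HDIVIDE:
            off = self._divide()
            if off is not None:
                event = ExecEvent("divide", off)
                moved = True  # parent restarts from position 0
        elif oc == OP_SGSENSE:
            r = self._resolve(op, ip)[0][1]
            regs[r] = self.world.sense() if self.world is not None else 0
        elif oc == OP_SGMOVE:
            if self.world is not None:
                self.world.move()
        elif oc == OP_SGROTL:
            if self.world is not None:
                self.world.rotate(-1)
        else:  # OP_SGROTR
            if self.world is not None:
                self.world.rotate(1)

        if not moved:
            self.heads[0] = (ip + 1) % L
        return event
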