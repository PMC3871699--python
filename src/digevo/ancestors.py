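"""Canonical self-replicating seed genomes.

Every architecture is seeded with an ancestor of the same canonical
form — allocate offspring space, locate the end-of-genome marker label
and park the WRITE head there, then run a copy loop that duplicates one
instruction per pass and divides once the marker itself has been copied:

    h-alloc
    <search>  <pattern nops>     ; FLOW -> just past the end marker
    mov-head  nop-C              ; WRITE head -> FLOW
    <neutral nop padding to the fixed length>
    <search>                     ; no label: FLOW -> next instruction
    h-copy                       ;   <- loop target
    <if-copied>  <pattern nops>  ; true once the end marker is copied
    h-divide
    mov-head                     ; IP -> FLOW (back to h-copy)
    [label]  nop-A nop-B         ; end marker (label-prefixed sets only)

Only the choice of search/if-copied variant and the nop patterns differ
between architectures (complement-matching sets search with the
predecessor codes of the marker, direct-matching sets with the marker
itself), keeping gestation-time differences attributable to instruction
semantics rather than genome content.  Genomes are padded with neutral
nops to a fixed length (default 50).

The ancestors perform no environmental tasks: they contain no I/O
instructions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .isa import ArchitectureSpec
from .vcpu import VirtualCPU

__all__ = ["build_ancestor", "validate_ancestor", "AncestorReport"]

DEFAULT_LENGTH = 50

# (search-from-start instruction, matching if-copied instruction), in
# preference order; label-prefixed variants first because raw direct
# sequence matching would find the if-copied modifier nops instead of
# the end marker
_VARIANT_PAIRS = [
    ("search-lbl-direct-s", "if-copied-lbl-direct", "direct", True),
    ("search-lbl-comp-s", "if-copied-lbl-comp", "complement", True),
    ("search-seq-comp-s", "if-copied-seq-comp", "complement", False),
]

_MARKER = (0, 1)  # nop-A nop-B


def build_ancestor(arch: ArchitectureSpec,
                   length: int = DEFAULT_LENGTH) -> list:
    """Canonical self-replicating genome for ``arch`` (opcode list)."""
    for m in ("h-alloc", "h-copy", "h-divide", "mov-head"):
        if not arch.has(m):
            raise ValueError(
                f"architecture {arch.name} lacks {m}; cannot self-replicate")
    for search_m, ifc_m, match, lbl in _VARIANT_PAIRS:
        if arch.has(search_m) and arch.has(ifc_m):
            break
    else:
        raise ValueError(
            f"architecture {arch.name} has no usable search/if-copied pair")

    n = arch.n_nops
    if match == "complement":
        # pattern whose cyclic complement is the marker
        pattern = tuple((c - 1) % n for c in _MARKER)
    else:
        pattern = _MARKER
    nop = arch.nop_opcode
    marker_ops = [nop(c) for c in _MARKER]
    if lbl:
        marker_ops = [arch.opcode("label")] + marker_ops

    head = ([arch.opcode("h-alloc"), arch.opcode(search_m)]
            + [nop(c) for c in pattern]
            + [arch.opcode("mov-head"), nop(2)])   # nop-C -> WRITE head
    tail = ([arch.opcode(search_m), arch.opcode("h-copy"),
             arch.opcode(ifc_m)]
            + [nop(c) for c in pattern]
            + [arch.opcode("h-divide"), arch.opcode("mov-head")]
            + marker_ops)
    pad = length - len(head) - len(tail)
    if pad < 0:
        raise ValueError(f"ancestor length {length} too short")
    return head + [nop(0)] * pad + tail


@dataclass
class AncestorReport:
    viable: bool
    gestation_cycles: Optional[int]
    offspring_identical: bool
    copied_fraction: float
    n_tasks_performed: int
    generations_checked: int = 0
    gestation_constant: bool = False


def validate_ancestor(genome: Sequence[int], arch: ArchitectureSpec,
                      generations: int = 3,
                      cycle_cap: int = 10_000) -> AncestorReport:
    """Execute a genome (mutations off) and report replication fidelity.

    Runs the genome for up to ``cycle_cap`` cycles per generation,
    following offspring for ``generations`` divides; checks that each
    offspring is an exact copy and that gestation time is constant.
    """
    current = list(genome)
    gestations = []
    identical = True
    copied_fraction = 0.0
    n_outputs = 0
    for _ in range(generations):
        cpu = VirtualCPU(arch, current)
        offspring = None
        for _ in range(cycle_cap):
            ev = cpu._exec_one()
            if ev is not None:
                if ev.kind == "divide":
                    offspring = ev.payload
                    break
                if ev.kind == "output":
                    n_outputs += 1
        if offspring is None:
            return AncestorReport(False, None, False, 0.0, n_outputs)
        gestations.append(cpu.gestation_cycles)
        copied_fraction = cpu.last_copied_fraction
        if offspring != current:
            identical = False
        current = offspring
    return AncestorReport(
        viable=True,
        gestation_cycles=gestations[0],
        offspring_identical=identical,
        copied_fraction=copied_fraction,
        n_tasks_performed=n_outputs,
        generations_checked=generations,
        gestation_constant=len(set(gestations)) == 1,
    )
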