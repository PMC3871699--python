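"""Virtual CPU semantics: arithmetic, conditionals, flow, stacks,
I/O and replication."""

import numpy as np
import pytest

from digevo import build_architecture
from digevo.vcpu import MASK32, VirtualCPU

from conftest import assemble, make_cpu, random_genome


def run_until(cpu, kind, cap=10_000):
    for _ in range(cap):
        ev = cpu.step()
        if ev.kind == kind:
            return ev
    return None


# ---------------------------------------------------------------------------
# Arithmetic / logic
# ---------------------------------------------------------------------------

def test_inc_default_bx(heads):
    cpu = make_cpu(heads, ["inc"])
    cpu.regs[1] = 5
    cpu.step()
    assert cpu.regs[1] == 6


def test_nop_and_label_advance_ip_only(heads):
    cpu = make_cpu(heads, ["nop-A", "inc"])
    before = (list(cpu.regs), list(cpu.stacks[0]))
    cpu.step()
    assert cpu.heads[0] == 1
    assert (list(cpu.regs), list(cpu.stacks[0])) == before
    lab = build_architecture("LABEL")
    cpu = make_cpu(lab, ["label", "inc"])
    cpu.step()
    assert cpu.heads[0] == 1 and all(r == 0 for r in cpu.regs)


def test_arithmetic_against_python_oracle(heads):
    rng = np.random.default_rng(3)
    for _ in range(100):
        b, c = (int(v) for v in rng.integers(0, 1 << 32, 2))
        for op, expect in [
                ("add", (b + c) & MASK32),
                ("sub", (b - c) & MASK32),
                ("nand", ~(b & c) & MASK32)]:
            cpu = make_cpu(heads, [op])
            cpu.regs[1], cpu.regs[2] = b, c
            cpu.step()
            assert cpu.regs[1] == expect, op


def test_shift_and_dec_edge_cases(heads):
    cpu = make_cpu(heads, ["shift-r"])
    cpu.regs[1] = 7
    cpu.step()
    assert cpu.regs[1] == 3  # divide by two
    cpu = make_cpu(heads, ["dec"])
    cpu.step()
    assert cpu.regs[1] == MASK32  # two's-complement wrap at zero
    cpu = make_cpu(heads, ["shift-l"])
    cpu.regs[1] = 0x80000001
    cpu.step()
    assert cpu.regs[1] == 2  # top bit falls off


def test_nand_all_ones_gives_zero(heads):
    cpu = make_cpu(heads, ["nand"])
    cpu.regs[1] = cpu.regs[2] = MASK32
    cpu.step()
    assert cpu.regs[1] == 0


# ---------------------------------------------------------------------------
# Conditionals and skipping
# ---------------------------------------------------------------------------

def test_if_less_true_executes_next(heads):
    cpu = make_cpu(heads, ["if-less", "inc", "dec"])
    cpu.regs[1], cpu.regs[2] = 2, 5
    cpu.step()
    assert cpu.heads[0] == 1  # next instruction will execute


def test_if_less_false_skips_instruction_and_its_nops(heads):
    # false condition skips inc together with its modifier nops
    cpu = make_cpu(heads, ["if-less", "inc", "nop-A", "nop-C", "dec", "sub"])
    cpu.regs[1], cpu.regs[2] = 5, 2
    cpu.step()
    assert cpu.heads[0] == 4  # lands on dec


def test_if_conditional_own_modifier_nops_are_skipped_too(heads):
    # nops directly after the if-* are its own modifiers; a false test
    # must jump past them and the guarded instruction
    cpu = make_cpu(heads, ["if-n-equ", "nop-B", "inc", "nop-A", "dec"])
    cpu.regs[1] = cpu.regs[2] = 9
    cpu.step()
    assert cpu.heads[0] == 4


@pytest.mark.parametrize("op,b,cond", [
    ("if-equ-0", 0, True), ("if-equ-0", 1, False),
    ("if-not-0", 0, False), ("if-not-0", 3, True),
    ("if-gtr-0", 1, True), ("if-gtr-0", 0, False),
    ("if-less-0", 0xFFFFFFFF, True),  # -1 signed
    ("if-less-0", 1, False),
])
def test_zero_comparisons(op, b, cond):
    arch = build_architecture("FLOW-IF0")
    cpu = make_cpu(arch, [op, "inc", "dec"])
    cpu.regs[1] = b
    cpu.step()
    assert (cpu.heads[0] == 1) == cond


def test_if_copied_complement_sequence(heads):
    # after copying nop-B nop-B nop-C the label nop-A nop-A nop-B matches
    cpu = make_cpu(heads, ["if-copied-seq-comp", "nop-A", "nop-A", "nop-B",
                           "h-divide", "inc"])
    cpu.copied = [heads.nop_opcode(1), heads.nop_opcode(1),
                  heads.nop_opcode(2)]
    cpu.step()
    assert cpu.heads[0] == 1  # condition true: execute next
    cpu2 = make_cpu(heads, ["if-copied-seq-comp", "nop-A", "nop-A", "nop-B",
                            "h-divide", "inc"])
    cpu2.copied = [heads.nop_opcode(0)]
    cpu2.step()
    assert cpu2.heads[0] == 5  # false: skip h-divide


def _ifx_constant_oracle(label, base=1):
    val = base
    for c in label:
        if c == 0:
            val = -val
        elif c in (1, 2, 3):
            val <<= c
    return val


def test_ifx_constant_matches_brute_force_fold():
    arch = build_architecture("FLOW-IFX")
    codes = range(arch.n_nops)
    labels = [[]] + [[a] for a in codes] + \
        [[a, b] for a in codes for b in codes] + \
        [[a, b, c] for a in (0, 1, 2, 3) for b in codes for c in codes]
    for label in labels:
        want = _ifx_constant_oracle(label)
        nops = [f"nop-{'ABCDEF'[c]}" for c in label]
        cpu = make_cpu(arch, ["if-equ-x"] + nops + ["swap-stk", "add"])
        cpu.regs[1] = want & MASK32
        cpu.step()
        assert cpu.heads[0] == 1, label    # equal: executes next
        cpu = make_cpu(arch, ["if-equ-x"] + nops + ["swap-stk", "add"])
        cpu.regs[1] = (want + 1) & MASK32
        cpu.step()
        assert cpu.heads[0] != 1, label    # unequal: skips


def test_ifx_shift_and_sign_examples():
    # nop-B doubles, nop-A negates the default constant
    assert _ifx_constant_oracle([1]) == 2
    assert _ifx_constant_oracle([0]) == -1
    assert _ifx_constant_oracle([2, 2]) == 16


# ---------------------------------------------------------------------------
# Flow control
# ---------------------------------------------------------------------------

def test_mov_head_moves_ip_to_flow(heads):
    g = ["mov-head"] + ["inc"] * 19
    cpu = make_cpu(heads, g)
    cpu.heads[3] = 17
    cpu.step()
    assert cpu.heads[0] == 17  # no extra advance when IP itself moves


def test_mov_head_on_other_head_advances_ip(heads):
    cpu = make_cpu(heads, ["mov-head", "nop-C", "inc"])
    cpu.heads[3] = 2
    cpu.step()
    assert cpu.heads[2] == 2      # WRITE head moved
    assert cpu.heads[0] == 1      # IP advanced normally


def test_jmp_head_zero_jump_advances_normally(heads):
    cpu = make_cpu(heads, ["jmp-head", "inc", "dec"])
    cpu.regs[2] = 0
    cpu.step()
    assert cpu.heads[0] == 1


def test_jmp_head_shifts_ip_by_cx(heads):
    g = ["jmp-head"] + ["inc"] * 9
    cpu = make_cpu(heads, g)
    cpu.regs[2] = 4
    cpu.step()
    assert cpu.heads[0] == 5  # ip + 4, then fetch advance


def test_jmp_head_negative_wraps(heads):
    g = ["jmp-head"] + ["inc"] * 9
    cpu = make_cpu(heads, g)
    cpu.regs[2] = (-3) & MASK32
    cpu.step()
    assert cpu.heads[0] == (0 - 3 + 1) % 10


def test_set_flow_modular(heads):
    g = ["set-flow"] + ["inc"] * 9
    cpu = make_cpu(heads, g)
    cpu.regs[2] = 13
    cpu.step()
    assert cpu.heads[3] == 3  # 13 mod 10


def test_get_head_copies_ip_into_cx(heads):
    cpu = make_cpu(heads, ["nop-A", "get-head", "inc"])
    cpu.step()
    cpu.step()
    assert cpu.regs[2] == 1


def test_conditional_mov_head():
    arch = build_architecture("FLOW-MVH")
    g = ["mov-head-if-less"] + ["inc"] * 9
    cpu = make_cpu(arch, g)
    cpu.heads[3] = 7
    cpu.regs[1], cpu.regs[2] = 1, 2
    cpu.step()
    assert cpu.heads[0] == 7      # test passed: IP moved
    cpu = make_cpu(arch, g)
    cpu.heads[3] = 7
    cpu.regs[1], cpu.regs[2] = 2, 1
    cpu.step()
    assert cpu.heads[0] == 1      # test failed: plain advance, no skip


def test_goto_jumps_to_label_prefixed_direct_match():
    arch = build_architecture("SEARCH-GOTO")
    g = assemble(arch, ["goto", "nop-A", "inc", "label", "nop-A", "dec",
                        "sub"])
    cpu = VirtualCPU(arch, g)
    cpu.step()
    assert cpu.heads[0] == 5  # after the matched run


def test_goto_without_match_is_ignored():
    arch = build_architecture("SEARCH-GOTO")
    cpu = make_cpu(arch, ["goto", "nop-A", "inc", "dec"])
    cpu.step()
    assert cpu.heads[0] == 1


def test_goto_if_less_failed_condition_never_jumps():
    arch = build_architecture("SEARCH-GOTOIF")
    g = ["goto-if-less", "nop-A", "inc", "label", "nop-A", "dec"]
    cpu = make_cpu(arch, g)
    cpu.regs[1], cpu.regs[2] = 5, 2  # BX >= CX
    cpu.step()
    assert cpu.heads[0] == 1


def test_search_fallback_places_flow_after_itself(heads):
    cpu = make_cpu(heads, ["search-seq-comp-s", "nop-A", "inc", "dec"])
    cpu.step()  # pattern [A]: complement nop-B absent -> fallback
    assert cpu.heads[3] == 2


# ---------------------------------------------------------------------------
# Stacks and data movement
# ---------------------------------------------------------------------------

def test_push_pop_round_trip(heads):
    cpu = make_cpu(heads, ["push", "pop"])
    cpu.regs[1] = 9
    cpu.step()
    cpu.regs[1] = 0
    cpu.step()
    assert cpu.regs[1] == 9


def test_pop_empty_stack_yields_zero(heads):
    cpu = make_cpu(heads, ["pop"])
    cpu.regs[1] = 77
    cpu.step()
    assert cpu.regs[1] == 0


def test_stack_is_ten_slot_ring_buffer(heads):
    cpu = make_cpu(heads, ["swap-stk"])
    for v in range(11):
        cpu._push(v)
    got = [cpu._pop() for _ in range(10)]
    assert got == list(range(10, 0, -1))  # last ten, LIFO
    assert cpu._pop() == 0


def test_swap_stk_toggles_active_stack(heads):
    cpu = make_cpu(heads, ["push", "swap-stk", "pop", "swap-stk", "pop"])
    cpu.regs[1] = 5
    cpu.step()          # push 5 on stack 0
    cpu.step()          # toggle
    cpu.step()          # pop from empty stack 1 -> 0
    assert cpu.regs[1] == 0
    cpu.step()          # toggle back
    cpu.regs[1] = 99
    cpu.step()          # pop from stack 0
    assert cpu.regs[1] == 5


def test_swap_exchanges_registers(heads):
    cpu = make_cpu(heads, ["swap"])
    cpu.regs[1], cpu.regs[2] = 4, 9
    cpu.step()
    assert (cpu.regs[1], cpu.regs[2]) == (9, 4)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_io_outputs_then_replaces_with_input(heads):
    cpu = make_cpu(heads, ["IO", "IO"], inputs=[11, 22])
    cpu.regs[1] = 5
    ev = cpu.step()
    assert ev.kind == "output" and ev.payload == 5
    assert cpu.regs[1] == 11
    ev = cpu.step()
    assert ev.payload == 11 and cpu.regs[1] == 22


def test_split_input_twice_gives_successive_values():
    arch = build_architecture("SPLIT-IO")
    cpu = make_cpu(arch, ["input", "input"], inputs=[7, 8, 9])
    cpu.step()
    assert cpu.regs[1] == 7
    cpu.step()
    assert cpu.regs[1] == 8


def test_split_output_leaves_register_unchanged():
    arch = build_architecture("SPLIT-IO")
    cpu = make_cpu(arch, ["output"], inputs=[7])
    cpu.regs[1] = 42
    ev = cpu.step()
    assert ev.kind == "output" and ev.payload == 42
    assert cpu.regs[1] == 42


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

def test_h_copy_advances_heads_and_writes(heads):
    cpu = make_cpu(heads, ["h-alloc", "h-copy", "inc", "dec"])
    cpu.step()
    assert len(cpu.mem) == 8  # doubled
    cpu.heads[2] = 4
    cpu.step()
    assert cpu.mem[4] == cpu.mem[0]
    assert cpu.heads[1] == 1 and cpu.heads[2] == 5
    assert cpu.written[4] == 1


def test_h_divide_with_nothing_copied_fails_silently(heads):
    cpu = make_cpu(heads, ["h-alloc", "h-divide", "inc"])
    cpu.step()
    ev = cpu.step()
    assert ev.kind == "none"
    assert cpu.heads[0] == 2  # execution simply continues


def test_divide_requires_half_of_offspring_written(heads):
    # copy only 1 of the 4 sites the divide span covers
    cpu = make_cpu(heads, ["h-alloc", "h-copy", "inc", "h-divide"])
    cpu.step()
    cpu.heads[2] = 4
    cpu.step()
    cpu.step()
    cpu.heads[1], cpu.heads[2] = 4, 8  # 4-site span, 1 written
    ev = cpu.step()
    assert ev.kind == "none"
    # a fully written span of the same shape divides fine
    cpu = make_cpu(heads, ["h-alloc", "h-copy", "h-copy", "h-divide"])
    cpu.step()
    cpu.heads[2] = 4
    cpu.step()
    cpu.step()
    cpu.heads[1], cpu.heads[2] = 4, 6  # 2-site span, 2 written
    assert cpu.step().kind == "divide"


# ---------------------------------------------------------------------------
# Totality, determinism
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("arch_name", ["HEADS", "HEADS-EX", "R16",
                                       "LABEL-SEQ-BOTH", "SEARCH-GOTOIF"])
def test_random_genomes_never_raise(arch_name):
    arch = build_architecture(arch_name)
    rng = np.random.default_rng(11)
    for _ in range(120):
        g = random_genome(arch, rng, int(rng.integers(1, 40)))
        cpu = VirtualCPU(arch, g, inputs=[1, 2, 3])
        for _ in range(250):
            cpu.step()
        assert all(0 <= r <= MASK32 for r in cpu.regs)
        assert all(0 <= h < len(cpu.mem) or h % len(cpu.mem) >= 0
                   for h in cpu.heads)


def test_step_is_deterministic(heads):
    rng = np.random.default_rng(5)
    g = random_genome(heads, rng, 30)
    traces = []
    for _ in range(2):
        cpu = VirtualCPU(heads, g, inputs=[4, 5, 6])
        trace = [cpu.step() for _ in range(500)]
        traces.append((trace, list(cpu.regs), list(cpu.heads)))
    assert traces[0] == traces[1]
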