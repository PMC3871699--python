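import numpy as np
import pytest

from digevo import build_architecture
from digevo.vcpu import VirtualCPU


@pytest.fixture(scope="session")
def heads():
    return build_architecture("HEADS")


@pytest.fixture(scope="session")
def fa():
    return build_architecture("FA")


def assemble(arch, mnemonics):
    """Genome (opcode list) from a list of mnemonics."""
    return [arch.opcode(m) for m in mnemonics]


def make_cpu(arch, mnemonics, **kw):
    return VirtualCPU(arch, assemble(arch, mnemonics), **kw)


def random_genome(arch, rng, length):
    return [int(v) for v in rng.integers(0, len(arch.instructions), length)]
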