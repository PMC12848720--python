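import pytest

from chemturing import (
    BUSY_BEAVER_START,
    adder_start,
    binary_adder_machine,
    busy_beaver_machine,
    default_platform,
)
from chemturing.tm_compiler import compile_machine, run_compiled


@pytest.fixture(scope="session")
def bb_machine():
    return busy_beaver_machine()


@pytest.fixture(scope="session")
def adder_machine():
    return binary_adder_machine()


@pytest.fixture(scope="session")
def bb_program(bb_machine):
    return compile_machine(bb_machine, initial=BUSY_BEAVER_START, cap=100)


@pytest.fixture(scope="session")
def bb_run(bb_program):
    """(trace, decoded sequence) of the compiled Busy Beaver run."""
    return run_compiled(bb_program)


@pytest.fixture(scope="session")
def adder_run(adder_machine):
    program = compile_machine(adder_machine, initial=adder_start(5, 3), cap=200)
    return run_compiled(program)


@pytest.fixture
def platform():
    return default_platform()
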