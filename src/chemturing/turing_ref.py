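"""Reference Turing-machine interpreter and the two demonstration machines.

A machine is a finite set of states (including the designated halt state
``HALT``), a finite alphabet (including the blank symbol ``"0"``), and a
total look-up table mapping (state, read symbol) to (write symbol, move
direction, next state).  Configurations live on a *finite* tape of N cells
(default 8) with a 1-based head position; moving off either end is a hard
error, mirroring the physical rig's finite row of vials rather than
silently clamping or growing the tape.

This module is the oracle against which compiled chemical programs are
checked: the compiler's decoded per-iteration configurations must match
:func:`tm_step` exactly, step for step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional

HALT = "HALT"
BLANK = "0"
MOVES = ("L", "R")


class TuringError(Exception):
    pass


class TapeOverrunError(TuringError):
    """The head was driven off the finite tape."""


class HaltedError(TuringError):
    """Attempted to step a configuration already in the halt state."""


@dataclass(frozen=True)
class TransitionRule:
    """One row of the look-up table: write a symbol, move the head one cell
    left or right, switch state."""

    write: str
    move: str  # "L" or "R"
    next: str


@dataclass(frozen=True)
class TuringMachine:
    """States, alphabet and a total transition table.

    ``states`` lists the non-halt states in declaration order followed by
    ``HALT``; that order is load-bearing downstream, where the compiler's
    color encoding enumerates states by declaration index.
    """

    states: tuple[str, ...]
    alphabet: tuple[str, ...]
    table: Mapping[tuple[str, str], TransitionRule]
    initial: str

    def __post_init__(self) -> None:
        if HALT not in self.states:
            raise ValueError(f"states must include {HALT}")
        if BLANK not in self.alphabet:
            raise ValueError(f"alphabet must include the blank symbol {BLANK!r}")
        if self.initial not in self.states or self.initial == HALT:
            raise ValueError(f"invalid initial state {self.initial!r}")
        working = [s for s in self.states if s != HALT]
        for state in working:
            for symbol in self.alphabet:
                if (state, symbol) not in self.table:
                    raise ValueError(f"table is not total: missing ({state}, {symbol})")
        for (state, symbol), rule in self.table.items():
            if state == HALT:
                raise ValueError("HALT must have no outgoing rules")
            if state not in self.states or symbol not in self.alphabet:
                raise ValueError(f"rule key ({state}, {symbol}) outside machine domain")
            if rule.write not in self.alphabet:
                raise ValueError(f"rule writes unknown symbol {rule.write!r}")
            if rule.move not in MOVES:
                raise ValueError(f"rule move must be L or R, got {rule.move!r}")
            if rule.next not in self.states:
                raise ValueError(f"rule targets unknown state {rule.next!r}")

    @property
    def working_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != HALT)


@dataclass(frozen=True)
class TMConfiguration:
    """A finite tape, a 1-based head position and the current state."""

    tape: tuple[str, ...]
    head: int
    state: str

    def __post_init__(self) -> None:
        if not 1 <= self.head <= len(self.tape):
            raise ValueError(f"head {self.head} outside tape of length {len(self.tape)}")

    @property
    def tape_string(self) -> str:
        return "".join(self.tape)

    @classmethod
    def from_string(cls, tape: str, head: int, state: str) -> "TMConfiguration":
        return cls(tuple(tape), head, state)


def tm_step(machine: TuringMachine, config: TMConfiguration) -> TMConfiguration:
    """Apply one transition.  Pure: returns a new configuration.

    Raises :class:`HaltedError` on a halted configuration and
    :class:`TapeOverrunError` if the move would leave the tape.
    """
    if config.state == HALT:
        raise HaltedError("cannot step a halted configuration")
    symbol = config.tape[config.head - 1]
    rule = machine.table[(config.state, symbol)]
    tape = list(config.tape)
    tape[config.head - 1] = rule.write
    head = config.head + (1 if rule.move == "R" else -1)
    if not 1 <= head <= len(tape):
        raise TapeOverrunError(
            f"head moved to position {head} on a {len(tape)}-cell tape"
        )
    return TMConfiguration(tuple(tape), head, rule.next)


def tm_configurations(
    machine: TuringMachine, config: TMConfiguration, max_steps: int
) -> Iterator[TMConfiguration]:
    """Yield successive configurations after each step, up to ``max_steps``
    or the halt state.  Tape overrun propagates after the yielded prefix."""
    for _ in range(max_steps):
        if config.state == HALT:
            return
        config = tm_step(machine, config)
        yield config


def tm_run(
    machine: TuringMachine, config: TMConfiguration, max_steps: int
) -> tuple[TMConfiguration, bool, int]:
    """Iterate :func:`tm_step` until HALT or ``max_steps``.

    Returns ``(final configuration, halted, steps taken)``.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    steps = 0
    for cfg in tm_configurations(machine, config, max_steps):
        config = cfg
        steps += 1
    return config, config.state == HALT, steps


def count_max_consecutive(tape: tuple[str, ...] | str, symbol: str) -> int:
    """Length of the longest run of ``symbol`` on the tape (the busy-beaver
    score when counting 1s)."""
    if len(tape) == 0:
        raise ValueError("tape must be nonempty")
    best = current = 0
    for cell in tape:
        current = current + 1 if cell == symbol else 0
        best = max(best, current)
    return best


# ---------------------------------------------------------------------------
# the two demonstration machines
# ---------------------------------------------------------------------------

TAPE_LENGTH = 8

#: Where the Busy Beaver starts: all-blank 8-cell tape, head at position 3,
#: state A.
BUSY_BEAVER_START = TMConfiguration((BLANK,) * TAPE_LENGTH, 3, "A")


def busy_beaver_machine() -> TuringMachine:
    """The 3-state, 2-symbol busy-beaver champion (six 1s, Σ(3) ≥ 6).

    From :data:`BUSY_BEAVER_START` it halts after 14 steps with the tape
    reading ``01111110`` — six consecutive 1s flanked by 0s — without the
    head ever leaving the 8 cells.
    """
    rules = {
        ("A", "0"): TransitionRule("1", "R", "B"),
        ("A", "1"): TransitionRule("1", "R", HALT),
        ("B", "0"): TransitionRule("0", "R", "C"),
        ("B", "1"): TransitionRule("1", "R", "B"),
        ("C", "0"): TransitionRule("1", "L", "C"),
        ("C", "1"): TransitionRule("1", "L", "A"),
    }
    return TuringMachine(
        states=("A", "B", "C", HALT),
        alphabet=("0", "1"),
        table=rules,
        initial="A",
    )


#: Where the binary adder starts: head on the rightmost bit of the left
#: addend (position 3), in the first decrement state.
ADDER_INITIAL_STATE = "DEC3"
ADDER_INITIAL_HEAD = 3


def adder_start(left: int, right: int) -> TMConfiguration:
    """Initial adder configuration for two 3-bit addends: tape
    ``abc x 0 def`` with the head at position 3."""
    if not (0 <= left < 8 and 0 <= right < 8):
        raise ValueError("addends must be 3-bit numbers")
    tape = f"{left:03b}x0{right:03b}"
    return TMConfiguration.from_string(tape, ADDER_INITIAL_HEAD, ADDER_INITIAL_STATE)


def binary_adder_machine() -> TuringMachine:
    """A machine over alphabet {0, 1, x, y} adding two 3-bit binary numbers.

    The tape holds ``abc x 0def``: a 3-bit addend, the separator ``x``, and
    a 4-bit accumulator field initialized to ``0def``.  The machine loops:
    binary-decrement the left addend (borrow depth tracked in the DEC
    states), then walk right past ``x`` and binary-increment the
    accumulator at position 8, carrying leftward.  When the decrement finds
    the addend already zero (a borrow walks off its leftmost bit), the
    ZERO states restore the addend's zeros, FIN erases the separator and
    the machine halts with the tape reading ``0000ssss`` — the 4-bit sum.

    The symbol ``y`` completes the four-letter alphabet; no reachable
    transition emits it, and the table maps every (state, y) pair straight
    to HALT to stay total.
    """
    t: dict[tuple[str, str], TransitionRule] = {}
    # decrement the left addend; borrow depth is tracked in the state
    t[("DEC3", "1")] = TransitionRule("0", "R", "SEEK")
    t[("DEC3", "0")] = TransitionRule("1", "L", "DEC2")
    t[("DEC2", "1")] = TransitionRule("0", "R", "SEEK")
    t[("DEC2", "0")] = TransitionRule("1", "L", "DEC1")
    t[("DEC1", "1")] = TransitionRule("0", "R", "SEEK")
    # addend was 000: undo the borrow flips, erase x, halt
    t[("DEC1", "0")] = TransitionRule("0", "R", "ZERO2")
    t[("ZERO2", "1")] = TransitionRule("0", "R", "ZERO3")
    t[("ZERO3", "1")] = TransitionRule("0", "R", "FIN")
    t[("FIN", "x")] = TransitionRule("0", "R", HALT)
    # walk right: x is the landmark, then four cells to position 8
    for sym in "01":
        t[("SEEK", sym)] = TransitionRule(sym, "R", "SEEK")
    t[("SEEK", "x")] = TransitionRule("x", "R", "M3")
    for state, nxt in (("M3", "M2"), ("M2", "M1"), ("M1", "INC")):
        for sym in "01":
            t[(state, sym)] = TransitionRule(sym, "R", nxt)
    # increment the accumulator, carrying leftward
    t[("INC", "0")] = TransitionRule("1", "L", "RET")
    t[("INC", "1")] = TransitionRule("0", "L", "INC")
    # return to the rightmost addend bit
    for sym in "01":
        t[("RET", sym)] = TransitionRule(sym, "L", "RET")
    t[("RET", "x")] = TransitionRule("x", "L", "DEC3")

    states = ("DEC3", "DEC2", "DEC1", "ZERO2", "ZERO3", "FIN",
              "SEEK", "M3", "M2", "M1", "INC", "RET", HALT)
    alphabet = ("0", "1", "x", "y")
    # pad unreachable (state, symbol) pairs so the table is total
    for state in states[:-1]:
        for sym in alphabet:
            t.setdefault((state, sym), TransitionRule(sym, "R", HALT))
    return TuringMachine(states=states, alphabet=alphabet, table=t,
                         initial=ADDER_INITIAL_STATE)


def decode_adder_sum(tape: tuple[str, ...] | str) -> int:
    """Read the 4-bit accumulator (positions 5..8) of a halted adder tape."""
    return int("".join(tape[4:8]), 2)


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def machine_to_json(machine: TuringMachine) -> str:
    return json.dumps(
        {
            "states": list(machine.states),
            "alphabet": list(machine.alphabet),
            "blank": BLANK,
            "initial": machine.initial,
            "rules": [
                {"state": s, "read": r, "write": rule.write, "move": rule.move,
                 "next": rule.next}
                for (s, r), rule in sorted(machine.table.items())
            ],
        },
        indent=2,
    )


def machine_from_json(text: str) -> TuringMachine:
    data = json.loads(text)
    table = {
        (r["state"], r["read"]): TransitionRule(r["write"], r["move"], r["next"])
        for r in data["rules"]
    }
    return TuringMachine(
        states=tuple(data["states"]),
        alphabet=tuple(data["alphabet"]),
        table=table,
        initial=data["initial"],
    )


def config_to_json(config: TMConfiguration) -> str:
    return json.dumps(
        {"tape": config.tape_string, "head": config.head, "state": config.state}
    )


def config_from_json(text: str) -> TMConfiguration:
    data = json.loads(text)
    return TMConfiguration.from_string(data["tape"], int(data["head"]), data["state"])
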