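"""Fixture generation and human-readable run reports.

Provides seed-deterministic random Turing machines for the oracle-
equivalence sweeps (the property that makes the Turing-completeness claim
testable on more than two hand-built machines), plus plain-text execution
summaries in the row-per-step style of the demonstration figures.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Optional, Sequence

from .turing_ref import BLANK, HALT, TMConfiguration, TransitionRule, TuringMachine
from .virtual_platform import PlatformState
from .xdl_core import ExecutionTrace

_STATE_NAMES = tuple("ABCDEFGHIJKLMNO")  # up to 15 working states
_SYMBOLS = ("0", "1", "x", "y")


@dataclass(frozen=True)
class RandomMachineSpec:
    """Parameters of a random machine draw.  The seed fully determines the
    output; ``require_halt`` guarantees at least one rule targets HALT so
    the machine has a chance of terminating (no guarantee that it does)."""

    n_states: int
    n_symbols: int
    seed: int
    require_halt: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_states <= len(_STATE_NAMES):
            raise ValueError(f"n_states must be in 1..{len(_STATE_NAMES)}")
        if not 2 <= self.n_symbols <= len(_SYMBOLS):
            raise ValueError(f"n_symbols must be in 2..{len(_SYMBOLS)}")


def generate_machine(spec: RandomMachineSpec) -> TuringMachine:
    """Draw a total, seed-deterministic machine."""
    rng = random.Random(spec.seed)
    working = _STATE_NAMES[: spec.n_states]
    states = working + (HALT,)
    alphabet = _SYMBOLS[: spec.n_symbols]
    table: dict[tuple[str, str], TransitionRule] = {}
    for state in working:
        for symbol in alphabet:
            table[(state, symbol)] = TransitionRule(
                write=rng.choice(alphabet),
                move=rng.choice(("L", "R")),
                next=rng.choice(states),
            )
    if spec.require_halt and not any(r.next == HALT for r in table.values()):
        key = rng.choice(sorted(table))
        rule = table[key]
        table[key] = TransitionRule(rule.write, rule.move, HALT)
    return TuringMachine(states=states, alphabet=alphabet, table=table,
                         initial=working[0])


def blank_start(tape_length: int = 8, head: int = 3, state: str = "A") -> TMConfiguration:
    return TMConfiguration((BLANK,) * tape_length, head, state)


# ---------------------------------------------------------------------------
# decoded-sequence interchange (JSON lines)
# ---------------------------------------------------------------------------


def decoded_to_jsonl(decoded: Sequence[TMConfiguration]) -> str:
    return "\n".join(
        json.dumps(
            {"iteration": i, "state": c.state, "head": c.head, "tape": c.tape_string},
            sort_keys=True,
        )
        for i, c in enumerate(decoded)
    )


def decoded_from_jsonl(text: str) -> list[TMConfiguration]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        data = json.loads(line)
        out.append(
            TMConfiguration.from_string(data["tape"], int(data["head"]), data["state"])
        )
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*(\d+)\s+(\S+)\s+(\d+)\s+(\S+)\s*$")


def report(
    trace: ExecutionTrace,
    decoded: Sequence[TMConfiguration],
    platform: Optional[PlatformState] = None,
) -> str:
    """Plain-text execution summary: one row per machine step (iteration,
    state, head position, tape), then trace statistics and resource usage.

    The rows parse back with :func:`parse_report_rows`.
    """
    lines = ["iter state head tape", "---- ----- ---- ----"]
    for i, cfg in enumerate(decoded):
        lines.append(f"{i:>4} {cfg.state:>5} {cfg.head:>4} {cfg.tape_string}")
    if decoded:
        final = decoded[-1]
        lines.append("")
        lines.append(f"final tape: {final.tape_string} (state {final.state})")

    executed = sum(1 for ev in trace.events if ev.kind == "step_executed")
    skipped = sum(1 for ev in trace.events if ev.kind == "step_skipped")
    measured = sum(1 for ev in trace.events if ev.kind == "measurement")
    loops = sum(1 for ev in trace.events if ev.kind == "loop_iteration")
    lines.append("")
    lines.append(
        f"trace: {executed} executed, {skipped} skipped, {measured} measurements,"
        f" {loops} loop iterations, status={trace.status}"
    )

    consumed: dict[str, Decimal] = {}
    for ev in trace.events:
        if ev.kind == "step_executed" and ev.name == "Add" and ev.params:
            params = dict(ev.params)
            reagent = params.get("reagent", "?")
            consumed[reagent] = consumed.get(reagent, Decimal(0)) + Decimal(
                params.get("volume", "0")
            )
    if consumed:
        usage = ", ".join(f"{r}: {v} mL" for r, v in sorted(consumed.items()))
        lines.append(f"reagents consumed: {usage}")
    if platform is not None:
        waste = platform.vessels[platform.waste_id].total_volume()
        lines.append(f"waste collected: {waste} mL")
    return "\n".join(lines) + "\n"


def parse_report_rows(text: str) -> list[TMConfiguration]:
    """Recover the configuration rows from a report (round-trip check)."""
    out = []
    for line in text.splitlines():
        m = _ROW_RE.match(line)
        if m:
            out.append(
                TMConfiguration.from_string(m.group(4), int(m.group(3)), m.group(2))
            )
    return out
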