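"""Compile Turing machines into conditional-XDL programs on colored vials.

The bridge between the abstract machine and the liquid-handling rig:

* :class:`ColorEncoding` maps tape symbols to vial colors (blank is always
  the empty/white vial) and states to ordered color pairs for the two state
  vials — base-4 over (white, orange, blue, green), so up to 16 states.
* :func:`encode_configuration` / :func:`decode_configuration` translate
  between a machine configuration and a platform state: tape vial *i* holds
  the color of ``tape[i]``, the head row holds a single orange vial at the
  head position, and the two state vials hold the state's color pair.
* :func:`compile_machine` emits the nested-blueprint document: a
  ``TuringMachine`` Repeat loop over ``ReadState``, ``ReadTape`` and
  ``LookUpTable``, with one guarded blueprint per transition rule.

The dialect has no integer variables — only booleans written by Measure
steps — so every piece of position logic is unrolled over the N tape cells
behind ``head at i`` guards, a Θ(N) blow-up per rule that is the price of
the dialect's austerity.

Moving the head off the finite tape is compiled, not prevented: the emitted
document references head vials 0 and N+1, which exist in the document's
declarations but not on the platform, so an off-tape move surfaces at run
time as a platform error — the same failure mode as the physical rig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import virtual_platform as vp
from . import xdl_core as xc
from .turing_ref import (
    BLANK,
    HALT,
    TMConfiguration,
    TuringMachine,
    tm_configurations,
    TapeOverrunError,
)
from .virtual_platform import PlatformState, WHITE

COLOR_ORDER = (WHITE, "orange", "blue", "green")
HEAD_COLOR = "orange"
MAX_STATES = len(COLOR_ORDER) ** 2  # two state vials, four colors each


class EncodingError(Exception):
    """A symbol or state cannot be represented in the color encoding."""


class DecodeError(Exception):
    """The platform state is not a valid encoding of any configuration."""


@dataclass(frozen=True)
class ColorEncoding:
    """Symbol↔color and state↔vial-pair mapping."""

    symbol_to_color: dict[str, str]
    state_to_pair: dict[str, tuple[str, str]]
    tape_length: int

    @property
    def head_row_length(self) -> int:
        return self.tape_length

    def __post_init__(self) -> None:
        colors = set(self.symbol_to_color.values())
        if len(colors) != len(self.symbol_to_color):
            raise EncodingError("symbol-to-color mapping must be injective")
        if not colors <= set(COLOR_ORDER):
            raise EncodingError(f"colors must come from {COLOR_ORDER}")
        if self.symbol_to_color.get(BLANK) != WHITE:
            raise EncodingError("the blank symbol must map to the empty (white) vial")
        pairs = set(self.state_to_pair.values())
        if len(pairs) != len(self.state_to_pair):
            raise EncodingError("state-to-pair mapping must be injective")

    @property
    def color_to_symbol(self) -> dict[str, str]:
        return {c: s for s, c in self.symbol_to_color.items()}

    @property
    def pair_to_state(self) -> dict[tuple[str, str], str]:
        return {p: s for s, p in self.state_to_pair.items()}

    @classmethod
    def for_machine(cls, machine: TuringMachine, tape_length: int = 8) -> "ColorEncoding":
        """The canonical encoding of a machine.

        Symbols take colors in alphabet order with the blank forced to
        white (for the demonstration alphabet ``0,1,x,y`` this gives
        0↦white, 1↦orange, x↦blue, y↦green).  Non-halt states are numbered
        in declaration order and the index is written base-4 over
        ``COLOR_ORDER`` into the two vials; HALT always takes the last code
        (green, green) regardless of how many states the machine has.
        """
        symbols = [BLANK] + [s for s in machine.alphabet if s != BLANK]
        if len(symbols) > len(COLOR_ORDER):
            raise EncodingError(
                f"alphabet of {len(symbols)} symbols exceeds the {len(COLOR_ORDER)}"
                " available colors"
            )
        symbol_to_color = {s: COLOR_ORDER[i] for i, s in enumerate(symbols)}
        working = machine.working_states
        if len(working) > MAX_STATES - 1:
            raise EncodingError(
                f"{len(working)} states exceed the {MAX_STATES - 1} encodable"
                " non-halt states"
            )
        state_to_pair = {
            s: (COLOR_ORDER[i // 4], COLOR_ORDER[i % 4]) for i, s in enumerate(working)
        }
        state_to_pair[HALT] = (COLOR_ORDER[3], COLOR_ORDER[3])
        return cls(symbol_to_color, state_to_pair, tape_length)


# vessel naming on both the platform and in emitted documents
def _tape_vial(i: int) -> str:
    return f"tape_{i}"


def _head_vial(i: int) -> str:
    return f"head_{i}"


STATE_VIALS = ("state_1", "state_2")


# ---------------------------------------------------------------------------
# configuration <-> platform state
# ---------------------------------------------------------------------------


def encode_configuration(
    config: TMConfiguration,
    encoding: ColorEncoding,
    platform: Optional[PlatformState] = None,
) -> PlatformState:
    """Realize a configuration as liquid: write the tape, head marker and
    state pair onto a (fresh, by default) platform by dispensing from the
    stock flasks."""
    if len(config.tape) != encoding.tape_length:
        raise EncodingError(
            f"tape of length {len(config.tape)} does not fit an"
            f" {encoding.tape_length}-cell rig"
        )
    if platform is None:
        platform = vp.default_platform(encoding.tape_length)
    for i, symbol in enumerate(config.tape, start=1):
        try:
            color = encoding.symbol_to_color[symbol]
        except KeyError:
            raise EncodingError(f"symbol {symbol!r} is not encodable") from None
        if color != WHITE:
            vp.add_from_stock(platform, color, _tape_vial(i))
    vp.add_from_stock(platform, HEAD_COLOR, _head_vial(config.head))
    try:
        pair = encoding.state_to_pair[config.state]
    except KeyError:
        raise EncodingError(f"state {config.state!r} is not encodable") from None
    for vial, color in zip(STATE_VIALS, pair):
        if color != WHITE:
            vp.add_from_stock(platform, color, vial)
    return platform


def decode_configuration(
    platform: PlatformState, encoding: ColorEncoding
) -> TMConfiguration:
    """Read the platform back into a configuration (inverse of
    :func:`encode_configuration`)."""
    color_to_symbol = encoding.color_to_symbol
    tape = []
    for i in range(1, encoding.tape_length + 1):
        color = vp.sense(platform, _tape_vial(i), "color").value
        if color not in color_to_symbol:
            raise DecodeError(f"tape vial {i} reads unmapped color {color!r}")
        tape.append(color_to_symbol[color])
    head_positions = []
    for i in range(1, encoding.head_row_length + 1):
        color = vp.sense(platform, _head_vial(i), "color").value
        if color == HEAD_COLOR:
            head_positions.append(i)
        elif color != WHITE:
            raise DecodeError(f"head vial {i} reads foreign color {color!r}")
    if len(head_positions) != 1:
        raise DecodeError(
            f"head row must hold exactly one {HEAD_COLOR} vial, found"
            f" {len(head_positions)}"
        )
    pair = tuple(vp.sense(platform, vial, "color").value for vial in STATE_VIALS)
    state = encoding.pair_to_state.get(pair)  # type: ignore[arg-type]
    if state is None:
        raise DecodeError(f"state vials read unrecognized pair {pair}")
    return TMConfiguration(tuple(tape), head_positions[0], state)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


@dataclass
class CompiledProgram:
    """A Turing machine compiled to an XDL document, plus everything needed
    to run and verify it."""

    document: xc.XDLDocument
    encoding: ColorEncoding
    machine: TuringMachine
    initial: Optional[TMConfiguration] = None
    cap: int = 10_000
    metadata: dict = field(default_factory=dict)


def _sid_state(state: str, vial: int) -> str:
    return f"st_{state}_{vial}"


def _sid_head(i: int) -> str:
    return f"h_{i}"


def _sid_read(i: int, symbol: str) -> str:
    return f"rd_{i}_{symbol}"


def _rule_blueprint_id(state: str, symbol: str) -> str:
    return f"Rule_{state}_{symbol}"


def _measure_color(step_id: str, vessel: str, color: str) -> xc.Step:
    return xc.Step(
        "Measure",
        params={"vessel": vessel, "quantity": "color", "comparison": "equal",
                "value": color},
        step_id=step_id,
    )


def _read_state_blueprint(machine: TuringMachine, enc: ColorEncoding) -> xc.Blueprint:
    steps = []
    for state in machine.states:
        pair = enc.state_to_pair[state]
        for vial_idx, (vial, color) in enumerate(zip(STATE_VIALS, pair), start=1):
            steps.append(_measure_color(_sid_state(state, vial_idx), vial, color))
    return xc.Blueprint("ReadState", (), steps)


def _read_tape_blueprint(machine: TuringMachine, enc: ColorEncoding) -> xc.Blueprint:
    steps = []
    n = enc.tape_length
    for i in range(1, n + 1):
        steps.append(_measure_color(_sid_head(i), _head_vial(i), HEAD_COLOR))
    for i in range(1, n + 1):
        for symbol in machine.alphabet:
            steps.append(
                _measure_color(
                    _sid_read(i, symbol), _tape_vial(i), enc.symbol_to_color[symbol]
                )
            )
    return xc.Blueprint("ReadTape", (), steps)


def _rule_blueprint(
    state: str, symbol: str, machine: TuringMachine, enc: ColorEncoding
) -> xc.Blueprint:
    """The action triplet of one look-up-table row, unrolled over the tape:
    Write (empty the tape vial under the head, dispense the write color),
    Move (relocate the head marker one vial left/right), Switch (set the
    state vials to the next state's pair)."""
    rule = machine.table[(state, symbol)]
    n = enc.tape_length
    delta = 1 if rule.move == "R" else -1
    write_color = enc.symbol_to_color[rule.write]
    steps: list[xc.Step] = []
    for i in range(1, n + 1):  # Write
        guard = _sid_head(i)
        steps.append(
            xc.Step("EmptyToWaste", params={"vessel": _tape_vial(i)}, condition=guard)
        )
        if write_color != WHITE:
            steps.append(
                xc.Step(
                    "Add",
                    params={"vessel": _tape_vial(i), "reagent": write_color,
                            "volume": "1.0"},
                    condition=guard,
                )
            )
    for i in range(1, n + 1):  # Move
        guard = _sid_head(i)
        steps.append(
            xc.Step("EmptyToWaste", params={"vessel": _head_vial(i)}, condition=guard)
        )
        steps.append(
            xc.Step(
                "Add",
                params={"vessel": _head_vial(i + delta), "reagent": HEAD_COLOR,
                        "volume": "1.0"},
                condition=guard,
            )
        )
    pair = enc.state_to_pair[rule.next]  # Switch
    for vial, color in zip(STATE_VIALS, pair):
        steps.append(xc.Step("EmptyToWaste", params={"vessel": vial}))
        if color != WHITE:
            steps.append(
                xc.Step(
                    "Add", params={"vessel": vial, "reagent": color, "volume": "1.0"}
                )
            )
    return xc.Blueprint(_rule_blueprint_id(state, symbol), (), steps)


def _rule_condition(state: str, symbol: str, enc: ColorEncoding) -> str:
    """"State is S and the symbol under the head is a": the state-pair
    booleans conjoined with a disjunction over tape positions, since only
    per-position read booleans exist in the dialect."""
    position_terms = " or ".join(
        f"{_sid_head(i)} and {_sid_read(i, symbol)}"
        for i in range(1, enc.tape_length + 1)
    )
    return (
        f"{_sid_state(state, 1)} and {_sid_state(state, 2)} and ({position_terms})"
    )


def _halt_exit_condition() -> str:
    return f"not ({_sid_state(HALT, 1)} and {_sid_state(HALT, 2)})"


def compile_machine(
    machine: TuringMachine,
    encoding: Optional[ColorEncoding] = None,
    initial: Optional[TMConfiguration] = None,
    cap: int = 10_000,
) -> CompiledProgram:
    """Compile a machine's look-up table into a nested-blueprint document.

    Structure: the main procedure invokes blueprint ``TuringMachine``,
    which measures the state once (the loop guard must have stored values
    before its first evaluation) and then Repeats ``[ReadState; ReadTape;
    LookUpTable]`` while the state vials do not read HALT.  All booleans
    are re-measured on every iteration; re-executed Measures overwrite
    their entries.

    Emitted step counts (N = tape length, A = alphabet size, S = number of
    states including HALT): ``ReadState`` holds 2S Measures, ``ReadTape``
    N + N·A Measures, each rule blueprint N·(1 + [write ≠ blank]) + 2N + 2 +
    (non-white colors in the next state's pair) steps, ``LookUpTable`` one
    guarded invocation per rule, ``TuringMachine`` 2 + 3 steps and the main
    procedure 1 — Θ(|rules|·N) overall.  :func:`expected_step_count` states
    the same formula in code.
    """
    if encoding is None:
        encoding = ColorEncoding.for_machine(machine)
    n = encoding.tape_length
    for state in machine.states:
        if state not in encoding.state_to_pair:
            raise EncodingError(f"state {state!r} missing from encoding")
    for symbol in machine.alphabet:
        if symbol not in encoding.symbol_to_color:
            raise EncodingError(f"symbol {symbol!r} missing from encoding")

    blueprints: dict[str, xc.Blueprint] = {}
    for bp in (_read_state_blueprint(machine, encoding),
               _read_tape_blueprint(machine, encoding)):
        blueprints[bp.id] = bp

    lut_steps = []
    for (state, symbol) in sorted(machine.table):
        bp = _rule_blueprint(state, symbol, machine, encoding)
        blueprints[bp.id] = bp
        lut_steps.append(
            xc.Step(bp.id, condition=_rule_condition(state, symbol, encoding))
        )
    blueprints["LookUpTable"] = xc.Blueprint("LookUpTable", (), lut_steps)

    loop = xc.Step(
        "Repeat",
        params={"max_iterations": str(cap)},
        condition=_halt_exit_condition(),
        children=[xc.Step("ReadState"), xc.Step("ReadTape"), xc.Step("LookUpTable")],
    )
    blueprints["TuringMachine"] = xc.Blueprint(
        "TuringMachine", (), [xc.Step("ReadState"), loop]
    )

    vessels = (
        [_tape_vial(i) for i in range(1, n + 1)]
        + [_head_vial(i) for i in range(0, n + 2)]  # 0 and N+1 exist only on paper
        + list(STATE_VIALS)
    )
    reagents = {c: c for c in vp.SOLUTION_COLORS}
    doc = xc.XDLDocument(
        reagents=reagents,
        vessels=vessels,
        blueprints=blueprints,
        main=[xc.Step("TuringMachine")],
    )
    xc.validate_document(doc)
    return CompiledProgram(
        document=doc,
        encoding=encoding,
        machine=machine,
        initial=initial,
        cap=cap,
        metadata={
            "tape_length": n,
            "cap": cap,
            "initial": None
            if initial is None
            else {"tape": initial.tape_string, "head": initial.head,
                  "state": initial.state},
        },
    )


def _count_steps(steps: list[xc.Step]) -> int:
    return sum(1 + _count_steps(s.children) for s in steps)


def compiled_step_count(program: CompiledProgram) -> int:
    """Number of Step elements actually emitted across the whole document."""
    doc = program.document
    total = _count_steps(doc.main)
    for bp in doc.blueprints.values():
        total += _count_steps(bp.steps)
    return total


def expected_step_count(machine: TuringMachine, encoding: ColorEncoding) -> int:
    """The counting formula the compiler promises (see
    :func:`compile_machine`); Θ(|rules| × N)."""
    n = encoding.tape_length
    n_states = len(machine.states)
    n_symbols = len(machine.alphabet)
    total = 2 * n_states  # ReadState
    total += n + n * n_symbols  # ReadTape
    for rule in machine.table.values():
        write_steps = n * (1 + (encoding.symbol_to_color[rule.write] != WHITE))
        move_steps = 2 * n
        pair = encoding.state_to_pair[rule.next]
        switch_steps = 2 + sum(1 for c in pair if c != WHITE)
        total += write_steps + move_steps + switch_steps
    total += len(machine.table)  # LookUpTable invocations
    total += 2 + 3  # TuringMachine blueprint: ReadState, Repeat and its body
    total += 1  # main procedure
    return total


# ---------------------------------------------------------------------------
# running compiled programs
# ---------------------------------------------------------------------------

#: Worst-case stock draw per loop iteration and color: one tape write, one
#: head move, two state-vial writes.
_ML_PER_ITERATION = 4


def _sized_platform(encoding: ColorEncoding, cap: int) -> PlatformState:
    stock = _ML_PER_ITERATION * (cap + 1) + encoding.tape_length + 3
    return vp.default_platform(encoding.tape_length, stock_volume=stock)


def run_compiled(
    program: CompiledProgram,
    platform: Optional[PlatformState] = None,
    initial: Optional[TMConfiguration] = None,
) -> tuple[xc.ExecutionTrace, list[TMConfiguration]]:
    """Execute a compiled program on the virtual platform and decode the
    vials back after every loop iteration.

    Returns the raw execution trace and the decoded configuration sequence,
    whose first element is the (decoded) initial configuration.  The loop's
    final pass — the one in which ReadState discovers the HALT pair and no
    rule fires — changes nothing and is not appended.  A decode failure
    mid-run propagates: it flags a compiler bug, not a program outcome.
    """
    initial = initial or program.initial
    if initial is None:
        raise ValueError("no initial configuration given")
    if platform is None:
        platform = _sized_platform(program.encoding, program.cap)
    encode_configuration(initial, program.encoding, platform)
    decoded = [decode_configuration(platform, program.encoding)]

    def on_iteration(_: int) -> None:
        if decoded[-1].state != HALT:
            decoded.append(decode_configuration(platform, program.encoding))

    trace = xc.execute_procedure(
        program.document,
        platform,
        limits=xc.ExecutionLimits(max_iterations=program.cap),
        iteration_hook=on_iteration,
    )
    return trace, decoded


# ---------------------------------------------------------------------------
# oracle equivalence (the Turing-completeness check)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of comparing a compiled run against the reference
    interpreter.  ``outcome`` is one of ``halted``, ``cap``, ``overrun``."""

    equivalent: bool
    reference: tuple[TMConfiguration, ...]
    compiled: tuple[TMConfiguration, ...]
    reference_outcome: str
    compiled_outcome: str


def _reference_sequence(
    machine: TuringMachine, initial: TMConfiguration, cap: int
) -> tuple[tuple[TMConfiguration, ...], str]:
    seq = [initial]
    try:
        for cfg in tm_configurations(machine, initial, cap):
            seq.append(cfg)
    except TapeOverrunError:
        return tuple(seq), "overrun"
    if seq[-1].state == HALT:
        return tuple(seq), "halted"
    return tuple(seq), "cap"


_STATUS_TO_OUTCOME = {
    xc.HALT_COMPLETED: "halted",
    xc.HALT_CAP: "cap",
    xc.HALT_PLATFORM_ERROR: "overrun",
}


def verify_machine(
    machine: TuringMachine,
    initial: TMConfiguration,
    cap: int = 200,
    encoding: Optional[ColorEncoding] = None,
) -> VerificationResult:
    """Run a machine both ways — reference interpreter and compiled program
    on the virtual platform — and compare the configuration sequences
    exactly.  This is the simulation-soundness check: identical sequences
    for arbitrary machines are what make the chemical system Turing
    complete."""
    program = compile_machine(machine, encoding=encoding, initial=initial, cap=cap)
    ref_seq, ref_outcome = _reference_sequence(machine, initial, cap)
    trace, decoded = run_compiled(program)
    if decoded and decoded[-1].state == HALT:
        # the machine halted; with the halt on the very last allowed
        # iteration the loop never gets its confirming pass, so the trace
        # alone would say "cap"
        compiled_outcome = "halted"
    else:
        compiled_outcome = _STATUS_TO_OUTCOME.get(trace.status, trace.status)
    equivalent = (
        tuple(decoded) == ref_seq and compiled_outcome == ref_outcome
    )
    return VerificationResult(
        equivalent=equivalent,
        reference=ref_seq,
        compiled=tuple(decoded),
        reference_outcome=ref_outcome,
        compiled_outcome=compiled_outcome,
    )
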