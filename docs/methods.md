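# Methods

## The dialect and its semantics

The conditional-XDL dialect implemented in `xdl_core` has seven step kinds:
`Add`, `Transfer`, `EmptyToWaste`, `Wait`, `Measure`, `Repeat`, and
blueprint invocation (an element named by the blueprint's id). The design
choices that fix the semantics:

* **Conditions guard execution only.** A `condition` decides whether a step
  runs; there are no arithmetic or string variables anywhere in the
  dialect. The only mutable program state is the boolean store written by
  `Measure` steps. This austerity is deliberate: it is the smallest
  extension of a linear unit-operation language that yields universality,
  and it is what forces the compiler's fully unrolled design.
* **Unset variables are errors, never false.** A condition referencing a
  step_id that no `Measure` has written aborts the run. A silent default
  would mask a mis-wired look-up table, which is precisely the class of bug
  the equivalence tests exist to catch.
* **Evaluation is total, not short-circuiting**, so the unset-variable
  error cannot be hidden by an operand that already decides the result.
* **`Repeat` is continue-while**: the condition is re-evaluated before
  every iteration (so an already-satisfied exit gives zero iterations), and
  every loop carries an iteration cap (attribute `max_iterations`, default
  10,000 from `ExecutionLimits`). A cap hit is recorded as a distinct halt
  reason, never as silent success — whether an arbitrary program halts is
  undecidable, so a supervisory time-out is the only honest option.
* **Comparison boundaries**: `less_than`/`greater_than` are strict,
  `between` is inclusive on both ends ("below 50 °C" excludes 50;
  "between 4 and 9" includes both). Colors support only
  `equal`/`not_equal`.
* **step_ids are unique per document.** Re-executing the same `Measure`
  inside a loop overwrites its entry — overwrite semantics are what let a
  fixed set of booleans track an evolving machine configuration.
* **Blueprints cannot recurse** (the call graph must be acyclic); looping
  power lives solely in `Repeat`. Parameter binding is by exact value
  substitution of formal names in step parameters.

Execution produces a JSON-lines trace (`step_executed`, `step_skipped`,
`measurement`, `loop_iteration`, `halt`) whose terminal event distinguishes
`completed`, `iteration_cap`, `platform_error` and `runtime_error`; the CLI
maps these to exit codes 0/4/3/3 and document validation failures to 2.

## The virtual platform

`virtual_platform` models vessels with colored contents, three stock
flasks, an unbounded waste, and a pump/valve backbone graph (three pumps,
five valves in the default rig) through which reachability is checked.
Numerical choices:

* **Exact volume accounting** with `decimal.Decimal`, so global
  conservation is asserted with equality, not tolerances, over thousands of
  operations.
* **Transactionality** is implemented by checking every precondition before
  the first mutation; a failed operation leaves the state bit-identical.
* **Camera floor**: a vial below 0.1 mL total reads `white`. The unit write
  volume is 1.0 mL and vial capacity 10 mL — arbitrary but fixed
  conventions; every result in the package is invariant to the volume
  scale.
* **No color mixing**: the dominant solution color by volume wins, ties
  broken by lexicographic label. The compiled programs always empty a vial
  before writing, so mixtures only arise under faults; the deterministic
  tie-break keeps traces reproducible.
* There is no fluid dynamics, no kinetics, and no image processing; pH and
  temperature are settable attributes read by the virtual probes.

## The compiler

`tm_compiler` encodes a configuration as liquid (tape symbols to colors
with blank ↦ white; head marker orange; state index written base-4 over
(white, orange, blue, green) into the two state vials, `HALT` fixed at
(green, green)) and emits the nested-blueprint document:

```
Procedure:      TuringMachine
TuringMachine:  ReadState; Repeat[not (st_HALT_1 and st_HALT_2)]
                  { ReadState; ReadTape; LookUpTable }
ReadState:      2 color Measures per state (the two state vials)
ReadTape:       8 head Measures (h_i) + 8×|alphabet| tape Measures (rd_i_a)
LookUpTable:    per rule (q,a): invoke Rule_q_a with condition
                st_q_1 and st_q_2 and (h_1 and rd_1_a or … or h_8 and rd_8_a)
Rule_q_a:       Write (empty+dispense per cell, guarded by h_i),
                Move (marker to i±1, guarded by h_i), Switch (state vials)
```

Design decisions worth recording:

* **One extra ReadState precedes the loop** so the exit condition has
  stored values before its first evaluation.
* **Per-position read booleans.** Tape reads get per-cell step_ids
  (`rd_3_1`), measured unguarded at every cell each iteration, and rule
  selection conjoins the state pair with a disjunction over cells. A single
  shared "read is a" boolean would need either duplicate step_ids or lazy
  evaluation, both of which the dialect's semantics forbid.
* **The exit check lags by one iteration**: the loop condition sees the
  state booleans measured at the *start* of the previous iteration, so
  after the halting step the loop runs one discovery pass in which
  ReadState finds the HALT pair and no rule fires. That pass changes
  nothing and is excluded from the decoded sequence, which therefore equals
  the reference interpreter's, step for step.
* **Guards are frozen booleans.** Rule bodies mutate the vials they are
  guarded on, but conditions read the store, not the sensors, so exactly
  one rule fires per iteration and the Write→Move→Switch order within it is
  safe.
* **Off-tape moves are compiled, not clamped.** Head vials 0 and 9 are
  declared in the document (validation requires declared vessels) but do
  not exist on the platform, so a move off the finite tape surfaces as a
  runtime platform error — the same failure mode as a physical rig, and the
  reference interpreter's tape-overrun error is matched against it in the
  equivalence check.
* **Emitted size** is Θ(|rules| × N); `expected_step_count` states the
  exact formula and is asserted against the actual document.
* **Stock sizing.** The default rig carries 50 mL per stock — ample for the
  Busy Beaver, whose full compiled run draws 31 mL of orange. `run_compiled`
  provisions stocks at 4·(cap+1) + N + 3 mL (the worst-case draw per
  iteration is one tape write, one head move and two state writes) so that
  long capped runs are never resource-limited; stock depletion remains a
  first-class platform error for restricted configurations.

## Fixture machines

The paper-style demonstrations pin behavior by output, and the transition
tables here are validated against those outputs rather than transcribed:

* **Busy Beaver**: the classical 3-state, 2-symbol champion
  (A0→1RB, A1→1R HALT, B0→0RC, B1→1RB, C0→1LC, C1→1LA). From a blank
  8-cell tape, head at position 3, state A, it halts in 14 steps with
  `01111110` and never leaves the tape; the tests assert the halting tape,
  the score of six and step-for-step agreement between both execution
  paths.
* **Binary adder**: a 12-working-state construction that repeatedly
  binary-decrements the 3-bit addend left of the separator `x` (borrow
  depth tracked in the `DEC` states) and binary-increments the 4-bit
  accumulator at positions 5–8 (carry propagating leftward, which provably
  never reaches the separator for 3-bit inputs). When the addend is
  exhausted the `ZERO` states restore its zeros, `FIN` erases `x`, and the
  machine halts with the sum in the right field. The head starts at
  position 3 in state `DEC3`; correctness is checked exhaustively over all
  64 input pairs (longest run: 84 steps). The fourth symbol `y` completes
  the demonstration alphabet but no reachable transition uses it; its table
  rows map to HALT only to keep the table total.

## Random-machine sweeps

`fixtures.generate_machine` draws total, seed-deterministic machines (≤ 15
working states, ≤ 4 symbols, at least one rule targeting HALT). Random
machines may legitimately never halt and frequently run off the 8-cell
tape, so equivalence is compared on *bounded* runs: sequences must match
exactly up to HALT, the iteration cap (200 in the sweeps), or a tape
overrun, and the outcome class must agree. One edge is classified
deliberately: a machine that halts on the very last allowed iteration is
"halted" even though the loop never got its confirming pass.

## What the tests do and do not show

All execution is virtual. The digital twin preserves the *logical* physics
that the construction relies on — conservation, reachability, sensor
determinism, the color gamut, finite stocks — and the test suite pins
exactly those invariants plus bit-level equivalence with the reference
interpreter. It deliberately does not model optics, mixing dynamics,
droplet loss or sensor noise, so passing tests certify the construction
and its compiler, not the robustness of any particular physical rig.

Problem sizes used throughout: 8-cell tapes (matching the demonstration
strings), iteration cap 200 for sweeps, 50-machine equivalence sweeps in
the acceptance tests and 12 in the unit tests, 1,000-operation conservation
runs — sizes chosen so the whole suite pins every claim while running in
seconds.
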