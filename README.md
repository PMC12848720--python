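# chemturing

A Turing-complete chemical programming stack, in software: a conditional
dialect of XDL (the XML-based Chemical Description Language), a virtual
Chemputer-style liquid-handling platform to execute it on, and a compiler
that turns any Turing-machine transition table into a nested-blueprint XDL
program running on vials of colored liquid.

The package is for people working on chemical programming languages and
autonomous synthesis platforms who want an executable, testable model of
*why* conditional execution makes such a platform universal — and a harness
for experimenting with the construction (different machines, encodings,
platform topologies) without hardware.

## The model

A Turing machine is a head on a tape of cells, driven by a look-up table
mapping (state *q*, read symbol *a*) to (write symbol *w*, move *d* ∈
{L, R}, next state *q′*); it terminates on reaching the state `HALT`. The
chemical realization (here, virtual) uses:

* a row of N = 8 **tape vials** — each symbol of a ≤ 4-letter alphabet is a
  vial color: empty/white, orange, blue, green;
* a row of 8 **head vials**, exactly one holding orange to mark the head
  position;
* two **state vials** whose ordered color pair encodes the state base-4
  (up to 16 states; `HALT` is always the pair (green, green));
* three reagent **stock flasks**, a **waste** container, and a backbone of
  three pumps and five valves connecting everything.

The XDL dialect contributes exactly enough logic to drive it: `Measure`
steps read a sensor, compare, and store a boolean under a unique `step_id`;
any step may carry a `condition` — a boolean expression over stored
step_ids (`not` > `and` > `or`) — and is skipped when it is false; `Repeat`
loops continue while their condition holds, bounded by an iteration cap.
There are no numeric variables, so the compiler unrolls all position logic
over the 8 cells behind `head at i` guards: per transition rule it emits a
guarded blueprint of Write (empty the tape vial under the head, dispense
the write color), Move (relocate the head marker), Switch (reset the state
vials), selected by a condition of the form
`st_q_1 and st_q_2 and (h_1 and rd_1_a or … or h_8 and rd_8_a)`.

Two classical programs demonstrate the construction:

* **Busy Beaver** — a 3-state, 2-symbol machine started on a blank tape
  (head at position 3, state A) halts with `01111110`: six consecutive 1s,
  witnessing Σ(3) ≥ 6.
* **Binary adder** — over alphabet {0, 1, x, y}, tape `abc x 0def` holds two
  3-bit numbers around the separator `x`; from `101x0011` (5 + 3) the
  machine halts on `00001000`, the sum 8 in the 4-bit field.

The soundness claim is checked the way Turing completeness is classically
argued — by simulation: for every test machine, the platform state decoded
after each loop iteration must equal the reference interpreter's
configuration sequence *exactly*, step for step.

## Worked example

```python
import chemturing as ct
from chemturing.tm_compiler import compile_machine, run_compiled
from chemturing.fixtures import report

bb = ct.busy_beaver_machine()
program = compile_machine(bb, initial=ct.BUSY_BEAVER_START, cap=100)
trace, decoded = run_compiled(program)
print(report(trace, decoded))
```

prints

```
iter state head tape
---- ----- ---- ----
   0     A    3 00000000
   1     B    4 00100000
   2     C    5 00100000
   3     C    4 00101000
   4     C    3 00111000
   5     A    2 00111000
   6     B    3 01111000
   7     B    4 01111000
   8     B    5 01111000
   9     B    6 01111000
  10     C    7 01111000
  11     C    6 01111010
  12     C    5 01111110
  13     A    4 01111110
  14  HALT    5 01111110

final tape: 01111110 (state HALT)

trace: 156 executed, 454 skipped, 488 measurements, 15 loop iterations, status=completed
reagents consumed: blue: 6.0 mL, green: 2.0 mL, orange: 31.0 mL
```

Each row is one machine step, decoded from the vials after the
corresponding loop iteration of the compiled program (row 0 is the initial
encoding). The tape string reads the 8 tape vials left to right (white = 0,
orange = 1): the run ends in `HALT` with six consecutive 1s. The trace
summary counts the XDL-level events behind those 14 steps — every skipped
step is a guarded branch the look-up table did not take — and the reagent
totals are the liquid the run actually dispensed.

The same flow from the shell:

```bash
chemturing generate --states 3 --symbols 2 --seed 7 -o m.json   # random machine
chemturing compile m.json -o m.xdl
chemturing run m.xdl --machine m.json --trace t.jsonl --decoded d.jsonl
chemturing report t.jsonl d.jsonl
chemturing verify m.json          # compile + run + compare against the oracle
```

`verify` exits 0 only when the compiled run and the reference interpreter
agree configuration-for-configuration.

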