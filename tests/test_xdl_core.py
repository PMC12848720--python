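"""Document model, validation, measurement semantics and the executor."""

from decimal import Decimal

import pytest

from chemturing.virtual_platform import add_from_stock, default_platform
from chemturing.xdl_core import (
    ExecutionLimits,
    ExecutionTrace,
    MeasureSpec,
    TraceEvent,
    VariableStore,
    XDLValidationError,
    execute_measure,
    execute_procedure,
    parse_xdl,
    serialize_xdl,
)

MINIMAL = """
<XDL>
  <Reagents><Reagent id="quencher" color="blue"/></Reagents>
  <Vessels><Vessel id="reactor"/></Vessels>
  <Procedure>
    <Measure step_id="C" vessel="reactor" quantity="color" comparison="equal"
             value="orange"/>
    <Add vessel="reactor" reagent="quencher" volume="1.0" condition="C"/>
  </Procedure>
</XDL>
"""


def branching_doc():
    """The quench-or-transfer program: measure a color, quench (add reagent)
    if it matches, transfer the mixture onward if it does not."""
    return parse_xdl(
        """
        <XDL>
          <Reagents><Reagent id="quencher" color="blue"/></Reagents>
          <Vessels><Vessel id="reactor"/><Vessel id="flask"/></Vessels>
          <Procedure>
            <Measure step_id="C" vessel="reactor" quantity="color"
                     comparison="equal" value="orange"/>
            <Add vessel="reactor" reagent="quencher" volume="1.0" condition="C"/>
            <Transfer from_vessel="reactor" to_vessel="flask" volume="0.5"
                      condition="not C"/>
          </Procedure>
        </XDL>
        """
    )


def branch_platform(color):
    platform = default_platform()
    # reuse two tape vials as reactor/flask by aliasing ids via config-free path
    platform.vessels["reactor"] = platform.vessels.pop("tape_1")
    platform.vessels["reactor"].id = "reactor"
    platform.vessels["flask"] = platform.vessels.pop("tape_2")
    platform.vessels["flask"].id = "flask"
    import networkx as nx

    platform.graph = nx.relabel_nodes(platform.graph, {"tape_1": "reactor",
                                                       "tape_2": "flask"})
    add_from_stock(platform, color, "reactor", Decimal("1.0"))
    return platform


def trace_kinds(trace):
    return [(ev.kind, ev.name) for ev in trace.events]


class TestParsing:
    def test_minimal_document(self):
        doc = parse_xdl(MINIMAL)
        assert len(doc.main) == 2
        assert doc.measure_step_ids() == {"C"}

    def test_undefined_condition_variable(self):
        bad = MINIMAL.replace('condition="C"', 'condition="D"')
        with pytest.raises(XDLValidationError, match="undefined condition variable D"):
            parse_xdl(bad)

    def test_measure_without_step_id(self):
        bad = MINIMAL.replace('step_id="C" ', "").replace('condition="C"', "")
        with pytest.raises(XDLValidationError, match="step_id"):
            parse_xdl(bad)

    def test_duplicate_step_id(self):
        dup = MINIMAL.replace(
            'condition="C"/>',
            'condition="C"/><Measure step_id="C" vessel="reactor" quantity="color"'
            ' comparison="equal" value="blue"/>',
        )
        with pytest.raises(XDLValidationError, match="duplicate step_id"):
            parse_xdl(dup)

    def test_unknown_step_name(self):
        bad = MINIMAL.replace("<Add ", "<Centrifuge ")
        with pytest.raises(XDLValidationError, match="unknown step name"):
            parse_xdl(bad)

    def test_undeclared_vessel(self):
        bad = MINIMAL.replace('vessel="reactor" reagent', 'vessel="ghost" reagent')
        with pytest.raises(XDLValidationError, match="undeclared vessel"):
            parse_xdl(bad)

    def test_malformed_xml(self):
        with pytest.raises(XDLValidationError, match="malformed XML"):
            parse_xdl("<XDL><Procedure>")

    def test_recursive_blueprint_rejected(self):
        with pytest.raises(XDLValidationError, match="recursive blueprint"):
            parse_xdl(
                """
                <XDL>
                  <Reagents/><Vessels/>
                  <Blueprint id="Ouro"><Boros/></Blueprint>
                  <Blueprint id="Boros"><Ouro/></Blueprint>
                  <Procedure><Ouro/></Procedure>
                </XDL>
                """
            )

    def test_round_trip_on_minimal_document(self):
        doc = parse_xdl(MINIMAL)
        assert parse_xdl(serialize_xdl(doc)) == doc

    def test_round_trip_on_compiled_document(self, bb_program):
        doc = bb_program.document
        assert parse_xdl(serialize_xdl(doc)) == doc


class TestMeasure:
    def test_color_equal_true_then_false(self, platform):
        add_from_stock(platform, "orange", "tape_1", Decimal("1.0"))
        store = VariableStore()
        spec = MeasureSpec("C", "tape_1", "color", "equal", "orange")
        assert execute_measure(spec, platform, store) is True
        assert store.get("C") is True

        add_from_stock(platform, "blue", "tape_2", Decimal("1.0"))
        spec2 = MeasureSpec("C", "tape_2", "color", "equal", "orange")
        assert execute_measure(spec2, platform, store) is False
        assert store.get("C") is False  # re-execution overwrites

    def test_less_than_is_strict_at_the_boundary(self, platform):
        platform.vessels["tape_1"].temperature = 50.0
        store = VariableStore()
        spec = MeasureSpec("T", "tape_1", "temperature", "less_than", "50")
        assert execute_measure(spec, platform, store) is False

    def test_between_is_inclusive(self, platform):
        platform.vessels["tape_1"].ph = 4.0
        store = VariableStore()
        spec = MeasureSpec("P", "tape_1", "pH", "between", "4", "9")
        assert execute_measure(spec, platform, store) is True

    def test_between_on_color_rejected(self, platform):
        spec = MeasureSpec("C", "tape_1", "color", "between", "blue", "green")
        with pytest.raises(XDLValidationError):
            execute_measure(spec, platform, VariableStore())

    def test_store_size_bounded_by_distinct_step_ids(self, platform):
        store = VariableStore()
        spec = MeasureSpec("C", "tape_1", "color", "equal", "orange")
        for _ in range(5):
            execute_measure(spec, platform, store)
        assert len(store) == 1


class TestExecutor:
    def test_quench_branch_taken_when_color_matches(self):
        platform = branch_platform("orange")
        trace = execute_procedure(branching_doc(), platform)
        kinds = trace_kinds(trace)
        assert ("step_executed", "Add") in kinds
        assert ("step_skipped", "Transfer") in kinds
        assert trace.status == "completed"

    def test_transfer_branch_taken_when_color_differs(self):
        platform = branch_platform("green")
        trace = execute_procedure(branching_doc(), platform)
        kinds = trace_kinds(trace)
        assert ("step_skipped", "Add") in kinds
        assert ("step_executed", "Transfer") in kinds

    def test_skipped_step_leaves_platform_bit_identical(self):
        platform = branch_platform("green")
        doc = parse_xdl(
            """
            <XDL>
              <Reagents><Reagent id="quencher" color="blue"/></Reagents>
              <Vessels><Vessel id="reactor"/></Vessels>
              <Procedure>
                <Measure step_id="C" vessel="reactor" quantity="color"
                         comparison="equal" value="orange"/>
                <Add vessel="reactor" reagent="quencher" volume="1.0" condition="C"/>
              </Procedure>
            </XDL>
            """
        )
        before = platform.snapshot()
        trace = execute_procedure(doc, platform)
        assert ("step_skipped", "Add") in trace_kinds(trace)
        assert platform.snapshot() == before

    def test_repeat_with_false_condition_never_runs(self, platform):
        doc = parse_xdl(
            """
            <XDL>
              <Reagents><Reagent id="dye" color="orange"/></Reagents>
              <Vessels><Vessel id="tape_1"/></Vessels>
              <Procedure>
                <Repeat condition="false" max_iterations="10">
                  <Add vessel="tape_1" reagent="dye" volume="1.0"/>
                </Repeat>
              </Procedure>
            </XDL>
            """
        )
        trace = execute_procedure(doc, platform)
        assert not any(ev.kind == "loop_iteration" for ev in trace.events)
        assert trace.status == "completed"

    def test_repeat_cap_is_recorded_not_silent(self, platform):
        doc = parse_xdl(
            """
            <XDL>
              <Reagents/><Vessels><Vessel id="tape_1"/></Vessels>
              <Procedure>
                <Repeat condition="true" max_iterations="3">
                  <Wait time="1"/>
                </Repeat>
              </Procedure>
            </XDL>
            """
        )
        trace = execute_procedure(doc, platform)
        assert trace.status == "iteration_cap"
        assert sum(1 for ev in trace.events if ev.kind == "loop_iteration") == 3

    def test_platform_error_aborts_with_partial_trace(self, platform):
        doc = parse_xdl(
            """
            <XDL>
              <Reagents><Reagent id="dye" color="orange"/></Reagents>
              <Vessels><Vessel id="tape_1"/></Vessels>
              <Procedure>
                <Wait time="1"/>
                <Add vessel="tape_1" reagent="dye" volume="100"/>
              </Procedure>
            </XDL>
            """
        )
        trace = execute_procedure(doc, platform)
        assert trace.status == "platform_error"
        assert ("step_executed", "Wait") in trace_kinds(trace)

    def test_blueprint_parameter_binding(self, platform):
        doc = parse_xdl(
            """
            <XDL>
              <Reagents><Reagent id="dye" color="green"/></Reagents>
              <Vessels><Vessel id="tape_1"/><Vessel id="tape_2"/></Vessels>
              <Blueprint id="Fill" params="target">
                <Add vessel="target" reagent="dye" volume="1.0"/>
              </Blueprint>
              <Procedure>
                <Fill target="tape_2"/>
              </Procedure>
            </XDL>
            """
        )
        execute_procedure(doc, platform)
        assert platform.vessels["tape_2"].contents == {"green": Decimal("1.0")}
        assert platform.vessels["tape_1"].contents == {}

    def test_determinism_identical_runs_identical_traces(self):
        t1 = execute_procedure(branching_doc(), branch_platform("orange"))
        t2 = execute_procedure(branching_doc(), branch_platform("orange"))
        assert t1 == t2

    def test_default_iteration_cap_from_limits(self, platform):
        doc = parse_xdl(
            """
            <XDL>
              <Reagents/><Vessels/>
              <Procedure>
                <Repeat condition="true"><Wait time="1"/></Repeat>
              </Procedure>
            </XDL>
            """
        )
        trace = execute_procedure(doc, platform, limits=ExecutionLimits(max_iterations=2))
        assert trace.status == "iteration_cap"
        assert sum(1 for ev in trace.events if ev.kind == "loop_iteration") == 2


def test_trace_serializes_losslessly():
    trace = ExecutionTrace(
        events=[
            TraceEvent("measurement", step_id="C", name="Measure", reading="orange",
                       result=True),
            TraceEvent("step_skipped", name="Transfer", condition="not C"),
            TraceEvent("loop_iteration", index=0),
            TraceEvent("step_executed", name="Add",
                       params=(("reagent", "dye"), ("vessel", "tape_1"))),
            TraceEvent("halt", reason="completed"),
        ]
    )
    assert ExecutionTrace.from_jsonl(trace.to_jsonl()) == trace


def test_compiled_trace_round_trips(bb_run):
    trace, _ = bb_run
    assert ExecutionTrace.from_jsonl(trace.to_jsonl()) == trace
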