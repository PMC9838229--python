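"""Author a circuit in the DSL, compile it, inspect the rule base and
run it against explicit stimuli — the full pipeline on a custom model.

The circuit is a two-step relay with a potentiation gate: an alert
opens the cue->act pathway only when cue and alert coincide.
"""

from virtcog import RunConfig, Stimulus, build_model, compile_circuit, parse_circuit, parse_term, run

SOURCE = """\
circuit relay
stream s
node sensor s cue cue(X)
node sensor s alert alert
node effector s act act(X)
edge synapse cue act weight=0
stp cue act trigger=alert duration=1
"""

spec = parse_circuit(SOURCE)
rulebase = compile_circuit(spec)
print("compiled implications:")
print(rulebase.render())

model = build_model(rulebase, RunConfig())
_, actions, trace = run(model, [
    Stimulus(parse_term("cue(7)"), 1),          # unattended: ignored
    Stimulus(parse_term("cue(9)"), 3),
    Stimulus(parse_term("alert"), 3),           # coincident alert opens the gate
])
print("\nactions:", [(a.cycle, str(a.term)) for a in actions])
print("\nweight table:")
print(model.weights.dump_tsv())
# only the attended cue acts: act(9) at cycle 3.  The weight table shows
# the cue->act entry still at 0 — the opening was transient (STP), not a
# lasting potentiation.
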