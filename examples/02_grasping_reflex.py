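"""The grasping reflex (sensory-motor substages 1-2).

Object and hand perceived at the same position X in the same cycle
drive grasp(obj(P,X)); a transient (short-term) potentiation opened by
the hand percept gates the object pathway, so mismatched positions or
cycles produce nothing.
"""

from virtcog import RunConfig, Stimulus, build_model, compile_circuit, parse_term, run
from virtcog.experiments import build_circuit

rulebase = compile_circuit(build_circuit("substage1_2"))

for label, obj_c, hand_c, obj_x, hand_x in [
    ("same field, same cycle", 1, 1, 3, 3),
    ("positions differ", 1, 1, 3, 4),
    ("one cycle apart", 1, 2, 3, 3),
]:
    model = build_model(rulebase, RunConfig())
    _, actions, _ = run(model, [
        Stimulus(parse_term(f"view(obj(toy,{obj_x}))"), obj_c),
        Stimulus(parse_term(f"view(hand({hand_x}))"), hand_c),
    ])
    print(f"{label:24s} ->", [str(a.term) for a in actions] or "no grasp")
# only the first case grasps: "all that is to be seen is also to be
# grasped" requires the shared visual field within one cycle.
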