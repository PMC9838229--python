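"""Partially invisible and fully invisible displacements (substages 5-6).

Observation 55: the toy vanishes inside a box that is secretly emptied
under a screen.  The subject first searches only the box; after two
failed repetitions an operant-style potentiation opens a screen search
driven by the remembered disappearance position <look(Q,Y)>.

Observation 64: with a covered box, watching it being loaded and closed
stores an internal image {image(box(F,I,X))}.  Retrieval opens the box
at rest; one empty find blocks re-opening forever (LTB); the image then
drives screen searches replaying the FIFO of passed screens in order.
"""

from virtcog import run_experiment

for name in ("obs55", "obs64"):
    outcome = run_experiment(name)
    print(name)
    for a in outcome.assertions:
        print(f"  [{'PASS' if a.passed else 'FAIL'}] {a.name}")
    for cycle, phase in outcome.phases:
        acts = [str(t) for t in outcome.actions_in_phase(phase)]
        print(f"  {phase:16s} {acts}")
    if name == "obs64":
        stores = [e.payload for e in outcome.trace.events if e.kind == "store"]
        print("  stored images:", stores)
    print()
# obs55 phase III shows the learned order: open the box, find it empty,
# then search the screen.  obs64 phase II searches s3 then s4 — the exact
# order the box passed them, recalled from the FIFO memory.
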