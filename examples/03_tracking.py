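"""Visual tracking of a moving object (substage 3).

Each move percept sets a latched focus of attention at the anticipated
next position X+1.  A halt at the expected place is grasped; an
unexpected item there (an occluding screen) captures a look instead.
"""

from virtcog import run_experiment

for name in ("track_stop", "track_occluded"):
    outcome = run_experiment(name)
    print(name)
    for line in outcome.trace.canonical_lines():
        print("  " + line)
    print("  actions:", [str(a.term) for a in outcome.actions])
    print()
# track_stop: moves at positions 1,2 anticipate 3; the halt there yields
# grasp(obj(toy,3)).  track_occluded: the screen s1 appearing at the
# anticipated position yields look(obj(s1,3)) — attention accommodates
# to the occluder.
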