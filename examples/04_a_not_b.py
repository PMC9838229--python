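"""The A-not-B error and its correction (substage 4).

The toy is hidden under screen A (found and retrieved), then visibly
hidden under screen B.  Under weak plasticity the potentiated
look->search pathway stays bound to its first instantiation, so the
subject searches A again — the A-not-B error.  Under strong plasticity
the pathway rebinds and the search follows the object to B.  The two
traces are byte-identical up to that very search.
"""

from virtcog import compare_traces, run_experiment

weak = run_experiment("anotb_weak")
strong = run_experiment("anotb_strong")

print("weak   actions:", [(a.cycle, str(a.term)) for a in weak.actions])
print("strong actions:", [(a.cycle, str(a.term)) for a in strong.actions])

diff = compare_traces(weak.trace, strong.trace)
print(f"\ntraces diverge at event {diff['index']}:")
print("  weak  :", diff["left"])
print("  strong:", diff["right"])
# weak searches search(obj(s1,3)) after the second hiding (perseveration);
# strong searches search(obj(s2,7)) and grasps the toy there.
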