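"""Classical and operant conditioning on the virtual substrate.

Classical: a weak conditioned stimulus (cs) paired twice with a strong
unconditioned one (us) potentiates the cs->motor pathway until cs alone
drives the withdrawal reflex.  Operant: an excite reinforcement
disinhibits the accept response and closes the exploratory path.
"""

from virtcog import run_experiment

aplysia = run_experiment("aplysia")
print("classical conditioning (aplysia)")
print("  actions:", [(a.cycle, str(a.term)) for a in aplysia.actions])
print("  cs->motor weight after training:",
      aplysia.model.weights.get("reflex", "s_cs", "motor"))
# cycle 1 probes cs alone (no response); pairings at cycles 3 and 5 raise
# the weight to 2; the final lone cs at cycle 8 now fires motor(cs).

for variant in ("operant_excite", "operant_inhibit"):
    outcome = run_experiment(variant)
    print(f"\n{variant}")
    print("  actions:", [(a.cycle, str(a.term)) for a in outcome.actions])
    print("  watch->spot weight (LTD-closed):",
          outcome.model.weights.get("learn", "s_watch", "spot"))
# after one reinforced presentation the repeat presentation is answered
# deterministically (accept or reject), and the exploratory spot pathway
# reads weight 0.
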