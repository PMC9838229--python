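"""The experiment suite: circuits, scripts and behavioral assertions.

Each simulated experiment bundles a circuit, a scenario script and a set
of ordered effector-sequence assertions (quoted-behavior checks, e.g.
"searches the box, does not search the screen").  The circuits form an
extension chain mirroring the developmental progression:

* ``substage1_2`` — the grasping reflex: object and hand perceived in
  the same visual field drive ``grasp`` through a short-term
  potentiation.
* ``substage3``   — visual tracking: a moving object sets a latched
  *focus of attention* at the anticipated position X+1; a halt in view
  drives grasping, an occluder at the expected position captures a
  ``look``.
* ``substage4``   — tracking + searching: the disappearance (look +
  stop coincidence) potentiates a ``search`` pathway.  Weak plasticity
  freezes the pathway on the first hiding place — the A-not-B error;
  strong plasticity rebinds and searches the second screen.
* ``substage5``   — partially invisible displacement (observation 55):
  an operant-conditioning sub-circuit learns, from repeated failures of
  the prepotent box search, to drive a screen search from the remembered
  position held in the FIFO memory <look(Q,Y)>.
* ``substage6``   — invisible displacement (observation 64): watching
  the box being loaded and covered is stored as an internal image
  {image(box(F,I,X))} (LTS); retrieval (LTR) opens the closed box after
  it stops, an empty find blocks re-opening (LTB), and image-driven
  retrieval replays the FIFO of passed screens in order.

Plus the two conditioning demos: ``aplysia`` (classical conditioning by
coincidence-detecting LTP) and ``operant`` (learning by disinhibition:
LTP opens the response path, LTD closes the exploratory one).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from .compiler import CircuitSpec, RuleBase, compile_circuit, parse_circuit
from .machine import Action, Model, RunConfig, Trace, build_model, compare_traces
from .terms import Term, format_term, parse_term, unify
from .world import ScenarioScript, WorldState, _apply_mutation, make_scenario, world_step

__all__ = [
    "CIRCUITS",
    "EXPERIMENTS",
    "Experiment",
    "Outcome",
    "AssertionResult",
    "build_circuit",
    "build_experiment_model",
    "run_closed_loop",
    "run_experiment",
    "list_experiments",
    "regress",
]


SUBSTAGE1_2 = """\
circuit substage1_2
stream vision
node sensor vision s_obj view(obj(P,X))
node sensor vision s_hand view(hand(X))
node effector vision grasp grasp(obj(P,X))
# both percepts must share the visual field X within one cycle;
# seeing the hand transiently opens the object->grasp pathway
edge conj s_obj,s_hand grasp weight=s_obj:0,s_hand:1
stp s_obj grasp trigger=s_hand duration=1
"""

SUBSTAGE3 = """\
circuit substage3
stream vision
node sensor vision s_move move(obj(P,Y))
node sensor vision s_see see(obj(Q,Y))
node sensor vision s_halt halt(obj(P,Y))
node internal vision focus focus(obj(P,Y)) latch
node internal vision assim track(obj(P,Y))
node effector vision look look(obj(Q,Y))
node effector vision grasp grasp(obj(P,Y))
# anticipate the next position of the moving object (saccade to X+1)
edge synapse s_move focus as=focus(obj(P,Y+1))
# the expected object at the expected place is assimilated; anything
# else at that place captures attention (look at the occluder)
edge conj focus,s_see assim group=seechoice when=s_see:see(obj(P,Y))
edge conj focus,s_see look group=seechoice
# the tracked object standing still in view is grasped
edge conj focus,s_halt grasp
"""

SUBSTAGE4 = SUBSTAGE3.replace("circuit substage3", "circuit substage4") + """\
node sensor vision s_stop stop(obj(P,Y))
node sensor vision s_view view(obj(P,Y))
node effector vision search search(obj(Q,Y))
# the disappearance (attention captured by the occluder while the toy
# halts out of sight) potentiates looking-place -> search;
# weak plasticity binds the pathway to the first hiding place
edge synapse look search weight=0
ltp look search trigger=s_stop partner=look window=1
# uncovering the object drives a grasping reflex, primed by the search
edge synapse s_view grasp weight=0
stp s_view grasp trigger=search duration=2
"""

SUBSTAGE5 = SUBSTAGE4.replace("circuit substage4", "circuit substage5") + """\
node sensor vision s_boxview view(box(F,I,Y))
node sensor vision s_spot spot(box(F,C,Y))
node internal vision spotneg spotneg(box(F,Y))
node effector vision openbox open(box(F,Y))
# remember where the object disappeared, in displacement order
stm-push lookmem look
# remember what went into the box
stm-push inboxmem s_boxview
# prepotent schema: seeing the box at rest, with something remembered
# inside, drives searching in the box
edge synapse s_view openbox when=s_view:view(obj(F,Y)) stm=inboxmem stmwhen=view(box(F,I,_))
# the spot thread discriminates the find: empty vs a wanted item
edge synapse s_spot spotneg group=spotchoice when=s_spot:spot(box(F,empty,Y))
edge synapse s_spot grasp group=spotchoice when=s_spot:spot(box(F,I,Y)) as=grasp(obj(I,Y))
# practical apprenticeship (operant conditioning): the coincidence of a
# failed box search with the remembered disappearance opens the
# halt -> search pathway; it takes two reinforcements to open
edge synapse s_halt search weight=0 theta=2 when=s_halt:halt(obj(_,_)) stm=lookmem stmwhen=look(obj(Q,Y))
ltp s_halt search trigger=spotneg partner=look window=12
"""

SUBSTAGE6 = SUBSTAGE5.replace("circuit substage5", "circuit substage6") + """\
stream engram
node sensor engram s_open open(box(F,I,Y))
node sensor engram s_close close(box(F,C,Y))
node internal engram image image(box(F,I,Y))
node sensor vision s_fail fail(obj(Q,Y))
node internal vision viewmem evoke(obj(Q,Y))
# watching the box being loaded then covered forms an internal image,
# committed to the associative store {image(box(F,I,Y))}
edge conj s_open,s_close image as=image(box(F,I,Y)) when=s_close:close(box(F,_,Y))
lts image
# retrieval of the image opens the closed box once it is seen at rest
ltr s_view openbox trigger=s_view when=view(obj(F,Y)) pattern=image(box(F,I,_))
# finding the box empty permanently blocks re-opening it
ltb s_view openbox trigger=spotneg
# suspended attention or a failed screen search evokes the image and
# replays the remembered disappearance positions in FIFO order
edge synapse s_halt viewmem when=s_halt:halt(obj(Q,Y)) as=evoke(obj(Q,Y))
edge synapse s_fail viewmem as=evoke(obj(Q,Y))
edge synapse viewmem search weight=0 theta=9 stm=lookmem stmwhen=look(obj(Q,Y))
ltr viewmem search trigger=viewmem when=evoke(obj(_,_)) pattern=image(box(F,I,_)) stm=lookmem stmwhen=look(obj(Q,Y))
"""

APLYSIA = """\
circuit aplysia
stream reflex
node sensor reflex s_cs cs
node sensor reflex s_us us
node effector reflex motor motor(X)
# the unconditioned pathway is open; the conditioned one starts closed
edge synapse s_cs motor weight=0 bind=X:cs
edge synapse s_us motor weight=1 bind=X:us
# the ltp interneuron detects the temporal pairing of cs and us and
# reinforces the cs -> motor pathway (hebbian learning)
ltp s_cs motor trigger=s_cs partner=s_us window=1
"""

OPERANT = """\
circuit operant
stream learn
node sensor learn s_watch watch(I)
node sensor learn s_excite excite
node sensor learn s_inhibit inhibit
node internal learn spot spot(I)
node effector learn accept accept(I)
node effector learn reject reject(I)
# baseline: the exploratory path is open, both responses are inhibited
edge synapse s_watch spot weight=1
edge synapse s_watch accept weight=0
edge synapse s_watch reject weight=0
# reinforcement disinhibits one response and closes the exploratory path
ltp s_watch accept trigger=spot partner=s_excite window=1
ltp s_watch reject trigger=spot partner=s_inhibit window=1
ltd s_watch spot trigger=spot partner=s_excite window=1
ltd s_watch spot trigger=spot partner=s_inhibit window=1
"""

CIRCUITS: dict[str, str] = {
    "substage1_2": SUBSTAGE1_2,
    "substage3": SUBSTAGE3,
    "substage4": SUBSTAGE4,
    "substage5": SUBSTAGE5,
    "substage6": SUBSTAGE6,
    "aplysia": APLYSIA,
    "operant": OPERANT,
}

_CIRCUIT_ALIASES = {
    "grasp": "substage1_2",
    "track": "substage3",
    "anotb": "substage4",
    "obs55": "substage5",
    "obs64": "substage6",
}


def build_circuit(name: str) -> CircuitSpec:
    """Return the named circuit spec (substage id or demo alias)."""
    key = _CIRCUIT_ALIASES.get(name, name)
    if key not in CIRCUITS:
        raise KeyError(f"unknown circuit {name!r} (choose from {sorted(CIRCUITS)})")
    return parse_circuit(CIRCUITS[key])


# ---------------------------------------------------------------------------
# closed perception-action loop

@dataclass
class AssertionResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class Outcome:
    name: str
    actions: list[Action]
    trace: Trace
    model: Model
    world: WorldState
    phases: list[tuple[int, str]]
    assertions: list[AssertionResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(a.passed for a in self.assertions)

    def actions_in_phase(self, phase: str) -> list[Term]:
        start = end = None
        for i, (cycle, name) in enumerate(self.phases):
            if name == phase:
                start = cycle
                end = self.phases[i + 1][0] if i + 1 < len(self.phases) else None
        if start is None:
            return []
        return [
            a.term for a in self.actions if a.cycle >= start and (end is None or a.cycle < end)
        ]


def run_closed_loop(
    model: Model, script: ScenarioScript, max_cycles: Optional[int] = None
) -> Outcome:
    """Drive the machine against the scripted world: scripted stimuli
    and one-cycle-delayed action feedback are sensed each cycle until
    the script is exhausted and the machine falls quiescent."""
    max_cycles = max_cycles or model.config.max_cycles
    world = script.world.clone()
    feedback: list[Term] = []
    phases: list[tuple[int, str]] = []
    last = script.last_cycle()
    start = model.cycle
    while model.cycle < start + max_cycles:
        c = model.cycle
        for mut in script.mutations_at(c):
            _apply_mutation(world, mut)
        phase = script.phase_at(c)
        if phase is not None:
            phases.append((c, phase))
            model.trace.add(c, "phase", phase)
        stimuli = feedback + script.stimuli_at(c)
        feedback = []
        n_before = len(model.actions)
        model.step_cycle(stimuli)
        new_actions = [a.term for a in model.actions[n_before:]]
        world, feedback = world_step(world, c, new_actions)
        if c >= last and not feedback and model.quiescent():
            break
    else:
        model.trace.add(model.cycle, "note", "cycle limit reached; run truncated")
    return Outcome(
        name=script.name,
        actions=list(model.actions),
        trace=model.trace,
        model=model,
        world=world,
        phases=phases,
    )


def _check_assertions(outcome: Outcome, spec: list[dict]) -> list[AssertionResult]:
    results = []
    for a in spec:
        phase = a["phase"]
        acts = outcome.actions_in_phase(phase)
        ok = True
        detail = ""
        i = 0
        for pat_text in a.get("must", []):
            pat = parse_term(pat_text)
            while i < len(acts) and unify(pat, acts[i]) is None:
                i += 1
            if i == len(acts):
                ok = False
                detail = f"missing {pat_text} in phase {phase}: actions={[format_term(t) for t in acts]}"
                break
            i += 1
        if ok:
            for pat_text in a.get("forbid", []):
                pat = parse_term(pat_text)
                hits = [t for t in acts if unify(pat, t) is not None]
                if hits:
                    ok = False
                    detail = f"forbidden {pat_text} in phase {phase}: {[format_term(t) for t in hits]}"
                    break
        results.append(AssertionResult(a.get("name", f"{phase}"), ok, detail))
    return results


# ---------------------------------------------------------------------------
# experiment registry

@dataclass(frozen=True)
class Experiment:
    name: str
    circuit: str
    scenario: str
    scenario_params: dict = field(default_factory=dict)
    plasticity: str = "strong"
    assertions: tuple = ()


EXPERIMENTS: dict[str, Experiment] = {}


def _register(exp: Experiment) -> None:
    EXPERIMENTS[exp.name] = exp


_register(Experiment(
    name="aplysia",
    circuit="aplysia",
    scenario="aplysia",
    assertions=(
        {"name": "no reflex to cs before training", "phase": "pretrain", "forbid": ["motor(_)"]},
        {"name": "cs alone triggers the withdrawal reflex after pairing",
         "phase": "posttrain", "must": ["motor(cs)"]},
    ),
))

_register(Experiment(
    name="operant_excite",
    circuit="operant",
    scenario="operant",
    scenario_params={"reinforcement": "excite"},
    assertions=(
        {"name": "repeat presentation is accepted", "phase": "repeat",
         "must": ["accept(i1)"], "forbid": ["reject(_)"]},
    ),
))

_register(Experiment(
    name="operant_inhibit",
    circuit="operant",
    scenario="operant",
    scenario_params={"reinforcement": "inhibit"},
    assertions=(
        {"name": "repeat presentation is rejected", "phase": "repeat",
         "must": ["reject(i1)"], "forbid": ["accept(_)"]},
    ),
))

_register(Experiment(
    name="grasp",
    circuit="substage1_2",
    scenario="grasp",
    assertions=(
        {"name": "all that is seen (with the hand) is grasped", "phase": "reach",
         "must": ["grasp(obj(toy,3))"]},
    ),
))

_register(Experiment(
    name="track_stop",
    circuit="substage3",
    scenario="track",
    scenario_params={"variant": "stops_in_view"},
    assertions=(
        {"name": "the toy standing still in sight is grasped at X+1", "phase": "tracking",
         "must": ["grasp(obj(toy,3))"], "forbid": ["look(_)"]},
    ),
))

_register(Experiment(
    name="track_occluded",
    circuit="substage3",
    scenario="track",
    scenario_params={"variant": "occluded"},
    assertions=(
        {"name": "the occluding item captures the look", "phase": "tracking",
         "must": ["look(obj(s1,3))"], "forbid": ["grasp(_)"]},
    ),
))

_register(Experiment(
    name="anotb_weak",
    circuit="substage4",
    scenario="anotb",
    plasticity="weak",
    assertions=(
        {"name": "first hiding: search at A succeeds", "phase": "hide_at_a",
         "must": ["search(obj(s1,_))", "grasp(obj(toy,_))"]},
        {"name": "A-not-B error: second search returns to A", "phase": "hide_at_b",
         "must": ["search(obj(s1,_))"], "forbid": ["search(obj(s2,_))"]},
    ),
))

_register(Experiment(
    name="anotb_strong",
    circuit="substage4",
    scenario="anotb",
    plasticity="strong",
    assertions=(
        {"name": "first hiding: search at A succeeds", "phase": "hide_at_a",
         "must": ["search(obj(s1,_))", "grasp(obj(toy,_))"]},
        {"name": "correct sequential search at B", "phase": "hide_at_b",
         "must": ["search(obj(s2,_))", "grasp(obj(toy,_))"], "forbid": ["search(obj(s1,_))"]},
    ),
))

_register(Experiment(
    name="obs55",
    circuit="substage5",
    scenario="obs55",
    assertions=(
        {"name": "I: searches the box, not the screen", "phase": "phase_I_trial1",
         "must": ["open(box(f,_))"], "forbid": ["search(_)"]},
        {"name": "II: immediately searches the screen and grasps", "phase": "phase_II",
         "must": ["search(obj(s1,_))", "grasp(obj(toy,_))"], "forbid": ["open(_)"]},
        {"name": "III: box search, failure, then screen search", "phase": "phase_III",
         "must": ["open(box(f,_))", "search(obj(s1,_))", "grasp(obj(toy,_))"]},
    ),
))

_register(Experiment(
    name="obs64",
    circuit="substage6",
    scenario="obs64",
    assertions=(
        {"name": "Ia: empty box search, then screen search", "phase": "phase_Ia",
         "must": ["open(box(f,_))", "search(obj(s1,_))", "grasp(obj(toy,_))"]},
        {"name": "Ib: immediate second-screen search, no box opening", "phase": "phase_Ib",
         "must": ["search(obj(s2,_))", "grasp(obj(toy,_))"], "forbid": ["open(_)"]},
        {"name": "II: ordered two-screen search via FIFO memory", "phase": "phase_II",
         "must": ["search(obj(s3,_))", "search(obj(s4,_))", "grasp(obj(toy,_))"],
         "forbid": ["open(_)"]},
    ),
))


def list_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


def build_experiment_model(
    name: str, plasticity: Optional[str] = None, config: Optional[RunConfig] = None
) -> tuple[Model, ScenarioScript, Experiment]:
    exp = EXPERIMENTS[name]
    cfg = config or RunConfig()
    cfg.plasticity = plasticity or exp.plasticity
    rulebase = compile_circuit(build_circuit(exp.circuit))
    model = build_model(rulebase, cfg)
    script = make_scenario(exp.scenario, exp.scenario_params)
    return model, script, exp


def run_experiment(
    name: str,
    plasticity: Optional[str] = None,
    config: Optional[RunConfig] = None,
    max_cycles: Optional[int] = None,
) -> Outcome:
    """Compile, run and evaluate one registered experiment.
    Deterministic: repeated runs yield byte-identical canonical traces."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r} (choose from {list_experiments()})")
    model, script, exp = build_experiment_model(name, plasticity, config)
    outcome = run_closed_loop(model, script, max_cycles)
    outcome.assertions = _check_assertions(outcome, list(exp.assertions))
    return outcome


def regress(golden_dir: str) -> dict:
    """Re-run every experiment and compare its canonical trace with the
    versioned golden trace; missing goldens are listed, not fatal."""
    report = {"equal": [], "diff": {}, "missing": [], "unknown": []}
    known = set()
    for name in list_experiments():
        known.add(f"{name}.trc")
        path = os.path.join(golden_dir, f"{name}.trc")
        outcome = run_experiment(name)
        if not os.path.exists(path):
            report["missing"].append(name)
            continue
        with open(path) as fh:
            golden = fh.read()
        current = outcome.trace.to_text()
        if golden == current:
            report["equal"].append(name)
        else:
            g_lines = golden.rstrip("\n").split("\n")
            c_lines = current.rstrip("\n").split("\n")
            idx = next(
                (i for i, (a, b) in enumerate(zip(g_lines, c_lines)) if a != b),
                min(len(g_lines), len(c_lines)),
            )
            report["diff"][name] = {
                "index": idx,
                "golden": g_lines[idx] if idx < len(g_lines) else None,
                "current": c_lines[idx] if idx < len(c_lines) else None,
            }
    if os.path.isdir(golden_dir):
        for fn in sorted(os.listdir(golden_dir)):
            if fn.endswith(".trc") and fn not in known:
                report["unknown"].append(fn)
    return report
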