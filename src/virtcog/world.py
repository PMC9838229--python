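"""Synthetic one-dimensional environment and scenario scripting.

The world is the experimental chamber: a 1-D integer axis with movable
objects, occluding screens and (lidded) boxes.  Scenario scripts emit
the stimulus vocabulary (``view/move/see/halt/stop/open/close/spot``) on
a fixed schedule and mutate the world — including the experimenter's
*covert* manipulations (emptying a box under a screen), which change
the world WITHOUT emitting stimuli: that silence is precisely what makes
a displacement invisible to the simulated subject.

Effector actions are converted back into stimuli one cycle later (the
closed perception-action loop):

* ``search(obj(S, X))`` at a screen hiding something uncovers it:
  ``view(obj(O, X))`` next cycle (an object inside a box under the
  screen counts as found — the box-opening details are elided); at an
  empty screen it yields ``fail(obj(S, X))``.
* ``open(box(F, X))`` reveals the box contents:
  ``spot(box(F, C, X))`` with C the first content or ``empty``.
* ``grasp(obj(P, X))`` takes a visible object into the hand.

Motion is +1 per scripted step along the axis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .terms import Atom, Int, Struct, Term, format_term, parse_term

__all__ = [
    "WorldState",
    "ScenarioEvent",
    "ScenarioScript",
    "ScenarioError",
    "world_step",
    "make_scenario",
    "load_scenario",
    "save_scenario",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "SCENARIO_NAMES",
]


class ScenarioError(ValueError):
    pass


@dataclass
class WorldState:
    """Locations are exclusive: an object is visible on the axis, under
    a screen, inside a box, held by the subject, or gone — never two at
    once."""

    objects: dict = field(default_factory=dict)  # id -> {"pos": int, "loc": str}
    screens: dict = field(default_factory=dict)  # id -> {"pos": int}
    boxes: dict = field(default_factory=dict)  # id -> {"pos": int, "contents": [ids], "covered": bool}

    def clone(self) -> "WorldState":
        return copy.deepcopy(self)

    def location(self, obj: str) -> str:
        return self.objects[obj]["loc"]

    def hidden_under(self, screen: str) -> list[str]:
        """Objects recoverable by searching under ``screen`` — directly
        hidden ones plus the contents of any box resting there."""
        out = [o for o, st in self.objects.items() if st["loc"] == f"screen:{screen}"]
        for bid, box in self.boxes.items():
            if box.get("under") == screen:
                out.extend(o for o in box["contents"])
        return out

    def check_conservation(self) -> list[str]:
        problems = []
        for obj, st in self.objects.items():
            loc = st["loc"]
            if loc.startswith("box:"):
                bid = loc.split(":", 1)[1]
                if obj not in self.boxes.get(bid, {}).get("contents", []):
                    problems.append(f"{obj} claims {loc} but box disagrees")
            elif loc not in ("axis", "held", "gone") and not loc.startswith("screen:"):
                problems.append(f"{obj} in unknown location {loc}")
        for bid, box in self.boxes.items():
            for o in box["contents"]:
                if self.objects[o]["loc"] != f"box:{bid}":
                    problems.append(f"box {bid} lists {o} but object disagrees")
        return problems


@dataclass(frozen=True)
class ScenarioEvent:
    cycle: int
    kind: str  # stimulus | phase | put | covert-empty-box | cover-box | box-under
    data: dict


@dataclass
class ScenarioScript:
    name: str
    world: WorldState
    events: list[ScenarioEvent]
    plasticity: Optional[str] = None  # suggested mode, overridable

    def stimuli_at(self, cycle: int) -> list[Term]:
        return [
            parse_term(e.data["term"])
            for e in self.events
            if e.cycle == cycle and e.kind == "stimulus"
        ]

    def mutations_at(self, cycle: int) -> list[ScenarioEvent]:
        return [e for e in self.events if e.cycle == cycle and e.kind not in ("stimulus", "phase")]

    def phase_at(self, cycle: int) -> Optional[str]:
        for e in self.events:
            if e.cycle == cycle and e.kind == "phase":
                return e.data["name"]
        return None

    def last_cycle(self) -> int:
        return max((e.cycle for e in self.events), default=0)

    def validate(self) -> None:
        prev = 0
        for i, e in enumerate(self.events):
            if e.cycle < prev:
                raise ScenarioError(f"event {i}: cycles must be non-decreasing")
            prev = e.cycle


# ---------------------------------------------------------------------------
# the perception-action loop

def _apply_mutation(world: WorldState, event: ScenarioEvent) -> None:
    d = event.data
    if event.kind == "put":
        obj, loc = d["object"], d["loc"]
        prev = world.objects.get(obj, {}).get("loc")
        if prev and prev.startswith("box:"):
            world.boxes[prev.split(":", 1)[1]]["contents"].remove(obj)
        world.objects[obj] = {"pos": d.get("pos", 0), "loc": loc}
        if loc.startswith("box:"):
            world.boxes[loc.split(":", 1)[1]]["contents"].append(obj)
    elif event.kind == "box-under":
        world.boxes[d["box"]]["under"] = d.get("screen")
        if "pos" in d:
            world.boxes[d["box"]]["pos"] = d["pos"]
    elif event.kind == "covert-empty-box":
        # the experimenter's sleight of hand: tip the box's contents out
        # under a screen; no stimulus is emitted.
        box = world.boxes[d["box"]]
        for o in list(box["contents"]):
            box["contents"].remove(o)
            world.objects[o]["loc"] = f"screen:{d['screen']}"
            world.objects[o]["pos"] = world.screens[d["screen"]]["pos"]
    elif event.kind == "cover-box":
        world.boxes[d["box"]]["covered"] = bool(d.get("covered", True))
    else:
        raise ScenarioError(f"unknown mutation {event.kind!r}")


def world_step(
    world: WorldState, cycle: int, actions: list[Term]
) -> tuple[WorldState, list[Term]]:
    """Apply effector actions; return the updated world and the stimuli
    they provoke (delivered at the NEXT cycle — feedback latency is one
    cycle).  Actions naming nonexistent entities are logged no-ops."""
    world = world.clone()
    stimuli: list[Term] = []
    for act in actions:
        if not isinstance(act, Struct):
            continue
        if act.functor == "search" and len(act.args) == 1:
            inner = act.args[0]
            if not (isinstance(inner, Struct) and inner.functor == "obj"):
                continue
            sid = format_term(inner.args[0])
            pos = inner.args[1]
            if sid not in world.screens:
                continue
            found = world.hidden_under(sid)
            if found:
                obj = found[0]
                loc = world.objects[obj]["loc"]
                if loc.startswith("box:"):
                    world.boxes[loc.split(":", 1)[1]]["contents"].remove(obj)
                world.objects[obj]["loc"] = "axis"
                world.objects[obj]["pos"] = pos.value if isinstance(pos, Int) else 0
                stimuli.append(Struct("view", (Struct("obj", (Atom(obj), pos)),)))
            else:
                stimuli.append(Struct("fail", (Struct("obj", (Atom(sid), pos)),)))
        elif act.functor == "open" and len(act.args) == 1:
            inner = act.args[0]
            if not (isinstance(inner, Struct) and inner.functor == "box"):
                continue
            bid = format_term(inner.args[0])
            pos = inner.args[1]
            if bid not in world.boxes:
                continue
            contents = world.boxes[bid]["contents"]
            spotted = Atom(contents[0]) if contents else Atom("empty")
            stimuli.append(Struct("spot", (Struct("box", (Atom(bid), spotted, pos)),)))
        elif act.functor == "grasp" and len(act.args) == 1:
            inner = act.args[0]
            if not (isinstance(inner, Struct) and inner.functor == "obj"):
                continue
            oid = format_term(inner.args[0])
            if oid in world.objects and world.objects[oid]["loc"] == "axis":
                world.objects[oid]["loc"] = "held"
    return world, stimuli


# ---------------------------------------------------------------------------
# built-in scenarios (deterministic; parameters control counts/positions)

def _stim(cycle: int, term: str) -> ScenarioEvent:
    return ScenarioEvent(cycle, "stimulus", {"term": term})


def _phase(cycle: int, name: str) -> ScenarioEvent:
    return ScenarioEvent(cycle, "phase", {"name": name})


def make_scenario(name: str, params: Optional[dict] = None) -> ScenarioScript:
    """Build one of the built-in experiment scripts.

    Names: aplysia, operant, grasp, track, anotb, obs55, obs64.  Pure:
    identical params yield identical scripts.
    """
    params = dict(params or {})
    builder = _BUILDERS.get(name)
    if builder is None:
        raise ScenarioError(f"unknown scenario {name!r} (choose from {sorted(_BUILDERS)})")
    script = builder(params)
    script.validate()
    return script


def _scn_aplysia(p: dict) -> ScenarioScript:
    pairings = int(p.get("pairings", 2))
    gap = int(p.get("gap", 0))  # cycles between cs and us within a pairing
    events = [_phase(1, "pretrain"), _stim(1, "cs"), _phase(3, "train")]
    c = 3
    for _ in range(pairings):
        events.append(_stim(c, "cs"))
        events.append(_stim(c + gap, "us"))
        c += max(1, gap) + 1
    events.append(_phase(c + 1, "posttrain"))
    events.append(_stim(c + 1, "cs"))
    return ScenarioScript("aplysia", WorldState(), events)


def _scn_operant(p: dict) -> ScenarioScript:
    item = p.get("item", "i1")
    reinforcement = p.get("reinforcement", "excite")
    events = [
        _phase(1, "learn"),
        _stim(1, f"watch({item})"),
        _stim(1, reinforcement),
        _phase(3, "repeat"),
        _stim(3, f"watch({item})"),
    ]
    return ScenarioScript("operant", WorldState(), events)


def _scn_grasp(p: dict) -> ScenarioScript:
    x_obj = int(p.get("object_pos", 3))
    x_hand = int(p.get("hand_pos", 3))
    lag = int(p.get("hand_lag", 0))
    obj = p.get("object", "toy")
    world = WorldState(objects={obj: {"pos": x_obj, "loc": "axis"}})
    events = [
        _phase(1, "reach"),
        _stim(1, f"view(obj({obj},{x_obj}))"),
        _stim(1 + lag, f"view(hand({x_hand}))"),
    ]
    return ScenarioScript("grasp", world, events)


def _track_prefix(obj: str, start: int, steps: int, c0: int = 1) -> tuple[list[ScenarioEvent], int, int]:
    """Shared motion prelude: the toy is seen moving +1 per cycle."""
    events = []
    c, x = c0, start
    for i in range(steps):
        events.append(_stim(c, f"move(obj({obj},{x}))"))
        if i > 0:
            events.append(_stim(c, f"see(obj({obj},{x}))"))
        c += 1
        x += 1
    return events, c, x  # next cycle, expected position


def _scn_track(p: dict) -> ScenarioScript:
    variant = p.get("variant", "stops_in_view")
    steps = int(p.get("steps", 2))
    obj = p.get("object", "toy")
    screen = p.get("screen", "s1")
    events, c, x = _track_prefix(obj, int(p.get("start", 1)), steps)
    world = WorldState(objects={obj: {"pos": x, "loc": "axis"}})
    events.insert(0, _phase(1, "tracking"))
    if variant == "stops_in_view":
        events.append(_stim(c, f"halt(obj({obj},{x}))"))
    elif variant == "occluded":
        world.screens[screen] = {"pos": x}
        world.objects[obj]["loc"] = f"screen:{screen}"
        events.append(_stim(c, f"see(obj({screen},{x}))"))
    else:
        raise ScenarioError(f"unknown track variant {variant!r}")
    return ScenarioScript("track", world, events)


def _scn_anotb(p: dict) -> ScenarioScript:
    screens = p.get("screens", ["s1", "s2"])
    if len(screens) != 2:
        raise ScenarioError("anotb needs exactly two screens")
    obj = p.get("object", "toy")
    steps = int(p.get("steps", 2))
    a, b = screens
    pos_a = 1 + steps
    world = WorldState(
        objects={obj: {"pos": 1, "loc": "axis"}},
        screens={a: {"pos": pos_a}},
    )
    events: list[ScenarioEvent] = [_phase(1, "hide_at_a")]
    ev, c, x = _track_prefix(obj, 1, steps)
    events.extend(ev)
    # the toy disappears under screen A and comes to rest there
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": f"screen:{a}", "pos": x}))
    events.append(_stim(c, f"see(obj({a},{x}))"))
    events.append(_stim(c, f"stop(obj({obj},{x}))"))
    c += 4  # search + uncover + grasp feedback happen here
    events.append(_phase(c, "hide_at_b"))
    start_b = x + 2
    pos_b = start_b + steps
    world.screens[b] = {"pos": pos_b}
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": "axis", "pos": start_b}))
    ev, c2, x2 = _track_prefix(obj, start_b, steps, c)
    events.extend(ev)
    events.append(ScenarioEvent(c2, "put", {"object": obj, "loc": f"screen:{b}", "pos": x2}))
    events.append(_stim(c2, f"see(obj({b},{x2}))"))
    events.append(_stim(c2, f"stop(obj({obj},{x2}))"))
    return ScenarioScript("anotb", world, events)


def _obs55_trial(events, world, c, phase_name, obj, box, screen, *, bring_out_empty, halt_after):
    """One observation-55 trial.  The toy goes into the box in view of
    the subject; the box passes under the screen; covertly the toy stays
    behind; the box may be brought out and rest in view."""
    events.append(_phase(c, phase_name))
    box_pos = world.boxes[box]["pos"]
    scr_pos = world.screens[screen]["pos"]
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": f"box:{box}", "pos": box_pos}))
    events.append(_stim(c, f"view(box({box},{obj},{box_pos}))"))
    c += 1
    events.append(_stim(c, f"move(obj({box},{scr_pos - 1}))"))
    c += 1
    events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": screen, "pos": scr_pos}))
    events.append(_stim(c, f"see(obj({screen},{scr_pos}))"))
    if bring_out_empty:
        events.append(ScenarioEvent(c, "covert-empty-box", {"box": box, "screen": screen}))
        c += 1
        out_pos = scr_pos + 1
        events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": None, "pos": out_pos}))
        events.append(_stim(c, f"view(obj({box},{out_pos}))"))
        c += 2  # open + spot feedback land here
        if halt_after:
            c += 1
            events.append(_stim(c, f"halt(obj({screen},{scr_pos}))"))
            c += 3  # search + uncover + grasp
    else:
        c += 1
        events.append(_stim(c, f"halt(obj({screen},{scr_pos}))"))
        c += 3
    return c + 2


def _scn_obs55(p: dict) -> ScenarioScript:
    repetitions = int(p.get("repetitions", 2))
    obj, box, screen = p.get("object", "toy"), p.get("box", "f"), p.get("screen", "s1")
    world = WorldState(
        objects={obj: {"pos": 2, "loc": "axis"}},
        screens={screen: {"pos": 4}},
        boxes={box: {"pos": 2, "contents": [], "covered": False, "under": None}},
    )
    events: list[ScenarioEvent] = []
    c = 1
    for i in range(repetitions):
        c = _obs55_trial(
            events, world, c, f"phase_I_trial{i + 1}", obj, box, screen,
            bring_out_empty=True, halt_after=False,
        )
    c = _obs55_trial(
        events, world, c, "phase_II", obj, box, screen,
        bring_out_empty=False, halt_after=False,
    )
    c = _obs55_trial(
        events, world, c, "phase_III", obj, box, screen,
        bring_out_empty=True, halt_after=True,
    )
    return ScenarioScript("obs55", world, events, plasticity="strong")


def _obs64_episode(events, world, c, phase_name, obj, box, screens, *, bring_out):
    """One observation-64 episode with the covered box passing under one
    or two screens."""
    events.append(_phase(c, phase_name))
    box_pos = world.boxes[box]["pos"]
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": f"box:{box}", "pos": box_pos}))
    events.append(_stim(c, f"open(box({box},{obj},{box_pos}))"))
    events.append(ScenarioEvent(c, "cover-box", {"box": box, "covered": True}))
    events.append(_stim(c, f"close(box({box},covered,{box_pos}))"))
    c += 1
    last_screen = screens[-1]
    pos = box_pos
    for i, screen in enumerate(screens):
        scr_pos = world.screens[screen]["pos"]
        events.append(_stim(c, f"move(obj({box},{scr_pos - 1}))"))
        c += 1
        events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": screen, "pos": scr_pos}))
        events.append(_stim(c, f"see(obj({screen},{scr_pos}))"))
        if screen == last_screen:
            events.append(ScenarioEvent(c, "covert-empty-box", {"box": box, "screen": screen}))
        c += 1
    final_scr = world.screens[last_screen]["pos"]
    if bring_out:
        out_pos = final_scr + 1
        events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": None, "pos": out_pos}))
        events.append(_stim(c, f"view(obj({box},{out_pos}))"))
        c += 2  # open + spot (or nothing once blocked)
    events.append(_stim(c, f"halt(obj({last_screen},{final_scr}))"))
    c += 2 + 2 * len(screens)  # searches, failures and the final grasp
    return c + 2


def _scn_obs64(p: dict) -> ScenarioScript:
    obj, box = p.get("object", "toy"), p.get("box", "f")
    world = WorldState(
        objects={obj: {"pos": 2, "loc": "axis"}},
        screens={
            "s1": {"pos": 4},
            "s2": {"pos": 8},
            "s3": {"pos": 12},
            "s4": {"pos": 14},
        },
        boxes={box: {"pos": 2, "contents": [], "covered": True, "under": None}},
    )
    events: list[ScenarioEvent] = []
    c = 1
    c = _obs64_episode(events, world, c, "phase_Ia", obj, box, ["s1"], bring_out=True)
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": "axis", "pos": 6}))
    events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": None, "pos": 6}))
    c = _obs64_episode(events, world, c, "phase_Ib", obj, box, ["s2"], bring_out=True)
    events.append(ScenarioEvent(c, "put", {"object": obj, "loc": "axis", "pos": 10}))
    events.append(ScenarioEvent(c, "box-under", {"box": box, "screen": None, "pos": 10}))
    c = _obs64_episode(events, world, c, "phase_II", obj, box, ["s3", "s4"], bring_out=False)
    return ScenarioScript("obs64", world, events, plasticity="strong")


_BUILDERS = {
    "aplysia": _scn_aplysia,
    "operant": _scn_operant,
    "grasp": _scn_grasp,
    "track": _scn_track,
    "anotb": _scn_anotb,
    "obs55": _scn_obs55,
    "obs64": _scn_obs64,
}

SCENARIO_NAMES = tuple(sorted(_BUILDERS))


# ---------------------------------------------------------------------------
# YAML round-trip

def scenario_to_yaml(script: ScenarioScript) -> str:
    doc = {
        "name": script.name,
        "plasticity": script.plasticity,
        "world": {
            "objects": script.world.objects,
            "screens": script.world.screens,
            "boxes": script.world.boxes,
        },
        "events": [
            {"cycle": e.cycle, "kind": e.kind, **e.data} for e in script.events
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> ScenarioScript:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "events" not in doc:
        raise ScenarioError("scenario document must be a mapping with an 'events' list")
    world = WorldState(
        objects=doc.get("world", {}).get("objects", {}) or {},
        screens=doc.get("world", {}).get("screens", {}) or {},
        boxes=doc.get("world", {}).get("boxes", {}) or {},
    )
    events = []
    for i, e in enumerate(doc["events"]):
        if "cycle" not in e or "kind" not in e:
            raise ScenarioError(f"event {i}: needs 'cycle' and 'kind'")
        data = {k: v for k, v in e.items() if k not in ("cycle", "kind")}
        events.append(ScenarioEvent(int(e["cycle"]), e["kind"], data))
    script = ScenarioScript(doc.get("name", "unnamed"), world, events, doc.get("plasticity"))
    script.validate()
    return script


def save_scenario(script: ScenarioScript, path) -> None:
    with open(path, "w") as fh:
        fh.write(scenario_to_yaml(script))


def load_scenario(path) -> ScenarioScript:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ScenarioError(f"{path}: empty scenario file")
    return scenario_from_yaml(text)
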