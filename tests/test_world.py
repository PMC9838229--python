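"""The scripted one-dimensional world and the perception-action loop."""

import pytest

from virtcog.terms import format_term, parse_term
from virtcog.world import (
    ScenarioError,
    ScenarioScript,
    WorldState,
    load_scenario,
    make_scenario,
    save_scenario,
    scenario_from_yaml,
    scenario_to_yaml,
    world_step,
)

T = parse_term


def _world_with_screen(hiding=None):
    w = WorldState(screens={"s1": {"pos": 2}})
    if hiding:
        w.objects[hiding] = {"pos": 2, "loc": "screen:s1"}
    return w


class TestWorldStep:
    def test_search_uncovers_hidden_object(self):
        w = _world_with_screen(hiding="toy")
        w2, stimuli = world_step(w, 1, [T("search(obj(s1,2))")])
        assert [format_term(s) for s in stimuli] == ["view(obj(toy,2))"]
        assert w2.objects["toy"]["loc"] == "axis"

    def test_search_empty_screen_fails(self):
        w = _world_with_screen()
        w2, stimuli = world_step(w, 1, [T("search(obj(s1,2))")])
        assert [format_term(s) for s in stimuli] == ["fail(obj(s1,2))"]
        assert w2.screens == w.screens and w2.objects == w.objects

    def test_open_box_spots_contents_or_empty(self):
        w = WorldState(
            objects={"toy": {"pos": 3, "loc": "box:f"}},
            boxes={"f": {"pos": 3, "contents": ["toy"], "covered": True, "under": None}},
        )
        _, stimuli = world_step(w, 1, [T("open(box(f,3))")])
        assert [format_term(s) for s in stimuli] == ["spot(box(f,toy,3))"]
        w.boxes["f"]["contents"] = []
        w.objects["toy"]["loc"] = "gone"
        _, stimuli = world_step(w, 1, [T("open(box(f,3))")])
        assert [format_term(s) for s in stimuli] == ["spot(box(f,empty,3))"]

    def test_box_under_screen_counts_as_findable(self):
        w = WorldState(
            objects={"toy": {"pos": 2, "loc": "box:f"}},
            screens={"s1": {"pos": 2}},
            boxes={"f": {"pos": 2, "contents": ["toy"], "covered": False, "under": "s1"}},
        )
        _, stimuli = world_step(w, 1, [T("search(obj(s1,2))")])
        assert [format_term(s) for s in stimuli] == ["view(obj(toy,2))"]

    def test_grasp_takes_visible_object(self):
        w = WorldState(objects={"toy": {"pos": 2, "loc": "axis"}})
        w2, stimuli = world_step(w, 1, [T("grasp(obj(toy,2))")])
        assert w2.objects["toy"]["loc"] == "held" and stimuli == []

    def test_action_on_missing_entity_is_noop(self):
        w = WorldState()
        w2, stimuli = world_step(w, 1, [T("search(obj(ghost,9))"), T("open(box(x,1))")])
        assert stimuli == [] and w2.objects == {}


class TestScenarios:
    @pytest.mark.parametrize("name", ["aplysia", "operant", "grasp", "track",
                                      "anotb", "obs55", "obs64"])
    def test_make_scenario_is_pure(self, name):
        a = scenario_to_yaml(make_scenario(name))
        b = scenario_to_yaml(make_scenario(name))
        assert a == b

    def test_unknown_scenario(self):
        with pytest.raises(ScenarioError, match="unknown scenario"):
            make_scenario("warp")

    def test_track_variants(self):
        stops = make_scenario("track", {"variant": "stops_in_view"})
        terms = [e.data["term"] for e in stops.events if e.kind == "stimulus"]
        assert terms[-1].startswith("halt(obj(toy,")
        occluded = make_scenario("track", {"variant": "occluded"})
        terms = [e.data["term"] for e in occluded.events if e.kind == "stimulus"]
        assert terms[-1].startswith("see(obj(s1,")

    def test_anotb_full_schedule(self):
        script = make_scenario("anotb", {"screens": ["s1", "s2"]})
        stims = [e.data["term"] for e in script.events if e.kind == "stimulus"]
        assert "see(obj(s1,3))" in stims and "see(obj(s2,7))" in stims
        assert "stop(obj(toy,3))" in stims and "stop(obj(toy,7))" in stims

    def test_yaml_round_trip(self, tmp_path):
        script = make_scenario("anotb")
        path = tmp_path / "anotb.yaml"
        save_scenario(script, path)
        loaded = load_scenario(path)
        assert scenario_to_yaml(loaded) == scenario_to_yaml(script)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with pytest.raises(ScenarioError, match="empty"):
            load_scenario(path)

    def test_decreasing_cycles_rejected(self):
        with pytest.raises(ScenarioError, match="non-decreasing"):
            scenario_from_yaml(
                "name: bad\nevents:\n- {cycle: 3, kind: stimulus, term: cs}\n"
                "- {cycle: 1, kind: stimulus, term: us}\n"
            )


class TestClosedLoopInvariants:
    def test_object_conservation_through_obs64(self):
        from virtcog.experiments import run_experiment

        outcome = run_experiment("obs64")
        assert outcome.world.check_conservation() == []
        assert outcome.world.objects["toy"]["loc"] == "held"

    def test_feedback_latency_is_one_cycle(self):
        """Every action->stimulus world rule answers at the next cycle."""
        from virtcog.experiments import run_experiment

        from virtcog.world import make_scenario
        from virtcog.experiments import EXPERIMENTS

        for name in ("anotb_strong", "obs55", "obs64"):
            exp = EXPERIMENTS[name]
            script = make_scenario(exp.scenario, exp.scenario_params)
            scripted = {
                (e.cycle, e.data["term"]) for e in script.events if e.kind == "stimulus"
            }
            outcome = run_experiment(name)
            events = outcome.trace.events
            feedback = [
                e for e in events
                if e.kind == "stimulus"
                and (e.cycle, e.payload) not in scripted
            ]
            assert feedback  # the loop is genuinely closed
            for e in feedback:
                provoking = [
                    a for a in events if a.kind == "action" and a.cycle == e.cycle - 1
                ]
                assert provoking, f"{name}: {e} has no action at cycle {e.cycle - 1}"
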