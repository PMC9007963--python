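import numpy as np
import pytest

import evacnet as ev


def all_stay_policy(params, state, visible, tick, rng):
    """Deterministic policy: never press, never evacuate."""
    return "none"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dynamic_dddd_log():
    cfg = ev.GameConfig(condition="dynamic_network",
                        disaster_pattern=[True] * 4, seed=3)
    return ev.run_session(cfg, session_id="dddd")


@pytest.fixture(scope="session")
def mixed_logs():
    """A small mixed-pattern batch of dynamic-network sessions."""
    logs = []
    for name, pattern in [("DDDD", [True] * 4),
                          ("DNDN", [True, False, True, False]),
                          ("NDND", [False, True, False, True])]:
        for s in range(3):
            cfg = ev.GameConfig(condition="dynamic_network",
                                disaster_pattern=pattern, seed=40 + s)
            logs.append(ev.run_session(cfg, session_id=f"{name}-{s}"))
    return logs


def make_handcrafted_log(events_spec, n_players=4, edges=(), duration=75.0,
                         disaster=False, persistence=5.0):
    """Build a one-round SessionLog directly from an event script.

    ``events_spec`` is a list of (t, player_id, kind) with kind in
    {press_safe, press_danger, evacuate}.  Round results are derived from
    the evacuations and the disaster flag.
    """
    cfg = ev.GameConfig(n_players=max(n_players, 12), condition="static_network",
                        disaster_pattern=[disaster], n_rounds=1, seed=0,
                        signal_persistence=persistence)
    net = ev.DirectedNetwork.from_edges(range(cfg.n_players), edges)
    evs = [ev.engine.Event(1, 0.0, None, "round_start",
                           {"duration": duration, "disaster_scheduled": disaster})]
    for t, pid, kind in sorted(events_spec):
        evs.append(ev.engine.Event(1, t, pid, kind, {}))
    if disaster:
        evs.append(ev.engine.Event(1, duration, None, "disaster_strike", {}))
    evs.append(ev.engine.Event(1, duration, None, "round_end", {}))
    evac = {pid: t for t, pid, kind in events_spec if kind == "evacuate"}
    per_player = {}
    for pid in range(cfg.n_players):
        evacuated = pid in evac
        per_player[pid] = {
            "action": "evacuated" if evacuated else "stayed",
            "correct": evacuated == disaster,
            "struck": disaster and not evacuated,
            "safe_display_seconds": 0.0,
            "danger_display_seconds": 0.0,
            "round_bonus": 0.0,
        }
    res = ev.RoundResult(1, duration, disaster, per_player)
    return ev.SessionLog(cfg, evs, [net], [res], informants=[0], session_id="hand")
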