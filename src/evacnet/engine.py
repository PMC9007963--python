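"""Event-driven engine for one round and one session of the evacuation game.

Each round, every player holds a $1.00 endowment and may pay $0.50 at any
moment to evacuate.  A disaster, when scheduled, strikes exactly at the
(unannounced) end of the round: players still present lose everything that
round.  Players who were not struck additionally earn $0.05 for every
*other* player who took the correct action (stay in a safe round, evacuate
in a disaster round).  In networked conditions players broadcast "Safe" or
"Danger" assessments that their followers see for 5 s.

Time is continuous in the log; agent decision epochs advance on a 1 s tick.
Round durations are drawn from Normal(75 s, 10 s), truncated below at a
configurable floor (30 s by default) to exclude degenerate draws.
All money is held internally in integer cents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import agents as agents_mod
from .agents import AgentParams, RewiringHeuristic
from .network import DirectedNetwork, generate_initial_network, sample_rewiring_offers, apply_rewiring

__all__ = [
    "GameConfig",
    "ExperienceRecord",
    "PlayerState",
    "RoundResult",
    "Event",
    "SessionLog",
    "CONDITIONS",
    "CANONICAL_PATTERNS",
    "round_bonus",
    "visible_displays",
    "run_round",
    "run_session",
    "session_earnings",
]

CONDITIONS = (
    "independent",
    "static_network",
    "dynamic_network",
    "random_informant",
    "isomorphic",
)

#: The four disaster arrangements of the main design: every round, never,
#: and the two alternating patterns.  Exactly half the rounds strike.
CANONICAL_PATTERNS = {
    "DDDD": [True, True, True, True],
    "NNNN": [False, False, False, False],
    "DNDN": [True, False, True, False],
    "NDND": [False, True, False, True],
}

_TICK = 1.0  # seconds between agent decision epochs


def _cents(dollars: float) -> int:
    return int(round(dollars * 100))


@dataclass(frozen=True)
class GameConfig:
    n_players: int = 16
    condition: str = "dynamic_network"
    disaster_pattern: list[bool] = field(default_factory=lambda: [True, True, True, True])
    round_duration_mean: float = 75.0
    round_duration_sd: float = 10.0
    round_duration_floor: float = 30.0
    signal_persistence: float = 5.0
    endowment: float = 1.00
    evacuation_cost: float = 0.50
    per_other_correct_bonus: float = 0.05
    completion_bonus: float = 1.00
    show_up_fee: float = 2.00
    initial_density: float = 0.25
    rewiring_fraction: float = 0.4
    n_rounds: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (12 <= self.n_players <= 16):
            raise ValueError("n_players must be in 12..16")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition != "isomorphic" and len(self.disaster_pattern) != self.n_rounds:
            raise ValueError("disaster_pattern length must equal n_rounds")
        for name in ("endowment", "evacuation_cost", "per_other_correct_bonus",
                     "completion_bonus", "show_up_fee"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.initial_density <= 1):
            raise ValueError("initial_density must be in (0, 1]")
        if not (0 <= self.rewiring_fraction <= 1):
            raise ValueError("rewiring_fraction must be in [0, 1]")


@dataclass
class ExperienceRecord:
    rounds_played: int = 0
    disasters_experienced: int = 0
    disasters_struck_by: int = 0

    def validate(self):
        if not (0 <= self.disasters_struck_by <= self.disasters_experienced
                <= self.rounds_played):
            raise ValueError("inconsistent experience record")


@dataclass
class PlayerState:
    player_id: int
    is_informant: bool = False
    knows_disaster: Optional[bool] = None
    evacuated_at: Optional[float] = None
    display_kind: Optional[str] = None  # "safe" | "danger" | None
    display_started_at: Optional[float] = None
    display_expires_at: Optional[float] = None
    last_own_signal: Optional[str] = None
    experience: ExperienceRecord = field(default_factory=ExperienceRecord)
    # per-round display-time accumulators, reset each round
    safe_display_seconds: float = 0.0
    danger_display_seconds: float = 0.0

    def display_at(self, t: float) -> str:
        """Current node color: 'grey', 'safe' or 'danger'.

        Evacuated players show grey forever after; a press shows its color
        on [t_press, t_press + persistence)."""
        if self.evacuated_at is not None and t >= self.evacuated_at:
            return "grey"
        if self.display_kind is not None and t < self.display_expires_at:
            return self.display_kind
        return "grey"

    def _close_display(self, t: float):
        """Credit the open display interval, clipped to t."""
        if self.display_kind is None:
            return
        end = min(self.display_expires_at, t)
        if end > self.display_started_at:
            secs = end - self.display_started_at
            if self.display_kind == "safe":
                self.safe_display_seconds += secs
            else:
                self.danger_display_seconds += secs
        self.display_kind = None
        self.display_started_at = None
        self.display_expires_at = None

    def press(self, kind: str, t: float, persistence: float):
        if self.evacuated_at is not None:
            raise ValueError("evacuated players cannot press")
        if self.display_kind == kind and t < self.display_expires_at:
            # re-press extends the window, never shortens it
            self.display_expires_at = t + persistence
        else:
            self._close_display(t)
            self.display_kind = kind
            self.display_started_at = t
            self.display_expires_at = t + persistence
        self.last_own_signal = kind

    def evacuate(self, t: float):
        if self.evacuated_at is not None:
            raise ValueError("already evacuated")
        self._close_display(t)
        self.evacuated_at = t


@dataclass
class RoundResult:
    round_index: int  # 1-based
    duration: float
    disaster_struck: bool
    per_player: dict  # player_id -> dict(action, correct, struck, *_display_seconds, round_bonus)


@dataclass
class Event:
    round: int
    t: float
    player_id: Optional[int]
    kind: str
    payload: dict = field(default_factory=dict)


@dataclass
class SessionLog:
    config: GameConfig
    events: list[Event]
    network_snapshots: list[DirectedNetwork]  # one per round, at round start
    round_results: list[RoundResult]
    informants: list[int] = field(default_factory=list)  # per round
    session_id: str = ""


def round_bonus(action: str, disaster: bool, n_other_correct: int, config: GameConfig) -> float:
    """Bonus for one player's round, in dollars.

    Struck players (stayed through a disaster) earn nothing, including the
    per-other bonus.  Evacuees pay the evacuation cost but keep the
    per-other bonus whether or not the disaster materializes.
    """
    if n_other_correct < 0:
        raise ValueError("n_other_correct must be >= 0")
    if n_other_correct > config.n_players - 1:
        raise ValueError("n_other_correct exceeds number of other players")
    if action not in ("stayed", "evacuated"):
        raise ValueError(f"unknown action {action!r}")
    per_other = _cents(config.per_other_correct_bonus) * n_other_correct
    if action == "stayed":
        if disaster:
            return 0.0
        return (_cents(config.endowment) + per_other) / 100
    return (_cents(config.endowment) - _cents(config.evacuation_cost) + per_other) / 100


def visible_displays(
    network: DirectedNetwork, players: dict[int, PlayerState], ego: int, t: float
) -> dict[int, str]:
    """Displays the ego currently sees: exactly their followees' colors."""
    if ego not in network.nodes:
        raise KeyError(ego)
    return {j: players[j].display_at(t) for j in network.followees(ego)}


def run_round(
    config: GameConfig,
    network: DirectedNetwork,
    players: dict[int, PlayerState],
    round_index: int,
    rng: np.random.Generator,
    agent_params: AgentParams | None = None,
    policy: Callable | None = None,
    events: list[Event] | None = None,
    duration: float | None = None,
    disaster: bool | None = None,
) -> RoundResult:
    """Run one round in place, mutating player states and appending events.

    ``duration`` and ``disaster`` override the config draw/pattern (used by
    the isomorphic condition, which replays a donor round's settings).
    """
    if not players:
        raise ValueError("empty player set")
    if set(players) != set(network.nodes):
        raise ValueError("network node set must equal player set")
    params = agent_params or agents_mod.DEFAULT_AGENT_PARAMS
    decide = policy or agents_mod.act
    ev = events if events is not None else []

    if disaster is None:
        disaster = bool(config.disaster_pattern[round_index - 1])
    if duration is None:
        duration = float(
            max(config.round_duration_floor,
                rng.normal(config.round_duration_mean, config.round_duration_sd))
        )
    duration = round(duration, 3)

    # fresh per-round state
    for p in players.values():
        p.evacuated_at = None
        p.display_kind = None
        p.display_started_at = None
        p.display_expires_at = None
        p.last_own_signal = None
        p.safe_display_seconds = 0.0
        p.danger_display_seconds = 0.0
        p.knows_disaster = disaster if p.is_informant else None

    ev.append(Event(round_index, 0.0, None, "round_start",
                    {"duration": duration, "disaster_scheduled": disaster}))

    order = sorted(players)
    t = _TICK
    while t <= duration:
        for pid in order:
            p = players[pid]
            if p.evacuated_at is not None:
                continue
            vis = visible_displays(network, players, pid, t)
            action = decide(params, p, vis, _TICK, rng)
            if action == "none":
                continue
            if action in ("press_safe", "press_danger"):
                kind = "safe" if action == "press_safe" else "danger"
                p.press(kind, t, config.signal_persistence)
                ev.append(Event(round_index, t, pid, action, {}))
            elif action == "evacuate":
                p.evacuate(t)
                ev.append(Event(round_index, t, pid, "evacuate", {}))
            else:
                raise ValueError(f"policy returned unknown action {action!r}")
        t += _TICK

    # close any open display windows at round end
    for p in players.values():
        p._close_display(duration)

    if disaster:
        ev.append(Event(round_index, duration, None, "disaster_strike", {}))

    # resolve outcomes and experience
    per_player = {}
    correct_flags = {}
    for pid in order:
        p = players[pid]
        evacuated = p.evacuated_at is not None
        correct_flags[pid] = evacuated == disaster
    for pid in order:
        p = players[pid]
        evacuated = p.evacuated_at is not None
        struck = disaster and not evacuated
        k = sum(1 for q, c in correct_flags.items() if q != pid and c)
        action = "evacuated" if evacuated else "stayed"
        per_player[pid] = {
            "action": action,
            "correct": correct_flags[pid],
            "struck": struck,
            "safe_display_seconds": round(p.safe_display_seconds, 3),
            "danger_display_seconds": round(p.danger_display_seconds, 3),
            "round_bonus": round_bonus(action, disaster, k, config),
        }
        p.experience.rounds_played += 1
        if disaster:
            p.experience.disasters_experienced += 1
            if struck:
                p.experience.disasters_struck_by += 1
        p.experience.validate()

    ev.append(Event(round_index, duration, None, "round_end", {}))
    return RoundResult(round_index, duration, disaster, per_player)


def _rewire_between_rounds(
    config: GameConfig,
    network: DirectedNetwork,
    result: RoundResult,
    heuristic: RewiringHeuristic,
    rng: np.random.Generator,
    events: list[Event],
    round_index: int,
) -> DirectedNetwork:
    info = {
        pid: {
            "evacuated": rec["action"] == "evacuated",
            "correct": rec["correct"],
            "safe_display_seconds": rec["safe_display_seconds"],
            "danger_display_seconds": rec["danger_display_seconds"],
        }
        for pid, rec in result.per_player.items()
    }
    offers = sample_rewiring_offers(network, config.rewiring_fraction, rng, info)
    decisions = []
    for offer in offers:
        action = agents_mod.decide_rewiring(heuristic, offer, rng)
        decisions.append((offer, action))
        if action == "keep":
            kind = "tie_keep_present" if offer.tie_exists else "tie_keep_absent"
        else:
            kind = "tie_make" if action == "make" else "tie_break"
        events.append(Event(round_index, result.duration, offer.follower, kind,
                            {"followee": offer.followee}))
    return apply_rewiring(network, decisions)


def run_session(
    config: GameConfig,
    agent_params: AgentParams | None = None,
    heuristic: RewiringHeuristic | None = None,
    policy: Callable | None = None,
    isomorphic_setup: dict | None = None,
    session_id: str = "",
) -> SessionLog:
    """Run a full session (n_rounds rounds, with between-round rewiring in
    the dynamic conditions) and return its event-sourced log.

    The isomorphic condition requires ``isomorphic_setup`` with keys
    ``network`` (donor final-round DirectedNetwork), ``informant``,
    ``duration`` and ``disaster``; fresh agents play a single round on it.
    """
    rng = np.random.default_rng(config.seed)
    heuristic = heuristic or agents_mod.DEFAULT_REWIRING_HEURISTIC
    n = config.n_players
    players = {i: PlayerState(player_id=i) for i in range(n)}
    events: list[Event] = []
    snapshots: list[DirectedNetwork] = []
    results: list[RoundResult] = []
    informants: list[int] = []

    if config.condition == "isomorphic":
        if isomorphic_setup is None:
            raise ValueError("isomorphic condition requires isomorphic_setup")
        network = isomorphic_setup["network"]
        informant = isomorphic_setup["informant"]
        players[informant].is_informant = True
        snapshots.append(network)
        informants.append(informant)
        res = run_round(
            config, network, players, 1, rng,
            agent_params=agent_params, policy=policy, events=events,
            duration=isomorphic_setup["duration"],
            disaster=isomorphic_setup["disaster"],
        )
        results.append(res)
        return SessionLog(config, events, snapshots, results, informants, session_id)

    if config.condition == "independent":
        network = DirectedNetwork.from_edges(range(n), [])
    else:
        network = generate_initial_network(n, config.initial_density, rng)

    informant = int(rng.integers(n))
    players[informant].is_informant = True

    n_rounds = config.n_rounds
    for r in range(1, n_rounds + 1):
        if config.condition == "random_informant" and r > 1:
            players[informant].is_informant = False
            informant = int(rng.integers(n))
            players[informant].is_informant = True
        informants.append(informant)
        snapshots.append(network)
        res = run_round(config, network, players, r, rng,
                        agent_params=agent_params, policy=policy, events=events)
        results.append(res)
        if r < n_rounds and config.condition in ("dynamic_network", "random_informant"):
            network = _rewire_between_rounds(config, network, res, heuristic,
                                             rng, events, r)
    return SessionLog(config, events, snapshots, results, informants, session_id)


def session_earnings(log: SessionLog) -> dict[int, float]:
    """Total earnings per player: show-up fee + completion bonus + round bonuses."""
    cfg = log.config
    totals = {}
    for pid in range(cfg.n_players):
        cents = _cents(cfg.show_up_fee) + _cents(cfg.completion_bonus)
        for res in log.round_results:
            cents += _cents(res.per_player[pid]["round_bonus"])
        totals[pid] = cents / 100
    return totals
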