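"""Serialization, study replication, and session quality control.

Session logs are stored as JSON Lines: a header line carrying the config,
informants, per-round network edge lists and round results, followed by one
event per line.  Configs round-trip through YAML; metric tables are written
as tidy CSV elsewhere in the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams, RewiringHeuristic
from .engine import (
    CANONICAL_PATTERNS,
    Event,
    GameConfig,
    RoundResult,
    SessionLog,
    run_session,
)
from .network import DirectedNetwork

__all__ = [
    "StudyDesign",
    "QCReport",
    "session_to_jsonl",
    "session_from_jsonl",
    "save_session",
    "load_session",
    "events_to_csv",
    "edges_to_csv",
    "config_to_yaml",
    "config_from_yaml",
    "session_seed",
    "run_study",
    "qc_filter",
    "write_manifest",
]

MAIN_SETTINGS = ("independent", "static_network", "dynamic_network")


@dataclass(frozen=True)
class StudyDesign:
    """The replication grid: 3 group settings x 4 disaster patterns x
    n_sessions_per_cell main sessions, plus the random-informant and
    isomorphic supplements (the full published design is 120 + 20 + 40)."""

    n_sessions_per_cell: int = 10
    n_random_informant: int = 20
    n_isomorphic: int = 40
    include_supplements: bool = True
    n_players: int = 16

    @property
    def n_main(self) -> int:
        return len(MAIN_SETTINGS) * len(CANONICAL_PATTERNS) * self.n_sessions_per_cell

    @property
    def n_total(self) -> int:
        if not self.include_supplements:
            return self.n_main
        return self.n_main + self.n_random_informant + self.n_isomorphic


@dataclass(frozen=True)
class QCReport:
    session_id: str
    informant_dropped: bool
    drop_fraction: float
    passed: bool


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _round3(t: float) -> float:
    return float(round(t, 3))


def session_to_jsonl(log: SessionLog) -> str:
    header = {
        "session_id": log.session_id,
        "config": dataclasses.asdict(log.config),
        "informants": list(log.informants),
        "networks": [
            [[u, v] for u, v in net.sorted_edges()] for net in log.network_snapshots
        ],
        "n_nodes": log.config.n_players,
        "round_results": [
            {
                "round_index": r.round_index,
                "duration": _round3(r.duration),
                "disaster_struck": r.disaster_struck,
                "per_player": {str(pid): rec for pid, rec in r.per_player.items()},
            }
            for r in log.round_results
        ],
    }
    lines = [json.dumps({"header": header}, sort_keys=True)]
    for e in log.events:
        lines.append(json.dumps({
            "round": e.round,
            "t": _round3(e.t),
            "player_id": e.player_id,
            "kind": e.kind,
            "payload": e.payload,
        }, sort_keys=True))
    return "\n".join(lines) + "\n"


def session_from_jsonl(text: str) -> SessionLog:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = json.loads(lines[0])["header"]
    config = GameConfig(**header["config"])
    nets = [
        DirectedNetwork.from_edges(range(header["n_nodes"]),
                                   [(u, v) for u, v in edges])
        for edges in header["networks"]
    ]
    results = [
        RoundResult(
            round_index=r["round_index"],
            duration=r["duration"],
            disaster_struck=r["disaster_struck"],
            per_player={int(pid): rec for pid, rec in r["per_player"].items()},
        )
        for r in header["round_results"]
    ]
    events = []
    for ln in lines[1:]:
        d = json.loads(ln)
        events.append(Event(d["round"], d["t"], d["player_id"], d["kind"], d["payload"]))
    return SessionLog(config, events, nets, results,
                      informants=list(header["informants"]),
                      session_id=header["session_id"])


def save_session(log: SessionLog, path: Path | str):
    Path(path).write_text(session_to_jsonl(log))


def load_session(path: Path | str) -> SessionLog:
    return session_from_jsonl(Path(path).read_text())


def events_to_csv(log: SessionLog) -> pd.DataFrame:
    return pd.DataFrame([
        {"session_id": log.session_id, "round": e.round, "t": _round3(e.t),
         "player_id": e.player_id, "kind": e.kind,
         "payload": json.dumps(e.payload, sort_keys=True)}
        for e in log.events
    ])


def edges_to_csv(log: SessionLog) -> pd.DataFrame:
    rows = []
    for r, net in enumerate(log.network_snapshots, start=1):
        for u, v in net.sorted_edges():
            rows.append({"session_id": log.session_id, "round": r,
                         "follower": u, "followee": v})
    return pd.DataFrame(rows)


def config_to_yaml(config: GameConfig, agents: AgentParams | None = None,
                   heuristic: RewiringHeuristic | None = None) -> str:
    doc = {"game": dataclasses.asdict(config)}
    if agents is not None:
        doc["agents"] = dataclasses.asdict(agents)
    if heuristic is not None:
        doc["rewiring_heuristic"] = dataclasses.asdict(heuristic)
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> tuple[GameConfig, AgentParams | None, RewiringHeuristic | None]:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "game" not in doc:
        raise ValueError("config must contain a 'game' section")
    try:
        cfg = GameConfig(**doc["game"])
    except TypeError as exc:
        raise ValueError(f"malformed game config: {exc}") from exc
    agents = AgentParams(**doc["agents"]) if "agents" in doc else None
    heur = (RewiringHeuristic(**doc["rewiring_heuristic"])
            if "rewiring_heuristic" in doc else None)
    return cfg, agents, heur


# ---------------------------------------------------------------------------
# study replication
# ---------------------------------------------------------------------------

def session_seed(base_seed: int, index: int) -> int:
    """Counter-based per-session seed: each session is independently
    reproducible from (base_seed, session index)."""
    return int(np.random.SeedSequence([int(base_seed), int(index)])
               .generate_state(1)[0] % (2**31))


def run_study(
    design: StudyDesign,
    base_seed: int = 0,
    agent_params: AgentParams | None = None,
    heuristic: RewiringHeuristic | None = None,
) -> list[SessionLog]:
    """Run the full condition grid deterministically.

    Isomorphic sessions copy the final-round network, informant, round
    duration and disaster flag from their donor dynamic-network session
    (one donor per isomorphic session, cycling over the main design's
    dynamic sessions) but instantiate fresh agents with zero experience.
    """
    logs: list[SessionLog] = []
    idx = 0
    dynamic_logs: list[SessionLog] = []
    for setting in MAIN_SETTINGS:
        for pname, pattern in CANONICAL_PATTERNS.items():
            for s in range(design.n_sessions_per_cell):
                cfg = GameConfig(
                    n_players=design.n_players,
                    condition=setting,
                    disaster_pattern=list(pattern),
                    seed=session_seed(base_seed, idx),
                )
                sid = f"{setting}-{pname}-{s:02d}"
                log = run_session(cfg, agent_params=agent_params,
                                  heuristic=heuristic, session_id=sid)
                logs.append(log)
                if setting == "dynamic_network":
                    dynamic_logs.append(log)
                idx += 1
    if not design.include_supplements:
        return logs

    patterns = list(CANONICAL_PATTERNS.items())
    for s in range(design.n_random_informant):
        pname, pattern = patterns[s % len(patterns)]
        cfg = GameConfig(
            n_players=design.n_players,
            condition="random_informant",
            disaster_pattern=list(pattern),
            seed=session_seed(base_seed, idx),
        )
        logs.append(run_session(cfg, agent_params=agent_params,
                                heuristic=heuristic,
                                session_id=f"random_informant-{pname}-{s:02d}"))
        idx += 1

    if design.n_isomorphic and not dynamic_logs:
        raise ValueError("isomorphic sessions requested before donor sessions exist")
    for s in range(design.n_isomorphic):
        donor = dynamic_logs[s % len(dynamic_logs)]
        final = donor.round_results[-1]
        cfg = GameConfig(
            n_players=donor.config.n_players,
            condition="isomorphic",
            disaster_pattern=[final.disaster_struck],
            n_rounds=1,
            seed=session_seed(base_seed, idx),
        )
        setup = {
            "network": donor.network_snapshots[-1],
            "informant": donor.informants[-1],
            "duration": final.duration,
            "disaster": final.disaster_struck,
        }
        logs.append(run_session(cfg, agent_params=agent_params,
                                heuristic=heuristic, isomorphic_setup=setup,
                                session_id=f"isomorphic-{donor.session_id}-{s:02d}"))
        idx += 1
    return logs


def qc_filter(
    sessions: list[tuple[SessionLog, list[dict]]]
) -> tuple[list[SessionLog], list[QCReport]]:
    """Apply the session quality-control rules to ingested logs.

    Each item is ``(log, drops)`` where drops is a list of
    ``{"player_id": ..., "round": ...}`` records (only real, ingested data
    has drops; the simulator produces none).  A session fails if its
    informant dropped in any round, or if more than 25% of initial players
    dropped."""
    passed_logs, reports = [], []
    for log, drops in sessions:
        dropped_ids = {d["player_id"] for d in drops}
        informant_dropped = any(
            d["player_id"] == log.informants[min(d.get("round", 1), len(log.informants)) - 1]
            for d in drops
        )
        frac = len(dropped_ids) / log.config.n_players
        ok = (not informant_dropped) and frac <= 0.25
        reports.append(QCReport(log.session_id, informant_dropped, frac, ok))
        if ok:
            passed_logs.append(log)
    return passed_logs, reports


def write_manifest(logs: list[SessionLog], base_seed: int, out_dir: Path | str) -> dict:
    """JSON manifest listing seeds, per-cell counts and session checksums."""
    out_dir = Path(out_dir)
    cells: dict[str, int] = {}
    sessions = []
    for log in logs:
        key = f"{log.config.condition}"
        cells[key] = cells.get(key, 0) + 1
        text = session_to_jsonl(log)
        sessions.append({
            "session_id": log.session_id,
            "condition": log.config.condition,
            "seed": log.config.seed,
            "sha256": hashlib.sha256(text.encode()).hexdigest(),
        })
    manifest = {"base_seed": base_seed, "n_sessions": len(logs),
                "per_condition": cells, "sessions": sessions}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
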