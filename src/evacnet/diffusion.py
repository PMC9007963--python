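"""Signal diffusion chains: source identification, chain attribution, size
distributions, and prevalence curves.

A *diffusion source* is a player who presses a signal when none of their
followees has pressed that signal type earlier in the round.  A press (or,
for danger signals, an evacuation) that follows at least one followee's
earlier same-type press joins the chain of the followee with the earliest
qualifying press.  Each player belongs to at most one chain per
(signal type, round), at their first qualifying action; the chain size
counts all distinct members including the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import SessionLog

__all__ = [
    "DiffusionChain",
    "ChainSizeDistribution",
    "extract_chains",
    "ccdf",
    "compare_size_distributions",
    "prevalence_curves",
    "display_intervals",
]


@dataclass
class DiffusionChain:
    signal_type: str  # "safe" | "danger"
    round: int
    source: int
    members: list = field(default_factory=list)  # (player_id, t, via)

    @property
    def size(self) -> int:
        return len({pid for pid, _, _ in self.members})


@dataclass
class ChainSizeDistribution:
    sizes: list[int]
    ccdf: dict[int, float]  # size s -> fraction of chains with size >= s


def _round_events(log: SessionLog, round_index: int):
    evs = [e for e in log.events if e.round == round_index]
    if not any(e.kind == "round_start" for e in evs):
        raise ValueError(f"round {round_index} not in log")
    return evs


def extract_chains(
    log: SessionLog, round_index: int, require_display_open: bool = False
) -> list[DiffusionChain]:
    """Attribute the round's presses (and danger-chain evacuations) to chains.

    ``require_display_open`` switches to the strict mode in which a
    followee's press only qualifies while its 5 s display window is still
    open at the responder's action time; the default only requires the
    press to precede the action within the round.

    Ties in qualifying-press time are broken toward the smaller player
    identifier.  Evacuations never seed chains; they can only join danger
    chains.
    """
    if round_index - 1 >= len(log.network_snapshots):
        raise ValueError("missing network snapshot for round")
    network = log.network_snapshots[round_index - 1]
    evs = _round_events(log, round_index)
    persistence = log.config.signal_persistence

    presses = {"safe": [], "danger": []}  # (t, player)
    for e in evs:
        if e.kind == "press_safe":
            presses["safe"].append((e.t, e.player_id))
        elif e.kind == "press_danger":
            presses["danger"].append((e.t, e.player_id))
    evacuations = [(e.t, e.player_id) for e in evs if e.kind == "evacuate"]

    chains: list[DiffusionChain] = []
    for sig in ("safe", "danger"):
        stream = [(t, pid, "press") for t, pid in presses[sig]]
        if sig == "danger":
            stream += [(t, pid, "evacuation") for t, pid in evacuations]
        stream.sort(key=lambda x: (x[0], x[1], 0 if x[2] == "press" else 1))

        member_chain: dict[int, DiffusionChain] = {}
        press_log: list[tuple[float, int]] = sorted(presses[sig])
        for t, pid, via in stream:
            if pid in member_chain:
                continue
            followees = set(network.followees(pid))
            qualifying = [
                (tq, q) for tq, q in press_log
                if q in followees and tq < t
                and (not require_display_open or t < tq + persistence)
            ]
            if qualifying:
                tq, q = min(qualifying)
                member_chain[pid] = member_chain[q]
                member_chain[pid].members.append((pid, t, via))
            elif via == "press":
                chain = DiffusionChain(sig, round_index, pid, [(pid, t, "press")])
                chains.append(chain)
                member_chain[pid] = chain
            # an unattributed evacuation joins nothing
    return chains


def ccdf(chains: list[DiffusionChain]) -> ChainSizeDistribution:
    """Complementary cumulative distribution of chain sizes:
    ccdf(s) = fraction of chains with size >= s, at each observed size."""
    if not chains:
        raise ValueError("no chains")
    sizes = sorted(c.size for c in chains)
    n = len(sizes)
    out = {s: sum(1 for x in sizes if x >= s) / n for s in sorted(set(sizes))}
    return ChainSizeDistribution(sizes=sizes, ccdf=out)


def compare_size_distributions(a, b) -> dict:
    """Two-sample Kolmogorov–Smirnov comparison of chain-size multisets.

    Uses the exact null distribution when both samples have n <= 25 and
    the asymptotic approximation otherwise."""
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("empty sample")
    method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def display_intervals(log: SessionLog, round_index: int) -> dict[int, list[tuple]]:
    """Per-player display windows [(start, end, kind)] reconstructed from the
    round's press/evacuate events with 5 s persistence and extension on
    same-type re-press."""
    evs = _round_events(log, round_index)
    duration = next(e.payload["duration"] for e in evs if e.kind == "round_start")
    persistence = log.config.signal_persistence
    out: dict[int, list[tuple]] = {}
    open_win: dict[int, list] = {}  # pid -> [start, expire, kind]

    def close(pid, at):
        if pid in open_win:
            s, x, k = open_win.pop(pid)
            end = min(x, at)
            if end > s:
                out.setdefault(pid, []).append((s, end, k))

    for e in sorted(evs, key=lambda e: (e.t, e.player_id is None, e.player_id or 0)):
        if e.kind in ("press_safe", "press_danger"):
            kind = "safe" if e.kind == "press_safe" else "danger"
            pid = e.player_id
            if pid in open_win and open_win[pid][2] == kind and e.t < open_win[pid][1]:
                open_win[pid][1] = e.t + persistence
            else:
                close(pid, e.t)
                open_win[pid] = [e.t, e.t + persistence, kind]
        elif e.kind == "evacuate":
            close(e.player_id, e.t)
    for pid in list(open_win):
        close(pid, duration)
    return out


def prevalence_curves(log: SessionLog, round_index: int, grid: float = 1.0) -> pd.DataFrame:
    """Fractions of players showing safe, showing danger, and evacuated at
    each grid time in the round; the grey fraction is the remainder."""
    if grid <= 0:
        raise ValueError("grid step must be > 0")
    evs = _round_events(log, round_index)
    duration = next(e.payload["duration"] for e in evs if e.kind == "round_start")
    n = log.config.n_players
    windows = display_intervals(log, round_index)
    evac_t = {e.player_id: e.t for e in evs if e.kind == "evacuate"}

    times = np.arange(0.0, duration + 1e-9, grid)
    rows = []
    for t in times:
        evac = sum(1 for tt in evac_t.values() if tt <= t)
        safe = danger = 0
        for pid, ivs in windows.items():
            if pid in evac_t and evac_t[pid] <= t:
                continue
            for s, e, k in ivs:
                if s <= t < e:
                    if k == "safe":
                        safe += 1
                    else:
                        danger += 1
                    break
        rows.append({
            "t": float(t),
            "showing_safe": safe / n,
            "showing_danger": danger / n,
            "evacuated": evac / n,
        })
    return pd.DataFrame(rows)
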