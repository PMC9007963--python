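"""Session-level outcome metrics and the small statistics toolkit.

Accuracy profiles use the *session* as the unit of analysis: the fraction
of players taking the correct action is computed per session and round,
then averaged within condition, with 95% t-intervals among sessions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import SessionLog

__all__ = [
    "accuracy_by_round",
    "decision_consistency",
    "welch_t",
    "paired_t",
    "two_prop_z",
    "wilson_ci",
]


def _t_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return (m, m)
    half = sps.t.ppf((1 + level) / 2, n - 1) * np.std(values, ddof=1) / math.sqrt(n)
    return (m - half, m + half)


def accuracy_by_round(logs: list[SessionLog], by_disaster: bool = False) -> pd.DataFrame:
    """Average fraction of players taking the correct action, per condition
    and round (optionally split by whether the round's disaster struck),
    with 95% t-intervals across sessions."""
    if not logs:
        raise ValueError("no logs")
    recs = []
    for log in logs:
        for res in log.round_results:
            frac = float(np.mean([p["correct"] for p in res.per_player.values()]))
            recs.append({
                "condition": log.config.condition,
                "round": res.round_index,
                "disaster": res.disaster_struck,
                "fraction": frac,
            })
    df = pd.DataFrame(recs)
    keys = ["condition", "round"] + (["disaster"] if by_disaster else [])
    rows = []
    for key, grp in df.groupby(keys):
        vals = grp["fraction"].to_numpy()
        lo, hi = _t_interval(vals)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({
            "fraction_correct": float(np.mean(vals)),
            "n_sessions": len(vals),
            "ci_lower": lo,
            "ci_upper": hi,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def decision_consistency(logs: list[SessionLog]) -> pd.DataFrame:
    """Fraction of players making the identical stay/evacuate decision in
    every no-disaster round, per condition.  Conditions whose pattern has
    fewer than two no-disaster rounds are reported absent (NaN)."""
    if not logs:
        raise ValueError("no logs")
    per_cond: dict[str, list[bool]] = {}
    insufficient: set[str] = set()
    for log in logs:
        cond = log.config.condition
        nd_rounds = [r for r in log.round_results if not r.disaster_struck]
        if len(nd_rounds) < 2:
            insufficient.add(cond)
            continue
        for pid in range(log.config.n_players):
            decisions = {r.per_player[pid]["action"] for r in nd_rounds}
            per_cond.setdefault(cond, []).append(len(decisions) == 1)
    rows = []
    for cond in sorted(set(per_cond) | insufficient):
        flags = per_cond.get(cond)
        rows.append({
            "condition": cond,
            "fraction_consistent": float(np.mean(flags)) if flags else np.nan,
            "n_players": len(flags) if flags else 0,
        })
    return pd.DataFrame(rows)


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t-test; returns (t, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t-test; returns (t, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.allclose(a - b, (a - b)[0]) and np.std(a - b) == 0 and (a - b)[0] == 0:
        return 0.0, 1.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance; returns (z, two-sided p)."""
    if min(n1, n2) < 1 or k1 < 0 or k2 < 0 or k1 > n1 or k2 > n2:
        raise ValueError("invalid counts")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if denom == 0:
        return 0.0, 1.0
    z = (p1 - p2) / denom
    return z, float(2 * sps.norm.sf(abs(z)))


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError("invalid counts")
    z = sps.norm.ppf((1 + level) / 2)
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == n else min(1.0, center + half)
    return (lo, hi)
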