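"""Individual responsiveness: counting-process construction and a Cox
proportional-hazards fitter with time-varying covariates and an optional
per-player gamma frailty.

The hazard of player i's terminal action (evacuation, or first signal) is

    lambda_i(t | P_i, X_i(t), G_i, Y_i(t))
        = lambda_0(t) * exp(b_P'P_i + b_X'X_i(t) + b_G'G_i + b_Y'Y_i(t) + g_i)

where P_i is pre-round experience (rounds played, disasters experienced,
disasters struck by), X_i(t) counts followees *currently displaying* each
signal (left-continuous, so a change at t affects the hazard only after t),
G_i is network position (out-degree, in-degree, plasticity indicator), and
Y_i(t) counts the player's own prior presses of each signal.  g_i is an
individual random effect, modeled here as log-gamma frailty.

Estimation maximizes the Breslow partial likelihood by Newton iteration;
the frailty variance is profiled on a grid using a Laplace approximation to
the marginal likelihood.  The module follows the statsmodels convention:
``EvacuationHazardModel`` is built from data and ``fit()`` returns a
``HazardResults`` carrying estimates, standard errors and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .diffusion import display_intervals
from .engine import SessionLog

__all__ = [
    "build_counting_process",
    "EvacuationHazardModel",
    "HazardResults",
    "cumulative_action_probability",
    "conditional_evacuation_table",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = [
    "rounds_played", "disasters_experienced", "disasters_struck_by",
    "x_safe", "x_danger",
    "out_degree", "in_degree", "plasticity",
    "y_safe", "y_danger",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# counting-process construction
# ---------------------------------------------------------------------------

def _experience_before(log: SessionLog, round_index: int) -> dict[int, tuple[int, int, int]]:
    out = {}
    for pid in range(log.config.n_players):
        rounds = disasters = struck = 0
        for res in log.round_results[: round_index - 1]:
            rounds += 1
            if res.disaster_struck:
                disasters += 1
                if res.per_player[pid]["struck"]:
                    struck += 1
        out[pid] = (rounds, disasters, struck)
    return out


def build_counting_process(
    log: SessionLog,
    terminal: str = "evacuation",
    rounds: list[int] | None = None,
) -> pd.DataFrame:
    """Expand a session log into (start, stop] intervals with constant
    covariates, one block per player-round.

    The timeline of each player-round is split at every covariate change
    point: a followee's display switching on or off, and the player's own
    presses (which increment the Y block).  Covariates are left-continuous:
    the value on (start, stop] is the value just after ``start``, so an
    exposure beginning at t cannot explain an action at t.  Follow-up is
    right-censored at round end; ``terminal`` selects evacuation or the
    first signal press as the event (for first_signal, evacuation censors).
    """
    if terminal not in ("evacuation", "first_signal"):
        raise ValueError("terminal must be 'evacuation' or 'first_signal'")
    rows = []
    plasticity = int(log.config.condition in ("dynamic_network", "random_informant"))
    for r in rounds or range(1, len(log.round_results) + 1):
        res = log.round_results[r - 1]
        network = log.network_snapshots[r - 1]
        evs = [e for e in log.events if e.round == r]
        duration = res.duration
        exp_before = _experience_before(log, r)
        windows = display_intervals(log, r)
        evac_t = {e.player_id: e.t for e in evs if e.kind == "evacuate"}
        press_t = {}
        for e in evs:
            if e.kind in ("press_safe", "press_danger"):
                kind = "safe" if e.kind == "press_safe" else "danger"
                press_t.setdefault(e.player_id, []).append((e.t, kind))

        for pid in range(log.config.n_players):
            own = sorted(press_t.get(pid, []))
            if terminal == "evacuation":
                if pid in evac_t:
                    t_end, event = evac_t[pid], True
                else:
                    t_end, event = duration, False
            else:
                first = own[0][0] if own else np.inf
                stop_at = min(first, evac_t.get(pid, np.inf), duration)
                t_end, event = float(stop_at), bool(first == stop_at and np.isfinite(first))
            if t_end > duration + 1e-9:
                raise ValueError("terminal action after round end (corrupt log)")
            if t_end <= 0:
                continue

            followees = network.followees(pid)
            cuts = {0.0, t_end}
            fw = []  # (s, e, kind) windows of followees
            for j in followees:
                for s, e, k in windows.get(j, []):
                    fw.append((s, e, k))
                    for c in (s, e):
                        if 0.0 < c < t_end:
                            cuts.add(c)
            for t, _ in own:
                if 0.0 < t < t_end:
                    cuts.add(t)
            grid = sorted(cuts)
            rp, de, ds = exp_before[pid]
            for a, b in zip(grid[:-1], grid[1:]):
                m = 0.5 * (a + b)
                x_safe = sum(1 for s, e, k in fw if k == "safe" and s <= m < e)
                x_danger = sum(1 for s, e, k in fw if k == "danger" and s <= m < e)
                y_safe = sum(1 for t, k in own if k == "safe" and t < m)
                y_danger = sum(1 for t, k in own if k == "danger" and t < m)
                rows.append({
                    "session_id": log.session_id,
                    "player_id": pid,
                    "subject": f"{log.session_id}:{pid}",
                    "round": r,
                    "start": a,
                    "stop": b,
                    "event": bool(event and b == grid[-1]),
                    "is_informant": pid in log.informants[r - 1:r],
                    "rounds_played": rp,
                    "disasters_experienced": de,
                    "disasters_struck_by": ds,
                    "x_safe": x_safe,
                    "x_danger": x_danger,
                    "out_degree": network.out_degree(pid),
                    "in_degree": network.in_degree(pid),
                    "plasticity": plasticity,
                    "y_safe": y_safe,
                    "y_danger": y_danger,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial-likelihood machinery
# ---------------------------------------------------------------------------

def _risk_mask(start, stop, times):
    """Boolean (K, n): row k marks intervals at risk at event time t_k."""
    return (start[None, :] < times[:, None]) & (times[:, None] <= stop[None, :])


def _pl_parts(start, stop, event, X, beta, ties="breslow"):
    """Partial log-likelihood, gradient and Hessian (Breslow or Efron ties).

    The Breslow path is fully vectorized over event times for narrow
    designs and falls back to a per-event-time loop when the design is wide
    (frailty fits, where the per-subject indicator block makes the S2
    matvec route quadratic).  The Efron path always loops over event times,
    with an inner loop over the tied events."""
    if ties == "efron":
        return _pl_parts_efron(start, stop, event, X, beta)
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    times = np.unique(stop[event])
    K = len(times)
    k_idx = np.searchsorted(times, stop[event])
    d = np.bincount(k_idx, minlength=K).astype(float)
    M = _risk_mask(start, stop, times).astype(float)
    S0 = M @ w
    S1 = M @ (w[:, None] * X)
    xbar = S1 / S0[:, None]
    ll = float(eta[event].sum() - (d * np.log(S0)).sum())
    sum_x_events = np.zeros((K, p))
    np.add.at(sum_x_events, k_idx, X[event])
    grad = sum_x_events.sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
    hess = np.zeros((p, p))
    if p <= 20:
        for a in range(p):
            for b in range(a, p):
                S2ab = M @ (w * X[:, a] * X[:, b])
                h = -(d * (S2ab / S0 - xbar[:, a] * xbar[:, b])).sum()
                hess[a, b] = h
                hess[b, a] = h
    else:
        Mb = M.astype(bool)
        for k in range(K):
            r = Mb[k]
            Xr = X[r]
            S2 = (Xr * w[r][:, None]).T @ Xr
            hess -= d[k] * (S2 / S0[k] - np.outer(xbar[k], xbar[k]))
    return ll, grad, hess, times, d, S0


def _pl_parts_efron(start, stop, event, X, beta):
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    times = np.unique(stop[event])
    M = _risk_mask(start, stop, times)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for k, t in enumerate(times):
        r = M[k]
        D = event & (stop == t)
        d = int(D.sum())
        Xr, wr = X[r], w[r]
        XD, wD = X[D], w[D]
        S0, S0D = wr.sum(), wD.sum()
        S1, S1D = wr @ Xr, wD @ XD
        S2 = (Xr * wr[:, None]).T @ Xr
        S2D = (XD * wD[:, None]).T @ XD
        ll += eta[D].sum()
        grad += XD.sum(axis=0)
        for l in range(d):
            f = l / d
            den = S0 - f * S0D
            xbar = (S1 - f * S1D) / den
            ll -= np.log(den)
            grad -= xbar
            hess -= (S2 - f * S2D) / den - np.outer(xbar, xbar)
    d_all = np.array([np.sum(event & (stop == t)) for t in times], dtype=float)
    S0_all = M @ w
    return ll, grad, hess, times, d_all, S0_all


def _newton(start, stop, event, X, penalty=None, tol=1e-8, max_iter=100,
            ties="breslow"):
    """Newton–Raphson on the (optionally penalized) partial likelihood.

    ``penalty`` is a callable beta -> (value, grad, hess_diag_update) or
    None.  Returns (beta, loglik_unpenalized, hess, n_iter, grad_norm)."""
    p = X.shape[1]
    beta = np.zeros(p)

    def objective(b):
        ll, g, h, *_ = _pl_parts(start, stop, event, X, b, ties=ties)
        if penalty is not None:
            pv, pg, ph = penalty(b)
            return ll + pv, g + pg, h + ph, ll
        return ll, g, h, ll

    obj, grad, hess, ll_plain = objective(beta)
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            return beta, ll_plain, hess, it - 1, gnorm
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iter {it}") from exc
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            new_obj, new_grad, new_hess, new_ll = objective(cand)
            if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                break
            alpha *= 0.5
        beta, obj, grad, hess, ll_plain = cand, new_obj, new_grad, new_hess, new_ll
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "diverging coefficients (|beta| > 50): likely complete separation"
            )
    gnorm = float(np.linalg.norm(grad))
    if gnorm >= tol:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (last |grad| = {gnorm:.3g})"
        )
    return beta, ll_plain, hess, max_iter, gnorm


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class EvacuationHazardModel:
    """Proportional-hazards model on counting-process data.

    Parameters
    ----------
    data : DataFrame with ``start``, ``stop``, boolean ``event`` and the
        covariate columns.
    covariates : columns entering the linear predictor.  Covariates that
        are constant across all rows are dropped with a warning.
    subject_col : column identifying the individual, required for the
        frailty fit and for cluster-robust errors.
    """

    def __init__(self, data: pd.DataFrame, covariates: list[str] | None = None,
                 subject_col: str = "subject"):
        if data.empty:
            raise ValueError("empty counting-process data")
        if not data["event"].any():
            raise ValueError("no events in data")
        covariates = list(covariates or [c for c in DEFAULT_COVARIATES if c in data.columns])
        kept = []
        for c in covariates:
            if data[c].nunique() <= 1:
                warnings.warn(f"dropping constant covariate {c!r}", stacklevel=2)
            else:
                kept.append(c)
        if not kept:
            raise ValueError("no non-constant covariates")
        # drop exactly collinear columns (e.g. rounds_played ==
        # disasters_experienced under an every-round disaster pattern)
        Xc = data[kept].to_numpy(float)
        Xc = Xc - Xc.mean(axis=0)
        _, R = np.linalg.qr(Xc)
        diag = np.abs(np.diag(R))
        scale = diag.max() if diag.size else 1.0
        independent = []
        for j, c in enumerate(kept):
            if diag[j] > 1e-10 * max(scale, 1.0):
                independent.append(c)
            else:
                warnings.warn(f"dropping collinear covariate {c!r}", stacklevel=2)
        if not independent:
            raise ValueError("no linearly independent covariates")
        kept = independent
        self.data = data.reset_index(drop=True)
        self.covariates = kept
        self.subject_col = subject_col

    @classmethod
    def from_counting_process(cls, data: pd.DataFrame, **kw) -> "EvacuationHazardModel":
        return cls(data, **kw)

    @classmethod
    def from_logs(cls, logs: list[SessionLog], terminal: str = "evacuation",
                  covariates: list[str] | None = None) -> "EvacuationHazardModel":
        frames = [build_counting_process(log, terminal=terminal) for log in logs]
        return cls(pd.concat(frames, ignore_index=True), covariates=covariates)

    def _arrays(self):
        d = self.data
        return (d["start"].to_numpy(float), d["stop"].to_numpy(float),
                d["event"].to_numpy(bool), d[self.covariates].to_numpy(float))

    def fit(self, frailty: bool = False, robust_cluster: str | None = None,
            ties: str = "breslow",
            theta_grid=(0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)) -> "HazardResults":
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        start, stop, event, X = self._arrays()
        Xc = X - X.mean(axis=0)  # center for numerical stability
        beta, ll, hess, niter, gnorm = _newton(start, stop, event, Xc, ties=ties)
        scaled = np.abs(beta) * Xc.std(axis=0)
        if np.any(scaled > 8):
            worst = self.covariates[int(np.argmax(scaled))]
            raise ConvergenceError(
                f"coefficient for {worst!r} diverges: complete separation suspected"
            )
        info_inv = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(info_inv))
        frailty_var = 0.0
        gamma = None
        if frailty:
            beta, gamma, frailty_var, ll = self._fit_frailty(
                start, stop, event, Xc, theta_grid, fallback=(beta, ll))
            # report fixed-effect SEs from the no-frailty information as an
            # approximation when frailty variance is estimated at zero
            if frailty_var > 0:
                se = np.sqrt(np.diag(np.linalg.inv(-self._joint_hess(
                    start, stop, event, Xc, beta, gamma, frailty_var)))[: len(beta)])
        cov = None
        if robust_cluster is not None:
            cov = self._robust_cov(start, stop, event, Xc, beta, info_inv,
                                   self.data[robust_cluster].to_numpy())
            se = np.sqrt(np.diag(cov))
        baseline = self._breslow_baseline(start, stop, event, Xc, beta, gamma)
        return HazardResults(
            model=self,
            params=pd.Series(beta, index=self.covariates),
            bse=pd.Series(se, index=self.covariates),
            loglik=float(ll),
            frailty_variance=float(frailty_var),
            frailty=gamma,
            baseline_cumhazard=baseline,
            n_events=int(event.sum()),
            n_intervals=len(stop),
            n_iter=niter,
            gradient_norm=gnorm,
            covariate_means=pd.Series(X.mean(axis=0), index=self.covariates),
        )

    # -- frailty -----------------------------------------------------------
    def _subject_design(self):
        subj = self.data[self.subject_col].astype(str).to_numpy()
        labels, idx = np.unique(subj, return_inverse=True)
        return labels, idx

    def _fit_frailty(self, start, stop, event, X, theta_grid, fallback):
        labels, idx = self._subject_design()
        q = len(labels)
        n, p = X.shape
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        W = np.hstack([X, Z])
        beta0, ll0 = fallback
        best = (0.0, beta0, None, ll0, ll0)  # theta, beta, gamma, lm, plain ll
        for theta in theta_grid:
            nu = 1.0 / theta

            def penalty(b, nu=nu):
                g = b[p:]
                val = nu * np.sum(g - np.exp(g))
                grad = np.zeros_like(b)
                grad[p:] = nu * (1.0 - np.exp(g))
                hess = np.zeros((p + q, p + q))
                hess[p:, p:] = -np.diag(nu * np.exp(g))
                return val, grad, hess

            try:
                coef, ll_plain, hess_pen, *_ = _newton(
                    start, stop, event, W, penalty=penalty, tol=1e-6)
            except ConvergenceError:
                continue
            g = coef[p:]
            dens = np.sum(nu * np.log(nu) - gammaln(nu) + nu * g - nu * np.exp(g))
            Hgg = -hess_pen[p:, p:]
            sign, logdet = np.linalg.slogdet(Hgg)
            if sign <= 0:
                continue
            lm = ll_plain + dens + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet
            if lm > best[3]:
                best = (theta, coef[:p], g, lm, ll_plain)
        theta, beta, gamma, _, ll_plain = best
        if gamma is not None:
            gamma = pd.Series(gamma, index=labels)
        return beta, gamma, theta, ll_plain

    def _joint_hess(self, start, stop, event, X, beta, gamma, theta):
        labels, idx = self._subject_design()
        q = len(labels)
        n, p = X.shape
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        W = np.hstack([X, Z])
        coef = np.concatenate([beta, gamma.to_numpy() if gamma is not None else np.zeros(q)])
        _, _, hess, *_ = _pl_parts(start, stop, event, W, coef)
        nu = 1.0 / theta
        hess[p:, p:] -= np.diag(nu * np.exp(coef[p:]))
        return hess

    # -- robust errors -----------------------------------------------------
    def _robust_cov(self, start, stop, event, X, beta, info_inv, clusters):
        eta = X @ beta
        w = np.exp(eta)
        times = np.unique(stop[event])
        M = _risk_mask(start, stop, times)
        d = np.array([np.sum(event & (stop == t)) for t in times], dtype=float)
        S0 = M @ w
        S1 = M @ (w[:, None] * X)
        xbar = S1 / S0[:, None]
        U = np.zeros_like(X)
        for k, t in enumerate(times):
            D = event & (stop == t)
            U[D] += X[D] - xbar[k]
            at_risk = M[k]
            U[at_risk] -= (d[k] * w[at_risk] / S0[k])[:, None] * (X[at_risk] - xbar[k])
        groups = pd.DataFrame(U).groupby(pd.Series(clusters)).sum().to_numpy()
        meat = groups.T @ groups
        return info_inv @ meat @ info_inv

    def _breslow_baseline(self, start, stop, event, X, beta, gamma):
        eta = X @ beta
        if gamma is not None:
            _, idx = self._subject_design()
            eta = eta + gamma.to_numpy()[idx]
        w = np.exp(eta)
        times = np.unique(stop[event])
        M = _risk_mask(start, stop, times)
        d = np.array([np.sum(event & (stop == t)) for t in times], dtype=float)
        increments = d / (M @ w)
        return pd.DataFrame({"t": times, "cum_hazard": np.cumsum(increments)})


@dataclass
class HazardResults:
    """Fitted proportional-hazards results (coefficients on the log-hazard
    scale, for covariates centered at their sample means)."""

    model: EvacuationHazardModel
    params: pd.Series
    bse: pd.Series
    loglik: float
    frailty_variance: float
    frailty: pd.Series | None
    baseline_cumhazard: pd.DataFrame
    n_events: int
    n_intervals: int
    n_iter: int
    gradient_norm: float
    covariate_means: pd.Series

    def confint(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.confint()
        return pd.DataFrame({
            "coef": self.params,
            "exp(coef)": np.exp(self.params),
            "se(coef)": self.bse,
            "z": self.zvalues,
            "p": self.pvalues,
            "ci95_lower": ci["lower"],
            "ci95_upper": ci["upper"],
        })

    def cumulative_action_probability(
        self, covariates: dict, horizon: float | None = None
    ) -> pd.DataFrame:
        """P(action by t) = 1 - exp(-Lambda0(t) * exp(x'beta)) for a fixed
        covariate scenario held constant over time."""
        missing = set(self.params.index) - set(covariates)
        if missing:
            raise ValueError(f"scenario missing covariates: {sorted(missing)}")
        x = np.array([covariates[c] for c in self.params.index], dtype=float)
        x = x - self.covariate_means[self.params.index].to_numpy()
        risk = float(np.exp(x @ self.params.to_numpy()))
        base = self.baseline_cumhazard
        if horizon is not None and horizon > base["t"].iloc[-1]:
            warnings.warn("horizon beyond last event time; curve truncated",
                          stacklevel=2)
        sel = base if horizon is None else base[base["t"] <= horizon]
        return pd.DataFrame({
            "t": sel["t"].to_numpy(),
            "prob": 1.0 - np.exp(-sel["cum_hazard"].to_numpy() * risk),
        })


def cumulative_action_probability(fit: HazardResults, covariates: dict,
                                  horizon: float | None = None) -> pd.DataFrame:
    """Functional alias for :meth:`HazardResults.cumulative_action_probability`."""
    return fit.cumulative_action_probability(covariates, horizon)


# ---------------------------------------------------------------------------
# conditional evacuation rates (experience effect at round 2)
# ---------------------------------------------------------------------------

def conditional_evacuation_table(logs: list[SessionLog]) -> pd.DataFrame:
    """Round-2 evacuation rate of non-informants, stratified by whether the
    round-1 disaster struck, per condition; Wilson 95% intervals and a
    two-proportion z-test between the strata."""
    from .stats import two_prop_z, wilson_ci

    counts: dict[tuple, list[int]] = {}
    for log in logs:
        if len(log.round_results) < 2:
            raise ValueError("need at least 2 rounds")
        cond = log.config.condition
        d1 = log.round_results[0].disaster_struck
        informant = log.informants[1]
        for pid, rec in log.round_results[1].per_player.items():
            if pid == informant:
                continue
            key = (cond, d1)
            k, n = counts.get(key, [0, 0])
            counts[key] = [k + (rec["action"] == "evacuated"), n + 1]

    rows = []
    for (cond, d1), (k, n) in sorted(counts.items()):
        lo, hi = wilson_ci(k, n)
        rows.append({
            "condition": cond, "round1_disaster": d1,
            "n": n, "n_evacuated": k, "rate": k / n,
            "ci_lower": lo, "ci_upper": hi,
        })
    df = pd.DataFrame(rows)
    zs, ps = [], []
    for _, row in df.iterrows():
        other = df[(df["condition"] == row["condition"])
                   & (df["round1_disaster"] != row["round1_disaster"])]
        if len(other) == 1:
            o = other.iloc[0]
            z, p = two_prop_z(int(row["n_evacuated"]), int(row["n"]),
                              int(o["n_evacuated"]), int(o["n"]))
            zs.append(z)
            ps.append(p)
        else:
            zs.append(np.nan)
            ps.append(np.nan)
    df["z_vs_other_stratum"] = zs
    df["p_vs_other_stratum"] = ps
    return df
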