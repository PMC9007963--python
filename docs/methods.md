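# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `evacnet`.

## Game engine

The engine is an event-sourced simulator of one session (default four
rounds) of the evacuation game for 12–16 players.

* **Time.** Event timestamps are continuous seconds from round start
  (serialized to 3 decimals); agent decision epochs advance on a fixed 1 s
  tick. The 1 s resolution is finer than any dynamic the analysis
  measures (the shortest relevant scale is the 5 s display window), and
  makes runs exactly reproducible. Within a tick, players are evaluated in
  ascending id order against the current display state, so a press at tick
  *t* is visible to players later in that tick's order; at 1 s resolution
  this ordering effect is negligible and deterministic.
* **Round duration** is drawn from Normal(75 s, 10 s), truncated below at
  a configurable floor (30 s default) to exclude degenerate draws; the
  truncation probability at the default is ~3×10⁻⁶, so the realized mean
  stays within Monte-Carlo error of 75 s.
* **Signals.** A press displays its color for exactly 5 s. Re-pressing the
  same button while the display is active extends the window to
  press-time + 5 s (never shortens it); pressing the other button switches
  the display immediately. Evacuation clears the display permanently.
  Per-round display seconds are accumulated per signal for the rewiring
  feedback.
* **Disaster resolution** happens exactly at round end; any player not yet
  evacuated at that instant is struck. Payoffs: a struck player earns $0
  for the round (including the per-other bonus); an unstruck stayer earns
  the $1.00 endowment; an evacuee earns $0.50 regardless of the disaster;
  unstruck players add $0.05 per other correct player. Money is held in
  integer cents internally to avoid floating-point drift.
* **Informant.** One player per session (re-drawn each round in the
  random-informant condition) carries a boolean knowledge flag — the
  advance message is modeled as knowledge, not as a text channel.
* Sessions re-run with the same config and seed serialize byte-identically.

## Networks and rewiring

Directed edges point follower → followee: the follower sees the followee's
display. The initial graph samples exactly round(0.25·n(n−1)) edges
uniformly without replacement (half-up rounding; for n = 16 that is 60
edges, density exactly 0.25). Between rounds in the dynamic conditions,
exactly round(0.4·n(n−1)) *ordered* pairs (96 for n = 16) are offered;
the follower decides unilaterally. Over the three between-round steps a
fixed ordered pair is offered at least once with probability
1 − 0.6³ = 0.784.

Structural metrics: density |E|/(n(n−1)); mean directed shortest-path
length over reachable ordered pairs with the unreachable fraction reported
alongside; clustering as global transitivity of the undirected projection
(no directed variant is singled out by the analysis; the choice is
documented and swappable in code).

## Synthetic agents

Agents are Markov within a tick given current exposure and accumulated
experience — the minimal behavioral structure consistent with the
proportional-hazards analysis applied to the logs. Action hazards
(events/second):

* press safe: `base_rate_safe · exp(b_safe_exposure·x_safe + repeat boost)`
* press danger: `base_rate_danger · exp(b_danger_exposure·x_danger +
  b_struck_on_danger·struck_by + repeat boost)`
* evacuate: `base_rate_evacuate · exp(b_danger_exposure·x_danger +
  b_struck_on_evacuate·struck_by)`

where `x_*` counts followees currently displaying that signal and
`struck_by` counts prior rounds in which the agent was struck. Informants
add `informant_truth_rate` to the truthful button's hazard and never press
the untruthful one. Per tick, an action fires with probability
1 − exp(−Σλ·tick) and is chosen proportionally to the hazards.

**Defaults are calibrated, not fitted.** The shipped parameters
(`provenance="calibrated"`) were chosen once by forward simulation so the
default population reproduces the qualitative experimental pattern: strong
status-quo bias (safe presses dominate danger presses absent experience),
rare first-round evacuation (~15%), high correct-stay in safe environments
(~83%), and evacuation rising steeply with strikes experienced. No claim
is made that they equal any human-fitted coefficients.
`calibrate_defaults` exposes the grid-search used, so users can re-target
the profile.

Tie-rewiring decisions are single Bernoulli draws at the four measured
rates conditioned on (tie exists, counterpart correct): 77.8% / 23.0% /
50.6% / 48.9%. The offer also carries the counterpart's signal-display
seconds; the default heuristic ignores them (correctness-only), leaving a
signal-aware heuristic as an extension hook.

**What the generator does and does not emulate.** It reproduces the study
design (group sizes, conditions, disaster patterns, timing, payoffs,
rewiring protocol) and a behaviorally plausible contagion process. It does
not emulate mid-game player dropping, learning within a round, strategic
reasoning about payoff externalities, or heterogeneity across subjects
(all agents share one parameter set; the frailty machinery will correctly
estimate ~zero heterogeneity on such logs). Passing tests therefore
validate the pipeline's correctness and the qualitative learning
mechanism, not quantitative human-subject outcomes.

## Diffusion chains

Within a (round, signal type), a press is a *source* iff no followee of
the presser pressed that type earlier in the round; otherwise the presser
joins the chain of the followee with the earliest qualifying press (ties
broken toward the smaller player id). Each player joins at most one chain
per type and round, at their first qualifying action. For danger chains,
an evacuation following a followee's danger press enrolls the evacuee
(`via="evacuation"`); evacuations never seed chains. Influence requires
precedence, not an open display window — `require_display_open=True`
switches to the strict 5 s-window reading. Cross-type triggering and
cross-round memory are excluded. Chain sizes feed CCDFs
(fraction of chains ≥ s) and two-sample Kolmogorov–Smirnov comparisons
(exact null when both n ≤ 25, asymptotic otherwise, via scipy).

## Hazard model

`build_counting_process` expands each player-round into (start, stop]
intervals split at every covariate change point (followee display on/off,
own presses). Covariates are left-continuous — the value on (start, stop]
is the value just after `start` — so a player's own press at *t* cannot
predict itself, and exposure means *currently displayed* signals, not
cumulative presses. Follow-up is right-censored at round end; rounds are
separate strata of a player's history only through the experience
covariates (P block), not through recurrent-event dependence.

The fitter maximizes the partial likelihood by Newton–Raphson with
step-halving to gradient norm < 1e−8, with Breslow tie handling by default
and Efron available (`ties="efron"`; the tick clock produces heavily tied
event times, and the cross-check against lifelines' time-varying fitter
uses Efron for that reason). Covariates are centered before fitting;
constant and exactly collinear columns are dropped with a warning (e.g.
rounds played equals disasters experienced under an every-round disaster
pattern). Diverging scaled coefficients raise a separation error rather
than returning a spurious fit. Standard errors come from the inverse
observed information; a cluster-robust (by session) sandwich variant is
available.

The individual random effect γ_i is modeled as log-gamma frailty
estimated by penalized partial likelihood; the frailty variance θ is
profiled over a grid by a Laplace approximation to the marginal
likelihood, which degenerates smoothly to the plain partial likelihood as
θ → 0. This is a documented approximation: the original random-effect
formulation is not fully specified, and gamma frailty is the standard
tractable choice. Cumulative action probabilities use the Breslow
baseline: P(t) = 1 − exp(−Λ₀(t)·exp(x′β)) for a held-fixed exposure
scenario (e.g. four followees: one safe, one danger, two silent) at each
prior struck-by count.

## Outcome metrics

Accuracy profiles use the session as the unit: fraction correct per
session-round, averaged within condition (optionally by disaster stratum),
with 95% t-intervals among sessions. Decision consistency is the fraction
of players making the identical stay/evacuate decision in all no-disaster
rounds (absent when fewer than two such rounds exist). The toolkit
(Welch/paired t, two-proportion z, Wilson interval) uses the textbook
definitions with two-sided p-values.

## Study replication and QC

`run_study` executes the full grid — 3 settings × 4 canonical disaster
patterns × 10 sessions (120), plus 20 random-informant and 40 isomorphic
sessions (180 total) — with per-session seeds derived counter-style from
the base seed, so any cell is independently reproducible. Isomorphic
sessions copy the donor dynamic session's final network, informant node,
round duration and disaster flag, with fresh zero-experience agents, for a
single round. Quality control for ingested (real) logs drops sessions
whose informant dropped or where more than 25% of initial players dropped;
the simulator itself produces no drops.

## Problem sizes in the shipped tests

The test suite runs the brute-force diffusion oracle on 1,000 random small
games, the Cox coverage study at 500 replicates of n = 2,000 subjects, and
the qualitative learning check on 20 sessions per cell — sizes chosen so
the full suite completes in a few minutes on one CPU while leaving the
Monte-Carlo error well below each assertion's margin.

## Known limitations

* Agent parameters are calibrated to a qualitative profile; numeric
  outcomes (e.g. exact round-4 accuracy) are properties of that
  calibration, not predictions of human data.
* The frailty estimate is Laplace-approximate and profiled on a coarse
  grid; it is meant for detecting heterogeneity, not precise variance
  estimation.
* Chain attribution resolves genuinely ambiguous multi-parent cascades by
  the earliest-press rule; alternative attributions would change chain
  sizes on dense graphs.
* No ingestion adapter for external deposited datasets is bundled; a
  column-mapping hook (the JSONL/CSV schemas) is the intended entry point.
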