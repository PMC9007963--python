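# evacnet

Agent-based simulation and analysis of iterated group **evacuation games**
on dynamic directed networks.

The package is aimed at researchers studying collective behavior and social
contagion under uncertainty: how groups of 12–16 people, one of whom (the
*informant*) secretly knows whether a disaster will strike, spread true
warnings and false reassurance through a directed communication network,
how individuals learn from being struck, and how between-round tie
rewiring reshapes the network around reliable sources.

## The game

Each round every player holds a $1.00 endowment and may pay $0.50 at any
moment to evacuate. A disaster, when scheduled, strikes at the unannounced
end of the round (duration ~ Normal(75 s, 10 s)): players still present
lose the round's earnings. Players not struck additionally earn $0.05 for
every *other* player who acted correctly (stay in a safe round, evacuate in
a disaster round). In networked conditions players broadcast "Safe"/"Danger"
signals their followers see for 5 s. In the dynamic-network condition, 40%
of ordered player pairs are offered for rewiring between rounds and each
follower unilaterally makes, breaks, or keeps the tie given the
counterpart's last-round performance. A session is four rounds; disaster
patterns cover always / never / alternating designs, and supplementary
conditions rotate the informant each round or replay an evolved network
topology with fresh players.

## The models

**Synthetic subjects** act by competing hazards: at each 1 s decision epoch
the rate of action *a* ∈ {press safe, press danger, evacuate} is

λ_a = base_a · exp(β·exposure + β·struck-by experience),

so warnings and evacuation become more likely as a player sees more danger
signals and accumulates disaster damage. Tie-rewiring decisions are
Bernoulli draws at the four empirically measured rates (make|correct 77.8%,
break|correct 23.0%, make|incorrect 50.6%, break|incorrect 48.9%).

**Analysis.** Signal *diffusion chains* are traced from spontaneous sources
(a presser none of whose followees pressed that signal type earlier)
through followee→follower influence, with size CCDFs and two-sample
Kolmogorov–Smirnov comparisons. *Individual responsiveness* is estimated
with a Cox proportional-hazards model on counting-process data with
time-varying exposure covariates,

λ_i(t | P_i, X_i(t), G_i, Y_i(t)) = λ_0(t) · exp(β_P′P_i + β_X′X_i(t) + β_G′G_i + β_Y′Y_i(t) + γ_i),

where X_i(t) counts followees currently displaying each signal, P_i is
prior experience (rounds, disasters experienced, disasters struck by),
G_i is network position, Y_i(t) counts own prior presses, and γ_i is an
optional per-player gamma frailty. The fitter follows the statsmodels
pattern: `EvacuationHazardModel(...).fit()` returns a `HazardResults` with
`params`, `bse`, `confint()`, `summary()` and cumulative action
probability curves.

## Worked example

```python
import evacnet as ev

logs = [ev.run_session(
            ev.GameConfig(condition="dynamic_network",
                          disaster_pattern=[True, False, True, False],
                          seed=s),
            session_id=f"demo-{s}")
        for s in range(10)]

print(ev.accuracy_by_round(logs, by_disaster=True).round(3).to_string(index=False))
r1 = [c.size for log in logs for c in ev.extract_chains(log, 1)]
r4 = [c.size for log in logs for c in ev.extract_chains(log, 4)]
print("KS round1 vs round4:", ev.compare_size_distributions(r1, r4))
print(ev.EvacuationHazardModel.from_logs(logs).fit().summary().round(3))
```

prints (abridged):

```
      condition  round  disaster  fraction_correct  n_sessions  ci_lower  ci_upper
dynamic_network      1      True             0.125          10     0.046     0.204
dynamic_network      2     False             0.650          10     0.583     0.717
dynamic_network      3      True             0.294          10     0.215     0.373
dynamic_network      4     False             0.462          10     0.361     0.564

KS round1 vs round4: {'D': 0.4883, 'p': 0.0001}

                        coef  exp(coef)  se(coef)      p
disasters_struck_by    0.989      2.689     0.224  0.000
x_danger               0.446      1.562     0.121  0.000
x_safe                 0.107      1.113     0.120  0.373
```

Reading it: with the default calibrated agents, almost nobody evacuates in
the first disaster round (12.5% correct), and performance in disaster
rounds improves as players are struck (29.4% by round 3). The chain-size
distribution shifts significantly between rounds 1 and 4 (Kolmogorov–
Smirnov D = 0.49). The hazard fit recovers what drives evacuation: each
prior strike multiplies the evacuation hazard by ~2.7, each currently
displayed danger signal by ~1.6, while safe-signal exposure has no
significant effect — the generating behavioral rules, recovered from the
event logs alone.

A command-line interface wraps the same operations:

```bash
evacnet replicate-study --seed 0 --sessions-per-cell 10 --out scratch/study
evacnet analyze-accuracy --logs scratch/study --out scratch/accuracy.csv
evacnet analyze-hazard   --logs scratch/study --out scratch/hazard.csv
```

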