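# bicascade

Bi-threshold behavioural diffusion on directed social networks: forward
simulation, heterogeneous threshold estimation, and rolling-window forecast
evaluation, with a synthetic-cascade generator for fully controlled testing.

## The problem

Classical threshold models of social contagion hold that a person adopts a
behaviour once enough of their contacts have: user *i* acts at hour *t+1* iff
the weighted fraction of active influencing neighbours meets a personal
threshold,

```
y_i(t+1) = 1   iff   Σ_{j∈N_i} w_ij y_j(t) ≥ θ_i            (linear threshold)
```

where `N_i` is the set of accounts *i* follows and `w_ij = 1/|N_i|` under
uniform weighting. This captures adoption but not *disadoption* — people also
stop sharing a news item once "everyone is already talking about it". The
bi-threshold model adds an upper threshold that triggers disengagement:

```
y_i(t+1) = 1   iff   θ_i^lower ≤ Σ_{j∈N_i∩E(t)} w_ij ≤ θ_i^upper   and   i ∈ A(t)
```

Two empirical extensions make the rule fit social-media data:

* **Login schedule `A(t)`** — the hours at which a user can act. Patterns:
  `constant` (one login every `Tlogin` hours), `linear_decay` (after an
  engagement, login gaps grow 1, 2, 3, … back to `Tlogin`), and `exp_decay`
  (gaps 1, 2, 4, … capped at `Tlogin`); any new engagement resets the decay.
* **Effective window `E(t)`** — a neighbour's engagement stays visible for
  `Teffect` hours (∞ = every past engagement counts).

Thresholds are heterogeneous and unobserved. They are estimated from hourly
activity logs by maximising a CATE-style objective over the decision
observations `(s_i(t), y_i(t+1))` of logged-in users: the mean action when
influence falls inside a candidate band minus the mean action when it falls
outside (maximum +1 for a perfectly separating band). Heterogeneity across
users is expressed through a binary feature-partition tree grown with an
honest train/validation penalty; each leaf carries the band fitted to its
sub-population.

Prediction quality is scored with a rolling-origin protocol: 24-hour test
windows shifted by 6 hours, each split into four 6-hour intervals; per
interval the predicted number of active users `n̂` is compared to the
observed `n` via `100·|n̂−n|/n`, averaged over the window's four intervals.

## Worked example

Generate a noisy synthetic cascade whose ground truth includes a binding
upper threshold (one user group disengages at influence 0.6), then fit and
evaluate both model classes on five held-out rolling windows:

```python
from bicascade import (GeneratorSpec, gen_cascade, make_windows,
                       evaluate_model, compare_models)

spec = GeneratorSpec(seed=7, noise=0.05)      # 200 users, bands (0.2,1.0) / (0.2,0.6)
casc = gen_cascade(spec)
windows = make_windows(72, 96, shift_hours=6)
results = {
    model: evaluate_model(model, casc.network, casc.log, windows,
                          features=casc.features,
                          t_login=spec.t_login, pattern=spec.pattern)
    for model in ("linear", "bi")
}
table, summary = compare_models(results["linear"], results["bi"])
print(table.to_string(index=False))
print(summary)
```

prints

```
 window_start  mape_linear  mape_bi winner
           72    26.020408 0.765306     bi
           78    25.505051 0.505051     bi
           84    25.505051 0.505051     bi
           90    25.505051 0.505051     bi
           96    25.505051 0.505051     bi
{'mean_mape_linear': 25.608122036693466, 'mean_mape_bi': 0.5571016285302,
 'wins_linear': 0, 'wins_bi': 5, 'ties': 0, 'n_windows': 5}
```

Each row is one evaluation window (test start in hours from the episode
start) with the two models' mean absolute percentage errors over the four
6-hour test intervals. The linear model cannot represent disadoption, so it
keeps predicting the disengaged group active and carries a ~25% error; the
bi-threshold model recovers both bands from the training data and tracks the
decline almost exactly (the residual error is the 5% action-flip noise).

The same workflow is available from the shell (`bicascade synth / fit /
simulate / evaluate / compare`); run `bicascade --help`.

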