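# counterbart

Simulation and analysis pipeline for **counterfactual curiosity** in a
risk task: why do people pay — money, effort, or time — to learn what
they *could* have won, when that information is useless for future play
and likely to make them feel worse?

The package implements, as tested and reusable code, the full
quantitative chain of a multi-experiment study of this question built on
an advance-bid Balloon Analogue Risk Task (BART):

- `counterbart.task` — the generative task rules. A bid of `n` pumps
  (1–12) against a hidden safe limit drawn uniformly from the integers
  0–12 busts iff `n > limit`; banked points are `n × pump value` with
  the value uniform on 1–100. Closed forms: `P(bank | n) = (13 − n)/13`,
  expected points `n(13 − n)/13`, optimal bid tied at **6 or 7**. Cost
  variants (none / 5-point fee / Bernoulli effort gate / waiting time)
  govern access to the counterfactual information.
- `counterbart.agents` — hypothetical-agent simulation of the
  information's (non-)instrumentality: *information seekers* adjust
  their next bid toward the seen limit (`n + (limit − n)α + e`),
  *outcome observers* toward the extreme limit consistent with bank/bust
  (`n + (12 − n)α + e` or `n − nα + e`), against a Gaussian random-walk
  baseline, with `e ~ N(0, σ²)`. The sweep reports each strategy's
  maximum point gain over α per volatility level and the seeker-minus-
  observer benefit.
- `counterbart.cohort` — a synthetic participant-cohort generator with
  plantable fixed effects, random effects, seek base rates, and an
  emotion → next-bid feedback loop, emitting tidy per-trial CSV tables;
  includes the 361-person one-shot replication design.
- `counterbart.models` — variable coding (effect-coded seeking,
  within-participant centering), per-experiment linear mixed models of
  emotion change with uncorrelated random slopes (REML, Wald z,
  documented singular-fit fallback), simple slopes, Welch's t, and the
  replication's OLS interaction model.
- `counterbart.meta` — random-effects meta-analysis (DerSimonian–Laird
  τ², REML optional) with Q, τ², and I² heterogeneity.
- `counterbart.paths` — the downstream path model (seeking → emotion →
  behavior adjustment → next-trial performance) with participant-
  clustered sandwich errors and product-of-coefficients mediation.

No external data are required; everything the analyses consume can be
generated synthetically. Tables of real per-trial data in the same tidy
schema can be dropped into the same functions.

## Worked example

```python
import numpy as np
from counterbart import cohort, models, meta, task

print(task.optimal_pumps())          # {6, 7}
print(round((13 - 4.97) / 13, 2))    # 0.62  — bank rate at the observed mean bid

# five synthetic experiments planting a -0.163 seeking effect on emotion
spec = cohort.GeneratorSpec(beta_is=-0.163, beta_pv=0.015, beta_mo=-0.142,
                            beta_is_pv=0.0, beta_is_mo=0.0)
tables, manifest = cohort.generate_study(spec, seed=7)
fits = [models.fit_emotion_model(models.prepare_variables(t, "bank"), step=1)
        for t in tables.values()]
pooled = meta.integrate_fits(fits, models.COEF_IS)
print(round(pooled.pooled_b, 3), round(pooled.pooled_se, 3), round(pooled.i2, 1))
```

prints

```
{6, 7}
0.62
-0.167 0.017 0.0
```

i.e. the pooled information-seeking coefficient recovers the planted
−0.163 well within its pooled SE (seeking information predicts feeling
worse, in standardized emotion-change units), with no heterogeneity
across the five cost conditions — the planted effects are homogeneous,
so I² ≈ 0.

The agent sweep and the one-shot replication run the same way:

```bash
counterbart simulate-agents --sigmas 0,1,2,3 --agents 10000 --trials 60 \
    --alpha-step 0.02 --seed 1 --out sweep.csv
counterbart generate-cohort --seed 2 --out study/
counterbart fit --in study/exp1.csv --step 2 --out fit1.json
```

`sweep.csv` holds, per volatility level, each strategy's best adjustment
rate (`alpha_star`), its maximum point gain over the random-walk
baseline, and the seekers-minus-observers `benefit` — the number showing
that seeing the exact limit is worth almost nothing (at best ~0, at
worst about −0.08 points per trial here) compared with knowing only
bank/bust.

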