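# attiso — attitude-isolation analysis of vaccine survey data

`attiso` is a Python toolkit for studying why neutral people drift toward
anti-vaccine rather than pro-vaccine positions, using the *attitude space*:
a network in which every response option of a Likert survey ("Vaccines are
safe: strongly agree", …) is a node, and edge weights are the phi
correlations between response options across respondents. Attitudes that
are frequently co-held sit close together; social-influence theory says
closeness is what enables persuasion.

The package is aimed at computational social scientists and vaccine-policy
analysts working with multi-country Likert surveys of the Wellcome Global
Monitor type (three 5-level vaccine items with a neutral option, plus
4-level trust-in-science/institutions items).

## The core statistic

Each item is dummy-coded into one binary indicator per response level. For
two attitudes *a*, *b* of different items, the edge weight is the phi
coefficient

φ(a, b) = (n₁₁n₀₀ − n₁₀n₀₁) / √(n₁·n₀·n·₁n·₀),

the Pearson correlation of the two indicators. Within-item pairs are
mutually exclusive by construction and are excluded. Whole-network
significance uses a permutation bootstrap: every item's response column is
independently permuted across respondents (preserving all one-hot
constraints and column counts), and the statistic Σ|φ| is recomputed per
resample; p = (1 + #{null ≥ observed}) / (1 + n_iter).

**Attitude-isolation** of the strongly pro-vaccine side is

I = −mean φ(strong-trust vaccine attitude, other vaccine attitude),

averaged over the 3 × 8 cross-item pairs. Large I means people holding
strong-trust answers hold little else — the pro-vaccine bloc is isolated
and cannot reach the neutrals. The package verifies isolation three
independent ways (trust-band average correlations, Ward clustering of the
15 vaccine attitudes, neutral-overlap conditional probabilities), feeds
survey-seeded opinion dynamics (Deffuant, three Hegselmann–Krause
variants, Axelrod) that track the initially skeptical population
(summed score ≤ 9 on the 3–15 scale), simulates two trust-raising
policies, and correlates country-level isolation with subsequent
vaccination-coverage and distrust changes.

## Worked example

```python
import numpy as np
from attiso import (GeneratorParams, generate_isolation_gradient,
                    attitude_isolation, bootstrap_test,
                    ModelConfig, run_study, apply_policy, PolicySpec)

# five synthetic countries whose strong-trust decoupling rises 0.0 -> 0.8
base = GeneratorParams(n_countries=5, n_per_country=1000, seed=11)
data = generate_isolation_gradient(base, [0.0, 0.2, 0.4, 0.6, 0.8])

for c in data.countries:
    print(c, round(attitude_isolation(data, c).isolation, 3))
# C01 0.075   C02 0.082   C03 0.118   C04 0.128   C05 0.173

boot = bootstrap_test(data, n_iter=200, seed=1)
print(boot.observed_stat, boot.null_stats.max(), boot.p_value)
# 49.4  5.4  0.005  -> the network is far outside the independence null

study = run_study(data, ModelConfig(model="deffuant", eps=6, seed=2), n_runs=100)
print(study.r)   # -0.84: higher isolation -> skeptics end with lower trust

_, out = apply_policy(data, PolicySpec(policy_id="policy2", seed=3))
print(out.percent_change)  # -4.5: targeting weak-trust profiles de-isolates
```

Per-country isolation rises monotonically with the generator's decoupling
knob; the bootstrap observed statistic (49.4) dwarfs the largest of 200
null statistics (5.4); the Deffuant study's negative r says countries with
more isolated pro-vaccine attitudes leave their skeptics less trusting;
and the policy-2 intervention (promote one attitude of people holding only
weak-trust answers) lowers isolation by 4.5%.

The same steps are available from the shell:

```bash
attiso synth --config params.yaml --out data.csv
attiso network --data data.csv --schema data.schema.yaml \
       --bootstrap 1000 --seed 7 --out net.gexf --report report.json
attiso confirm  --data data.csv --schema data.schema.yaml --out confirm.json
attiso simulate --data data.csv --schema data.schema.yaml --model hk_g --eps 6 \
       --runs 1000 --seed 11 --out study.csv
attiso policy   --data data.csv --schema data.schema.yaml --policy policy2 --seed 3 \
       --out outcome.json
attiso predict  --isolation i.csv --coverage c.csv --distrust v.csv \
       --wealth w.csv --out pred.json
```

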