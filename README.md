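# vivoplan

Optimized design and analysis of preclinical *in vivo* intervention
studies: optimal baseline matching of animals, blinded randomization,
matched paired-difference mixed-effects inference of longitudinal
treatment effects, and bootstrap model-based power analysis.

## The problem

Animal studies routinely allocate mice to treatment arms by hand, balance
on a single baseline variable, skip power calculations, and analyze
correlated longitudinal measurements as if they were independent. The
result is confounded arms, underpowered designs and irreproducible
effects. `vivoplan` is for experimentalists and biostatisticians planning
studies such as xenograft efficacy experiments, where each animal carries
several baseline covariates (body weight, baseline PSA, batch, ...) and
the outcome is a growth trajectory.

## The method

**Matching.** Given the symmetric baseline dissimilarity matrix D (several
metrics, mixed numeric/categorical covariates), partition the N animals
into N/G *submatches* of size G minimizing the total within-submatch
pairwise distance — equivalently, find the binary symmetric matching
matrix X (zero diagonal, all row/column sums G−1, G-clique components)
minimizing ½·Σ X∘D. A branch-and-bound solver returns the certified
global optimum; a seeded genetic algorithm handles instances beyond exact
reach; brute-force enumeration serves as the testing oracle. Batches are
matched as separate problems so no submatch — and hence no confounding —
crosses a batch boundary.

**Randomization and blinding.** Each submatch's members are randomized
uniformly over the G arms (one per arm), and arms can be coded (`T1..TG`)
with the key in a separate file, so the allocation is simultaneously
optimal, random and blinded. Monte-Carlo balance diagnostics quantify the
benefit: the frequency of significant baseline imbalance (one-way ANOVA /
chi-square at α) under matched versus fully random allocation.

**Inference.** The conventional model fits
`y = β₀ + β₁·t + β₂·g₂·t + γᵢ₀ + γᵢ₁·t + ε` per animal; β₂ is the
intervention's slope effect. The matched model instead differences each
cross-arm pair within a submatch at shared time points and fits
`Δ(t) = β_intervention·t + γ₀ + γ₁·t + ε` with pair-level random effects —
the longitudinal analogue of a paired t-test, with p-values from
Satterthwaite degrees of freedom. A paired Hotelling T² test covers
multivariate single-endpoint comparisons.

**Power.** Bootstrap resampling of whole animals (or matched pairs) with
refitting at each candidate per-arm size n yields a power curve and the
smallest n reaching the conventional 0.8 threshold, with censoring
patterns and within-animal correlation preserved by construction.

## Worked example

```python
import vivoplan as vp
from vivoplan.synthdata import SimulationScenario, generate_study

# a VCaP-like two-arm study: 30 animals, true slope effect -5 PSA/week
sc = SimulationScenario(n_units=30, arms=("Vehicle", "MDV"),
                        arm_offsets=(0.0, -5.0), seed=42)
table, hidden, partition, plan, psa = generate_study(sc, seed=42)

unmatched = vp.fit_unmatched(psa, "Vehicle", "MDV")
diffs = vp.build_paired_differences(psa, partition, plan, "Vehicle", "MDV")
matched = vp.fit_matched(diffs)
curve = vp.bootstrap_power(psa, "matched", ("Vehicle", "MDV"),
                           n_grid=[5, 10, 15], n_boot=200, alpha=0.05,
                           seed=7, partition=partition, plan=plan)
```

prints (via the fields shown):

```
30 animals -> 15 submatches (solver=ga, cost=16.878)
unmatched beta_intervention = -5.883 (SE 1.486, df 28.0, p = 0.000469)
matched   beta_intervention = -5.889 (SE 0.846, df 12.9, p = 1.05e-05)
matched pair SDs: intercept 5.74, slope 3.15, residual 8.57
matched power: {5: 0.885, 10: 1.0, 15: 1.0} -> required n = 5
```

Both models recover the simulated effect (−5), but the matched model's
standard error is roughly half the unmatched one: pairing animals that
were similar at baseline removes the between-animal slope heterogeneity
from the contrast, which is exactly why fewer animals suffice for 0.8
power.

The same pipeline is available from the shell:

```sh
vivoplan simulate --seed 42 --out-base base.csv --out-long psa.csv --out-alloc alloc.csv
vivoplan match    --covariates base.csv --groups 3 --solver auto --seed 1 --out part.csv
vivoplan allocate --partition part.csv --arms Vehicle,ARN,MDV --seed 2 --blinded \
                  --out alloc.csv --key key.csv
vivoplan balance  --covariates base.csv --groups 3 --nsim 10000 --seed 3 --out balance.json
vivoplan fit      --long psa.csv --alloc alloc.csv --contrast MDV:Vehicle \
                  --model matched --out fit.json
vivoplan power    --long psa.csv --alloc alloc.csv --contrast MDV:Vehicle \
                  --model matched --ngrid 3:30:3 --nboot 500 --seed 7 --out power.json
```

Every command writes a JSON manifest next to its output recording inputs,
parameters and seeds, so results can be regenerated exactly.

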