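# odmodels

Spatial interaction models for origin–destination count data, evaluated
the way count data demand: by Poisson likelihood, BIC and deviance
rather than Gaussian-error measures.

Given a set of sites — each with a population `P_i`, commuters
departing `O_i`, commuters arriving `I_i`, and pairwise great-circle
distances `d_ij` — these models predict the flow `F_ij` between every
ordered pair of distinct sites. Such models are the movement kernel in
metapopulation models of disease spread, and the workhorse of
transport and commuting studies. `odmodels` implements two
production-constrained families and a statistical engine to fit and
rank them:

**Gravity** (power-law or exponential deterrence):

    F̂_ij = t_i · n_j · f(d_ij) / Σ_{k≠i} n_k · f(d_ik),     f(d) = d^(−β) or e^(−βd)

which satisfies the production constraint Σ_j F̂_ij = t_i exactly. The
conventional data mapping is t_i = O_i, n_j = I_j, with the single
global exponent β fitted by maximum likelihood.

**Radiation** (intervening opportunities):

    F̂_ij = t_i · m_i · n_j / [(m_i + s_ij)(m_i + n_j + s_ij)]

where `s_ij` is the total attractiveness of sites strictly closer to
*i* than *j* (excluding both endpoints) and `m_i` is an aspiration
parameter. Row sums fall short of `t_i` by a factor `(N_c − m_i)/N_c`
with `N_c = Σ_k n_k`; the *normalised* form multiplies by
`N_c/(N_c − m_i)` to restore the constraint exactly. Eight
conventional mappings of the data columns `(P, O, I)` onto `(m, n, t)`
are provided as variants A–H, three of which (F, G, H) carry a fitted
global scale factor α.

**Evaluation.** Observed flows are modelled as independent Poisson
counts with means `F̂_ij`, giving

    lnL(F_min) = Σ_{i≠j, F_ij > F_min} [ −F̂_ij + F_ij ln F̂_ij − ln F_ij! ]

optionally truncated to flows above a threshold `F_min` (the sentinel
`include-zeros` keeps every pair). Models are ranked by
`BIC = k·ln(n) − 2·lnL` and judged absolutely by the deviance
`D = 2(lnL_sat − lnL) ≥ 0` against the saturated model. The legacy
Sørensen–Dice coefficient ("common part of commuters") and R² are
computed for comparison with older practice. Fitted global parameters
get Hessian-based standard errors (exact for α, finite-difference
for β).

A seeded synthetic generator produces census-like systems — heavy-
tailed lognormal populations, zero-inflated right-skewed flows,
sites with strong in/out asymmetry — so the whole pipeline runs and is
tested without any external download.

## Worked example

```python
from odmodels import fit_beta, generate_system
from odmodels.synthetic import SyntheticConfig

system = generate_system(SyntheticConfig(n_sites=150, seed=42))
fit = fit_beta(system.flows, system.sites, system.distances, "power")
```

This simulates 150 sites (2,467,466 total commuters, 21.3 % of ordered
pairs with zero flow) and fits the gravity exponent. Printing the
result (`examples/02_fit_gravity.py`):

```
fitted deterrence exponent: beta = 1.7576 +/- 0.0007
log-likelihood  lnL = -321,253  (saturated -38,991)
BIC = 642,516   deviance = 564,523
Sorensen-Dice = 0.823   R^2 = 0.844
```

β̂ ≈ 1.76 is the maximum-likelihood deterrence exponent when the model
is driven by the observable marginals `t = O`, `n = I` (the generator's
truth used β = 2 with latent inputs; refitting the generating family
itself recovers 2.000 ± 0.001 — see `examples/04_parameter_recovery.py`).
The gap between lnL and the saturated value says the model is far from
the data in an absolute sense even though it ranks first: running
`examples/03_compare_model_family.py` scores all nine models and the
fitted gravity model beats every radiation variant by hundreds of
thousands of log-likelihood points, with variant A (raw populations in
every slot) worst.

The `examples/` scripts each demonstrate one capability: simulation,
gravity fitting, family-wide comparison, parameter recovery.

## Command line

```bash
odmodels simulate --config sim.yaml --out data/
odmodels evaluate --sites data/sites.csv --flows data/flows.csv \
    --distances data/distances.csv --models gravity,A,B,C,D,E,F,G,H \
    --fmin include-zeros,0,10 --bic-n pairs --out results/
odmodels recover --config sim.yaml --replicates 20 --out recovery/
```

`evaluate` writes `comparison.csv` (one row per model and truncation
level) and `results.json`; file formats are plain CSV
(`site_id,lat,lon,population,out_flow,in_flow`; `origin,dest,flow`;
`site_a,site_b,km`), so county-to-county census tables drop in
directly.

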