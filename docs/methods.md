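# Methods

## Models

All models predict the mean flow `F̂_ij > 0` between ordered pairs of
distinct sites and are *production constrained*: site *i*'s predicted
outflow is governed by a parameter `t_i`. Constraining every model the
same way is what makes a comparison between families meaningful — a
difference in score then reflects the part of the model being tested
(deterrence versus intervening opportunities, choice of input columns,
normalisation, fitted factors), not a difference in constraints.

### Gravity

`F̂_ij = t_i n_j f(d_ij) / Σ_{k≠i} n_k f(d_ik)` with `f(d) = d^(−β)`
(power) or `e^(−βd)` (exponential). Two readings of the denominator
are possible; we sum over `k ≠ i` because the diagonal term is
singular under the power law (`d_ii = 0`) and because only this
reading yields the production constraint `Σ_{j≠i} F̂_ij = t_i`
identically. Note the units: the power-law β is dimensionless, while
the exponential β is an inverse distance (per km here), so plausible
values differ by orders of magnitude between the two forms.

### Radiation

`F̂_ij = t_i m_i n_j / [(m_i + s_ij)(m_i + n_j + s_ij)]`, where the
intervening opportunities `s_ij = Σ_{k≠i} n_k θ(d_ij − d_ik)` count
the attractiveness strictly closer to *i* than *j*. θ is strict
(θ(0) = 0), which excludes `k = j` automatically and also excludes
sites exactly tied in distance. Exact ties break the telescoping
row-sum identity `Σ_{j≠i} F̂_ij = t_i (N_c − m_i)/N_c` (valid when
`m = n` elementwise and all distances from each origin are distinct);
the implementation warns when ties are present and offers a seeded
1e-9-km jitter (`models.jitter_distances`), off by default, for
structurally tied geometries such as lattices. The normalised form
multiplies each row by `N_c/(N_c − m_i)`, enforcing the production
constraint exactly; the factor requires `m_i < N_c` and is close to 1
whenever the system is much larger than any one site.

Sites with `m_i = 0` have an undefined outflow distribution: an error
when `t_i > 0`, a zero row when `t_i = 0`.

Variant D (`m = O`, `n = I`, unnormalised) is implemented exactly like
the others even though the naive disentangling of inflow and outflow
columns it embodies has no derivation behind it; it acts as a built-in
regression check that the scoring machinery exposes bad mappings
rather than hiding them.

## Inference

Each observed flow is treated as an independent Poisson count with
mean `F̂_ij`. This respects the three properties of real flow data
that break Gaussian assumptions — integer values, no negatives, a
preponderance of small counts — and both model families can be read as
mean predictions of underlying Poisson processes.

* Truncation: `lnL(F_min)` sums pairs with `F_ij > F_min` (strict).
  The sentinel `include-zeros` (internally −1) keeps all pairs; the
  inclusion mask depends only on observed flows, never on predictions.
* `ln F!` is computed by log-gamma; there is no factorial overflow.
* `BIC = k ln(n) − 2 lnL` with `k` the number of *fitted global*
  parameters (0 for radiation A–E, 1 for gravity and F–H). What
  counts as `n` is genuinely ambiguous in the literature — the number
  of included pairs or the number of sites. The default is included
  pairs; `bic_n="paper"` switches to the site count. The choice is
  recorded in every JSON report. Because lnL values dwarf `k ln(n)`
  in any realistically sized system, rankings are insensitive to it.
* Deviance `D = 2(lnL_sat − lnL)` is computed directly in its
  algebraic form with the `0·ln 0 = 0` convention; the identity with
  the saturated likelihood is verified, not assumed, in the tests.
* α (variants F–H): predictions are linear in α, so the truncated
  MLE has the closed form `α̂ = ΣF / ΣF̂⁰` over included pairs with
  exact-Hessian standard error `α̂/√(ΣF)`.
* β (gravity): bounded scalar search on [1e-3, 20], tolerance 1e-6.
  An optimum within 100 tolerances of a bound is flagged in
  `FitResult.warnings`, never silently accepted. The SE is
  `(−d²lnL/dβ²)^(−1/2)` by central finite difference with step
  `1e-4·max(1, |β̂|)`. β values where the deterrence underflows to
  zero on included pairs are treated as `lnL = −∞` via a penalty that
  grows with β, so the search recovers instead of aborting.
* Sørensen–Dice and R² are reported untruncated over all ordered
  pairs; they are legacy measures with no distributional basis,
  provided only for comparison with older studies.
* No multiplicity correction is applied when many models are
  compared; rankings use raw lnL/BIC/deviance.

## Synthetic data generator

The generator emulates three signatures of county-scale commuting
data: heavy-tailed site populations, a zero-inflated right-skewed
flow-size distribution, and large in/out asymmetries at individual
sites. Defaults (chosen once as a scaled-down county system):

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 200 | sites scattered uniformly in a lat/lon box |
| `lat_range`, `lon_range` | (33, 47), (−117, −81) | continental-US-like extent (~1500 × 3000 km) |
| `pop_lognormal_mu`, `sigma` | 10.0, 1.4 | log-scale of `P_i`; median ≈ 22 000, heavy right tail |
| `outflow_fraction` | 0.35 | `t_i = fraction · P_i` commuters depart |
| truth model | gravity, power, β = 2 | generating family |

Pipeline: scatter sites and draw populations → form truth-model means
with `t_i = 0.35 P_i` and attractiveness `n_i = P_i` → draw each flow
as an independent Poisson count → write the *realised* marginals
`O_i, I_i` (row/column sums of the sampled matrix) back into the site
table. Fitting therefore sees data values, exactly as with a census
table, never the latent truth inputs. Radiation truths that map to
`O/I` columns cannot bootstrap from an empty site table; they take
provisional marginals `O = I = round(0.35 P)` as their inputs.

All randomness flows from one mandatory seed through deterministically
spawned substreams, so every artefact is byte-identical across runs
with the same config.

What the generator does **not** emulate: spatial correlation of
populations (real metropolitan clusters), the extreme sparsity of a
3109-site national table (97 %+ zero pairs; at 150–200 sites in a
fixed box, ~20 % of pairs are zero), survey artefacts such as
long-distance inflation from occasional work locations, and any
departure of the true error law from Poisson (e.g. overdispersion).
Passing tests on these systems show the machinery is correct and
well-calibrated under the stated model, not that the models describe
any particular real dataset.

## Parameter recovery: two fits, two questions

`fit_beta` (and `evaluate_model`) answer the *data analysis* question:
they plug the observable marginals `t = O`, `n = I` into the model, as
one must with a real census table. On synthetic data this plug-in fit
is deliberately slightly misspecified, because a site's realised
inflow is a geography-smoothed transform of the truth attractiveness,
not the attractiveness itself; the resulting β̂ is the best-fitting
exponent for the model-as-used (≈ 1.7–1.8 when the truth is 2 on the
default geometry). This mirrors real analyses, where the mapping of
data columns to model parameters is itself part of the model choice.

`refit_global_parameter` answers the *calibration* question: with the
per-site inputs held at the values the generating model actually used,
is the global parameter recovered with valid standard errors? This is
a correctly specified one-parameter Poisson regression, and the
acceptance experiments confirm estimates within 3 SE of truth with
replicate scatter matching the reported SE. A self-consistent
generative model in which attractiveness equals its own induced
inflow does not exist except degenerately (iterating
`n ← expected inflow(n)` collapses all weight onto a few sites), which
is why the two questions need two fits.

## Numerical choices and degenerate inputs

* Great-circle distances use the haversine formula with the IUGG mean
  Earth radius 6371.0088 km; the matrix is symmetrised after rounding
  and validated (symmetric, zero diagonal, nonnegative). Zero
  inter-site distance is an error under power-law deterrence.
* Self-flows in input edge lists are dropped with a warning; duplicate
  edges are summed; unlisted pairs are zero.
* Flow matrices are dense `int64`; predictions dense `float64`. The
  intended scale is up to a few thousand sites (the 3109-county system
  fits comfortably); there is no out-of-core path.
* Canonical site order is input-file row order; every matrix shares it.
* CSV dialects are fixed (UTF-8, `\n`, no index) so write→read round
  trips are exact.

## Known limitations

* Only power and exponential deterrence forms are implemented.
* No doubly constrained gravity variant (input constraints would add
  no parameters but are not used here).
* The β search bracket [1e-3, 20] assumes the power-law form's scale;
  exponential fits on very fine-grained (sub-km) distances could in
  principle want β > 20 per km and would be flagged at the bound.
* Distance ties are warned about, not resolved, unless the optional
  jitter is applied explicitly.
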