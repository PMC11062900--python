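"""Pooled multilevel meta-analysis with the CAR(year) random structure.

Fits the three-level random-effects model — experiment intercepts,
dataset-level noise, and a continuous-time AR(1) over measurement years
within experiment — by REML, and prints the pooled effect, variance
components and heterogeneity statistics.
"""

import numpy as np

from ermeta import TruthConfig, fit, q_statistics, simulate_database, wald_ci
from ermeta.effects import compute_effect_sizes, percent_change

flux, _, truth = simulate_database(TruthConfig(seed=7))
effects, _ = compute_effect_sizes(flux)

for es_type in ("SMD", "lnROM"):
    sub = effects[effects.es_type == es_type]
    model = fit(sub.estimate, sub.variance, experiment=sub.experiment_id,
                years=sub.year, names=["intercept"], ml_refit=True)
    ci = wald_ci(model)
    tests = q_statistics(sub.estimate.to_numpy(), sub.variance.to_numpy(),
                         np.ones((len(sub), 1)), model)
    print(f"\n== {es_type} meta-analysis (k={model.k}) ==")
    print(f"pooled estimate {model.beta[0]:.3f} "
          f"[{ci.ci_low[0]:.3f}, {ci.ci_high[0]:.3f}]")
    if es_type == "lnROM":
        print(f"  -> percent ER change {percent_change(model.beta[0]):.1f}% "
              f"[{percent_change(ci.ci_low[0]):.1f}, "
              f"{percent_change(ci.ci_high[0]):.1f}]")
    print(f"variance components: experiment {model.sigma2_exp:.4f}, "
          f"dataset {model.sigma2_dataset:.4f}, "
          f"CAR tau2 {model.tau2_car:.4f} (rho {model.rho_car:.2f})")
    print(f"Q = {tests.Q_total:.0f} (df {tests.Q_df}, p = {tests.Q_p:.2g}); "
          f"AIC = {model.aic:.1f}")

# The pooled SMD is the weighted mean warming effect accounting for the
# nesting and repeated years; Q far above its df signals real heterogeneity
# across datasets (the generating truth here uses mu=0.57 with experiment-
# and year-level variation, so both are expected).
print(f"\ngenerating truth: mu = {truth['config']['mu_true']}")
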