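"""The parental-lifespan association battery on one simulated score.

Runs stratified correlations, the upper-vs-lower-decile lifespan
contrast, a covariate-adjusted linear model on dead parents, and a Cox
proportional-hazards model that keeps alive parents as right-censored.
"""

import pandas as pd

from plskit import (
    SimConfig,
    compute_scores,
    decile_contrast,
    filter_panel,
    harmonize,
    lifespan_correlations,
    lifespan_cox_model,
    lifespan_linear_model,
    simulate_panel,
    simulate_phenotypes,
    truth_score_definition,
)

cfg = SimConfig(n_individuals=8000, n_variants=300, n_causal=30, n_pcs=10,
                beta_pls=1.0, seed=4)
panel = simulate_panel(cfg)
phenos, truth = simulate_phenotypes(panel, cfg)

filt = filter_panel(panel)
d = truth_score_definition(panel, truth)
s = compute_scores(filt, harmonize(d, filt))
s = (s - s.mean()) / s.std()  # per-SD units
s.name = "pls"

pear, spear = lifespan_correlations(s, phenos, "father", participant_sex="male")
print(f"father lifespan vs score (male participants): Pearson r = "
      f"{pear.estimate:.4f} (p = {pear.p_value:.2e}, n = {pear.n_used})")

dec = decile_contrast(s, phenos, "father")
print(f"upper vs lower decile lifespan gap: {dec.estimate:.2f} years "
      f"(p = {dec.p_value:.2e})")

lin = lifespan_linear_model(s, phenos, "father", "all", n_pcs=10)
print(f"linear model (dead fathers): {lin.estimate:.3f} +/- {lin.se:.3f} "
      f"years per SD of score (generating value {cfg.beta_pls})")
print("  -> restricting to dead fathers truncates the lifespan distribution,")
print("     which attenuates the dead-only linear estimate; the Cox model")
print("     below uses alive fathers as censored and avoids that selection")

cox = lifespan_cox_model(s, phenos, "father", "all", n_pcs=10)
lo, hi = cox.ratio_ci
print(f"Cox model (all fathers, censored): HR = {cox.ratio:.3f} "
      f"[{lo:.3f}, {hi:.3f}] per SD of score")
print("  -> HR < 1 means each SD of the score lowers the hazard of death,")
print("     consistent with the positive linear lifespan effect")
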