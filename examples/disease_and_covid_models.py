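"""Disease and COVID-death logistic models co-adjusted for a disease
risk score.

The generator gives each disease a risk-increasing polygenic risk score
(PRS) and lets the longevity score (PLS) act protectively; the logistic
model should recover both odds ratios simultaneously.
"""

import numpy as np
import pandas as pd

from plskit import (
    SimConfig,
    covid_death_model,
    disease_logistic_model,
    simulate_panel,
    simulate_phenotypes,
)

cfg = SimConfig(n_individuals=12000, n_variants=200, n_causal=20, n_pcs=10,
                covid_infected_fraction=0.1, seed=6)
panel = simulate_panel(cfg)
phenos, truth = simulate_phenotypes(panel, cfg)

pls = pd.Series(truth.true_score, index=pd.Index(phenos["sample_id"]), name="pls")
prs = phenos.set_index("sample_id")["prs_cad"].rename("prs_cad")

pls_res, prs_res = disease_logistic_model(pls, prs, phenos, "cad", n_pcs=10)
print(f"coronary artery disease ({int(phenos['cad'].sum())} cases):")
print(f"  PLS odds ratio per SD: {pls_res.ratio:.3f} "
      f"[{pls_res.ratio_ci[0]:.3f}, {pls_res.ratio_ci[1]:.3f}] "
      f"(generating OR 0.80, protective)")
print(f"  PRS odds ratio per SD: {prs_res.ratio:.3f} "
      f"[{prs_res.ratio_ci[0]:.3f}, {prs_res.ratio_ci[1]:.3f}] "
      f"(generating OR 1.50, risk-increasing)")

b_pls, _ = disease_logistic_model(
    pls, phenos.set_index("sample_id")["prs_breast_cancer"], phenos,
    "breast_cancer", n_pcs=10,
)
print(f"breast cancer (single-sex): design columns = {b_pls.design_columns[:4]} ...")
print("  -> no sex column for a single-sex disease")

covid = covid_death_model(pls, phenos, n_pcs=10)
print(f"COVID death among the infected (n = {covid.n_used}): "
      f"OR per SD = {covid.ratio:.3f} (generating OR {cfg.covid_death_or_pls})")
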