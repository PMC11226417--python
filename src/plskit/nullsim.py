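"""Random-variant null scores and population-structure profiling.

A cheap but sharp robustness check for any score-phenotype association:
rebuild the score with the same weights but randomly chosen variants
(100% random), or with half the variants replaced (50% random), recompute
it on the cohort, and re-run the association.  Fully random scores should
show null associations; half-random scores should land between the null
and the real score.  A companion profile of score-vs-PC correlations flags
scores that secretly track population structure.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .associations import analysis_cohort, PARENTS
from .panel import DosagePanel
from .scoring import ScoreDefinition, WeightedVariant, compute_scores, harmonize

__all__ = [
    "NullStudyResult",
    "make_random_score",
    "null_correlation_study",
    "pc_correlation_profile",
]


def make_random_score(
    real: ScoreDefinition,
    panel: DosagePanel,
    fraction_replaced: float,
    seed: int | np.random.Generator = 0,
) -> ScoreDefinition:
    """Replace a fraction of a definition's variants with random panel
    variants, keeping the weight multiset in its original order.

    ``fraction_replaced=1.0`` resamples every variant identity;
    ``0.5`` replaces ceil(n/2) randomly chosen members and keeps the rest
    verbatim; ``0.0`` returns the definition unchanged.  Replacements are
    drawn without replacement from panel variants not already present in
    the kept portion; a replacement's effect allele is the panel's counted
    allele.
    """
    if not (0.0 <= fraction_replaced <= 1.0):
        raise ValueError("fraction_replaced must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(b"nullsim")]))
    )
    n = len(real)
    n_replace = math.ceil(n * fraction_replaced)
    if n_replace == 0:
        return ScoreDefinition(score_id=real.score_id, variants=list(real.variants))
    replace_at = set(rng.choice(n, size=n_replace, replace=False).tolist())
    kept_keys = {v.key for i, v in enumerate(real.variants) if i not in replace_at}

    panel_keys = panel.variant_keys()
    eligible = [j for j, k in enumerate(panel_keys) if k not in kept_keys]
    if len(eligible) < n_replace:
        raise ValueError(
            f"panel has only {len(eligible)} eligible variants for "
            f"{n_replace} replacements"
        )
    chosen = rng.choice(len(eligible), size=n_replace, replace=False)
    picks = iter(eligible[int(c)] for c in chosen)

    v = panel.variants
    new_variants: list[WeightedVariant] = []
    for i, orig in enumerate(real.variants):
        if i not in replace_at:
            new_variants.append(orig)
            continue
        j = next(picks)
        new_variants.append(
            WeightedVariant(
                variant_id=str(v.at[j, "variant_id"]),
                effect_allele=str(v.at[j, "counted_allele"]),
                other_allele=str(v.at[j, "other_allele"]),
                weight=orig.weight,
                chrom=str(v.at[j, "chrom"]),
                pos=int(v.at[j, "pos"]),
            )
        )
    label = f"{real.score_id}_rand{int(round(fraction_replaced * 100))}"
    return ScoreDefinition(score_id=label, variants=new_variants)


@dataclass
class NullStudyResult:
    """Per-iteration correlations of random scores with parental lifespan."""

    records: pd.DataFrame  # iteration, parent, metric, r, p
    fraction_replaced: float
    n_iterations: int
    seed: int
    pc_correlations: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        """Mean r (and mean |r|) per parent x metric over iterations."""
        g = self.records.groupby(["parent", "metric"])["r"]
        out = g.agg(mean_r="mean", mean_abs_r=lambda x: x.abs().mean()).reset_index()
        out["fraction_replaced"] = self.fraction_replaced
        return out


def null_correlation_study(
    real: ScoreDefinition,
    panel: DosagePanel,
    phenos: pd.DataFrame,
    fraction_replaced: float,
    n_iterations: int = 10,
    seed: int = 0,
) -> NullStudyResult:
    """Repeat: randomize the definition, recompute scores, correlate with
    each parent's lifespan (dead parents, unstratified by participant
    sex).  Returns per-iteration Pearson and Spearman r with p-values.
    """
    rows = []
    for it in range(n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(b"nullsim"), it])
        )
        rand_def = make_random_score(real, panel, fraction_replaced, seed=rng)
        harm = harmonize(rand_def, panel, drop_palindromic=False)
        scores = compute_scores(panel, harm)
        for parent in PARENTS:
            df = analysis_cohort(phenos, parent, require_dead=True)
            s = scores.reindex(df["sample_id"]).to_numpy(dtype=float)
            y = df[f"{parent}_age"].to_numpy(dtype=float)
            pear = stats.pearsonr(s, y)
            spear = stats.spearmanr(s, y)
            rows.append({"iteration": it, "parent": parent, "metric": "pearson",
                         "r": float(pear.statistic), "p": float(pear.pvalue)})
            rows.append({"iteration": it, "parent": parent, "metric": "spearman",
                         "r": float(spear.statistic), "p": float(spear.pvalue)})
    return NullStudyResult(
        records=pd.DataFrame(rows),
        fraction_replaced=fraction_replaced,
        n_iterations=n_iterations,
        seed=seed,
    )


def pc_correlation_profile(
    score: pd.Series, phenos: pd.DataFrame, n_pcs: int = 40
) -> pd.DataFrame:
    """Pearson correlation of the score with each leading genotype PC.

    Elevated correlations flag a score that tracks population structure;
    compare against the profile of a random score to get a null band.
    """
    cols = [f"pc{i + 1}" for i in range(n_pcs)]
    missing = [c for c in cols if c not in phenos.columns]
    if missing:
        raise ValueError(
            f"phenotype table has fewer PCs than requested: missing {missing[:3]}"
        )
    s = score.reindex(phenos["sample_id"]).to_numpy(dtype=float)
    rows = []
    for i, c in enumerate(cols, start=1):
        res = stats.pearsonr(s, phenos[c].to_numpy(dtype=float))
        rows.append({"pc": i, "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
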