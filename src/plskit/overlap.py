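"""Comparing score definitions and computed scores.

Two published scores can agree because they share variants, because their
shared variants carry most of the weight, or merely because their computed
values correlate across individuals.  This module quantifies all three:
shared-variant counts, the variant weight overlap (VWO) statistic, and
Pearson/Spearman correlation matrices of computed score values.

VWO between scores x and y is

    VWO(x, y) = sum over shared variants i of |w_ix * w_iy| / (T_x * T_y),

with T_x = sum_i |w_ix| the total absolute weight of x.  Disjoint variant
lists give exactly 0; two single-variant lists sharing their variant give
exactly 1.  For multi-variant lists the statistic rewards pairs whose
shared variants carry a larger fraction of each list's weight.  Note that
two identical k-variant lists give sum_i (|w_i|/T)^2, which is below 1 for
k > 1; the ``variant="share_mean"`` alternative — the mean of the shared
weight fractions, sum_i (|w_ix|/T_x + |w_iy|/T_y)/2 — reaches 1 for
identical lists and is offered for sensitivity analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ScoreDefinition

__all__ = [
    "shared_variant_count",
    "total_weight",
    "vwo",
    "overlap_matrix",
    "score_correlation_matrix",
    "OverlapMatrix",
]


def shared_variant_count(a: ScoreDefinition, b: ScoreDefinition) -> int:
    """Number of variants common to both definitions (harmonization keys)."""
    return len(set(a.keys()) & set(b.keys()))


def total_weight(a: ScoreDefinition) -> float:
    """T = sum of absolute variant weights."""
    return float(sum(abs(v.weight) for v in a.variants))


def vwo(a: ScoreDefinition, b: ScoreDefinition, variant: str = "canonical") -> float:
    """Variant weight overlap between two score definitions.

    ``variant="canonical"`` evaluates the product formula above;
    ``variant="share_mean"`` evaluates the non-canonical averaged
    weight-share alternative (returns 1 for identical lists).
    """
    t_a, t_b = total_weight(a), total_weight(b)
    if t_a == 0 or t_b == 0:
        raise ValueError(
            f"VWO undefined: total weight is zero for "
            f"{a.score_id if t_a == 0 else b.score_id!r}"
        )
    wa = a.weights_by_key()
    wb = b.weights_by_key()
    shared = wa.keys() & wb.keys()
    if variant == "canonical":
        return float(sum(abs(wa[k] * wb[k]) for k in shared) / (t_a * t_b))
    if variant == "share_mean":
        return float(
            sum((abs(wa[k]) / t_a + abs(wb[k]) / t_b) / 2.0 for k in shared)
        )
    raise ValueError(f"unknown VWO variant {variant!r}")


@dataclass
class OverlapMatrix:
    """Pairwise shared-variant counts and VWO values for a set of scores."""

    score_ids: list[str]
    counts: pd.DataFrame  # integer; diagonal = definition sizes
    vwo: pd.DataFrame  # real in [0, 1]; diagonal = self-VWO

    def to_square_table(self) -> pd.DataFrame:
        """Single square table: sizes on the diagonal, shared counts above,
        VWO below — the customary compact layout."""
        ids = self.score_ids
        out = pd.DataFrame(index=ids, columns=ids, dtype=object)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i == j:
                    out.at[a, b] = int(self.counts.at[a, b])
                elif i < j:
                    out.at[a, b] = int(self.counts.at[a, b])
                else:
                    out.at[a, b] = round(float(self.vwo.at[a, b]), 6)
        return out

    def to_long(self) -> pd.DataFrame:
        rows = []
        ids = self.score_ids
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    rows.append(
                        {
                            "score_a": a,
                            "score_b": b,
                            "shared_variants": int(self.counts.at[a, b]),
                            "vwo": float(self.vwo.at[a, b]),
                        }
                    )
        return pd.DataFrame(rows)


def overlap_matrix(definitions: list[ScoreDefinition]) -> OverlapMatrix:
    """All pairwise shared counts and VWO values (symmetric matrices)."""
    ids = [d.score_id for d in definitions]
    if len(set(ids)) != len(ids):
        raise ValueError("score ids must be unique")
    n = len(definitions)
    counts = np.zeros((n, n), dtype=int)
    vmat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            counts[i, j] = counts[j, i] = shared_variant_count(definitions[i], definitions[j])
            vmat[i, j] = vmat[j, i] = vwo(definitions[i], definitions[j])
    return OverlapMatrix(
        score_ids=ids,
        counts=pd.DataFrame(counts, index=ids, columns=ids),
        vwo=pd.DataFrame(vmat, index=ids, columns=ids),
    )


def score_correlation_matrix(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson and Spearman correlation matrices of computed score values.

    ``scores`` is samples x scores.  Missing values are handled
    pairwise-complete.  A constant score column makes the correlation
    undefined and raises, naming the score.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 samples for score correlations")
    for col in scores.columns:
        if scores[col].dropna().nunique() <= 1:
            raise ValueError(f"score {col!r} is constant; correlation undefined")
    pearson = scores.corr(method="pearson")
    spearman = scores.corr(method="spearman")
    return pearson, spearman
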