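import numpy as np
import pandas as pd
import pytest

from plskit import (
    DosagePanel,
    ScoreDefinition,
    SimConfig,
    WeightedVariant,
    simulate_panel,
    simulate_phenotypes,
)


def make_panel(rows, dosages, samples=None):
    """Build a small panel by hand.

    ``rows``: list of (variant_id, chrom, pos, counted, other, info, maf);
    ``dosages``: n_samples x n_variants nested list (None = missing).
    """
    dosages = np.array(
        [[np.nan if d is None else float(d) for d in r] for r in dosages], dtype=float
    )
    variants = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "counted_allele", "other_allele", "info", "maf"],
    )
    if samples is None:
        samples = [f"s{i + 1}" for i in range(dosages.shape[0])]
    return DosagePanel(samples=samples, variants=variants, dosages=dosages)


def make_def(score_id, rows):
    """``rows``: list of (variant_id, effect, other, weight[, chrom, pos])."""
    variants = []
    for r in rows:
        vid, ea, oa, w = r[:4]
        chrom, pos = (r[4], r[5]) if len(r) > 4 else (None, None)
        variants.append(
            WeightedVariant(variant_id=vid, effect_allele=ea, other_allele=oa,
                            weight=w, chrom=chrom, pos=pos)
        )
    return ScoreDefinition(score_id=score_id, variants=variants)


@pytest.fixture
def hand_panel():
    return make_panel(
        rows=[
            ("rs1", "1", 100, "A", "G", 0.95, 0.30),
            ("rs2", "1", 200, "G", "A", 0.90, 0.25),
            ("rs3", "2", 300, "A", "T", 0.99, 0.40),  # palindromic
            ("rs4", "2", 400, "C", "T", 0.85, 0.10),
        ],
        dosages=[
            [0.0, 2.0, 1.0, 0.5],
            [1.0, 1.0, 0.0, None],
            [2.0, 0.0, 2.0, 1.5],
        ],
    )


@pytest.fixture(scope="session")
def biobank_small():
    """Structured biobank at test scale, default (censored) design."""
    cfg = SimConfig(
        n_individuals=2000, n_variants=200, n_causal=20, n_pcs=10,
        fst=0.1, seed=11,
    )
    panel = simulate_panel(cfg)
    phenos, truth = simulate_phenotypes(panel, cfg)
    return panel, phenos, truth, cfg


@pytest.fixture(scope="session")
def biobank_nocensor():
    """Selection-free design: assessment far in the future, so every parent
    is dead and regression recovery targets are unbiased."""
    cfg = SimConfig(
        n_individuals=6000, n_variants=150, n_causal=20, n_pcs=10,
        assessment_year=3000, seed=23,
    )
    panel = simulate_panel(cfg)
    phenos, truth = simulate_phenotypes(panel, cfg)
    return panel, phenos, truth, cfg
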