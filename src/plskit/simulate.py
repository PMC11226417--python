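"""Synthetic biobank generator.

Emulates the data structure a parental-lifespan / polygenic-score study
runs on: structured genotype dosages (Balding–Nichols populations at a
configurable F_ST), covariates (sex, birth year, genotyping batch,
assessment center, genotype principal components), right-censored parental
lifespans driven linearly by a latent genetic score, binary disease
outcomes driven jointly by a disease risk score (risk-increasing) and the
longevity score (protective), and a COVID infection/death layer.  A
:class:`TruthRecord` carries the generating parameters so association
models can be checked for parameter recovery.

All randomness flows from one integer seed through named substreams, one
per generation stage, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA

from .panel import DosagePanel
from .scoring import ScoreDefinition, WeightedVariant

__all__ = [
    "DiseaseSpec",
    "SimConfig",
    "TruthRecord",
    "simulate_panel",
    "simulate_phenotypes",
    "truth_score_definition",
]

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stage)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass(frozen=True)
class DiseaseSpec:
    """One simulated disease outcome.

    ``intercept`` is the log-odds at zero scores / average age;
    ``or_prs`` and ``or_pls`` are odds ratios per 1 SD of the disease risk
    score (risk-increasing, > 1) and of the latent longevity score
    (protective, < 1).  ``sex_restriction`` confines the disease to one sex
    (the other sex gets a missing indicator, as for single-sex cancers).
    """

    name: str
    intercept: float
    or_prs: float
    or_pls: float
    sex_restriction: str | None = None


def _default_diseases() -> list[DiseaseSpec]:
    return [
        DiseaseSpec("cad", intercept=-2.2, or_prs=1.5, or_pls=0.8),
        DiseaseSpec("t2d", intercept=-2.5, or_prs=1.4, or_pls=0.9),
        DiseaseSpec("breast_cancer", intercept=-2.8, or_prs=1.4, or_pls=1.0,
                    sex_restriction="female"),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic biobank.

    Defaults encode the reference conditions used throughout the test
    battery: 20,000 participants, 500 variants (50 causal), two
    subpopulations at F_ST = 0.05, lifespans Gaussian with SD 10 years and
    +0.5 years per 1 SD of the latent score.
    """

    n_individuals: int = 20_000
    n_variants: int = 500
    n_causal: int = 50
    n_populations: int = 2
    fst: float = 0.05
    recruitment_year: int = 2008
    assessment_year: int = 2008
    lifespan_mean_father: float = 72.0
    lifespan_mean_mother: float = 78.0
    lifespan_sd: float = 10.0
    beta_pls: float = 0.5
    beta_birthyear: float = 0.05
    batch_count: int = 5
    center_count: int = 10
    batch_sd: float = 0.2
    center_sd: float = 0.2
    generation_gap_mean: float = 28.0
    generation_gap_sd: float = 5.0
    adopted_fraction: float = 0.03
    missing_parent_fraction: float = 0.02
    imputation_noise_sd: float = 0.05
    palindromic_fraction: float = 0.10
    info_min_sim: float = 0.5
    disease_specs: list[DiseaseSpec] = field(default_factory=_default_diseases)
    disease_age_beta: float = 0.3
    disease_sex_beta: float = 0.2
    covid_infected_fraction: float = 0.03
    covid_death_or_pls: float = 0.8
    covid_death_intercept: float = -2.3
    n_pcs: int = 40
    lifespan_floor: float = 40.0
    transmit_half: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_causal", "n_populations",
                     "batch_count", "center_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie strictly in (0, 1)")
        if self.lifespan_sd <= 0:
            raise ValueError("lifespan_sd must be positive")
        if self.n_causal > self.n_variants:
            raise ValueError(
                f"n_causal={self.n_causal} exceeds n_variants={self.n_variants}"
            )
        for frac in ("adopted_fraction", "missing_parent_fraction",
                     "covid_infected_fraction", "palindromic_fraction"):
            if not (0.0 <= getattr(self, frac) <= 1.0):
                raise ValueError(f"{frac} must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Generating parameters and latent quantities, for recovery tests."""

    sample_ids: list[str]
    true_score: np.ndarray  # standardized: mean 0, SD 1
    population: np.ndarray  # subpopulation label per individual
    causal_variant_ids: list[str]
    causal_weights: np.ndarray
    beta_pls: float
    disease_coefs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        s = np.asarray(self.true_score, dtype=float)
        if abs(s.mean()) > 1e-6 or abs(s.std() - 1.0) > 1e-6:
            raise ValueError("true score must be standardized to mean 0, SD 1")


def _population_labels(config: SimConfig) -> np.ndarray:
    return _rng(config.seed, "populations").integers(
        0, config.n_populations, size=config.n_individuals
    )


def simulate_panel(config: SimConfig) -> DosagePanel:
    """Generate a structured dosage panel.

    Per variant: an ancestral frequency is drawn uniformly on [0.05, 0.95];
    population frequencies follow the Balding–Nichols beta construction
    with shape p(1-F)/F, (1-p)(1-F)/F; dosages are Binomial(2, p_pop) plus
    additive imputation noise clipped to [0, 2].  Info scores are drawn
    uniformly on [info_min_sim, 1]; the recorded MAF is empirical.
    """
    rng = _rng(config.seed, "panel")
    n, m = config.n_individuals, config.n_variants
    p_anc = rng.uniform(0.05, 0.95, size=m)
    shape_a = p_anc * (1.0 - config.fst) / config.fst
    shape_b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
    p_pop = rng.beta(shape_a, shape_b, size=(config.n_populations, m))
    p_pop = np.clip(p_pop, 1e-6, 1.0 - 1e-6)

    labels = _population_labels(config)
    dosages = rng.binomial(2, p_pop[labels, :]).astype(float)
    if config.imputation_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0.0, config.imputation_noise_sd, size=(n, m)), 0.0, 2.0
        )

    info = rng.uniform(config.info_min_sim, 1.0, size=m)
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    palindromic = rng.random(m) < config.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    nonpal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    counted, other = [], []
    for j in range(m):
        a, b = (
            _PALINDROMIC_PAIRS[pal_choice[j]]
            if palindromic[j]
            else _NONPALINDROMIC_PAIRS[nonpal_choice[j]]
        )
        counted.append(a)
        other.append(b)

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": [str(j % 22 + 1) for j in range(m)],
            "pos": [10_000 + j for j in range(m)],
            "counted_allele": counted,
            "other_allele": other,
            "info": info,
            "maf": maf,
        }
    )
    samples = [f"ind{i + 1:06d}" for i in range(n)]
    return DosagePanel(samples=samples, variants=variants, dosages=dosages)


def _draw_causal(panel: DosagePanel, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Causal variant columns and weights.

    Causal variants are drawn among variants that pass the default quality
    filters and are non-palindromic, so a score definition built from the
    truth record survives harmonization untouched.
    """
    rng = _rng(config.seed, "causal")
    v = panel.variants
    eligible = np.flatnonzero(
        (v["info"].to_numpy() > 0.8)
        & (v["maf"].to_numpy() > 0.01)
        & ~v.apply(lambda r: {r["counted_allele"], r["other_allele"]} in ({"A", "T"}, {"C", "G"}), axis=1).to_numpy()
    )
    if eligible.size < config.n_causal:
        raise ValueError(
            f"only {eligible.size} filter-passing non-palindromic variants available "
            f"for {config.n_causal} causal variants; increase n_variants"
        )
    idx = rng.choice(eligible, size=config.n_causal, replace=False)
    weights = rng.normal(0.0, 1.0, size=config.n_causal)
    return idx, weights


def simulate_phenotypes(
    panel: DosagePanel, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate covariates, parental lifespans, disease and COVID outcomes.

    Parental lifespan = sex-specific mean + beta_pls x true score
    + beta_birthyear x centered parent birth year + batch/center effects
    + Gaussian noise (SD = lifespan_sd), floored at ``lifespan_floor``.
    A parent is alive iff birth year + lifespan exceeds the assessment
    year; alive parents contribute their age at assessment (right
    censoring).  Disease indicators follow logistic models with a
    risk-increasing disease score and a protective longevity score; COVID
    death is sampled among the infected with a protective longevity term.
    """
    cfg = config
    n = cfg.n_individuals
    if panel.n_samples != n:
        raise ValueError("panel sample count does not match config.n_individuals")

    labels = _population_labels(cfg)
    rng = _rng(cfg.seed, "phenotypes")
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    # participants aged 40-69 at recruitment; the assessment (censoring)
    # date can advance independently, as in a followed-up cohort
    birth_year = rng.integers(cfg.recruitment_year - 69, cfg.recruitment_year - 39, size=n)
    batch = np.array([f"b{k + 1}" for k in rng.integers(0, cfg.batch_count, size=n)])
    center = np.array([f"c{k + 1}" for k in rng.integers(0, cfg.center_count, size=n)])
    adopted = (rng.random(n) < cfg.adopted_fraction).astype(int)

    site_rng = _rng(cfg.seed, "site_effects")
    batch_eff = dict(
        zip(
            [f"b{k + 1}" for k in range(cfg.batch_count)],
            site_rng.normal(0.0, cfg.batch_sd, size=cfg.batch_count),
        )
    )
    center_eff = dict(
        zip(
            [f"c{k + 1}" for k in range(cfg.center_count)],
            site_rng.normal(0.0, cfg.center_sd, size=cfg.center_count),
        )
    )

    causal_idx, causal_w = _draw_causal(panel, cfg)
    raw = np.nan_to_num(panel.dosages[:, causal_idx]) @ causal_w
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate true score (zero variance)")
    true_score = (raw - raw.mean()) / sd

    effect = cfg.beta_pls * (0.5 if cfg.transmit_half else 1.0)

    phenos = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "sex": sex,
            "birth_year": birth_year,
            "batch": batch,
            "center": center,
            "adopted": adopted,
            "age": cfg.assessment_year - birth_year,
        }
    )

    parent_rng = _rng(cfg.seed, "parents")
    site_shift = np.array([batch_eff[b] for b in batch]) + np.array(
        [center_eff[c] for c in center]
    )
    for parent, mean_life in (
        ("father", cfg.lifespan_mean_father),
        ("mother", cfg.lifespan_mean_mother),
    ):
        gap = parent_rng.normal(cfg.generation_gap_mean, cfg.generation_gap_sd, size=n)
        pby = birth_year - np.round(gap)
        lifespan = (
            mean_life
            + effect * true_score
            + cfg.beta_birthyear * (pby - pby.mean())
            + site_shift
            + parent_rng.normal(0.0, cfg.lifespan_sd, size=n)
        )
        lifespan = np.maximum(lifespan, cfg.lifespan_floor)
        alive = (pby + lifespan > cfg.assessment_year).astype(float)
        age = np.where(alive == 1, cfg.assessment_year - pby, lifespan)
        missing = parent_rng.random(n) < cfg.missing_parent_fraction
        age = np.where(missing, np.nan, age)
        alive = np.where(missing, np.nan, alive)
        phenos[f"{parent}_age"] = age
        phenos[f"{parent}_alive"] = alive

    # genotype principal components (ancestry covariates)
    pca_rng = _rng(cfg.seed, "pca")
    k = min(cfg.n_pcs, panel.n_variants, n - 1)
    X = np.nan_to_num(panel.dosages - np.nanmean(panel.dosages, axis=0))
    pcs = PCA(
        n_components=k,
        svd_solver="randomized",
        random_state=int(pca_rng.integers(0, 2**31 - 1)),
    ).fit_transform(X)
    for j in range(k):
        phenos[f"pc{j + 1}"] = pcs[:, j]

    disease_rng = _rng(cfg.seed, "diseases")
    age_z = (phenos["age"] - phenos["age"].mean()) / phenos["age"].std()
    male = (sex == "male").astype(float)
    disease_coefs: dict[str, dict[str, float]] = {}
    for spec in cfg.disease_specs:
        prs = disease_rng.normal(0.0, 1.0, size=n)
        logit = (
            spec.intercept
            + np.log(spec.or_prs) * prs
            + np.log(spec.or_pls) * true_score
            + cfg.disease_age_beta * age_z.to_numpy()
        )
        if spec.sex_restriction is None:
            logit = logit + cfg.disease_sex_beta * male
        case = (disease_rng.random(n) < expit(logit)).astype(float)
        if spec.sex_restriction is not None:
            case = np.where(sex == spec.sex_restriction, case, np.nan)
        phenos[spec.name] = case
        phenos[f"prs_{spec.name}"] = prs
        disease_coefs[spec.name] = {
            "intercept": spec.intercept,
            "log_or_prs": float(np.log(spec.or_prs)),
            "log_or_pls": float(np.log(spec.or_pls)),
        }

    covid_rng = _rng(cfg.seed, "covid")
    infected = (covid_rng.random(n) < cfg.covid_infected_fraction).astype(int)
    death_logit = (
        cfg.covid_death_intercept
        + np.log(cfg.covid_death_or_pls) * true_score
        + cfg.disease_age_beta * age_z.to_numpy()
        + cfg.disease_sex_beta * male
    )
    death = ((covid_rng.random(n) < expit(death_logit)) & (infected == 1)).astype(int)
    phenos["covid_infected"] = infected
    phenos["covid_death"] = death

    truth = TruthRecord(
        sample_ids=list(panel.samples),
        true_score=true_score,
        population=labels,
        causal_variant_ids=[panel.variants.at[int(j), "variant_id"] for j in causal_idx],
        causal_weights=causal_w,
        beta_pls=cfg.beta_pls,
        disease_coefs=disease_coefs,
    )
    return phenos, truth


def truth_score_definition(
    panel: DosagePanel, truth: TruthRecord, score_id: str = "true_pls"
) -> ScoreDefinition:
    """The causal variants and weights as a score definition.

    Effect alleles are the panel's counted alleles, so the computed score
    is an affine transform of the latent true score (up to imputation
    noise at the causal sites).
    """
    lookup = {vid: j for j, vid in enumerate(panel.variants["variant_id"])}
    variants = []
    for vid, w in zip(truth.causal_variant_ids, truth.causal_weights):
        row = panel.variants.iloc[lookup[vid]]
        variants.append(
            WeightedVariant(
                variant_id=vid,
                effect_allele=row["counted_allele"],
                other_allele=row["other_allele"],
                weight=float(w),
                chrom=row["chrom"],
                pos=int(row["pos"]),
            )
        )
    return ScoreDefinition(score_id=score_id, variants=variants)
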