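"""End-to-end orchestration: simulate -> score -> overlap -> associations
-> nulls -> report.

Each stage reads and writes plain-text artifacts in a run directory; every
table carries provenance header lines (package version, seed, config hash)
so any output can be regenerated byte-identically from its recorded
configuration.  Stages are independently re-runnable through the CLI; the
:func:`run_pipeline` entry point sequences them per the stage toggles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    covid_death_model,
    disease_logistic_model,
    lifespan_battery,
    results_to_frame,
)
from .io import (
    read_dosage_tsv,
    read_phenotypes,
    write_dosage_tsv,
    write_phenotypes,
    write_score_definition,
    write_scores,
    write_tsv,
)
from .nullsim import null_correlation_study, pc_correlation_profile
from .overlap import overlap_matrix, score_correlation_matrix
from .scoring import (
    ScoreDefinition,
    compute_scores,
    filter_panel,
    harmonize,
    read_score_definition,
)
from .simulate import DiseaseSpec, SimConfig, simulate_panel, simulate_phenotypes, truth_score_definition

__all__ = ["RunConfig", "StageError", "demo_config", "run_pipeline", "render_tables"]

ALL_STAGES = ("simulate", "score", "overlap", "assoc", "nullsim", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    """Flat run configuration with a nested simulation block."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    # optional external inputs (used instead of simulation outputs)
    panel_path: str | None = None
    phenotypes_path: str | None = None
    weights_paths: tuple[str, ...] = ()
    # scoring options
    info_min: float = 0.8
    maf_min: float = 0.01
    drop_palindromic: bool = True
    missing_policy: str = "mean"
    convention: str = "sum"
    # association options
    n_pcs: int = 40
    quantile: float = 0.10
    # null-simulation options
    null_fractions: tuple[float, ...] = (1.0, 0.5)
    null_iterations: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.sim, dict):
            sim = dict(self.sim)
            if "disease_specs" in sim:
                sim["disease_specs"] = [
                    d if isinstance(d, DiseaseSpec) else DiseaseSpec(**d)
                    for d in sim["disease_specs"]
                ]
            self.sim = SimConfig(**sim)
        self.stages = tuple(self.stages)
        self.weights_paths = tuple(self.weights_paths)
        self.null_fractions = tuple(self.null_fractions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:8]


def demo_config(seed: int = 0) -> RunConfig:
    """Bundled small-scale demonstration configuration (runs in seconds)."""
    sim = SimConfig(
        n_individuals=800,
        n_variants=300,
        n_causal=30,
        n_pcs=20,
        beta_pls=1.0,
        covid_infected_fraction=0.2,
        covid_death_intercept=-1.5,
        seed=seed,
    )
    return RunConfig(seed=seed, sim=sim, n_pcs=10, null_iterations=5)


def _half_definition(real: ScoreDefinition) -> ScoreDefinition:
    """The half of the definition carrying the largest absolute weights."""
    ordered = sorted(real.variants, key=lambda v: -abs(v.weight))
    keep = ordered[: math.ceil(len(ordered) / 2)]
    return ScoreDefinition(score_id=f"{real.score_id}_top", variants=keep)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages into ``outdir``; returns the run dir.

    Simulated or loaded inputs, per-score values, overlap matrices,
    association tables and null-study records are written as TSV with
    provenance headers; a ``manifest.json`` lists every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"plskit {__version__}", f"seed={config.seed}", f"config={config.config_hash()}"]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    panel = phenos = truth = None
    definitions: list[ScoreDefinition] = []
    scores: pd.DataFrame | None = None
    artifacts: list[str] = ["config.yaml"]

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        write_tsv(df, outdir / name, header_lines=header, index=index)
        artifacts.append(name)

    # -- inputs / simulation -------------------------------------------
    stage = "simulate"
    try:
        if config.panel_path:
            p = Path(config.panel_path)
            if not p.exists():
                raise FileNotFoundError(f"panel path does not exist: {p}")
            panel = read_dosage_tsv(p)
            if not config.phenotypes_path or not Path(config.phenotypes_path).exists():
                raise FileNotFoundError(
                    f"phenotypes path does not exist: {config.phenotypes_path}"
                )
            phenos = read_phenotypes(config.phenotypes_path)
        elif stage in config.stages:
            panel = simulate_panel(config.sim)
            phenos, truth = simulate_phenotypes(panel, config.sim)
            write_dosage_tsv(panel, outdir / "panel.tsv", header_lines=header)
            write_phenotypes(phenos, outdir / "phenotypes.csv", header_lines=header)
            truth_df = pd.DataFrame(
                {
                    "sample_id": truth.sample_ids,
                    "population": truth.population,
                    "true_score": truth.true_score,
                }
            )
            meta = header + [
                f"beta_pls={truth.beta_pls}",
                "causal_variants=" + ",".join(truth.causal_variant_ids),
                "disease_coefs=" + json.dumps(truth.disease_coefs),
            ]
            write_tsv(truth_df, outdir / "truth.tsv", header_lines=meta)
            artifacts += ["panel.tsv", "phenotypes.csv", "truth.tsv"]
        if config.weights_paths:
            for w in config.weights_paths:
                if not Path(w).exists():
                    raise FileNotFoundError(f"weights path does not exist: {w}")
                definitions.append(read_score_definition(w))
        elif truth is not None and panel is not None:
            real = truth_score_definition(panel, truth)
            definitions = [real, _half_definition(real)]
            wdir = outdir / "weights"
            for d in definitions:
                write_score_definition(d, wdir / f"{d.score_id}.tsv", header_lines=header)
                artifacts.append(f"weights/{d.score_id}.tsv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    if panel is None or phenos is None:
        raise StageError("simulate", "no panel/phenotypes available (stage disabled and no paths given)")

    n_pcs_avail = sum(1 for c in phenos.columns if c.startswith("pc"))
    n_pcs = min(config.n_pcs, n_pcs_avail)

    # -- scoring --------------------------------------------------------
    filtered = None
    if "score" in config.stages:
        stage = "score"
        try:
            if not definitions:
                raise ValueError("no score definitions available")
            filtered = filter_panel(panel, config.info_min, config.maf_min)
            harms = [
                harmonize(d, filtered, config.drop_palindromic, prefilter_panel=panel)
                for d in definitions
            ]
            _write_tsv(pd.DataFrame([h.summary() for h in harms]), "score_summary.tsv")
            cols = {
                h.score_id: compute_scores(
                    filtered, h, config.missing_policy, config.convention
                )
                for h in harms
            }
            scores = pd.DataFrame(cols)
            write_scores(scores, outdir / "scores.tsv", header_lines=header)
            artifacts.append("scores.tsv")
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # -- overlap ---------------------------------------------------------
    if "overlap" in config.stages and definitions:
        stage = "overlap"
        try:
            om = overlap_matrix(definitions)
            _write_tsv(om.to_square_table(), "overlap_square.tsv", index=True)
            _write_tsv(om.to_long(), "overlap_long.tsv")
            if scores is not None and len(scores.columns) >= 2:
                pear, spear = score_correlation_matrix(scores)
                _write_tsv(pear, "score_corr_pearson.tsv", index=True)
                _write_tsv(spear, "score_corr_spearman.tsv", index=True)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # -- associations ----------------------------------------------------
    if "assoc" in config.stages and scores is not None:
        stage = "assoc"
        try:
            life = lifespan_battery(scores, phenos, n_pcs=n_pcs, quantile=config.quantile)
            _write_tsv(results_to_frame(life), "assoc_lifespan.tsv")
            disease_names = [
                c.removeprefix("prs_") for c in phenos.columns if c.startswith("prs_")
            ]
            disease_results = []
            for name in disease_names:
                prs = phenos.set_index("sample_id")[f"prs_{name}"].rename(f"prs_{name}")
                for score_id in scores.columns:
                    disease_results.extend(
                        disease_logistic_model(scores[score_id], prs, phenos, name, n_pcs=n_pcs)
                    )
            if disease_results:
                _write_tsv(results_to_frame(disease_results), "assoc_disease.tsv")
            if "covid_infected" in phenos.columns and phenos["covid_death"].sum() > 0:
                covid = [
                    covid_death_model(scores[sid], phenos, n_pcs=n_pcs)
                    for sid in scores.columns
                ]
                _write_tsv(results_to_frame(covid), "assoc_covid.tsv")
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # -- null simulations -------------------------------------------------
    if "nullsim" in config.stages and definitions and filtered is not None:
        stage = "nullsim"
        try:
            real = definitions[0]
            recs, summaries = [], []
            for frac in config.null_fractions:
                study = null_correlation_study(
                    real, filtered, phenos, frac,
                    n_iterations=config.null_iterations, seed=config.seed,
                )
                r = study.records.copy()
                r["fraction_replaced"] = frac
                recs.append(r)
                summaries.append(study.summary())
            _write_tsv(pd.concat(recs, ignore_index=True), "null_records.tsv")
            _write_tsv(pd.concat(summaries, ignore_index=True), "null_summary.tsv")
            if scores is not None:
                profs = []
                for sid in scores.columns:
                    p = pc_correlation_profile(scores[sid], phenos, n_pcs=n_pcs)
                    p.insert(0, "score_id", sid)
                    profs.append(p)
                _write_tsv(pd.concat(profs, ignore_index=True), "pc_profile.tsv")
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if "report" in config.stages:
        stage = "report"
        try:
            render_tables(outdir)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    return outdir


def render_tables(run_dir: str | Path) -> Path:
    """Render report tables from a completed (or partial) run directory.

    Emits a score summary (variants requested vs used with drop tallies),
    the square overlap/VWO matrix, a stratified correlation grid, linear
    coefficient tables split by participant sex, and forest-plot inputs
    (label, ratio, CI bounds) for the Cox and disease models.  Missing
    stage outputs produce an explicit gap list, not a failure.
    """
    run_dir = Path(run_dir)
    report = run_dir / "report"
    report.mkdir(exist_ok=True)
    gaps: list[str] = []

    def _read(name: str) -> pd.DataFrame | None:
        p = run_dir / name
        if not p.exists():
            gaps.append(name)
            return None
        return pd.read_csv(p, sep="\t", comment="#", na_values=["NA"])

    summary = _read("score_summary.tsv")
    if summary is not None:
        write_tsv(summary, report / "table1_scores.tsv")

    square = run_dir / "overlap_square.tsv"
    if square.exists():
        write_tsv(pd.read_csv(square, sep="\t", comment="#", index_col=0),
                  report / "table2_overlap.tsv", index=True)
    else:
        gaps.append("overlap_square.tsv")

    life = _read("assoc_lifespan.tsv")
    if life is not None:
        corr = life[life["model"].isin(["pearson", "spearman"])].copy()
        corr["cell"] = corr["model"] + "/" + corr["stratum"]
        grid = corr.pivot_table(index="term", columns="cell", values="estimate")
        write_tsv(grid, report / "table3_correlations.tsv", index=True)
        linear = life[life["model"] == "linear"]
        for i, sex in enumerate(("male", "female")):
            sub = linear[linear["stratum"].str.startswith(sex)]
            wide = sub.pivot_table(
                index="term", columns="stratum", values=["estimate", "se", "p_value"]
            )
            wide.columns = [f"{a}_{b.split('/')[1]}" for a, b in wide.columns]
            write_tsv(wide, report / f"table{4 + i}_linear_{sex}.tsv", index=True)
        cox = life[life["model"] == "coxph"].copy()
        cox["hr"] = np.exp(cox["estimate"])
        cox["lo"] = np.exp(cox["estimate"] - 1.96 * cox["se"])
        cox["hi"] = np.exp(cox["estimate"] + 1.96 * cox["se"])
        write_tsv(cox[["term", "stratum", "hr", "lo", "hi", "p_value"]],
                  report / "forest_hr.tsv")

    disease = _read("assoc_disease.tsv")
    if disease is not None:
        d = disease.copy()
        d["or"] = np.exp(d["estimate"])
        d["lo"] = np.exp(d["estimate"] - 1.96 * d["se"])
        d["hi"] = np.exp(d["estimate"] + 1.96 * d["se"])
        write_tsv(d[["outcome", "term", "or", "lo", "hi", "p_value"]],
                  report / "forest_or.tsv")

    if gaps:
        (report / "GAPS.txt").write_text(
            "missing stage outputs:\n" + "\n".join(gaps) + "\n"
        )
    return report
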