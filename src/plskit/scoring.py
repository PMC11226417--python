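"""Score definitions, allele harmonization and weighted-sum scoring.

A polygenic (longevity or risk) score assigns each individual the weighted
sum of their effect-allele dosages over a published list of variants.  The
pipeline here is the classical one:

1. :func:`read_score_definition` parses a scoring file (PGS-Catalog-style
   TSV of effect allele / other allele / weight rows);
2. :func:`filter_panel` applies the quality filters to the genotype panel
   (imputation info score strictly > 0.8, MAF strictly > 1% by default);
3. :func:`harmonize` matches definition variants to panel variants by
   (chrom, pos, allele set) — or identifier when coordinates are absent —
   resolving effect-allele orientation and dropping, never proxying,
   anything that does not match;
4. :func:`compute_scores` evaluates score_i = sum_v w_v * d*_iv where
   d* is the dosage for direct orientation and 2 - dosage for swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable

import numpy as np
import pandas as pd

from .panel import DosagePanel, VALID_BASES, is_palindromic, variant_key

__all__ = [
    "WeightedVariant",
    "ScoreDefinition",
    "HarmonizedScore",
    "ScoreFileError",
    "read_score_definition",
    "filter_panel",
    "harmonize",
    "compute_scores",
]

# Column-name synonyms accepted in scoring files (PGS-Catalog layout first).
_COLUMN_SYNONYMS = {
    "variant_id": ["rsid", "rs_id", "variant_id", "id", "snp", "snpid", "markername"],
    "chrom": ["chr", "chrom", "chr_name", "chromosome"],
    "pos": ["pos", "position", "chr_position", "bp"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "reference_allele", "non_effect_allele"],
    "weight": ["effect_weight", "weight", "beta", "es", "effect_size"],
}


class ScoreFileError(ValueError):
    """Raised for malformed scoring files (message carries line numbers)."""


@dataclass(frozen=True)
class WeightedVariant:
    """One scored variant: effect allele, other allele and per-copy weight."""

    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: weight is not finite")

    @property
    def key(self) -> tuple[Hashable, ...]:
        return variant_key(self.chrom, self.pos, self.effect_allele, self.other_allele, self.variant_id)


@dataclass
class ScoreDefinition:
    """A named list of weighted variants (one published score)."""

    score_id: str
    variants: list[WeightedVariant]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"score {self.score_id!r}: definition is empty")
        seen: dict[Hashable, str] = {}
        for v in self.variants:
            if v.key in seen:
                raise ValueError(
                    f"score {self.score_id!r}: duplicate variant key for "
                    f"{seen[v.key]} and {v.variant_id}"
                )
            seen[v.key] = v.variant_id

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> list[tuple[Hashable, ...]]:
        return [v.key for v in self.variants]

    def weights_by_key(self) -> dict[Hashable, float]:
        return {v.key: v.weight for v in self.variants}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "weight": [v.weight for v in self.variants],
            }
        )


#: Reasons a definition variant can be dropped during harmonization.
DROP_REASONS = ("absent", "allele_mismatch", "palindromic", "filtered")


@dataclass
class HarmonizedScore:
    """A score definition matched against one panel.

    ``panel_index[i]`` is the panel column for the i-th matched variant,
    ``swapped[i]`` is True when the definition's effect allele is the
    panel's non-counted allele (score uses 2 - dosage), and ``dropped``
    tallies unmatched definition variants by reason.
    """

    score_id: str
    panel_index: np.ndarray
    swapped: np.ndarray
    weights: np.ndarray
    dropped: dict[str, int]
    n_input: int

    def __post_init__(self) -> None:
        self.panel_index = np.asarray(self.panel_index, dtype=int)
        self.swapped = np.asarray(self.swapped, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        unknown = set(self.dropped) - set(DROP_REASONS)
        if unknown:
            raise ValueError(f"unknown drop reasons: {unknown}")
        for r in DROP_REASONS:
            self.dropped.setdefault(r, 0)
        if self.n_matched + sum(self.dropped.values()) != self.n_input:
            raise ValueError("matched + dropped must equal definition size")

    @property
    def n_matched(self) -> int:
        return len(self.panel_index)

    def summary(self) -> dict[str, int]:
        out = {"score_id": self.score_id, "requested": self.n_input, "used": self.n_matched}
        out.update({f"dropped_{r}": self.dropped[r] for r in DROP_REASONS})
        return out


def _resolve_columns(header: list[str]) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    for canonical, names in _COLUMN_SYNONYMS.items():
        for name in names:
            if name in lower:
                resolved[canonical] = lower[name]
                break
    required = ("variant_id", "effect_allele", "other_allele", "weight")
    missing = [c for c in required if c not in resolved]
    if missing:
        raise ScoreFileError(
            f"scoring file header lacks required columns {missing}; got {header}"
        )
    return resolved


def read_score_definition(path: str | Path, score_id: str | None = None) -> ScoreDefinition:
    """Parse a scoring-file TSV into a :class:`ScoreDefinition`.

    The header must name at least a variant identifier, effect allele,
    other allele and weight (PGS-Catalog names and common synonyms are
    accepted); chromosome/position columns are optional.  Malformed rows
    are reported with their 1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(list(df.columns))
    variants: list[WeightedVariant] = []
    seen: dict[Hashable, tuple[str, int]] = {}
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header line
        raw_w = row[cols["weight"]]
        try:
            weight = float(raw_w)
        except (TypeError, ValueError):
            raise ScoreFileError(
                f"{path.name}:{line}: non-numeric weight {raw_w!r}"
            ) from None
        chrom = row[cols["chrom"]] if "chrom" in cols else None
        pos_raw = row[cols["pos"]] if "pos" in cols else None
        pos = None
        if pos_raw is not None and not pd.isna(pos_raw):
            pos = int(pos_raw)
        if pd.isna(chrom):
            chrom = None
        try:
            v = WeightedVariant(
                variant_id=str(row[cols["variant_id"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                weight=weight,
                chrom=chrom,
                pos=pos,
            )
        except ValueError as exc:
            raise ScoreFileError(f"{path.name}:{line}: {exc}") from None
        if v.key in seen:
            prev_id, prev_line = seen[v.key]
            raise ScoreFileError(
                f"{path.name}:{line}: duplicate variant {v.variant_id} "
                f"(previously {prev_id} at line {prev_line})"
            )
        seen[v.key] = (v.variant_id, line)
        variants.append(v)
    return ScoreDefinition(score_id=score_id or path.stem, variants=variants)


def filter_panel(
    panel: DosagePanel, info_min: float = 0.8, maf_min: float = 0.01
) -> DosagePanel:
    """Retain variants with info score > ``info_min`` and MAF > ``maf_min``.

    Both inequalities are strict; a variant at exactly the threshold is
    removed.  Variant order is preserved.
    """
    info = panel.variants["info"].to_numpy(dtype=float)
    maf = panel.variants["maf"].to_numpy(dtype=float)
    keep = np.flatnonzero((info > info_min) & (maf > maf_min))
    if keep.size == 0:
        raise ValueError(
            f"no variants pass info > {info_min} and MAF > {maf_min}; empty panel"
        )
    return panel.subset_variants(keep)


def harmonize(
    definition: ScoreDefinition,
    panel: DosagePanel,
    drop_palindromic: bool = True,
    prefilter_panel: DosagePanel | None = None,
) -> HarmonizedScore:
    """Match definition variants to panel columns and resolve orientation.

    A match requires key agreement (chrom/pos when the definition carries
    coordinates, identifier otherwise) and allele-pair agreement as a set.
    Orientation is ``direct`` when the effect allele is the panel's counted
    allele, ``swapped`` otherwise.  Unmatched variants are dropped, never
    proxied.  When ``prefilter_panel`` is supplied, variants present there
    but not in ``panel`` are tallied as ``filtered`` rather than ``absent``.
    """
    by_pos: dict[tuple, int] = {}
    by_id: dict[str, int] = {}
    v = panel.variants
    for j, (c, p, vid) in enumerate(zip(v["chrom"], v["pos"], v["variant_id"])):
        if c is not None and not pd.isna(c) and p is not None and not pd.isna(p):
            by_pos[(str(c), int(p))] = j
        by_id[str(vid)] = j

    pre_keys: set = set()
    if prefilter_panel is not None:
        pre_keys = set(prefilter_panel.variant_keys())
        pre_ids = set(map(str, prefilter_panel.variants["variant_id"]))

    index: list[int] = []
    swapped: list[bool] = []
    weights: list[float] = []
    dropped = {r: 0 for r in DROP_REASONS}
    for dv in definition.variants:
        if dv.chrom is not None and dv.pos is not None:
            j = by_pos.get((str(dv.chrom), int(dv.pos)))
        else:
            j = by_id.get(dv.variant_id)
        if j is None:
            if prefilter_panel is not None and (
                dv.key in pre_keys or dv.variant_id in pre_ids
            ):
                dropped["filtered"] += 1
            else:
                dropped["absent"] += 1
            continue
        counted = v.at[j, "counted_allele"]
        other = v.at[j, "other_allele"]
        if {dv.effect_allele, dv.other_allele} != {counted, other}:
            dropped["allele_mismatch"] += 1
            continue
        if drop_palindromic and is_palindromic(dv.effect_allele, dv.other_allele):
            dropped["palindromic"] += 1
            continue
        index.append(j)
        swapped.append(dv.effect_allele != counted)
        weights.append(dv.weight)
    return HarmonizedScore(
        score_id=definition.score_id,
        panel_index=np.array(index, dtype=int),
        swapped=np.array(swapped, dtype=bool),
        weights=np.array(weights, dtype=float),
        dropped=dropped,
        n_input=len(definition),
    )


def compute_scores(
    panel: DosagePanel,
    harmonized: HarmonizedScore,
    missing_policy: str = "mean",
    convention: str = "sum",
) -> pd.Series:
    """Weighted-sum score per individual.

    score_i = sum_v w_v * d*_iv with d* = dosage (direct) or 2 - dosage
    (swapped).  Missing dosages are handled per ``missing_policy``:
    ``"mean"`` (default) substitutes the variant's mean observed effect
    dosage, ``"zero"`` substitutes 0, ``"fail"`` raises naming the first
    offending sample.  ``convention="average"`` divides by twice the number
    of scored variants (the per-allele average used by some scoring tools);
    downstream analyses standardize scores, so the two conventions give
    identical associations.
    """
    if harmonized.n_matched == 0:
        raise ValueError(
            f"score {harmonized.score_id!r}: no variants matched the panel; cannot score"
        )
    if missing_policy not in ("mean", "zero", "fail"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if convention not in ("sum", "average"):
        raise ValueError(f"unknown convention {convention!r}")

    D = panel.dosages[:, harmonized.panel_index]
    D = np.where(harmonized.swapped[np.newaxis, :], 2.0 - D, D)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        if missing_policy == "fail":
            bad = int(np.argmax(nan_mask.any(axis=1)))
            raise ValueError(
                f"sample {panel.samples[bad]!r} has missing dosages and "
                "missing_policy='fail'"
            )
        if missing_policy == "mean":
            col_mean = np.nanmean(np.where(nan_mask, np.nan, D), axis=0)
            if np.isnan(col_mean).any():
                j = int(np.argmax(np.isnan(col_mean)))
                vid = panel.variants.at[int(harmonized.panel_index[j]), "variant_id"]
                raise ValueError(f"variant {vid!r} has no observed dosages to average")
            D = np.where(nan_mask, col_mean[np.newaxis, :], D)
        else:  # zero
            D = np.where(nan_mask, 0.0, D)
    scores = D @ harmonized.weights
    if convention == "average":
        scores = scores / (2.0 * harmonized.n_matched)
    return pd.Series(scores, index=pd.Index(panel.samples, name="sample_id"),
                     name=harmonized.score_id)
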