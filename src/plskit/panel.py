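"""Dosage panels: the genotype substrate on which every score is computed.

A :class:`DosagePanel` holds an individuals x variants matrix of imputed
allele dosages (expected counts of the *counted* allele, in [0, 2], NaN for
missing) together with per-variant metadata: identifier, coordinates,
counted/other allele, imputation info score and minor allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

#: Required columns of ``DosagePanel.variants`` (order is canonical on disk).
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "counted_allele",
    "other_allele",
    "info",
    "maf",
]

#: Allele pairs indistinguishable under strand flips.
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

VALID_BASES = frozenset("ACGT")


def variant_key(
    chrom, pos, allele_a: str, allele_b: str, variant_id: str
) -> tuple[Hashable, ...]:
    """Harmonization key for one variant.

    (chromosome, position, unordered allele pair) when coordinates are
    available, otherwise the variant identifier. Coordinates are 1-based.
    """
    if chrom is not None and pos is not None and not pd.isna(pos) and not pd.isna(chrom):
        return ("pos", str(chrom), int(pos), frozenset((allele_a, allele_b)))
    return ("id", str(variant_id))


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    return frozenset((allele_a, allele_b)) in PALINDROMIC_PAIRS


@dataclass
class DosagePanel:
    """Individuals x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    variants
        DataFrame with (at least) :data:`VARIANT_COLUMNS`, one row per
        matrix column.
    dosages
        ``(n_samples, n_variants)`` float array; entries in [0, 2] or NaN.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2] (or be NaN)")
        info = self.variants["info"].to_numpy(dtype=float)
        if np.any((info < 0) | (info > 1)):
            raise ValueError("info scores must lie in [0, 1]")
        maf = self.variants["maf"].to_numpy(dtype=float)
        if np.any((maf < 0) | (maf > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple[Hashable, ...]]:
        """Harmonization keys in panel column order."""
        v = self.variants
        return [
            variant_key(c, p, a1, a2, vid)
            for c, p, a1, a2, vid in zip(
                v["chrom"], v["pos"], v["counted_allele"], v["other_allele"], v["variant_id"]
            )
        ]

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "DosagePanel":
        """New panel restricted to the given variant columns (order preserved)."""
        index = np.asarray(index, dtype=int)
        return DosagePanel(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosagePanel":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[str(s)] for s in sample_ids]
        return DosagePanel(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )
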