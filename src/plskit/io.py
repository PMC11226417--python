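"""Readers and writers for the plain-text formats the pipeline exchanges.

Dosage panels travel as TSV (rows = variants: metadata columns then one
dosage column per sample) or as VCF with a ``DS`` FORMAT field; phenotype
tables as CSV; score definitions and score vectors as TSV.  Every writer
can prepend provenance comment lines (``# ...``); every reader skips them,
so round trips are bit-exact on the table body.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import DosagePanel, VARIANT_COLUMNS
from .scoring import ScoreDefinition

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_scores",
    "read_scores",
    "write_score_definition",
]


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = (), index: bool = False
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"],
        float_precision="round_trip", **kwargs,
    )


# -- dosage panel ------------------------------------------------------------

def write_dosage_tsv(
    panel: DosagePanel, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Rows = variants: id, chrom, pos, counted/other allele, info, maf,
    then one dosage column per sample (NA = missing)."""
    body = panel.variants[VARIANT_COLUMNS].copy()
    dose = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    write_tsv(pd.concat([body, dose.set_index(body.index)], axis=1), path, header_lines)


def read_dosage_tsv(path: str | Path) -> DosagePanel:
    df = read_tsv(path, dtype={"chrom": str, "variant_id": str})
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    return DosagePanel(
        samples=samples,
        variants=df[VARIANT_COLUMNS].copy(),
        dosages=df[samples].to_numpy(dtype=float).T,
    )


def write_vcf(panel: DosagePanel, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Minimal VCF 4.2 with a per-sample DS (dosage) FORMAT field.

    REF is the panel's other allele and ALT the counted allele, so DS is
    the expected ALT-allele count.  Info score and MAF are carried as the
    IIS and MAF INFO fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    chroms = list(dict.fromkeys(v["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines:
            fh.write(f"##comment={line}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=IIS,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j in range(panel.n_variants):
            row = v.iloc[j]
            dose = panel.dosages[:, j]
            ds = "\t".join("." if np.isnan(d) else f"{d:.6g}" for d in dose)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['other_allele']}\t{row['counted_allele']}\t.\tPASS\t"
                f"IIS={row['info']:.6g};MAF={row['maf']:.6g}\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> DosagePanel:
    """Read a dosage VCF (DS FORMAT field) into a panel.

    Requires cyvcf2 (optional dependency; ``pip install plskit[vcf]``).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    recs, cols = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ds = np.where(np.isfinite(ds), ds, np.nan)
        cols.append(ds)
        recs.append(
            {
                "variant_id": var.ID,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "counted_allele": var.ALT[0],
                "other_allele": var.REF,
                "info": float(var.INFO.get("IIS", 1.0)),
                "maf": float(var.INFO.get("MAF", 0.5)),
            }
        )
    return DosagePanel(
        samples=samples,
        variants=pd.DataFrame(recs),
        dosages=np.column_stack(cols) if cols else np.empty((len(samples), 0)),
    )


# -- phenotypes and scores ---------------------------------------------------

def write_phenotypes(
    phenos: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        phenos.to_csv(fh, index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", na_values=["NA"], dtype={"sample_id": str},
        float_precision="round_trip",
    )


def write_scores(
    scores: pd.Series | pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Score vectors as TSV: sample_id column then one column per score."""
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    write_tsv(df.reset_index().rename(columns={"index": "sample_id"}), path, header_lines)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"sample_id": str})
    return df.set_index("sample_id")


def write_score_definition(
    definition: ScoreDefinition, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    df = definition.to_frame().rename(
        columns={"variant_id": "rsID", "chrom": "chr", "pos": "pos", "weight": "effect_weight"}
    )
    write_tsv(df, path, header_lines)
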