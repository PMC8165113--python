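"""Reading and writing of the pipeline's plain-text formats.

Expression matrix: TSV, first column ``gene_id``, one column per sample.
Sample sheet:      TSV with sample_id, patient_id, sex, tissue.
Annotation:        TSV with gene_id, symbol, chromosome.
Clinical table:    CSV with the matching covariates.

Round-trips are lossless to ~1e-12 (floats written with repr precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SAMPLE_SHEET_COLUMNS

FLOAT_FORMAT = "%.17g"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate {what}(s): {dups[:5]}")


def read_expression(path) -> pd.DataFrame:
    """Expression TSV -> DataFrame indexed by gene id.

    Non-numeric cells are reported with their (gene, sample) coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(pd.Index(header[1:]), "sample id", path)  # pandas would mangle dups
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene id", path)
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        gene, sample = next(
            (g, s) for g in df.index for s in df.columns if bad.loc[g, s]
        )
        raise ValueError(
            f"{path}: non-numeric expression value {df.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        ) from None
    return values


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column(s): {missing}")
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample id", path)
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_expression_matrix(expression_path, sample_sheet_path) -> ExpressionMatrix:
    return ExpressionMatrix(read_expression(expression_path), read_sample_sheet(sample_sheet_path))


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "chromosome"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation missing column {col!r}")
    df = df.set_index("gene_id")
    _check_unique(df.index, "gene id", path)
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns or "sex" not in df.columns:
        raise ValueError(f"{path}: clinical table needs patient_id and sex columns")
    _check_unique(pd.Index(df["patient_id"]), "patient id", path)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """Generic TSV writer used for per-stage result tables."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def demo_cohort_dir() -> Path:
    """Location of the small packaged demo cohort."""
    from importlib import resources

    return Path(str(resources.files("valvesex").joinpath("data/demo")))


def load_demo_cohort():
    """The packaged seeded demo fixture: (ExpressionMatrix, annotation, clinical)."""
    d = demo_cohort_dir()
    expr = read_expression_matrix(d / "expression.tsv", d / "samples.tsv")
    annotation = read_annotation(d / "annotation.tsv")
    clinical = read_clinical(d / "clinical.csv")
    return expr, annotation, clinical
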