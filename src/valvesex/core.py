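"""Core data containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a log2 genes-by-samples
matrix together with its sample annotations (patient, sex, tissue grade).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Ordered tissue grades, from macroscopically healthy to calcified.
TISSUE_LEVELS = ("nondiseased", "intermediate", "calcified")

#: Ordinal disease score used by the generative model and the contrasts.
TISSUE_SCORE = {"nondiseased": 0.0, "intermediate": 0.5, "calcified": 1.0}

SEX_LEVELS = ("M", "F")

SAMPLE_SHEET_COLUMNS = ("sample_id", "patient_id", "sex", "tissue")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id. All values
        are finite floats on the log2 scale.
    samples
        DataFrame indexed by sample id with columns ``patient_id``, ``sex``
        (``M``/``F``) and ``tissue`` (one of :data:`TISSUE_LEVELS`). Row
        order matches the column order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [c for c in ("patient_id", "sex", "tissue") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {missing}")
        if list(self.values.columns) != list(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample sheet ids do not agree")
            # align order rather than erroring on a pure permutation
            self.samples = self.samples.loc[self.values.columns]
        bad_sex = set(self.samples["sex"].unique()) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex level(s): {sorted(bad_sex)}")
        bad_tissue = set(self.samples["tissue"].unique()) - set(TISSUE_LEVELS)
        if bad_tissue:
            raise ValueError(f"unknown tissue grade(s): {sorted(bad_tissue)}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` (order preserved as given)."""
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown gene ids: {missing[:5].tolist()}")
        return ExpressionMatrix(self.values.loc[gene_ids], self.samples.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {missing[:5].tolist()}")
        return ExpressionMatrix(self.values[sample_ids], self.samples.loc[sample_ids])

    def sample_lookup(self) -> dict:
        """(patient_id, tissue) -> sample_id mapping."""
        return {
            (row.patient_id, row.tissue): sid
            for sid, row in self.samples.iterrows()
        }


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for pipeline stage ``stage`` under global ``seed``.

    A fixed counter scheme: adding a later stage never perturbs the
    randomness of earlier ones.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stage),)))
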