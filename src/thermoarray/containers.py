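"""Shared in-memory containers: the annotated expression matrix.

Expression values are genes x samples on log2 scale (post-normalisation, as
produced by array preprocessing).  Sample annotations carry the three factorial
factors of the design:

- ``mean_temp``: developmental mean temperature, 15 or 25 (°C)
- ``regime``: ``constant`` or ``fluctuating`` developmental regime
- ``assay``: adult treatment before sampling, 20 (control) or 35 (ramped), °C
- ``replicate``: biological replicate index within the cell
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FACTORS = ("mean_temp", "regime", "assay")

__all__ = ["ExpressionMatrix", "FACTORS"]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with sample factor annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    annotations
        DataFrame indexed by sample id with at least the factor columns
        ``mean_temp``, ``regime``, ``assay`` and ``replicate``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.annotations.index):
            missing = set(self.values.columns) ^ set(self.annotations.index)
            raise ValueError(
                "expression columns and annotation rows must list the same "
                f"sample ids in the same order; mismatched: {sorted(map(str, missing))}"
            )
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, mask_or_ids) -> "ExpressionMatrix":
        """Sub-matrix restricted to a boolean mask over samples or a list of ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            ids = self.sample_ids[np.asarray(mask_or_ids)]
        else:
            ids = pd.Index(mask_or_ids)
        return ExpressionMatrix(self.values[ids], self.annotations.loc[ids])

    def samples_where(self, **factor_levels) -> pd.Index:
        """Sample ids whose annotations match every ``factor=level`` keyword."""
        mask = pd.Series(True, index=self.annotations.index)
        for factor, level in factor_levels.items():
            if factor not in self.annotations.columns:
                raise KeyError(f"unknown annotation column {factor!r}")
            mask &= self.annotations[factor] == level
        return self.annotations.index[mask]

    # --- I/O -------------------------------------------------------------
    def write(self, matrix_tsv, annotations_csv) -> None:
        """Write values as TSV (genes in rows) and annotations as CSV."""
        self.values.to_csv(matrix_tsv, sep="\t", index_label="gene_id")
        self.annotations.to_csv(annotations_csv, index_label="sample_id")

    @classmethod
    def read(cls, matrix_tsv, annotations_csv) -> "ExpressionMatrix":
        """Read and validate a TSV matrix plus CSV annotation pair.

        Raises a :class:`ValueError` naming the offending cell for non-numeric
        or missing entries, and the offending sample ids on a header mismatch.
        """
        values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
        ann = pd.read_csv(annotations_csv, index_col=0)
        for col in values.columns:
            numeric = pd.to_numeric(values[col], errors="coerce")
            bad = values.index[numeric.isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric or missing expression value at "
                    f"(gene {bad[0]!r}, sample {col!r})"
                )
            values[col] = numeric
        if set(values.columns) != set(ann.index):
            missing = sorted(map(str, set(values.columns) ^ set(ann.index)))
            raise ValueError(f"sample ids differ between matrix and annotations: {missing}")
        return cls(values, ann.loc[values.columns])
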