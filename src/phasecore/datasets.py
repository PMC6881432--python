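"""Core in-memory containers and TSV I/O for expression studies.

The pipeline operates on bulk RNA-seq expression matrices with per-sample
metadata describing the biological phase (gregarious ``G`` vs solitary ``S``),
the confounding design level (developmental stage, tissue, or treatment/time
combination) and the dataset of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHASES = ("G", "S")

#: Accepted aliases for phase labels.  Time-course samples are labelled by
#: treatment: CS (crowding of solitary animals, i.e. gregarization) maps to G,
#: IG (isolation of gregarious animals, solitarization) maps to S.
PHASE_ALIASES = {"G": "G", "S": "S", "CS": "G", "IG": "S"}


def normalize_phase(label: str) -> str:
    try:
        return PHASE_ALIASES[str(label).upper()]
    except KeyError:
        raise ValueError(f"unknown phase label {label!r}; expected one of "
                         f"{sorted(PHASE_ALIASES)}") from None


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        Non-negative matrix, genes as rows and samples as columns.
    meta
        Per-sample metadata indexed by sample id.  Must contain ``phase``
        (``G``/``S`` or the ``CS``/``IG`` aliases), ``confounder_level`` and
        ``dataset``.  Time-course metadata additionally carries ``timepoint``
        and ``treatment`` columns.
    kind
        ``"counts"`` for raw read counts, ``"rpkm"`` for length/depth
        normalized values.
    gene_lengths
        Gene lengths in nucleotides; required to convert counts to RPKM.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    kind: str = "counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "rpkm"):
            raise ValueError(f"kind must be 'counts' or 'rpkm', got {self.kind!r}")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        required = {"phase", "confounder_level", "dataset"}
        if not required <= set(self.meta.columns):
            raise ValueError(f"metadata must contain columns {sorted(required)}")
        self.meta = self.meta.loc[self.values.columns].copy()
        self.meta["phase"] = self.meta["phase"].map(normalize_phase)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def phases(self) -> pd.Series:
        return self.meta["phase"]

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = pd.Index(genes)
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[genes]
        return ExpressionDataset(self.values.loc[genes], self.meta.copy(),
                                 kind=self.kind, gene_lengths=lengths)

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = pd.Index(samples)
        return ExpressionDataset(self.values[samples], self.meta.loc[samples],
                                 kind=self.kind, gene_lengths=self.gene_lengths)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-as-rows expression TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def load_dataset(expr_path: str | Path, meta_path: str | Path,
                 kind: str = "counts",
                 lengths_path: str | Path | None = None) -> ExpressionDataset:
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionDataset(read_expression_tsv(expr_path),
                             read_metadata_tsv(meta_path),
                             kind=kind, gene_lengths=lengths)
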