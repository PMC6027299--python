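"""Expression-matrix container and tab-separated I/O.

The pipeline's central in-memory object is :class:`ExpressionMatrix`: a
genes × samples table of one RNA class (lncRNA, mRNA or miRNA) together
with a tumor/normal label for every sample.  Values are linear-scale
abundances (FPKM for genes, reads-per-million for miRNAs) until
:func:`cernet.preprocess.log2_transform` flips the ``transformed`` flag,
after which they are log2 expression levels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

GENE_CLASSES = ("lncRNA", "mRNA", "miRNA")
TUMOR = "tumor"
NORMAL = "normal"
SAMPLE_GROUPS = (TUMOR, NORMAL)

#: value written for missing entries in matrix TSVs
NA_TOKEN = "NA"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values for one RNA class.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    sample_groups
        Series mapping each sample id to ``"tumor"`` or ``"normal"``.
        Must cover every column of ``values``.
    gene_class
        One of ``"lncRNA"``, ``"mRNA"``, ``"miRNA"``.
    transformed
        False while values are on the linear scale, True after log2.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    gene_class: str
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene_class must be one of {GENE_CLASSES}, got {self.gene_class!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        self.values = self.values.rename_axis(index="gene_id", columns=None)
        bad = sorted(set(self.sample_groups) - set(SAMPLE_GROUPS))
        if bad:
            raise ValueError(f"unknown sample groups {bad}; expected {SAMPLE_GROUPS}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to one group (``"tumor"`` or ``"normal"``)."""
        if group not in SAMPLE_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.sample_groups.index[self.sample_groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def with_values(self, values: pd.DataFrame, *, transformed: bool | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (same samples/labels)."""
        return replace(
            self,
            values=values,
            sample_groups=self.sample_groups,
            transformed=self.transformed if transformed is None else transformed,
        )


# -- tab-separated readers/writers --------------------------------------------


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write genes × samples values as TSV (header row = sample ids)."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", na_rep=NA_TOKEN,
                         float_format="%.10g")
    return path


def read_matrix_tsv(
    path: str | Path,
    sample_groups: pd.Series,
    gene_class: str,
    *,
    transformed: bool = False,
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=[NA_TOKEN])
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, sample_groups, gene_class, transformed=transformed)


def write_sample_groups(sample_groups: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"sample_id": sample_groups.index, "group": sample_groups.values})
    df.to_csv(path, sep="\t", index=False)
    return path


def read_sample_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, group")
    s = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    bad = sorted(set(s) - set(SAMPLE_GROUPS))
    if bad:
        raise ValueError(f"{path}: unknown sample groups {bad}")
    return s


def warn_if_empty(matrix: ExpressionMatrix, context: str) -> None:
    if matrix.n_genes == 0:
        warnings.warn(f"{context}: empty matrix (no genes)", stacklevel=3)
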