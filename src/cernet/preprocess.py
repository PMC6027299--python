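"""Matrix preparation: expression filtering, half-minimum imputation, log2.

The preparation order is fixed — filter, impute, transform — because each
step's contract depends on the previous one: the expression filter needs
linear-scale values with genuine zeros, imputation needs the filter to have
removed all-zero genes, and the log2 transform needs strictly positive
values.  :func:`prepare_matrix` runs the three in order.

Gene-class assignment from a biotype table lives here too: transcripts
longer than 200 nt with a long-non-coding biotype are lncRNAs, biotype
``protein_coding`` is mRNA, everything else is left unclassified and
excluded downstream.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, warn_if_empty

#: biotypes treated as long non-coding RNA
DEFAULT_LNC_BIOTYPES = frozenset(
    {"lincRNA", "antisense", "processed_transcript", "non_coding"}
)

#: biotype vocabulary we recognise without warning
KNOWN_BIOTYPES = DEFAULT_LNC_BIOTYPES | {
    "protein_coding",
    "miRNA",
    "pseudogene",
    "processed_pseudogene",
    "snoRNA",
    "snRNA",
    "rRNA",
    "misc_RNA",
    "TEC",
}

#: minimum length (nt) for a transcript to count as lncRNA
LNC_LENGTH_THRESHOLD = 200


def filter_expressed(matrix: ExpressionMatrix, min_fraction: float = 0.9) -> ExpressionMatrix:
    """Keep genes expressed in more than ``min_fraction`` of samples.

    A gene counts as expressed in a sample when its value is present and
    strictly positive; missing values count as unexpressed.  The boundary
    is strict: a gene expressed in exactly 90% of samples is removed at
    the default ``min_fraction=0.9``.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if matrix.transformed:
        raise ValueError("filter_expressed expects an untransformed (linear-scale) matrix")
    warn_if_empty(matrix, "filter_expressed")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        return matrix
    expressed = (matrix.values > 0) & matrix.values.notna()
    frac = expressed.sum(axis=1) / matrix.n_samples
    kept = matrix.values.loc[frac > min_fraction]
    if kept.shape[0] == 0:
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    return matrix.with_values(kept)


def impute_half_min(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace zero/missing values by half the gene's minimum non-zero value.

    Computed per gene row.  Genes with no positive value cannot form a
    half-minimum and are rejected (they should not survive
    :func:`filter_expressed` at any positive ``min_fraction``).
    Idempotent: a matrix with no zeros or missing values is returned
    unchanged.
    """
    if matrix.transformed:
        raise ValueError("impute_half_min expects an untransformed matrix")
    vals = matrix.values
    if matrix.n_genes == 0:
        return matrix
    positive = vals.where(vals > 0)
    min_nonzero = positive.min(axis=1)
    dead = min_nonzero.isna()
    if dead.any():
        names = list(vals.index[dead])
        raise ValueError(
            f"cannot impute genes with no non-zero value: {names[:10]}"
            + ("..." if len(names) > 10 else "")
        )
    needs = vals.isna() | (vals <= 0)
    filled = vals.mask(needs, min_nonzero / 2.0, axis=0)
    return matrix.with_values(filled)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; refuses to run twice (guarded by the flag)."""
    if matrix.transformed:
        raise ValueError("matrix is already log2-transformed")
    vals = matrix.values
    bad = (vals <= 0) | vals.isna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-positive or missing value at gene {gene!r}, sample {sample!r}; "
            "run impute_half_min first"
        )
    return matrix.with_values(np.log2(vals), transformed=True)


def prepare_matrix(matrix: ExpressionMatrix, min_fraction: float = 0.9) -> ExpressionMatrix:
    """filter_expressed → impute_half_min → log2_transform, in that order."""
    return log2_transform(impute_half_min(filter_expressed(matrix, min_fraction)))


# -- gene-class assignment -----------------------------------------------------


def read_biotype_table(path: str | Path) -> pd.DataFrame:
    """Read a biotype TSV with columns gene_id, biotype and optional length."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "biotype": str})
    if not {"gene_id", "biotype"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, biotype[, length]")
    return df


def assign_classes(
    biotypes: pd.DataFrame,
    lnc_categories: frozenset[str] | set[str] = DEFAULT_LNC_BIOTYPES,
    length_threshold: int = LNC_LENGTH_THRESHOLD,
) -> pd.Series:
    """Map genes to lncRNA / mRNA / unclassified from biotype and length.

    A gene is lncRNA when its biotype is one of ``lnc_categories`` and its
    length, when known, exceeds ``length_threshold`` nucleotides;
    ``protein_coding`` is mRNA; anything else (including unknown biotype
    strings, which trigger a warning) is ``unclassified`` and excluded
    from downstream analysis.
    """
    lengths = biotypes["length"] if "length" in biotypes.columns else None
    unknown = sorted(set(biotypes["biotype"]) - KNOWN_BIOTYPES - set(lnc_categories))
    if unknown:
        warnings.warn(f"unknown biotypes treated as unclassified: {unknown}", stacklevel=2)
    out = {}
    for i, row in enumerate(biotypes.itertuples(index=False)):
        bt = row.biotype
        if bt == "protein_coding":
            cls = "mRNA"
        elif bt in lnc_categories:
            length = None if lengths is None else lengths.iloc[i]
            if length is None or pd.isna(length) or float(length) > length_threshold:
                cls = "lncRNA"
            else:
                cls = "unclassified"
        else:
            cls = "unclassified"
        out[row.gene_id] = cls
    return pd.Series(out, name="gene_class")
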