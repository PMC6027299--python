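"""Class-wise differential expression with Mann–Whitney U and BH FDR.

Tumor and normal groups are compared per gene with the two-tailed
Mann–Whitney U test; p-values are adjusted per RNA class with the
Benjamini–Hochberg step-up procedure.  "Fold change" throughout this
package means the log2 fold change — the difference of log2-scale group
means (tumor minus normal).  This is the only reading under which the
default gates are coherent: an upregulation cut of 1 for lncRNA/mRNA next
to a downregulation cut of −0.6 for miRNA can only live on the log2
scale.

Default gates (configurable per class):

=========  ==============  =========  =========
class      log2FC gate     FDR gate   direction
=========  ==============  =========  =========
lncRNA     ≥ 1             < 0.001    up
mRNA       ≥ 1             < 0.001    up
miRNA      ≤ −0.6          < 0.001    down
=========  ==============  =========  =========

The asymmetric miRNA cut keeps enough downregulated miRNAs to anchor
sponge triples; both fold-change bounds are inclusive, both FDR bounds
strict.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, NORMAL, TUMOR

#: total sample count at or below which the exact MWU null is enumerated
EXACT_MAX_N = 12


def mann_whitney_p(x, y, *, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Mann–Whitney U p-value for samples ``x`` vs ``y``.

    Uses exact enumeration of the U null distribution when the pooled
    sample size is at most ``exact_max_n`` and the data are tie-free;
    otherwise the normal approximation with tie and continuity
    correction.  Returns a p-value in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: no evidence either way
    if pooled.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def log2_fold_change(x_tumor, y_normal) -> float:
    """Difference of group means (tumor − normal) on the log2 scale."""
    x = np.asarray(x_tumor, dtype=float)
    y = np.asarray(y_normal, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(x.mean() - y.mean())


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Gate:
    """Selection gate for one RNA class.

    ``direction="up"`` keeps genes with log2fc ≥ fc_cut; ``"down"`` keeps
    log2fc ≤ fc_cut.  The FDR bound is strict in both cases.
    """

    fc_cut: float
    fdr_cut: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    def passes(self, log2fc: float, fdr: float) -> bool:
        if fdr >= self.fdr_cut:
            return False
        if self.direction == "up":
            return log2fc >= self.fc_cut
        return log2fc <= self.fc_cut


DEFAULT_GATES: dict[str, Gate] = {
    "lncRNA": Gate(fc_cut=1.0, fdr_cut=0.001, direction="up"),
    "mRNA": Gate(fc_cut=1.0, fdr_cut=0.001, direction="up"),
    "miRNA": Gate(fc_cut=-0.6, fdr_cut=0.001, direction="down"),
}


def de_table(matrix: ExpressionMatrix, *, adjust: bool = True) -> pd.DataFrame:
    """Per-gene DE statistics for one log2-transformed matrix.

    Returns a DataFrame with columns gene_id, gene_class, log2fc, p_value
    and (when ``adjust``) fdr; the BH adjustment is applied within this
    matrix, i.e. within one RNA class.  Set ``adjust=False`` when pooling
    classes before correction.
    """
    if not matrix.transformed:
        raise ValueError("de_table expects a log2-transformed matrix")
    tumor = matrix.group_values(TUMOR).to_numpy()
    normal = matrix.group_values(NORMAL).to_numpy()
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("need at least one tumor and one normal sample")
    rows = []
    for gi, gene in enumerate(matrix.gene_ids):
        x, y = tumor[gi], normal[gi]
        rows.append((gene, matrix.gene_class, log2_fold_change(x, y),
                     mann_whitney_p(x, y)))
    out = pd.DataFrame(rows, columns=["gene_id", "gene_class", "log2fc", "p_value"])
    if adjust:
        out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out


def select_dysregulated(
    results: pd.DataFrame,
    gates: dict[str, Gate] | None = None,
) -> pd.DataFrame:
    """Apply per-class gates; adds a ``direction`` column (up/down/null).

    ``results`` must carry gene_class, log2fc and fdr columns.  Genes of a
    class with no gate raise an error.  The returned frame is the input
    plus ``direction``: the gate's direction where it passes, ``"null"``
    otherwise.
    """
    gates = DEFAULT_GATES if gates is None else gates
    unknown = sorted(set(results["gene_class"]) - set(gates))
    if unknown:
        raise ValueError(f"no selection gate for class(es): {unknown}")
    direction = []
    for row in results.itertuples(index=False):
        gate = gates[row.gene_class]
        direction.append(gate.direction if gate.passes(row.log2fc, row.fdr) else "null")
    out = results.copy()
    out["direction"] = direction
    return out


def dysregulated_sets(results_with_direction: pd.DataFrame) -> dict[str, set[str]]:
    """Selected gene ids per class (the DEL / DEM / DEMi sets)."""
    hits = results_with_direction[results_with_direction["direction"] != "null"]
    out: dict[str, set[str]] = {}
    for cls, sub in hits.groupby("gene_class"):
        out[cls] = set(sub["gene_id"])
    return out
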