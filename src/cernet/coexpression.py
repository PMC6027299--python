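"""All-pairs Pearson co-expression with empirical-quantile thresholds.

Rather than fixing absolute correlation cutoffs, significance thresholds
are calibrated from the data: for each cross-class pair type (lnc–mrna,
lnc–mirna, mrna–mirna) the Pearson correlation of *every* cross pair is
computed over tumor samples, and the positive / negative cutoffs are the
upper / lower ``quantile_level`` quantiles of that empirical distribution
(type-7 linear interpolation).  A pair is then significantly positively
co-expressed when its PCC strictly exceeds the positive cut and its
correlation p-value is below ``p_cut`` (default 1e-4); negatively when
its PCC is strictly below the negative cut with the same p gate.

Correlations are computed over tumor samples only by default — the
competition signal lives in the tumor compartment — with an all-sample
mode behind ``samples="all"``.  Correlation p-values use the Student-t
transform t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, TUMOR

#: canonical cross-class pair labels; id_a / id_b follow this order
CLASS_PAIRS = ("lnc-mrna", "lnc-mirna", "mrna-mirna")

DEFAULT_QUANTILE_LEVEL = 0.95
DEFAULT_P_CUT = 1e-4


def pearson_cc(x, y) -> float:
    """Sample Pearson correlation (n−1 denominator, sample SDs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r = float(np.dot(x - x.mean(), y - y.mean()) / ((x.size - 1) * sx * sy))
    return max(-1.0, min(1.0, r))


def corr_p_value(pcc: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation on n observations."""
    if n < 4:
        raise ValueError("need n >= 4 for a correlation p-value")
    if abs(pcc) >= 1.0:
        warnings.warn("|pcc| = 1: p-value 0 by convention", stacklevel=2)
        return 0.0
    t = pcc * np.sqrt((n - 2) / (1.0 - pcc * pcc))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean, unit sample SD; flags zero-variance rows."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    sd[sd == 0] = 1.0  # placeholder; degenerate rows are masked by callers
    return (values - mean) / sd, degenerate


def cross_pcc(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    *,
    samples: str = "tumor",
) -> pd.DataFrame:
    """PCC of every (gene in A) × (gene in B) pair as a dense DataFrame.

    Computed over the shared tumor samples (or all samples with
    ``samples="all"``).  Zero-variance genes are dropped with a warning —
    their correlation is undefined.  Raises when the two matrices do not
    share the same sample set.
    """
    if not (matrix_a.transformed and matrix_b.transformed):
        raise ValueError("cross_pcc expects log2-transformed matrices")
    if samples == "tumor":
        cols_a, cols_b = matrix_a.samples_in(TUMOR), matrix_b.samples_in(TUMOR)
    elif samples == "all":
        cols_a, cols_b = matrix_a.sample_ids, matrix_b.sample_ids
    else:
        raise ValueError(f"samples must be 'tumor' or 'all', got {samples!r}")
    if set(cols_a) != set(cols_b):
        only_a = sorted(set(cols_a) - set(cols_b))
        only_b = sorted(set(cols_b) - set(cols_a))
        raise ValueError(f"sample sets differ: only in A {only_a}, only in B {only_b}")
    n = len(cols_a)
    if n < 3:
        raise ValueError(f"need at least 3 shared samples, have {n}")
    va = matrix_a.values[cols_a].to_numpy(dtype=float)
    vb = matrix_b.values[cols_a].to_numpy(dtype=float)
    za, dead_a = _standardize_rows(va)
    zb, dead_b = _standardize_rows(vb)
    if dead_a.any() or dead_b.any():
        n_dead = int(dead_a.sum() + dead_b.sum())
        warnings.warn(f"dropping {n_dead} zero-variance gene(s); PCC undefined",
                      stacklevel=2)
    r = za @ zb.T / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    out = pd.DataFrame(r, index=matrix_a.gene_ids, columns=matrix_b.gene_ids)
    return out.loc[~dead_a, ~dead_b]


def pcc_p_values(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided t-test p-values for Pearson correlations."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(t, df=n - 2)


def allpairs_pcc(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    class_pair: str,
    *,
    samples: str = "tumor",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Score every cross pair; returns (pair table, flat PCC distribution).

    The pair table has columns id_a, id_b, class_pair, pcc, p_value with
    id_a drawn from ``matrix_a``.  The flat array is the same PCCs and is
    what :func:`calibrate_thresholds` consumes.
    """
    if class_pair not in CLASS_PAIRS:
        raise ValueError(f"class_pair must be one of {CLASS_PAIRS}")
    r = cross_pcc(matrix_a, matrix_b, samples=samples)
    n = len(matrix_a.samples_in(TUMOR)) if samples == "tumor" else matrix_a.n_samples
    flat = r.to_numpy().ravel()
    idx = pd.MultiIndex.from_product([r.index, r.columns], names=["id_a", "id_b"])
    pairs = pd.DataFrame({"pcc": flat}, index=idx).reset_index()
    pairs.insert(2, "class_pair", class_pair)
    pairs["p_value"] = pcc_p_values(pairs["pcc"].to_numpy(), n)
    return pairs, flat


@dataclass
class ThresholdSet:
    """Calibrated positive/negative PCC cutoffs per class pair."""

    pos_cut: dict[str, float]
    neg_cut: dict[str, float]
    quantile_level: float = DEFAULT_QUANTILE_LEVEL
    p_cut: float = DEFAULT_P_CUT

    def __post_init__(self) -> None:
        if not 0.5 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in (0.5, 1)")
        for cp in self.pos_cut:
            if cp in self.neg_cut and not self.neg_cut[cp] < self.pos_cut[cp]:
                raise ValueError(f"{cp}: neg_cut must be below pos_cut")

    def to_dict(self) -> dict:
        return {
            "quantile_level": self.quantile_level,
            "p_cut": self.p_cut,
            "pos_cut": dict(self.pos_cut),
            "neg_cut": dict(self.neg_cut),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(pos_cut=dict(d["pos_cut"]), neg_cut=dict(d["neg_cut"]),
                   quantile_level=d["quantile_level"], p_cut=d["p_cut"])


def calibrate_thresholds(
    distributions: dict[str, np.ndarray],
    quantile_level: float = DEFAULT_QUANTILE_LEVEL,
    p_cut: float = DEFAULT_P_CUT,
) -> ThresholdSet:
    """Empirical quantile cutoffs from per-class-pair PCC distributions.

    pos_cut is the ``quantile_level`` quantile, neg_cut the
    ``1 − quantile_level`` quantile, both with type-7 (linear) quantile
    interpolation for reproducibility.
    """
    pos, neg = {}, {}
    for cp, values in distributions.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"{cp}: empty PCC distribution")
        if values.size < 100:
            warnings.warn(f"{cp}: only {values.size} pairs; quantiles will be noisy",
                          stacklevel=2)
        pos[cp] = float(np.quantile(values, quantile_level))
        neg[cp] = float(np.quantile(values, 1.0 - quantile_level))
    return ThresholdSet(pos_cut=pos, neg_cut=neg, quantile_level=quantile_level,
                        p_cut=p_cut)


def significant_pairs(
    pairs: pd.DataFrame,
    thresholds: ThresholdSet,
    sign: str,
) -> pd.DataFrame:
    """Filter a pair table to significant positive or negative pairs.

    Positive: pcc strictly above the class pair's pos_cut; negative:
    strictly below neg_cut; both additionally require p_value < p_cut.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if len(pairs) == 0:
        return pairs.copy()
    cuts = thresholds.pos_cut if sign == "positive" else thresholds.neg_cut
    missing = sorted(set(pairs["class_pair"]) - set(cuts))
    if missing:
        raise ValueError(f"no calibrated threshold for class pair(s): {missing}")
    cut = pairs["class_pair"].map(cuts)
    if sign == "positive":
        keep = pairs["pcc"] > cut
    else:
        keep = pairs["pcc"] < cut
    keep &= pairs["p_value"] < thresholds.p_cut
    return pairs.loc[keep].reset_index(drop=True)
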