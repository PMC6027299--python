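"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene set of size n drawn from a universe of N genes, and an
annotated term containing K universe genes, the over-representation
p-value is the upper hypergeometric tail P(X ≥ k) where k is the
observed overlap.  P-values are BH-adjusted across terms.  Term content
comes from user-supplied GMT files; no annotation database is bundled.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (term_id, term_name, then member genes, tab-separated)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
        sets.append(GeneSet(fields[0], fields[1], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.genes)]) + "\n")
    return path


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_ora(
    query: set[str],
    term_sets: list[GeneSet],
    universe: set[str],
    p_cut: float | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each term, BH-corrected.

    Query genes outside the universe are dropped with a warning; term
    membership is likewise intersected with the universe.  Results are
    sorted by p-value; pass ``p_cut`` to keep only terms below it
    (the conventional report filter is p < 0.05).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    outside = set(query) - set(universe)
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query gene(s) outside the universe",
            stacklevel=2,
        )
    query_in = set(query) & set(universe)
    cols = ["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    if not query_in:
        warnings.warn("empty query after universe restriction", stacklevel=2)
        out = pd.DataFrame(columns=cols + ["fdr"])
        return out
    N = len(universe)
    n = len(query_in)
    rows = []
    for term in term_sets:
        members = term.genes & set(universe)
        K = len(members)
        k = len(members & query_in)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((term.term_id, term.term_name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=cols)
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    if p_cut is not None:
        out = out.loc[out["p_value"] < p_cut].reset_index(drop=True)
    return out
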