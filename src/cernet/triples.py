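"""Interaction-evidence merging and ceRNA sponge-triple assembly.

A ceRNA triple is a (lncRNA, miRNA, mRNA) combination in which the
lncRNA and mRNA are significantly positively co-expressed, both interact
with the same miRNA, and both are significantly negatively co-expressed
with it.  Interaction evidence is routed asymmetrically, mirroring how
such catalogs are assembled: miRNA–mRNA support must come from validated
databases, while miRNA–lncRNA support is accepted from sequence-based
predictions (validated lncRNA catalogs barely exist).

The assembly itself is a join: for every significant positive
lncRNA–mRNA pair, emit one triple per miRNA that is negatively
co-expressed with (and interacts with) both partners.
"""
from __future__ import annotations

import pandas as pd

INTERACTION_COLUMNS = ["mirna_id", "target_id", "target_class", "evidence"]
TARGET_CLASSES = ("lncRNA", "mRNA")
EVIDENCE_LEVELS = ("validated", "predicted")  # strongest first

#: evidence class each arm of a triple must carry
DEFAULT_EVIDENCE_REQUIRED = {"lncRNA": "predicted", "mRNA": "validated"}

TRIPLE_COLUMNS = [
    "lnc_id", "mirna_id", "mrna_id",
    "pcc_lnc_mrna", "p_lnc_mrna",
    "pcc_lnc_mirna", "p_lnc_mirna",
    "pcc_mrna_mirna", "p_mrna_mirna",
]


def _check_interactions(df: pd.DataFrame) -> None:
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    bad_cls = sorted(set(df["target_class"]) - set(TARGET_CLASSES))
    if bad_cls:
        raise ValueError(f"unknown target_class values: {bad_cls}")
    bad_ev = sorted(set(df["evidence"]) - set(EVIDENCE_LEVELS))
    if bad_ev:
        raise ValueError(f"unknown evidence values: {bad_ev}")


def merge_interactions(sources: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of interaction tables, deduplicated on (miRNA, target).

    When a pair appears with both evidence levels, the strongest wins
    (validated > predicted).  A target annotated with two different
    classes across sources is an error.
    """
    if not sources:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    for src in sources:
        _check_interactions(src)
    merged = pd.concat([s[INTERACTION_COLUMNS] for s in sources], ignore_index=True)
    conflicts = merged.groupby("target_id")["target_class"].nunique()
    conflicts = conflicts[conflicts > 1]
    if len(conflicts):
        raise ValueError(
            f"target(s) annotated with conflicting classes: {list(conflicts.index)}"
        )
    rank = merged["evidence"].map({e: i for i, e in enumerate(EVIDENCE_LEVELS)})
    merged = (
        merged.assign(_rank=rank)
        .sort_values(["mirna_id", "target_id", "_rank"], kind="stable")
        .drop_duplicates(["mirna_id", "target_id"], keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return merged


def restrict_to_de(
    interactions: pd.DataFrame,
    del_set: set[str],
    dem_set: set[str],
    demi_set: set[str],
    evidence_required: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep interactions whose partners are dysregulated, routing evidence.

    Returns ``(del_demi, dem_demi)``: miRNA ∈ DEMi with a DEL target
    carrying the lncRNA-arm evidence class, and with a DEM target
    carrying the mRNA-arm evidence class.  Pass ``None`` as a class's
    required evidence to accept any.
    """
    _check_interactions(interactions)
    req = DEFAULT_EVIDENCE_REQUIRED if evidence_required is None else evidence_required
    in_demi = interactions["mirna_id"].isin(demi_set)

    def arm(target_class: str, target_set: set[str]) -> pd.DataFrame:
        keep = (
            in_demi
            & (interactions["target_class"] == target_class)
            & interactions["target_id"].isin(target_set)
        )
        need = req.get(target_class)
        if need is not None:
            keep &= interactions["evidence"] == need
        return interactions.loc[keep].reset_index(drop=True)

    return arm("lncRNA", del_set), arm("mRNA", dem_set)


def assemble_triples(
    pos_lnc_mrna: pd.DataFrame,
    neg_lnc_mirna: pd.DataFrame,
    neg_mrna_mirna: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three significant-pair tables into ceRNA triples.

    Inputs are pair tables (columns id_a, id_b, pcc, p_value) already
    filtered for significance and interaction support; in each, id_a is
    the lnc/lnc/mrna partner and id_b the mrna/mirna/mirna partner.  One
    triple is emitted per (lncRNA, miRNA, mRNA) combination, sorted by
    (lnc_id, mirna_id, mrna_id) for stable diffs; each row embeds the
    three supporting PCC and p-value records.
    """
    lnc_to_mirnas: dict[str, dict[str, tuple[float, float]]] = {}
    for row in neg_lnc_mirna.itertuples(index=False):
        lnc_to_mirnas.setdefault(row.id_a, {})[row.id_b] = (row.pcc, row.p_value)
    mrna_to_mirnas: dict[str, dict[str, tuple[float, float]]] = {}
    for row in neg_mrna_mirna.itertuples(index=False):
        mrna_to_mirnas.setdefault(row.id_a, {})[row.id_b] = (row.pcc, row.p_value)

    rows = []
    for row in pos_lnc_mrna.itertuples(index=False):
        lnc, mrna = row.id_a, row.id_b
        mirnas_l = lnc_to_mirnas.get(lnc)
        mirnas_g = mrna_to_mirnas.get(mrna)
        if not mirnas_l or not mirnas_g:
            continue
        for mirna in mirnas_l.keys() & mirnas_g.keys():
            pcc_lm, p_lm = mirnas_l[mirna]
            pcc_gm, p_gm = mirnas_g[mirna]
            rows.append((lnc, mirna, mrna, row.pcc, row.p_value,
                         pcc_lm, p_lm, pcc_gm, p_gm))
    out = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    return out.sort_values(["lnc_id", "mirna_id", "mrna_id"],
                           kind="stable").reset_index(drop=True)


def validate_triples(
    triples: pd.DataFrame,
    thresholds,
    interactions: pd.DataFrame | None = None,
) -> None:
    """Re-check every emitted triple against its threshold invariants.

    Raises AssertionError on the first violation; used as a belt-and-
    braces pass after assembly.
    """
    for row in triples.itertuples(index=False):
        assert row.pcc_lnc_mrna > thresholds.pos_cut["lnc-mrna"], row
        assert row.pcc_lnc_mirna < thresholds.neg_cut["lnc-mirna"], row
        assert row.pcc_mrna_mirna < thresholds.neg_cut["mrna-mirna"], row
        for p in (row.p_lnc_mrna, row.p_lnc_mirna, row.p_mrna_mirna):
            assert p < thresholds.p_cut, row
    if interactions is not None:
        have = set(zip(interactions["mirna_id"], interactions["target_id"]))
        for row in triples.itertuples(index=False):
            assert (row.mirna_id, row.lnc_id) in have, row
            assert (row.mirna_id, row.mrna_id) in have, row


def read_interactions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_interactions(df)
    return df


def write_interactions_tsv(interactions: pd.DataFrame, path):
    _check_interactions(interactions)
    interactions[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path
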