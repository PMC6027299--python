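"""End-to-end orchestration: matrices + interactions → triples → hubs.

Stage order: matrix preparation (filter → impute → log2) per RNA class;
class-wise differential expression with BH FDR and the fold-change
gates; all-pairs tumor-sample Pearson correlation of *all* surviving
genes to calibrate the empirical-quantile thresholds; significance
filtering of dysregulated pairs (the lncRNA–mRNA arm over all DEL × DEM
pairs, the two miRNA arms restricted to catalogued interactions);
sponge-triple assembly; network construction, betweenness ranking, hub
selection, subnetwork coverage; optional hypergeometric enrichment of
the hub-subnetwork mRNAs against a user GMT, with the universe
defaulting to every mRNA surviving preprocessing.

Every threshold is carried in :class:`RunConfig` and echoed verbatim
into the run summary, so a summary is a complete provenance record.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as cx
from . import diffexpr as de
from . import network as net
from . import triples as tr
from .enrichment import GeneSet, hypergeom_ora
from .expression import ExpressionMatrix, TUMOR
from .preprocess import prepare_matrix


@dataclass
class RunConfig:
    """All gates and thresholds of one pipeline run (defaults as documented)."""

    min_expressed_fraction: float = 0.9
    fc_cut_lnc: float = 1.0
    fc_cut_mrna: float = 1.0
    fc_cut_mirna: float = -0.6
    fdr_cut: float = 0.001
    pooled_fdr: bool = False
    quantile_level: float = 0.95
    corr_p_cut: float = 1e-4
    tumor_only_pcc: bool = True
    evidence_lnc: str = "predicted"
    evidence_mrna: str = "validated"
    hub_k: int = 3
    hub_class: str = "lncRNA"
    subnetwork_scope: str = "triples"
    ora_p_cut: float = 0.05
    seed: int = 0

    def gates(self) -> dict[str, de.Gate]:
        return {
            "lncRNA": de.Gate(self.fc_cut_lnc, self.fdr_cut, "up"),
            "mRNA": de.Gate(self.fc_cut_mrna, self.fdr_cut, "up"),
            "miRNA": de.Gate(self.fc_cut_mirna, self.fdr_cut, "down"),
        }

    def evidence_required(self) -> dict[str, str]:
        return {"lncRNA": self.evidence_lnc, "mRNA": self.evidence_mrna}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    """All intermediate tables plus the machine-readable summary."""

    summary: dict
    de_tables: dict[str, pd.DataFrame]
    thresholds: cx.ThresholdSet | None
    pairs: dict[str, pd.DataFrame]
    triples: pd.DataFrame
    graph: "object"
    ranked: pd.DataFrame
    hubs: list[str]
    reports: list[net.SubnetworkReport]
    coverage: pd.DataFrame | None
    enrichment: pd.DataFrame | None


def _empty_triples() -> pd.DataFrame:
    return pd.DataFrame(columns=tr.TRIPLE_COLUMNS)


def run_pipeline(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    interactions: pd.DataFrame,
    config: RunConfig | None = None,
    *,
    gene_sets: list[GeneSet] | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run every stage; returns tables and a JSON-serializable summary."""
    config = config or RunConfig()
    samples_mode = "tumor" if config.tumor_only_pcc else "all"

    # 1. matrix preparation
    prepared = {
        "lncRNA": prepare_matrix(lnc, config.min_expressed_fraction),
        "mRNA": prepare_matrix(mrna, config.min_expressed_fraction),
        "miRNA": prepare_matrix(mirna, config.min_expressed_fraction),
    }

    # 2. differential expression (BH within class unless pooled)
    de_tables = {cls: de.de_table(m, adjust=not config.pooled_fdr)
                 for cls, m in prepared.items()}
    if config.pooled_fdr:
        pooled = pd.concat(de_tables.values(), ignore_index=True)
        pooled["fdr"] = de.benjamini_hochberg(pooled["p_value"].to_numpy())
        de_tables = {cls: sub.reset_index(drop=True)
                     for cls, sub in pooled.groupby("gene_class")}
    gates = config.gates()
    de_tables = {cls: de.select_dysregulated(t, gates) for cls, t in de_tables.items()}
    sets = {}
    for cls, t in de_tables.items():
        sets[cls] = de.dysregulated_sets(t).get(cls, set())
    dels, dems, demis = sets["lncRNA"], sets["mRNA"], sets["miRNA"]

    # 3. all-pairs PCC over all surviving genes → threshold calibration
    pair_inputs = {
        "lnc-mrna": (prepared["lncRNA"], prepared["mRNA"]),
        "lnc-mirna": (prepared["lncRNA"], prepared["miRNA"]),
        "mrna-mirna": (prepared["mRNA"], prepared["miRNA"]),
    }
    all_pairs: dict[str, pd.DataFrame] = {}
    dists: dict[str, "object"] = {}
    for cp, (ma, mb) in pair_inputs.items():
        pairs, flat = cx.allpairs_pcc(ma, mb, cp, samples=samples_mode)
        all_pairs[cp] = pairs
        dists[cp] = flat
    thresholds = cx.calibrate_thresholds(dists, config.quantile_level,
                                         config.corr_p_cut)

    # 4. interaction restriction to DE genes with evidence routing
    merged = tr.merge_interactions([interactions]) if len(interactions) else interactions
    if len(merged):
        del_demi, dem_demi = tr.restrict_to_de(
            merged, dels, dems, demis, config.evidence_required()
        )
        lnc_mir_allowed = set(zip(del_demi["target_id"], del_demi["mirna_id"]))
        mrna_mir_allowed = set(zip(dem_demi["target_id"], dem_demi["mirna_id"]))
    else:
        del_demi = dem_demi = pd.DataFrame(columns=tr.INTERACTION_COLUMNS)
        lnc_mir_allowed = mrna_mir_allowed = set()

    # 5. significance filtering of dysregulated pairs
    def restrict(pairs: pd.DataFrame, keep_a: set, keep_b: set,
                 allowed: set | None) -> pd.DataFrame:
        m = pairs["id_a"].isin(keep_a) & pairs["id_b"].isin(keep_b)
        sub = pairs.loc[m]
        if allowed is not None:
            sub = sub.loc[[
                (a, b) in allowed for a, b in zip(sub["id_a"], sub["id_b"])
            ]]
        return sub.reset_index(drop=True)

    pos_lm = cx.significant_pairs(
        restrict(all_pairs["lnc-mrna"], dels, dems, None), thresholds, "positive")
    neg_lmi = cx.significant_pairs(
        restrict(all_pairs["lnc-mirna"], dels, demis, lnc_mir_allowed),
        thresholds, "negative")
    neg_gmi = cx.significant_pairs(
        restrict(all_pairs["mrna-mirna"], dems, demis, mrna_mir_allowed),
        thresholds, "negative")

    # 6. triple assembly and network analysis
    triple_table = tr.assemble_triples(pos_lm, neg_lmi, neg_gmi) if len(pos_lm) \
        else _empty_triples()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = net.build_network(triple_table)
        ranked = net.rank_bc(graph)
        hubs = net.select_hubs(ranked, config.hub_k, config.hub_class)
        reports = [
            net.extract_subnetwork(triple_table, h, graph=graph,
                                   scope=config.subnetwork_scope)
            for h in hubs
        ]
        coverage = net.coverage_table(reports, triple_table) if reports else None

    # 7. optional enrichment of the hub-subnetwork mRNAs
    enrich = None
    if gene_sets is not None and reports:
        universe = set(prepared["mRNA"].gene_ids)
        query = set().union(*(r.mrnas for r in reports))
        enrich = hypergeom_ora(query, gene_sets, universe, p_cut=config.ora_p_cut)

    summary = {
        "config": config.to_dict(),
        "n_tumor": len(prepared["mRNA"].samples_in(TUMOR)),
        "n_normal": prepared["mRNA"].n_samples - len(prepared["mRNA"].samples_in(TUMOR)),
        "genes_after_filter": {cls: m.n_genes for cls, m in prepared.items()},
        "n_del": len(dels),
        "n_dem": len(dems),
        "n_demi": len(demis),
        "thresholds": thresholds.to_dict(),
        "n_interactions": int(len(merged)),
        "n_del_demi_interactions": int(len(del_demi)),
        "n_dem_demi_interactions": int(len(dem_demi)),
        "pairs_kept": {
            "pos_lnc_mrna": int(len(pos_lm)),
            "neg_lnc_mirna": int(len(neg_lmi)),
            "neg_mrna_mirna": int(len(neg_gmi)),
        },
        "n_triples": int(len(triple_table)),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "nodes_by_class": {
            cls: sum(1 for _, d in graph.nodes(data=True) if d.get("cls") == cls)
            for cls in ("lncRNA", "miRNA", "mRNA")
        },
        "connected": net.is_connected(graph),
        "hubs": hubs,
        "coverage": coverage.to_dict(orient="records") if coverage is not None else [],
        "n_enriched_terms": int(len(enrich)) if enrich is not None else None,
    }

    result = RunResult(
        summary=summary, de_tables=de_tables, thresholds=thresholds,
        pairs={"pos_lnc_mrna": pos_lm, "neg_lnc_mirna": neg_lmi,
               "neg_mrna_mirna": neg_gmi},
        triples=triple_table, graph=graph, ranked=ranked, hubs=hubs,
        reports=reports, coverage=coverage, enrichment=enrich,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write every intermediate table, the exports and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls, t in result.de_tables.items():
        t.to_csv(outdir / f"de_{cls}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    for name, t in result.pairs.items():
        t.to_csv(outdir / f"pairs_{name}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    result.triples.to_csv(outdir / "triples.tsv", sep="\t", index=False,
                          float_format="%.6g")
    result.ranked.to_csv(outdir / "betweenness.tsv", sep="\t", index=False,
                         float_format="%.6g")
    if result.coverage is not None:
        result.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        (outdir / "coverage.json").write_text(
            json.dumps(result.coverage.to_dict(orient="records"), indent=1))
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    if result.graph.number_of_nodes():
        bc = dict(zip(result.ranked["node"], result.ranked["bc"]))
        net.write_sif(result.graph, outdir / "network.sif")
        net.write_graphml(result.graph, outdir / "network.graphml", bc=bc)
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True))


def table1_report(coverage: pd.DataFrame) -> str:
    """Render a coverage table as count-with-percentage text columns.

    Mirrors the conventional presentation: ``14 (87.5%)`` — counts with
    two-decimal percentages (trailing zeros trimmed) in parentheses.
    """
    def fmt(count, p) -> str:
        p = round(float(p), 2)
        text = f"{p:.2f}".rstrip("0").rstrip(".")
        return f"{int(count)} ({text}%)"

    lines = ["Associated network\tNo. of DEMis\tNo. of DEMs\tNo. of triples"]
    for row in coverage.itertuples(index=False):
        lines.append("\t".join([
            row.network,
            fmt(row.n_demis, row.demi_pct),
            fmt(row.n_dems, row.dem_pct),
            fmt(row.n_triples, row.triple_pct),
        ]))
    return "\n".join(lines) + "\n"
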