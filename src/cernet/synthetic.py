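"""Synthetic tumor/normal expression data with planted sponge triples.

The generator emulates the data regime the pipeline targets: log-scale
expression with occasional zeros, a heavily imbalanced tumor/normal
design, class-specific differential-expression direction (lncRNA and
mRNA up in tumor, miRNA down), and latent-factor-driven correlation
structure among planted triples.  For each planted triple and each tumor
sample j, a shared latent activity z_j ~ Normal(0, 1) is added to the
lncRNA and mRNA (loadings ``coupling_lnc`` / ``coupling_mrna``) and
subtracted from the miRNA (loading ``coupling_mirna``) on the log2
scale, on top of the tumor-mean shifts ``de_lfc_*``.  Normal samples
draw from baseline only, so correlations computed over tumor samples
carry all of the planted signal.  Independent Normal(0, noise_sd) noise
is added everywhere, values are exponentiated to the linear scale, and
zeros are injected at ``zero_rate`` so the half-minimum imputation path
is exercised downstream.

Ground truth (planted triples, DE labels, true vs decoy interactions)
is returned alongside the matrices so every downstream stage can be
scored for recovery.  One gene belongs to at most one planted triple.
No generative model is claimed for real data; this construction is a
stand-in whose purpose is calibrated, recoverable structure.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (
    ExpressionMatrix,
    NORMAL,
    TUMOR,
    read_matrix_tsv,
    read_sample_groups,
    write_matrix_tsv,
    write_sample_groups,
)
from .triples import (
    INTERACTION_COLUMNS,
    read_interactions_tsv,
    write_interactions_tsv,
)

FIXTURE_FILES = ("lnc.tsv", "mrna.tsv", "mirna.tsv", "samples.tsv",
                 "interactions.tsv", "truth.json")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    The defaults are the documented strong-signal condition used for
    end-to-end recovery checks: 100 tumor vs 20 normal samples, 20
    planted triples among 60 lncRNAs / 120 mRNAs / 30 miRNAs, unit
    latent-factor loadings against log2 noise of 0.5, tumor shifts of
    +2 (lncRNA, mRNA) and −1.5 (miRNA) on the log2 scale, 2% injected
    zeros, 200 decoy interaction edges and 20% background DE genes
    without correlation structure.
    """

    n_tumor: int = 100
    n_normal: int = 20
    n_lnc: int = 60
    n_mrna: int = 120
    n_mirna: int = 30
    n_triples: int = 20
    de_lfc_lnc: float = 2.0
    de_lfc_mrna: float = 2.0
    de_lfc_mirna: float = -1.5
    coupling_lnc: float = 1.0
    coupling_mrna: float = 1.0
    coupling_mirna: float = 1.0
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (3.0, 8.0)
    zero_rate: float = 0.02
    n_decoy_interactions: int = 200
    frac_de_background: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_tumor=self.n_tumor, n_normal=self.n_normal,
                      n_lnc=self.n_lnc, n_mrna=self.n_mrna,
                      n_mirna=self.n_mirna, n_triples=self.n_triples,
                      n_decoy_interactions=self.n_decoy_interactions)
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must lie in [0, 1)")
        if self.n_triples > min(self.n_lnc, self.n_mrna, self.n_mirna):
            raise ValueError(
                f"n_triples={self.n_triples} exceeds the smallest class size "
                f"{min(self.n_lnc, self.n_mrna, self.n_mirna)}"
            )
        if not 0 <= self.frac_de_background <= 1:
            raise ValueError("frac_de_background must lie in [0, 1]")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ValueError("baseline_mean_range must be an increasing interval")


def null_config(**overrides) -> SimConfig:
    """A signal-free configuration: zero couplings and zero DE shifts."""
    base = dict(de_lfc_lnc=0.0, de_lfc_mrna=0.0, de_lfc_mirna=0.0,
                coupling_lnc=0.0, coupling_mrna=0.0, coupling_mirna=0.0,
                frac_de_background=0.0)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Planted ground truth for recovery scoring."""

    planted_triples: list[tuple[str, str, str]]
    de_labels: dict[str, str]
    true_interactions: list[tuple[str, str]]
    decoy_interactions: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_triples": [list(t) for t in self.planted_triples],
            "de_labels": self.de_labels,
            "true_interactions": [list(t) for t in self.true_interactions],
            "decoy_interactions": [list(t) for t in self.decoy_interactions],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_triples=[tuple(t) for t in d["planted_triples"]],
            de_labels=dict(d["de_labels"]),
            true_interactions=[tuple(t) for t in d["true_interactions"]],
            decoy_interactions=[tuple(t) for t in d["decoy_interactions"]],
        )


@dataclass
class SimDataset:
    lnc: ExpressionMatrix
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    interactions: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_dataset(config: SimConfig) -> SimDataset:
    """Draw one synthetic dataset; identical config ⇒ bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{i:03d}" for i in range(1, config.n_tumor + 1)] + [
        f"N{i:03d}" for i in range(1, config.n_normal + 1)
    ]
    groups = pd.Series([TUMOR] * config.n_tumor + [NORMAL] * config.n_normal,
                       index=sample_ids, name="group")
    tumor_slice = slice(0, config.n_tumor)

    ids = {
        "lncRNA": _gene_ids("LNC", config.n_lnc),
        "mRNA": _gene_ids("MRNA", config.n_mrna),
        "miRNA": _gene_ids("MIR", config.n_mirna),
    }
    lfc = {"lncRNA": config.de_lfc_lnc, "mRNA": config.de_lfc_mrna,
           "miRNA": config.de_lfc_mirna}
    coupling = {"lncRNA": config.coupling_lnc, "mRNA": config.coupling_mrna,
                "miRNA": -config.coupling_mirna}  # miRNA loads negatively

    # shared latent activity per planted triple and tumor sample
    z = rng.standard_normal((config.n_triples, config.n_tumor))

    de_labels: dict[str, str] = {}
    log2mats: dict[str, np.ndarray] = {}
    for cls in ("lncRNA", "mRNA", "miRNA"):
        n_genes = len(ids[cls])
        baseline = rng.uniform(*config.baseline_mean_range, size=n_genes)
        mat = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                             size=(n_genes, n_samples))
        direction = "up" if lfc[cls] > 0 else ("down" if lfc[cls] < 0 else "null")
        # planted triple members: the first n_triples genes of each class
        for gi in range(config.n_triples):
            mat[gi, tumor_slice] += lfc[cls] + coupling[cls] * z[gi]
            de_labels[ids[cls][gi]] = direction
        # background DE genes: shifted, but uncorrelated
        n_free = n_genes - config.n_triples
        n_bg = int(round(config.frac_de_background * n_free))
        bg = rng.choice(np.arange(config.n_triples, n_genes), size=n_bg,
                        replace=False) if n_bg else np.array([], dtype=int)
        for gi in bg:
            mat[gi, tumor_slice] += lfc[cls]
            de_labels[ids[cls][gi]] = direction
        for gi in range(n_genes):
            de_labels.setdefault(ids[cls][gi], "null")
        log2mats[cls] = mat

    matrices: dict[str, ExpressionMatrix] = {}
    for cls in ("lncRNA", "mRNA", "miRNA"):
        linear = np.power(2.0, log2mats[cls])
        if config.zero_rate > 0:
            mask = rng.random(linear.shape) < config.zero_rate
            linear[mask] = 0.0
        values = pd.DataFrame(linear, index=ids[cls], columns=sample_ids)
        matrices[cls] = ExpressionMatrix(values, groups, cls, transformed=False)

    planted = [
        (ids["lncRNA"][i], ids["miRNA"][i], ids["mRNA"][i])
        for i in range(config.n_triples)
    ]
    true_pairs = []
    for lnc, mir, mrna in planted:
        true_pairs.append((mir, lnc))
        true_pairs.append((mir, mrna))
    true_set = set(true_pairs)

    # decoy interactions: uniform false (miRNA, target) pairs, disjoint
    # from the planted ones, with the evidence class their target needs
    all_targets = ids["lncRNA"] + ids["mRNA"]
    possible = [
        (m, t) for m in ids["miRNA"] for t in all_targets if (m, t) not in true_set
    ]
    n_decoy = min(config.n_decoy_interactions, len(possible))
    if n_decoy < config.n_decoy_interactions:
        raise ValueError(
            f"cannot place {config.n_decoy_interactions} decoys; only "
            f"{len(possible)} candidate pairs exist"
        )
    decoy_idx = rng.choice(len(possible), size=n_decoy, replace=False)
    decoys = [possible[i] for i in sorted(decoy_idx)]

    target_class = {g: "lncRNA" for g in ids["lncRNA"]}
    target_class.update({g: "mRNA" for g in ids["mRNA"]})
    evidence_of = {"lncRNA": "predicted", "mRNA": "validated"}
    rows = [
        (m, t, target_class[t], evidence_of[target_class[t]])
        for m, t in true_pairs + decoys
    ]
    interactions = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    interactions = interactions.sort_values(
        ["mirna_id", "target_id"], kind="stable"
    ).reset_index(drop=True)

    truth = SimTruth(
        planted_triples=planted,
        de_labels=de_labels,
        true_interactions=true_pairs,
        decoy_interactions=decoys,
    )
    return SimDataset(
        lnc=matrices["lncRNA"], mrna=matrices["mRNA"], mirna=matrices["miRNA"],
        interactions=interactions, truth=truth, config=config,
    )


def write_fixture(dataset: SimDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the file layout the CLI consumes.

    Emits lnc.tsv / mrna.tsv / mirna.tsv (genes × samples), samples.tsv
    (sample_id, group), interactions.tsv and truth.json (ground truth
    plus the generating configuration).  Round-trips losslessly through
    :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "lnc": write_matrix_tsv(dataset.lnc, directory / "lnc.tsv"),
        "mrna": write_matrix_tsv(dataset.mrna, directory / "mrna.tsv"),
        "mirna": write_matrix_tsv(dataset.mirna, directory / "mirna.tsv"),
        "samples": write_sample_groups(dataset.lnc.sample_groups,
                                       directory / "samples.tsv"),
        "interactions": write_interactions_tsv(dataset.interactions,
                                               directory / "interactions.tsv"),
    }
    truth_path = directory / "truth.json"
    payload = json.loads(Path(dataset.truth.to_json(truth_path)).read_text())
    payload["config"] = asdict(dataset.config)
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def read_fixture(directory: str | Path) -> SimDataset:
    directory = Path(directory)
    groups = read_sample_groups(directory / "samples.tsv")
    truth_payload = json.loads((directory / "truth.json").read_text())
    cfg_dict = truth_payload.get("config", {})
    if "baseline_mean_range" in cfg_dict:
        cfg_dict["baseline_mean_range"] = tuple(cfg_dict["baseline_mean_range"])
    config = SimConfig(**cfg_dict)
    truth = SimTruth(
        planted_triples=[tuple(t) for t in truth_payload["planted_triples"]],
        de_labels=dict(truth_payload["de_labels"]),
        true_interactions=[tuple(t) for t in truth_payload["true_interactions"]],
        decoy_interactions=[tuple(t) for t in truth_payload["decoy_interactions"]],
    )
    return SimDataset(
        lnc=read_matrix_tsv(directory / "lnc.tsv", groups, "lncRNA"),
        mrna=read_matrix_tsv(directory / "mrna.tsv", groups, "mRNA"),
        mirna=read_matrix_tsv(directory / "mirna.tsv", groups, "miRNA"),
        interactions=read_interactions_tsv(directory / "interactions.tsv"),
        truth=truth,
        config=config,
    )


def score_recovery(found_triples, truth: SimTruth) -> tuple[float, float]:
    """Precision and recall of recovered triples against the planted set.

    ``found_triples`` is any iterable of (lnc, mirna, mrna) tuples or a
    triple table DataFrame.  With nothing found, precision is reported
    as 0.0 (and recall is 0 unless nothing was planted).
    """
    if isinstance(found_triples, pd.DataFrame):
        found = set(zip(found_triples["lnc_id"], found_triples["mirna_id"],
                        found_triples["mrna_id"]))
    else:
        found = set(tuple(t) for t in found_triples)
    planted = set(tuple(t) for t in truth.planted_triples)
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall
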