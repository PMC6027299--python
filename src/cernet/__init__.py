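"""cernet: dysregulated lncRNA-associated ceRNA network inference.

Stages: matrix preparation, class-wise Mann–Whitney differential
expression, quantile-calibrated Pearson co-expression, sponge-triple
assembly from shared-miRNA interaction evidence, betweenness-centrality
hub discovery with subnetwork coverage statistics, and hypergeometric
over-representation analysis.  A synthetic-data generator with planted
sponge triples provides ground truth for every stage.
"""
from importlib import resources
import json

from .expression import ExpressionMatrix
from .pipeline import RunConfig, run_pipeline, table1_report
from .synthetic import SimConfig, generate_dataset, null_config, score_recovery

__version__ = "0.1.0"

__all__ = [
    "ExpressionMatrix",
    "RunConfig",
    "run_pipeline",
    "table1_report",
    "SimConfig",
    "generate_dataset",
    "null_config",
    "score_recovery",
    "load_gc_coverage_counts",
]


def load_gc_coverage_counts() -> dict:
    """Packaged worked-example coverage counts for the gastric-cancer network."""
    ref = resources.files("cernet").joinpath("data/gc_hub_coverage_counts.json")
    return json.loads(ref.read_text())
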