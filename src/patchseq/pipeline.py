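"""End-to-end Patch-seq analysis over an on-disk bundle.

Ties the stages together: sweep files -> 9-parameter ephys table ->
Dim1 maturity axis -> expression filter -> signed co-expression network ->
neuron-specific module -> maturation clusters -> biomarker candidates ->
enrichment.  Each stage is also available separately; this module only
sequences them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ephys
from .enrichment import GeneSetCollection, fisher_enrichment, read_gmt
from .expression import (ExpressionMatrix, filter_expressed, log_transform,
                         read_expression)
from .maturation import (GeneCluster, cross_reference_external,
                         gene_dim1_correlation, intersect_sets,
                         read_gene_list, threshold_clusters)
from .maturity import MaturityPCA, MaturityResult
from .network import NetworkConfig, NetworkResult, SignedCoexpressionNetwork
from .sweeps import read_sweeps_h5

__all__ = ["PipelineResult", "run_pipeline", "extract_parameter_table",
           "neuron_specific_module"]


@dataclass
class PipelineResult:
    """Everything the full analysis produces, one attribute per stage."""

    params: pd.DataFrame
    maturity: MaturityResult
    expression: ExpressionMatrix            # filtered, raw FPKM
    network: NetworkResult
    neuron_module_label: str
    correlations: pd.DataFrame
    green: GeneCluster
    magenta: GeneCluster
    candidates: list[str]                   # magenta ∩ neuron module
    biomarkers: list[str] | None            # candidates ∩ external list
    enrichment: pd.DataFrame | None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Patch-seq pipeline", "=" * 46,
                 f"cells: {len(self.params)}; "
                 f"expressed genes: {len(self.expression.genes)}",
                 f"neuron-specific module: {self.neuron_module_label} "
                 f"({self.network.module(self.neuron_module_label).size} genes)",
                 f"green cluster (immature-enriched): {self.green.size} genes",
                 f"magenta cluster (mature-enriched): {self.magenta.size} genes",
                 f"candidates (magenta ∩ module): {len(self.candidates)}"]
        if self.biomarkers is not None:
            lines.append(f"shared with external list: {len(self.biomarkers)}")
        return "\n".join(lines)


def extract_parameter_table(sweep_sets, dvdt_thresh: float = 10.0,
                            lowpass_hz: float | None = None) -> pd.DataFrame:
    feats = [(ss.cell_id, ephys.extract_features(ss, dvdt_thresh,
                                                 lowpass_hz=lowpass_hz))
             for ss in sweep_sets]
    return ephys.build_parameter_table(feats)


def neuron_specific_module(network: NetworkResult,
                           expr: ExpressionMatrix) -> str:
    """Label of the module whose genes are most neuron-enriched.

    Score = mean over module genes of (mean log2 expression in neurons -
    mean in contrast samples); the module with the largest score is the
    neuron-specific one.
    """
    logv = expr.values if expr.log_transformed else np.log2(expr.values + 1.0)
    neuron = expr.sample_class == "neuron"
    per_gene = logv.loc[:, neuron.to_numpy()].mean(axis=1) \
        - logv.loc[:, (~neuron).to_numpy()].mean(axis=1)
    best, best_score = None, -np.inf
    for mod in network.modules:
        score = float(per_gene.loc[mod.genes].mean())
        if score > best_score:
            best, best_score = mod.label, score
    if best is None:
        raise ValueError("network has no modules")
    return best


def run_pipeline(bundle_dir, network_config: NetworkConfig | None = None,
                 r_min: float = 0.4, alpha: float = 0.05,
                 fpkm_min: float = 0.1, dvdt_thresh: float = 10.0,
                 ) -> PipelineResult:
    """Run the full analysis over a bundle directory (see
    :func:`patchseq.simulate.generate_dataset` for the file layout)."""
    bundle = Path(bundle_dir)
    sweep_sets = read_sweeps_h5(bundle / "sweeps.h5")
    params = extract_parameter_table(sweep_sets, dvdt_thresh)
    maturity = MaturityPCA(params).fit()

    expr = read_expression(bundle / "expression.tsv",
                           str(bundle / "classes.csv"))
    expr = filter_expressed(expr, fpkm_min)
    log_expr = log_transform(expr)

    network = SignedCoexpressionNetwork(log_expr, network_config).fit()
    neuron_label = neuron_specific_module(network, log_expr)

    corrs = gene_dim1_correlation(log_expr, maturity.dim1)
    green, magenta = threshold_clusters(corrs, r_min, alpha)
    candidates = intersect_sets(magenta.genes,
                                network.module(neuron_label).genes)

    biomarkers = None
    external_path = bundle / "external_list.txt"
    if external_path.exists():
        external = read_gene_list(external_path)
        biomarkers, _ = cross_reference_external(candidates, external)

    enrich = None
    gmt_path = bundle / "annotations.gmt"
    if gmt_path.exists():
        coll = read_gmt(gmt_path)
        universe = list(expr.genes)
        enrich = fisher_enrichment(network.module(neuron_label).genes,
                                   universe, coll)

    return PipelineResult(params=params, maturity=maturity, expression=expr,
                          network=network, neuron_module_label=neuron_label,
                          correlations=corrs, green=green, magenta=magenta,
                          candidates=candidates, biomarkers=biomarkers,
                          enrichment=enrich)
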