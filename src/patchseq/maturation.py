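"""Maturation-correlated gene programs and biomarker set arithmetic.

Each gene's log-scale expression over the neuron samples is correlated with
the Dim1 maturity axis (Pearson r with the classical two-sided t-transform
p-value).  Genes with r > 0.4 and p < 0.05 form the immature-enriched
"green" cluster (Dim1 is anti-maturity); genes with r < -0.4 and p < 0.05
form the mature-enriched "magenta" cluster.  No multiple-testing correction
is applied — thresholding is on raw p-values by design, documented here
prominently as a reproduction choice.

Candidate biomarkers are the intersection of the magenta cluster with the
neuron-specific network module, optionally cross-referenced against an
external maturity gene list (one symbol per line, case-insensitive, with an
optional synonym map).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "gene_dim1_correlation", "threshold_clusters", "GeneCluster",
    "intersect_sets", "cross_reference_external", "read_gene_list",
]


@dataclass
class GeneCluster:
    """A maturation gene cluster: label plus per-gene correlation records."""

    label: str
    table: pd.DataFrame  # columns: gene, r, p (sorted by gene)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def size(self) -> int:
        return len(self.table)


def gene_dim1_correlation(expr: ExpressionMatrix,
                          dim1: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation with Dim1 over the neuron samples.

    p is the exact two-sided p-value of t = r * sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom.  Constant genes get r = 0, p = 1.  Raises when
    the Dim1 index does not match the neuron sample ids (listing the
    offenders), or when fewer than 4 matched samples exist.
    """
    if not expr.log_transformed:
        from .expression import log_transform
        expr = log_transform(expr)
    neuron = list(expr.neuron_samples())
    unmatched = sorted(set(neuron) ^ set(dim1.index))
    if unmatched:
        raise ValueError(
            f"neuron samples and Dim1 cell ids do not match: {unmatched}")
    if len(neuron) < 4:
        raise ValueError("need at least 4 neuron samples")
    X = expr.values[neuron].to_numpy(dtype=float)
    d = dim1.loc[neuron].to_numpy(dtype=float)
    n = d.size
    Xc = X - X.mean(axis=1, keepdims=True)
    dc = d - d.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sd = np.sqrt((dc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ dc) / (sx * sd)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    constant = sx == 0
    r[constant] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, 0.0, 1.0)
    p[constant] = 1.0
    p[np.abs(r) >= 1.0] = 0.0
    return pd.DataFrame({"gene": expr.genes, "r": r, "p": p}).reset_index(
        drop=True)


def threshold_clusters(correlations: pd.DataFrame, r_min: float = 0.4,
                       alpha: float = 0.05) -> tuple[GeneCluster, GeneCluster]:
    """Split correlation records into the green (r > r_min, immature-
    enriched) and magenta (r < -r_min, mature-enriched) clusters.

    Both thresholds are strict; p < alpha is required in both clusters.
    """
    sig = correlations["p"] < alpha
    green = correlations[(correlations["r"] > r_min) & sig]
    magenta = correlations[(correlations["r"] < -r_min) & sig]
    green = green.sort_values("gene", kind="mergesort").reset_index(drop=True)
    magenta = magenta.sort_values("gene", kind="mergesort").reset_index(
        drop=True)
    return GeneCluster("green", green), GeneCluster("magenta", magenta)


def intersect_sets(a, b) -> list[str]:
    """Exact set intersection with deterministic sorted output."""
    return sorted(set(a) & set(b))


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [l.strip() for l in lines if l.strip()]


def cross_reference_external(candidates, external,
                             id_map: dict[str, str] | None = None,
                             ) -> tuple[list[str], list[str]]:
    """Intersect candidate genes with an external gene list.

    Symbols are compared upper-cased; ``id_map`` optionally maps synonyms to
    canonical symbols (applied to both sides) to absorb cross-study symbol
    drift.  Returns (matches in the candidates' own spelling, sorted;
    unmatched candidates, sorted).
    """
    id_map = {k.upper(): v.upper() for k, v in (id_map or {}).items()}

    def canon(sym: str) -> str:
        s = sym.upper()
        return id_map.get(s, s)

    ext = {canon(s) for s in external}
    matches, unmatched = [], []
    for c in candidates:
        (matches if canon(c) in ext else unmatched).append(c)
    return sorted(matches), sorted(unmatched)
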