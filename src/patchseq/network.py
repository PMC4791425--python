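"""Signed weighted co-expression network construction and module detection.

The classic weighted co-expression recipe: gene-gene Pearson correlations on
log2(FPKM+1) values, the signed soft-threshold transform
``a_ij = ((1 + r_ij)/2)^beta`` with beta chosen by the scale-free topology
criterion, the topological overlap measure (TOM) as edge similarity,
average-linkage clustering of 1 - TOM with a dynamic dendrogram cut into
color-labeled modules, within-module connectivity ("hub-ness") ranking, and
a VisANT-style top-k edge export.

Dense matrices throughout: the target scale (<= 25k genes) fits comfortably
in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, log_transform

__all__ = [
    "NetworkConfig", "GeneModule", "signed_adjacency", "estimate_soft_power",
    "scale_free_fit", "topological_overlap", "cluster_modules",
    "node_centrality", "export_top_edges", "SignedCoexpressionNetwork",
    "NetworkResult", "MODULE_COLORS",
]

#: size-ordered module color names (largest module first); grey = unassigned
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class NetworkConfig:
    """Tuning knobs for network construction and module detection.

    power_grid : candidate soft powers beta (default 1..20)
    rsq_cut : scale-free topology fit threshold (default 0.8)
    min_module_size : smallest reported module (genes, default 30)
    cut_height : explicit dendrogram cut height; None -> height-range rule
    deep_split : 0-4 split sensitivity (higher cuts lower in the tree)
    pam_stage : optionally reassign leftover genes to the closest module
    kme_prune : drop module members whose eigengene membership (kME) is not
        Bonferroni-significant across genes at ``kme_alpha`` — keeps genes
        that merely track a module by sampling chance out of it
    n_bins : connectivity histogram bins for the scale-free fit
    """

    power_grid: tuple[int, ...] = tuple(range(1, 21))
    rsq_cut: float = 0.8
    min_module_size: int = 30
    cut_height: float | None = None
    deep_split: int = 2
    pam_stage: bool = False
    kme_prune: bool = True
    kme_alpha: float = 0.05
    n_bins: int = 10

    def __post_init__(self) -> None:
        if min(self.power_grid) < 1:
            raise ValueError("soft powers must be >= 1")
        if not 0 < self.rsq_cut < 1:
            raise ValueError("rsq_cut must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class GeneModule:
    """A detected co-expression module: color label, member genes, and
    within-module connectivity (hub-ness) statistics."""

    label: str
    genes: list[str]
    centrality: pd.Series | None = None
    hub_rank: list[str] | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def signed_adjacency(corr: np.ndarray | pd.DataFrame,
                     beta: float) -> np.ndarray | pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta, diagonal
    zeroed for connectivity purposes."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if c.min() < -1 - 1e-9 or c.max() > 1 + 1e-9:
        raise ValueError("correlation entries must lie in [-1, 1]")
    a = ((1.0 + np.clip(c, -1, 1)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    if isinstance(corr, pd.DataFrame):
        return pd.DataFrame(a, index=corr.index, columns=corr.columns)
    return a


def scale_free_fit(connectivity: np.ndarray,
                   n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the scale-free topology fit.

    Connectivity values are binned (equal width); log10 p(k) is regressed on
    log10 of the per-bin mean connectivity.  Returns (signed_r2, slope):
    signed_r2 = R^2 when the slope is negative, else -R^2, so only a
    decreasing degree distribution can pass the criterion.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2), float(slope)


def _corr_from_expression(expr) -> pd.DataFrame:
    """Gene-gene Pearson correlations on log2(FPKM+1) values."""
    if isinstance(expr, ExpressionMatrix):
        if not expr.log_transformed:
            expr = log_transform(expr)
        df = expr.values
    else:
        df = expr
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=1)
    c = np.corrcoef(X)
    # constant genes produce NaN correlations; treat as uncorrelated
    if (sd == 0).any():
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=df.index, columns=df.index)


def estimate_soft_power(expr, cfg: NetworkConfig | None = None,
                        ) -> tuple[int, pd.DataFrame]:
    """Choose the soft power beta by the scale-free topology criterion.

    Returns (beta, fit table indexed by beta with signed_r2, slope and
    mean connectivity).  beta is the smallest grid value whose signed fit
    R^2 reaches ``cfg.rsq_cut``; if none does, the argmax-R^2 beta is
    returned with a warning.
    """
    cfg = cfg or NetworkConfig()
    corr = _corr_from_expression(expr)
    if corr.shape[0] < 3:
        raise ValueError("need at least 3 genes to estimate soft power")
    n_samples = (expr.values.shape[1] if isinstance(expr, ExpressionMatrix)
                 else expr.shape[1])
    if n_samples < 3:
        raise ValueError("need at least 3 samples to estimate soft power")
    rows = []
    for beta in cfg.power_grid:
        a = signed_adjacency(corr.to_numpy(), beta)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k, cfg.n_bins)
        rows.append((beta, r2, slope, float(k.mean())))
    fits = pd.DataFrame(rows, columns=["beta", "signed_r2", "slope",
                                       "mean_k"]).set_index("beta")
    passing = fits.index[fits["signed_r2"] >= cfg.rsq_cut]
    if len(passing):
        return int(passing[0]), fits
    best = int(fits["signed_r2"].idxmax())
    warnings.warn(
        f"no soft power reaches scale-free fit R^2 >= {cfg.rsq_cut}; "
        f"using argmax-R^2 beta = {best}")
    return best, fits


def topological_overlap(adjacency: np.ndarray | pd.DataFrame,
                        ) -> np.ndarray | pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, TOM_ii = 1.  Requires a symmetric adjacency in [0, 1] with a
    zero diagonal; 1 - TOM is the clustering distance.
    """
    a = adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) \
        else np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index,
                            columns=adjacency.columns)
    return tom


def _cut_height(heights: np.ndarray, cfg: NetworkConfig) -> float:
    """Dynamic-cut height: a deep_split-dependent fraction of the merge
    height range, kept strictly below the top merge so the tree is always
    cut.  Cohesive modules merge low in a TOM dendrogram while unassigned
    genes chain in just below the maximum, so a high-but-not-top cut
    separates them; larger deep_split cuts lower, splitting more finely."""
    lo, top = float(heights.min()), float(heights.max())
    frac = 0.99 - 0.02 * cfg.deep_split
    h = lo + frac * (top - lo)
    if h >= top:
        h = top - 1e-9
    return h


def cluster_modules(tom: pd.DataFrame, cfg: NetworkConfig | None = None,
                    ) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a dynamic dendrogram cut.

    Clusters smaller than ``min_module_size`` are left unassigned (grey).
    With ``pam_stage``, each grey gene joins the module of highest mean TOM
    similarity when that similarity is at least the weakest member's.
    Returns a gene -> color label Series (size-ordered WGCNA palette).
    """
    cfg = cfg or NetworkConfig()
    genes = list(tom.index)
    n = len(genes)
    if cfg.min_module_size > n:
        raise ValueError("min_module_size exceeds the gene count")
    t = tom.to_numpy(dtype=float)
    d = 1.0 - (t + t.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = average(squareform(d, checks=False))
    h0 = cfg.cut_height if cfg.cut_height is not None \
        else _cut_height(Z[:, 2], cfg)
    flat = fcluster(Z, t=h0, criterion="distance")
    labels = np.zeros(n, dtype=int)  # 0 = grey
    sizes = pd.Series(flat).value_counts()
    next_id = 1
    for cl, size in sizes.sort_values(ascending=False).items():
        if size >= cfg.min_module_size:
            labels[flat == cl] = next_id
            next_id += 1
    if cfg.pam_stage and next_id > 1:
        sim = (t + t.T) / 2.0
        for mod in range(1, next_id):
            members = labels == mod
            intra = sim[np.ix_(members, members)]
            member_mean = (intra.sum(axis=1) - 1.0) / max(members.sum() - 1, 1)
            floor = member_mean.min()
            grey = np.flatnonzero(labels == 0)
            if grey.size == 0:
                break
            mean_to_mod = sim[np.ix_(grey, members)].mean(axis=1)
            labels[grey[mean_to_mod >= floor]] = mod
    # size-ordered color names
    counts = pd.Series(labels[labels > 0]).value_counts()
    order = list(counts.sort_values(ascending=False).index)
    color_of = {mod: (MODULE_COLORS[i] if i < len(MODULE_COLORS)
                      else f"module{i + 1}")
                for i, mod in enumerate(order)}
    named = ["grey" if l == 0 else color_of[l] for l in labels]
    return pd.Series(named, index=genes, name="module")


def module_eigengene(values: pd.DataFrame, genes) -> np.ndarray:
    """First principal component of the standardized module expression
    (one value per sample), oriented to correlate positively with the mean
    module profile."""
    X = values.loc[list(genes)].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, Z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return eig


def _prune_membership(values: pd.DataFrame, labels: pd.Series,
                      cfg: NetworkConfig) -> pd.Series:
    """Eigengene-membership (kME) pruning.

    A gene stays in its module only if its correlation with the module
    eigengene is significant after Bonferroni correction across all genes:
    at these sample sizes, genes tracking a large module by sampling chance
    alone reach |kME| ~ 0.3-0.45, and an uncorrected cut would keep them.
    Modules that fall below min_module_size dissolve into grey.
    """
    from scipy import stats

    n_samples = values.shape[1]
    n_genes = len(labels)
    out = labels.copy()
    for lab in [l for l in labels.unique() if l != "grey"]:
        genes = list(labels.index[labels == lab])
        eig = module_eigengene(values, genes)
        X = values.loc[genes].to_numpy(dtype=float)
        Xc = X - X.mean(axis=1, keepdims=True)
        ec = eig - eig.mean()
        denom = np.sqrt((Xc ** 2).sum(axis=1)) * np.sqrt((ec ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = np.where(denom > 0, (Xc @ ec) / denom, 0.0)
        kme = np.clip(kme, -1.0, 1.0)
        t = np.abs(kme) * np.sqrt((n_samples - 2)
                                  / np.clip(1.0 - kme ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(t, df=n_samples - 2)
        drop = p * n_genes >= cfg.kme_alpha
        if drop.any():
            out.loc[np.asarray(genes, dtype=object)[drop]] = "grey"
        if (out == lab).sum() < cfg.min_module_size:
            out.loc[out == lab] = "grey"
    return out


def node_centrality(adjacency: pd.DataFrame,
                    module: GeneModule | list[str]) -> pd.Series:
    """Within-module connectivity: centrality_i = sum_{j in module} a_ij.

    Hub rank is descending centrality with lexicographic tie-break.
    """
    genes = module.genes if isinstance(module, GeneModule) else list(module)
    if len(genes) == 0:
        raise ValueError("empty module")
    missing = [g for g in genes if g not in adjacency.index]
    if missing:
        raise ValueError(f"module gene(s) not in adjacency: {missing}")
    sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
    cent = sub.sum(axis=1)  # diagonal is zero by construction
    return pd.Series(cent, index=genes, name="centrality")


def hub_ranking(centrality: pd.Series) -> list[str]:
    order = sorted(centrality.index, key=lambda g: (-centrality[g], g))
    return order


def export_top_edges(adjacency: pd.DataFrame,
                     module: GeneModule | list[str], k: int = 100,
                     path=None) -> pd.DataFrame:
    """The k strongest within-module edges as (node1, node2, weight).

    Ties break by lexicographic node pair.  If fewer than k edges exist all
    are returned with a warning.  With ``path``, writes the VisANT dialect:
    tab-delimited, three columns, no header.
    """
    genes = sorted(module.genes if isinstance(module, GeneModule)
                   else list(module))
    if len(genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    edges = pd.DataFrame({
        "node1": np.asarray(genes, dtype=object)[iu],
        "node2": np.asarray(genes, dtype=object)[ju],
        "weight": sub[iu, ju],
    })
    if k > len(edges):
        warnings.warn(f"requested {k} edges but only {len(edges)} exist")
        k = len(edges)
    edges = edges.sort_values(["weight", "node1", "node2"],
                              ascending=[False, True, True],
                              kind="mergesort").head(k).reset_index(drop=True)
    if path is not None:
        edges.to_csv(path, sep="\t", header=False, index=False)
    return edges


@dataclass
class NetworkResult:
    """Fitted co-expression network: soft power, adjacency, TOM, modules."""

    beta: int
    power_fits: pd.DataFrame
    adjacency: pd.DataFrame = field(repr=False)
    tom: pd.DataFrame = field(repr=False)
    module_labels: pd.Series
    modules: list[GeneModule]
    config: NetworkConfig

    def module(self, label: str) -> GeneModule:
        for m in self.modules:
            if m.label == label:
                return m
        raise KeyError(f"no module labeled {label!r}")

    def module_table(self) -> pd.DataFrame:
        """Gene, module, centrality, hub_rank — the standard export."""
        rows = []
        for m in self.modules:
            ranks = {g: i + 1 for i, g in enumerate(m.hub_rank)}
            for g in m.genes:
                rows.append((g, m.label, float(m.centrality[g]), ranks[g]))
        grey = self.module_labels.index[self.module_labels == "grey"]
        for g in grey:
            rows.append((g, "grey", 0.0, 0))
        df = pd.DataFrame(rows, columns=["gene", "module", "centrality",
                                         "hub_rank"])
        return df.sort_values(["module", "hub_rank", "gene"]).reset_index(
            drop=True)

    def summary(self) -> str:
        lines = ["Signed co-expression network", "=" * 46,
                 f"genes: {len(self.module_labels)}",
                 f"soft power beta: {self.beta} "
                 f"(scale-free R^2 = "
                 f"{self.power_fits.loc[self.beta, 'signed_r2']:.3f})",
                 f"modules: {len(self.modules)} "
                 f"(grey: {(self.module_labels == 'grey').sum()} genes)"]
        for m in sorted(self.modules, key=lambda m: -m.size):
            hubs = ", ".join(m.hub_rank[:5])
            lines.append(f"  {m.label:<12} {m.size:>6} genes; top hubs: {hubs}")
        return "\n".join(lines)


class SignedCoexpressionNetwork:
    """Signed weighted co-expression network model over an expression matrix.

    ``fit()`` estimates the soft power (unless fixed), builds the signed
    adjacency and TOM, detects modules by dynamic dendrogram cut, and ranks
    genes by within-module connectivity; it returns a
    :class:`NetworkResult`.
    """

    def __init__(self, expr: ExpressionMatrix | pd.DataFrame,
                 config: NetworkConfig | None = None,
                 beta: int | None = None) -> None:
        self.expr = expr
        self.config = config or NetworkConfig()
        self.beta = beta

    def _log_values(self) -> pd.DataFrame:
        if isinstance(self.expr, ExpressionMatrix):
            m = self.expr if self.expr.log_transformed \
                else log_transform(self.expr)
            return m.values
        return self.expr

    def fit(self) -> NetworkResult:
        corr = _corr_from_expression(self.expr)
        if self.beta is not None:
            beta = self.beta
            a = signed_adjacency(corr, beta)
            k = a.to_numpy().sum(axis=1)
            r2, slope = scale_free_fit(k, self.config.n_bins)
            fits = pd.DataFrame({"signed_r2": [r2], "slope": [slope],
                                 "mean_k": [k.mean()]},
                                index=pd.Index([beta], name="beta"))
        else:
            beta, fits = estimate_soft_power(self.expr, self.config)
            a = signed_adjacency(corr, beta)
        tom = topological_overlap(a)
        labels = cluster_modules(tom, self.config)
        if self.config.kme_prune:
            labels = _prune_membership(self._log_values(), labels,
                                       self.config)
        modules = []
        for lab in labels.unique():
            if lab == "grey":
                continue
            genes = list(labels.index[labels == lab])
            cent = node_centrality(a, genes)
            modules.append(GeneModule(label=lab, genes=genes, centrality=cent,
                                      hub_rank=hub_ranking(cent)))
        modules.sort(key=lambda m: -m.size)
        return NetworkResult(beta=int(beta), power_fits=fits, adjacency=a,
                             tom=tom, module_labels=labels, modules=modules,
                             config=self.config)
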