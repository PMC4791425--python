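"""PCA-based electrophysiological maturity index (Dim1).

The cells x 9 parameter table is reduced by PCA on the correlation matrix
(variables standardized — units are heterogeneous: Hz, mV, MΩ, pA).  The
first component, oriented so that it anti-correlates with firing rate, is the
maturity axis: larger Dim1 = less mature.  A deterministic 1-D k-means on
Dim1 bins cells into immature / maturing / matured groups.

ND entries are imputed before PCA with a direction-aware rule: a parameter
that falls with maturation gets its observed column maximum, a parameter that
rises with maturation its observed column minimum — i.e. ND is read as "too
immature to measure".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DIRECTIONS", "impute_nd", "run_pca", "orient_dim1",
    "assign_groups", "MaturityPCA", "MaturityResult", "GROUP_LABELS",
]

#: parameter -> direction of change with maturation.  Firing rate, AP
#: amplitude, sodium current and PSC frequencies increase as neurons mature;
#: halfwidth, input resistance, rise time and threshold decrease.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "firing_rate": "maturation_positive",
    "amplitude": "maturation_positive",
    "na_current": "maturation_positive",
    "freq_epsc": "maturation_positive",
    "freq_ipsc": "maturation_positive",
    "halfwidth": "maturation_negative",
    "rin": "maturation_negative",
    "rise_time": "maturation_negative",
    "threshold": "maturation_negative",
}

GROUP_LABELS = ("matured", "maturing", "immature")


def impute_nd(table: pd.DataFrame,
              directions: dict[str, str] | None = None) -> pd.DataFrame:
    """Replace ND (NaN) entries by the column max (maturation-negative
    parameter) or column min (maturation-positive parameter).

    Raises if a column containing ND has no direction entry.
    """
    directions = DEFAULT_DIRECTIONS if directions is None else directions
    out = table.copy()
    nd_cols = [c for c in table.columns if table[c].isna().any()]
    missing = [c for c in nd_cols if c not in directions]
    if missing:
        raise ValueError(f"no maturation direction for ND column(s): {missing}")
    for c in nd_cols:
        observed = table[c].dropna()
        if observed.empty:
            raise ValueError(f"column {c!r} is entirely ND; cannot impute")
        fill = observed.max() if directions[c] == "maturation_negative" \
            else observed.min()
        out[c] = table[c].fillna(fill)
    return out


@dataclass
class MaturityResult:
    """PCA maturity decomposition of an ephys parameter table.

    Attributes
    ----------
    scores : DataFrame (cells x components)
        Component scores; ``dim1`` is the maturity axis after orientation.
    loadings : DataFrame (parameters x components)
        Eigenvectors of the correlation matrix.
    var_corr : DataFrame (parameters x components)
        Pearson correlation of each raw parameter with each score vector
        (the variable factor map).
    explained_variance : Series
        Fraction of total variance per component (non-increasing, sums <= 1).
    groups : Series or None
        Per-cell maturity label in {matured, maturing, immature}.
    oriented : bool
        Whether the firing-rate sign convention has been applied.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_corr: pd.DataFrame
    explained_variance: pd.Series
    groups: pd.Series | None = None
    oriented: bool = False
    table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def dim1(self) -> pd.Series:
        return self.scores["dim1"]

    @property
    def dim2(self) -> pd.Series:
        return self.scores["dim2"]

    def summary(self) -> str:
        lines = ["Maturity PCA", "=" * 46]
        ev = self.explained_variance
        lines.append("component  explained variance")
        for name, frac in ev.items():
            lines.append(f"{name:>9}  {frac:18.3f}")
        lines.append("")
        lines.append("parameter correlations with components (factor map):")
        lines.append(self.var_corr.round(3).to_string())
        if self.groups is not None:
            lines.append("")
            counts = self.groups.value_counts()
            lines.append("maturity groups: " + ", ".join(
                f"{lab}={counts.get(lab, 0)}" for lab in GROUP_LABELS))
        if "firing_rate" in self.var_corr.index:
            r = self.var_corr.loc["firing_rate", "dim1"]
            lines.append("")
            lines.append(f"corr(Dim1, firing rate) = {r:.3f}"
                         + ("  (oriented: higher Dim1 = less mature)"
                            if self.oriented else ""))
        return "\n".join(lines)


def run_pca(table: pd.DataFrame, n_components: int = 2) -> MaturityResult:
    """Unoriented PCA of a complete (no-ND) parameter table.

    Columns are standardized (zero mean, unit variance, ddof=1) and the
    correlation matrix eigendecomposed.  Raises on remaining ND, fewer than
    3 cells, or a zero-variance column.
    """
    if table.isna().any().any():
        bad = sorted(table.columns[table.isna().any()])
        raise ValueError(f"ND values remain in column(s) {bad}; impute first")
    if len(table) < 3:
        raise ValueError("PCA requires at least 3 cells")
    X = table.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        names = sorted(table.columns[zero])
        raise ValueError(
            f"zero-variance column(s) {names}: standardization undefined")
    Z = (X - mean) / sd
    corr = (Z.T @ Z) / (len(table) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_components = min(n_components, X.shape[1])
    names = [f"dim{i + 1}" for i in range(n_components)]
    V = eigvec[:, :n_components]
    scores = pd.DataFrame(Z @ V, index=table.index, columns=names)
    loadings = pd.DataFrame(V, index=table.columns, columns=names)
    ev = pd.Series(np.clip(eigval[:n_components], 0, None) / eigval.sum(),
                   index=names, name="explained_variance")
    var_corr = _variable_correlations(table, scores)
    return MaturityResult(scores=scores, loadings=loadings, var_corr=var_corr,
                          explained_variance=ev, table=table)


def _variable_correlations(table: pd.DataFrame,
                           scores: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=table.columns, columns=scores.columns,
                       dtype=float)
    for p in table.columns:
        x = table[p].to_numpy(dtype=float)
        for c in scores.columns:
            y = scores[c].to_numpy()
            sx, sy = x.std(), y.std()
            out.loc[p, c] = 0.0 if sx == 0 or sy == 0 else float(
                np.corrcoef(x, y)[0, 1])
    return out


def orient_dim1(res: MaturityResult,
                anchor: str = "firing_rate") -> MaturityResult:
    """Fix the arbitrary PC sign so Dim1 anti-correlates with the anchor
    (firing rate): larger Dim1 = less mature.  Idempotent."""
    if anchor not in res.var_corr.index:
        raise ValueError(f"anchor column {anchor!r} not in the table")
    if res.var_corr.loc[anchor, "dim1"] > 0:
        scores = res.scores.copy()
        scores["dim1"] = -scores["dim1"]
        loadings = res.loadings.copy()
        loadings["dim1"] = -loadings["dim1"]
        var_corr = res.var_corr.copy()
        var_corr["dim1"] = -var_corr["dim1"]
        return MaturityResult(scores=scores, loadings=loadings,
                              var_corr=var_corr,
                              explained_variance=res.explained_variance,
                              groups=res.groups, oriented=True,
                              table=res.table)
    return MaturityResult(scores=res.scores, loadings=res.loadings,
                          var_corr=res.var_corr,
                          explained_variance=res.explained_variance,
                          groups=res.groups, oriented=True, table=res.table)


def assign_groups(dim1: pd.Series, k: int = 3,
                  max_iter: int = 200) -> pd.Series:
    """Deterministic 1-D k-means on Dim1 scores.

    Centers start at the k quantile midpoints (percentiles (2i+1)/2k) and
    Lloyd iterations run to convergence.  Clusters ordered by mean Dim1 map
    to matured < maturing < immature (Dim1 anti-correlates with maturity).
    Degenerate scores (a cluster would be empty) fall back to a tertile
    split with a warning.
    """
    x = dim1.to_numpy(dtype=float)
    if x.size < k:
        raise ValueError(f"need at least k={k} cells")
    qs = [(2 * i + 1) / (2 * k) for i in range(k)]
    centers = np.quantile(x, qs)
    assign = None
    degenerate = False
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new = d.argmin(axis=1)
        if any((new == j).sum() == 0 for j in range(k)):
            degenerate = True
            break
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        centers = np.array([x[assign == j].mean() for j in range(k)])
    if degenerate or assign is None:
        warnings.warn("degenerate Dim1 scores; falling back to tertile split")
        ranks = pd.Series(x, index=dim1.index).rank(method="first") - 1
        assign = np.minimum((ranks.to_numpy() * k / x.size).astype(int), k - 1)
        order = np.arange(k)
    else:
        order = np.argsort([x[assign == j].mean() for j in range(k)])
    labels = (list(GROUP_LABELS) if k == 3
              else [f"group{i + 1}" for i in range(k)])
    remap = {int(old): labels[rank] for rank, old in enumerate(order)}
    return pd.Series([remap[int(a)] for a in assign], index=dim1.index,
                     name="group")


class MaturityPCA:
    """Maturity model over an ephys parameter table.

    ``fit()`` imputes ND entries, runs standardized PCA, orients Dim1 by
    the firing-rate anchor, and bins cells into ``n_groups`` maturity
    levels; it returns a :class:`MaturityResult`.

    Parameters
    ----------
    table : DataFrame (cells x parameters)
        The 9-parameter ephys table; NaN marks ND.
    directions : dict, optional
        Parameter -> maturation direction used for ND imputation.
    anchor : str
        Column anchoring the Dim1 sign convention.
    n_groups : int
        Number of maturity bins (3 per the immature/maturing/matured
        convention).
    """

    def __init__(self, table: pd.DataFrame,
                 directions: dict[str, str] | None = None,
                 anchor: str = "firing_rate", n_groups: int = 3,
                 n_components: int = 2) -> None:
        self.table = table
        self.directions = DEFAULT_DIRECTIONS if directions is None else directions
        self.anchor = anchor
        self.n_groups = n_groups
        self.n_components = n_components

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MaturityPCA":
        from .ephys import read_parameter_table
        return cls(read_parameter_table(path), **kwargs)

    def fit(self) -> MaturityResult:
        imputed = impute_nd(self.table, self.directions)
        res = run_pca(imputed, n_components=self.n_components)
        res = orient_dim1(res, anchor=self.anchor)
        res.groups = assign_groups(res.dim1, k=self.n_groups)
        return res


def plot_variable_factor_map(res: MaturityResult, ax=None):
    """Variable factor map: each parameter as an arrow whose tip is its
    correlation with (Dim1, Dim2), inside the unit circle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="0.7", lw=1)
    for p in res.var_corr.index:
        x, y = res.var_corr.loc[p, ["dim1", "dim2"]]
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.text(x * 1.07, y * 1.07, p, ha="center", va="center", fontsize=8)
    ax.axhline(0, color="0.85", lw=0.8)
    ax.axvline(0, color="0.85", lw=0.8)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_xlabel("Dim1 correlation")
    ax.set_ylabel("Dim2 correlation")
    ax.set_aspect("equal")
    return ax
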