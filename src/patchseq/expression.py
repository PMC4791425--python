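"""Expression-matrix IO, transforms and QC.

The pipeline consumes a genes x samples FPKM matrix with a per-sample class
label (``neuron`` or ``contrast``).  Three operations matter downstream:
the detected-expression filter (FPKM >= 0.1 in at least one sample), the
log2(FPKM + 1) transform, and the technical-replicate Pearson QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix", "read_expression", "write_expression",
    "read_class_map", "log_transform", "replicate_correlation",
    "filter_expressed",
]

VALID_CLASSES = {"neuron", "contrast"}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample class labels.

    values : DataFrame (genes x samples), non-negative
    sample_class : Series indexed by sample, values in {neuron, contrast}
    log_transformed : whether values are log2(FPKM + 1)
    """

    values: pd.DataFrame
    sample_class: pd.Series
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (v.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in v.columns if s not in self.sample_class.index]
        if missing:
            raise ValueError(f"sample_class missing sample(s): {missing}")
        self.sample_class = self.sample_class.reindex(v.columns)
        bad = sorted(set(self.sample_class.unique()) - VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown sample class(es): {bad}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def neuron_samples(self) -> pd.Index:
        return self.samples[self.sample_class == "neuron"]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)],
                                self.sample_class.loc[list(samples)],
                                self.log_transformed)


def read_class_map(path) -> dict[str, str]:
    """Two-column CSV (sample, class) -> dict."""
    df = pd.read_csv(path, header=None, names=["sample", "class"],
                     skipinitialspace=True)
    if df.iloc[0, 0] in ("sample", "sample_id"):  # tolerate a header row
        df = df.iloc[1:]
    return dict(zip(df["sample"].astype(str), df["class"].astype(str)))


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        warnings.warn(f"collapsing duplicate gene row(s) by max: {dupes}")
        df = df.groupby(level=0, sort=False).max()
    return df


def read_expression(path, class_map: dict[str, str] | str | Path,
                    ) -> ExpressionMatrix:
    """Read a TSV (genes x samples, header row, gene ids in column 1) or a
    MatrixMarket triple (``x.mtx`` + ``x.mtx.rows`` + ``x.mtx.cols``).

    Duplicate gene rows are collapsed by elementwise max (with a warning).
    Raises on non-numeric cells and on samples absent from ``class_map``.
    """
    path = Path(path)
    if not isinstance(class_map, dict):
        class_map = read_class_map(class_map)
    if path.suffix == ".mtx":
        mat = np.asarray(coo_matrix(mmread(path)).todense(), dtype=float)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raw = pd.read_csv(path, sep="\t", index_col=0)
        try:
            df = raw.astype(float)
        except ValueError:
            num = raw.apply(pd.to_numeric, errors="coerce")
            bad = np.argwhere(num.isna().to_numpy() & raw.notna().to_numpy())
            r, c = bad[0]
            raise ValueError(
                f"non-numeric cell at gene {raw.index[r]!r}, "
                f"sample {raw.columns[c]!r}") from None
    df = _collapse_duplicates(df)
    unknown = [s for s in df.columns if s not in class_map]
    if unknown:
        raise ValueError(f"sample(s) missing from class map: {unknown}")
    classes = pd.Series({s: class_map[s] for s in df.columns})
    return ExpressionMatrix(df, classes, log_transformed=False)


def write_expression(path, m: ExpressionMatrix, fmt: str = "tsv") -> None:
    """Write TSV or MatrixMarket (+ ``.rows``/``.cols`` sidecars)."""
    path = Path(path)
    if fmt == "tsv":
        m.values.to_csv(path, sep="\t")
    elif fmt == "mtx":
        mmwrite(str(path), coo_matrix(m.values.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(m.genes) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(m.samples) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1); raises on double application."""
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.sample_class,
                            log_transformed=True)


def replicate_correlation(m: ExpressionMatrix, sample_a: str,
                          sample_b: str) -> float:
    """Pearson correlation of two (log-scale) transcriptome columns.

    Technical replicates of the same library should approach r = 0.99.
    """
    if not m.log_transformed:
        raise ValueError("replicate QC is defined on the log-transformed matrix")
    for s in (sample_a, sample_b):
        if s not in m.samples:
            raise ValueError(f"sample {s!r} not present")
    a = m.values[sample_a].to_numpy()
    b = m.values[sample_b].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a replicate column")
    return float(np.corrcoef(a, b)[0, 1])


def filter_expressed(m: ExpressionMatrix,
                     fpkm_min: float = 0.1) -> ExpressionMatrix:
    """Keep genes expressed at >= ``fpkm_min`` FPKM in at least one sample.

    Operates on the raw FPKM scale (raises if log-transformed); idempotent.
    """
    if m.log_transformed:
        raise ValueError("expression filter applies to raw FPKM values")
    keep = (m.values >= fpkm_min).any(axis=1)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    return ExpressionMatrix(m.values.loc[keep], m.sample_class,
                            log_transformed=False)
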