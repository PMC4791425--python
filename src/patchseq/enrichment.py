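"""Fisher's-exact-test gene-set over-representation analysis.

Gene sets come in as a GMT collection; every term is scored against a query
set with a one-sided Fisher exact test on the 2x2 table
(overlap, query-only, set-only, neither) within a stated gene universe.
Raw p-values are reported (bars in the figures are -log10 p); an optional
Benjamini-Hochberg column is available for practical use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "fisher_enrichment"]


@dataclass
class GeneSetCollection:
    """term -> member gene set, plus term descriptions."""

    sets: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = sorted(t for t, s in self.sets.items() if not s)
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: term <tab> description <tab> genes...; duplicate genes
    within a set are deduplicated.  Raises (with the line number) on lines
    with fewer than 3 fields."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated "
                             f"fields, got {len(fields)}")
        term, desc, genes = fields[0], fields[1], fields[2:]
        sets[term] = {g for g in genes if g}
        names[term] = desc
    return GeneSetCollection(sets, names)


def write_gmt(path, coll: GeneSetCollection) -> None:
    lines = []
    for term in coll.sets:
        desc = coll.term_names.get(term, term)
        genes = sorted(coll.sets[term])
        lines.append("\t".join([term, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_enrichment(query, universe, coll: GeneSetCollection,
                      bh: bool = False) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per term.

    Gene sets are intersected with the universe before testing; the query
    must be a subset of the universe (offenders are listed otherwise).
    Results are sorted by p-value, then term id.  With ``bh=True`` a
    Benjamini-Hochberg ``q`` column is appended.
    """
    query = set(query)
    universe = set(universe)
    outside = sorted(query - universe)
    if outside:
        raise ValueError(f"query gene(s) outside the universe: {outside}")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(coll.sets):
        members = coll.sets[term] & universe
        n_set = len(members)
        overlap = len(query & members)
        table = [[overlap, n_query - overlap],
                 [n_set - overlap, n_univ - n_query - n_set + overlap]]
        _, p = stats.fisher_exact(table, alternative="greater")
        p = min(max(float(p), 5e-324), 1.0)
        rows.append((term, coll.term_names.get(term, term), overlap, n_query,
                     n_set, n_univ, p, -np.log10(p)))
    df = pd.DataFrame(rows, columns=["term", "description", "overlap",
                                     "query_size", "set_size",
                                     "universe_size", "p", "neg_log10_p"])
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    if bh:
        df["q"] = stats.false_discovery_control(df["p"], method="bh")
    return df
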