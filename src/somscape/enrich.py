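"""Over-representation analysis of gene lists against GMT gene-set collections.

The test is the one-sided Fisher exact test in its hypergeometric
upper-tail form: for a query of size n drawn from a universe of size N, the
probability of observing at least the attained overlap with a set of size K
is ``P(X >= x)`` for ``X ~ Hypergeometric(N, K, n)``.  P values are
corrected across the collection with Benjamini-Hochberg (or Bonferroni).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets, typically read from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (per line: set name, description, member genes, tab-separated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path.name}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + genes)
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def overrepresentation(
    query: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first; the query must be a subset
    of the universe.  Returns one row per set -- set size (in universe),
    overlap, upper-tail p, adjusted q and fold enrichment -- sorted by p.
    """
    uni = set(universe)
    qry = set(query)
    if not qry or not uni:
        raise ValueError("query and universe must be non-empty")
    if not qry <= uni:
        raise ValueError(f"{len(qry - uni)} query genes are outside the universe")
    n_uni, n_qry = len(uni), len(qry)
    rows = []
    for name, genes in collection.sets.items():
        in_uni = set(genes) & uni
        k = len(in_uni)
        if k == 0:
            continue
        overlap = len(in_uni & qry)
        p = float(hypergeom.sf(overlap - 1, n_uni, k, n_qry))
        fold = (overlap / n_qry) / (k / n_uni)
        rows.append((name, k, overlap, p, fold))
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "p_value", "fold_enrichment"]
    )
    if table.empty:
        return table.assign(q_value=pd.Series(dtype=float))
    table["q_value"] = multipletests(table["p_value"], method=method)[1]
    table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return table[["set_name", "set_size", "overlap", "p_value", "q_value",
                  "fold_enrichment"]]
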