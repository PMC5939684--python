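"""Over-representation analysis of the inversely expressed gene set.

A standard hypergeometric upper-tail test against an expressed-gene
universe, with Benjamini-Hochberg adjustment across terms.  The universe
is the set of retina-detected mRNA features (not the whole annotation) to
avoid expression-bias inflation.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeometric_upper", "enrich", "read_gmt", "write_gmt"]


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_set: set[str],
    universe: set[str],
    annotation: dict[str, tuple[str, set[str]]],
    min_term_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each term.

    Terms are intersected with the universe first; terms with effective
    size below ``min_term_size`` are not tested.  Results are sorted by
    adjusted p, then raw p.  ``alpha`` only sets the ``significant`` flag.
    """
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for term_id, (term_name, genes) in annotation.items():
        term = genes & universe
        K = len(term)
        if K < min_term_size:
            continue
        k = len(term & gene_set)
        rows.append((term_id, term_name, k, K, n, N, hypergeometric_upper(k, K, n, N)))
    result = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw"])
    if result.empty:
        result["p_adj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["p_adj"] = multipletests(result["p_raw"], method="fdr_bh")[1]
    result["significant"] = result["p_adj"] < alpha
    return result.sort_values(["p_adj", "p_raw"], kind="mergesort").reset_index(drop=True)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT gene-set file: term id, description, then member genes."""
    annotation = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term_id, desc, genes = parts[0], parts[1], set(parts[2:]) - {""}
            if term_id in annotation:
                raise ValueError(f"duplicate term id {term_id!r}")
            if not genes:
                raise ValueError(f"term {term_id!r} has no member genes")
            annotation[term_id] = (desc, genes)
    return annotation


def write_gmt(annotation: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, genes) in annotation.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")
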