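"""Over-representation analysis of gene lists against GMT annotation.

For a list of L genes drawn from a background of M, a term with K background
members and x list hits gets the upper-tail hypergeometric probability
P(X >= x). The EASE variant (the DAVID tool's conservative score) tests
P(X >= x - 1) instead, i.e. removes one hit before testing. Rows carry the
published table shape: term, count, percent of list, p-value and FDR (BH by
default, Bonferroni available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnnotationSet, DataError
from .rvm import bh_fdr

logger = logging.getLogger("mirnet")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    count: int
    percent: float
    p_value: float
    fdr: float


def hypergeom_upper_tail(count: int, background: int, term_size: int, list_size: int) -> float:
    """P(X >= count) for X ~ Hypergeometric(M=background, K=term_size, N=list_size)."""
    if count == 0:
        return 1.0
    return float(stats.hypergeom.sf(count - 1, background, term_size, list_size))


def hypergeometric_enrichment(gene_list, annotation: AnnotationSet,
                              background: set[str] | None = None,
                              min_count: int = 2, method: str = "hypergeom",
                              correction: str = "bh") -> pd.DataFrame:
    """Per-term over-representation of ``gene_list`` (sorted by p, then term id)."""
    if method not in ("hypergeom", "ease"):
        raise DataError(f"unknown method {method!r}")
    if correction not in ("bh", "bonferroni"):
        raise DataError(f"unknown correction {correction!r}")
    genes = set(gene_list)
    bg = set(background) if background is not None else set(annotation.universe())
    if not genes or not bg:
        raise DataError("gene list and background must be non-empty")
    if not genes <= bg:
        raise DataError(f"gene list not contained in background; e.g. {sorted(genes - bg)[:5]}")

    rows = []
    for tid, (name, members) in annotation.terms.items():
        term_bg = members & bg
        if not term_bg:
            logger.info("term %s entirely outside background; skipped", tid)
            continue
        count = len(genes & term_bg)
        if count < min_count:
            continue
        x = count - 1 if method == "ease" else count
        p = hypergeom_upper_tail(x, len(bg), len(term_bg), len(genes))
        rows.append((tid, name, count, 100.0 * count / len(genes), p))
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "count", "percent", "p_value", "fdr"])
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "count", "percent", "p_value"])
    if correction == "bh":
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
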