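"""Data-reduction of predicted miRNA targets.

Predicted miRNA-target pairs are narrowed in two restrictions: (i) keep only
targets on a tissue-specific gene list, and (ii) keep only pairs whose mRNA
differential direction is inverse to the miRNA's (miRNA up => target down and
vice versa), the rule behind published coordinate-expression tables. An
optional third restriction requires the paired expression series to be
anti-correlated when matched matrices are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import DataError, ExpressionMatrix, TargetPairSet

logger = logging.getLogger("mirnet")


@dataclass(frozen=True)
class CoordinatePair:
    """A predicted pair whose differential directions are inverse."""

    mirna_id: str
    mirna_direction: str
    gene_id: str
    gene_direction: str
    correlation: float | None = None

    def __post_init__(self) -> None:
        if self.mirna_direction not in ("up", "down") or self.gene_direction not in ("up", "down"):
            raise DataError("directions must be 'up' or 'down'")
        if self.mirna_direction == self.gene_direction:
            raise DataError(
                f"coordinate pair must be inverse: {self.mirna_id} {self.mirna_direction} "
                f"vs {self.gene_id} {self.gene_direction}")


def filter_tissue_specific(pairs: TargetPairSet, tissue_genes: set[str]) -> TargetPairSet:
    """Restrict predicted pairs to targets on the tissue-specific gene list."""
    if not tissue_genes:
        logger.warning("empty tissue-specific gene list; all pairs removed")
        return TargetPairSet(pairs=frozenset(), provenance=pairs.provenance)
    kept = frozenset(p for p in pairs.pairs if p[1] in tissue_genes)
    logger.info("tissue filter: %d -> %d pairs", len(pairs), len(kept))
    return TargetPairSet(pairs=kept, provenance=pairs.provenance)


def coordinate_pairs(pairs: TargetPairSet, mirna_calls: dict[str, str],
                     gene_calls: dict[str, str]) -> list[CoordinatePair]:
    """Keep predicted pairs with opposite miRNA/mRNA differential directions.

    The direction maps contain only up/down entries (non-significant features
    absent); pairs touching an uncalled feature are dropped.
    """
    out = []
    for m, g in sorted(pairs.pairs):
        md, gd = mirna_calls.get(m), gene_calls.get(g)
        if md is None or gd is None or md == gd:
            continue
        out.append(CoordinatePair(mirna_id=m, mirna_direction=md, gene_id=g, gene_direction=gd))
    return out


def group_by_mirna(cands: list[CoordinatePair]) -> dict[str, list[CoordinatePair]]:
    """Group retained pairs per miRNA (published coordinate-table shape)."""
    grouped: dict[str, list[CoordinatePair]] = {}
    for c in cands:
        grouped.setdefault(c.mirna_id, []).append(c)
    return grouped


def correlation_filter(cands: list[CoordinatePair], mirna_expr: ExpressionMatrix,
                       mrna_expr: ExpressionMatrix, r_max: float = 0.0) -> list[CoordinatePair]:
    """Keep pairs whose expression Pearson r across shared samples is <= r_max."""
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise DataError(f"need >=3 shared samples for correlation, have {len(shared)}")
    out = []
    for c in cands:
        if c.mirna_id not in mirna_expr.data.index or c.gene_id not in mrna_expr.data.index:
            continue
        x = mirna_expr.data.loc[c.mirna_id, shared].to_numpy(dtype=float)
        y = mrna_expr.data.loc[c.gene_id, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        r = float(stats.pearsonr(x[ok], y[ok]).statistic)
        if r <= r_max:
            out.append(CoordinatePair(c.mirna_id, c.mirna_direction, c.gene_id,
                                      c.gene_direction, correlation=r))
    return out
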