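"""Ligand-receptor co-expression and its spatial enrichment in colocalized spots.

Per spot, the co-expression score of a ligand-receptor pair is
R_LR = L(exp) * R(exp), each side aggregated over its subunits by geometric
mean. For every colocalized cell-type pair, spots are cross-classified by
joint occupancy (both types present) against co-expression (R_LR > 0) and a
one-sided Fisher exact test with BH correction flags spatially enriched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._logging import get_logger
from ._stats import bh_adjust, geometric_mean_rows
from .coloc import BooleanOccupancy, ColocalizationNetwork
from .datatypes import LOGNORM, ExpressionMatrix, LRDatabase

log = get_logger(__name__)


@dataclass
class CoexpressionScores:
    """Spots x ligand-receptor pairs co-expression scores (R_LR >= 0)."""

    values: np.ndarray
    obs_ids: list[str]
    pair_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.obs_ids), len(self.pair_ids)):
            raise ValueError("scores shape must be (n_spots, n_pairs)")
        if np.any(self.values < 0):
            raise ValueError("co-expression scores must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.pair_ids)


def coexpression_scores(em: ExpressionMatrix, db: LRDatabase) -> CoexpressionScores:
    """Per-spot R_LR = L(exp) * R(exp) for every pair with all subunits present.

    Multi-subunit sides aggregate by geometric mean (exactly 0 when any
    subunit is 0). Pairs with missing subunit genes are skipped with a warning.
    """
    if em.layer != LOGNORM:
        raise ValueError("coexpression_scores expects a lognorm matrix")
    genes = set(em.gene_ids)
    cols, ids = [], []
    skipped = []
    for pair in db:
        if not set(pair.genes) <= genes:
            skipped.append(pair.pair_id)
            continue
        lig = geometric_mean_rows(em.values, em.gene_index(pair.ligand_subunits))
        rec = geometric_mean_rows(em.values, em.gene_index(pair.receptor_subunits))
        cols.append(lig * rec)
        ids.append(pair.pair_id)
    if skipped:
        log.warning("coexpression_scores: skipped %d pairs with missing genes: %s",
                    len(skipped), skipped[:10])
    if not ids:
        raise ValueError("no ligand-receptor pair has all subunits in the matrix")
    return CoexpressionScores(np.column_stack(cols), list(em.obs_ids), ids)


def fisher_exact_greater(a: int, b: int, c: int, d: int):
    """One-sided (enrichment) Fisher exact test on the 2x2 table
    [[a, b], [c, d]]: p = P(X >= a) for X hypergeometric with the table's
    margins fixed.

    Odds ratio is ad/bc; +inf when bc = 0 with ad > 0, NaN when both products
    are 0 (degenerate table).
    """
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    p = 1.0 if n == 0 else min(float(hypergeom.sf(a - 1, n, a + c, a + b)), 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def _fisher_greater_vec(a, b, c, d) -> np.ndarray:
    n = a + b + c + d
    p = np.minimum(hypergeom.sf(a - 1, n, a + c, a + b), 1.0)
    return np.where(n == 0, 1.0, p)


def spatial_lr_enrichment(
    occ: BooleanOccupancy,
    co: CoexpressionScores,
    net: ColocalizationNetwork,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact enrichment of co-expressed pairs within colocalized spots.

    For each kept network edge (A, B) and each ligand-receptor pair, spots are
    classified by X = occupancy(A) AND occupancy(B) and Y = (R_LR > 0); the
    one-sided Fisher p-values are BH-adjusted jointly over all (edge, pair)
    rows. Returns the enrichment table (empty if the network has no edges).
    """
    if occ.obs_ids != co.obs_ids:
        raise ValueError("occupancy and co-expression spot ids differ")
    columns = ["type_a", "type_b", "pair_id", "a", "b", "c", "d",
               "odds_ratio", "p", "q", "enriched"]
    edges = sorted(tuple(sorted(e)) for e in net.kept_edges)
    if not edges:
        log.info("spatial_lr_enrichment: network has zero edges, empty table")
        return pd.DataFrame(columns=columns)
    Y = co.values > 0
    rows = []
    for ta, tb in edges:
        X = occ.column(ta) & occ.column(tb)
        a = (X[:, None] & Y).sum(axis=0)
        b = (X[:, None] & ~Y).sum(axis=0)
        c = (~X[:, None] & Y).sum(axis=0)
        d = (~X[:, None] & ~Y).sum(axis=0)
        p = _fisher_greater_vec(a, b, c, d)
        ad, bc = a * d, b * c
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = np.where(bc > 0, ad / np.maximum(bc, 1),
                            np.where(ad > 0, np.inf, np.nan))
        for k, pid in enumerate(co.pair_ids):
            rows.append((ta, tb, pid, a[k], b[k], c[k], d[k], odds[k], p[k]))
    table = pd.DataFrame(rows, columns=columns[:9])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["enriched"] = table["q"] < alpha
    log.info("spatial_lr_enrichment: %d/%d rows enriched over %d edges",
             int(table["enriched"].sum()), len(table), len(edges))
    return table
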