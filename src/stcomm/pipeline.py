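"""End-to-end spatially constrained communication pipeline.

Chains the four stages: colocalization network from deconvolution weights,
per-spot ligand-receptor co-expression, Fisher-exact spatial enrichment within
colocalized spots, and permutation-tested communication on reference single
cells, intersected into the final retained table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._logging import get_logger
from .coloc import BooleanOccupancy, ColocalizationNetwork, binarize_weights, \
    colocalization_network, pairwise_pcc
from .communication import communication_probability, stcomm_filter
from .config import AnalysisConfig
from .datatypes import CellTypeWeights, ExpressionMatrix, LRDatabase
from .enrichment import CoexpressionScores, coexpression_scores, \
    spatial_lr_enrichment
from .io import lognormalize

log = get_logger(__name__)


@dataclass
class STcommResult:
    """All stage outputs of one pipeline run."""

    network: ColocalizationNetwork
    occupancy: BooleanOccupancy
    coexpression: CoexpressionScores
    enrichment: pd.DataFrame
    ccc: pd.DataFrame
    table: pd.DataFrame  # joined, with the final `retained` flag

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]].reset_index(drop=True)


def run_stcomm(
    spot_expression: ExpressionMatrix,
    weights: CellTypeWeights,
    lr_db: LRDatabase,
    ref_expression: ExpressionMatrix,
    ref_labels,
    config: AnalysisConfig | None = None,
) -> STcommResult:
    """Run the full spatially constrained communication analysis.

    Raw-count inputs are log-normalized with the configured scale factor;
    already-normalized matrices are used as-is.
    """
    cfg = config or AnalysisConfig()
    if spot_expression.layer == "raw_counts":
        spot_expression = lognormalize(spot_expression, cfg.scale_factor)
    if ref_expression.layer == "raw_counts":
        ref_expression = lognormalize(ref_expression, cfg.scale_factor)

    pcc, p = pairwise_pcc(weights)
    net = colocalization_network(pcc, p, min_pcc=cfg.min_pcc, alpha=cfg.alpha)
    occ = binarize_weights(weights, threshold=cfg.weight_threshold)
    co = coexpression_scores(spot_expression, lr_db)
    enr = spatial_lr_enrichment(occ, co, net, alpha=cfg.alpha)
    ccc = communication_probability(
        ref_expression, ref_labels, lr_db,
        kh=cfg.kh, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha,
    )
    table = stcomm_filter(enr, ccc, net)
    return STcommResult(
        network=net, occupancy=occ, coexpression=co,
        enrichment=enr, ccc=ccc, table=table,
    )
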