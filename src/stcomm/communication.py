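"""Permutation-tested sender-to-receiver communication on reference single cells,
and the final spatially constrained intersection filter.

The communication score for a directed (sender, receiver, pair) triple is a
saturating ligand x receptor mass-action form,

    prob = (L_s * R_r) / (kh + L_s * R_r),

where L_s is the geometric mean over ligand subunits of the sender's mean
expression and R_r likewise for the receiver. Significance comes from a
one-sided global label-permutation test. This is a deliberate simplification
of full mass-action communication frameworks: it keeps the two testable
essentials (monotone saturating ligand-receptor product; one-sided permutation
p-value) and none of the cofactor machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._logging import get_logger
from .coloc import ColocalizationNetwork
from .datatypes import LOGNORM, ExpressionMatrix, LRDatabase

log = get_logger(__name__)


def group_means(em: ExpressionMatrix, labels) -> pd.DataFrame:
    """Arithmetic mean expression per cell type (types x genes).

    Every label must cover at least 3 cells.
    """
    labels = np.asarray([str(x) for x in labels])
    if labels.shape[0] != em.n_obs:
        raise ValueError("labels must have one entry per observation")
    types, counts = np.unique(labels, return_counts=True)
    small = [t for t, c in zip(types, counts) if c < 3]
    if small:
        raise ValueError(f"cell types with fewer than 3 cells: {small}")
    onehot = (labels[None, :] == types[:, None]).astype(float)
    onehot /= onehot.sum(axis=1, keepdims=True)
    means = onehot @ em.values.T
    return pd.DataFrame(means, index=types, columns=em.gene_ids)


def _pair_indices(em: ExpressionMatrix, db: LRDatabase):
    genes = set(em.gene_ids)
    usable, skipped = [], []
    for pair in db:
        if set(pair.genes) <= genes:
            usable.append(
                (pair.pair_id,
                 em.gene_index(pair.ligand_subunits),
                 em.gene_index(pair.receptor_subunits))
            )
        else:
            skipped.append(pair.pair_id)
    if skipped:
        log.warning("communication: skipped %d pairs with missing genes: %s",
                    len(skipped), skipped[:10])
    if not usable:
        raise ValueError("no ligand-receptor pair has all subunits in the matrix")
    return usable


def _side_means(means: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Geometric mean over subunit columns of a types x genes mean matrix."""
    sub = means[:, idx]
    if sub.shape[1] == 1:
        return sub[:, 0].copy()
    anyzero = np.any(sub == 0, axis=1)
    with np.errstate(divide="ignore"):
        gm = np.exp(np.mean(np.log(np.where(sub > 0, sub, 1.0)), axis=1))
    gm[anyzero] = 0.0
    return gm


def communication_probability(
    em: ExpressionMatrix,
    labels,
    db: LRDatabase,
    kh: float = 0.5,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Communication probability and permutation p for every ordered
    (sender, receiver) type pair and usable ligand-receptor pair.

    p_perm = (1 + #{permutations with prob* >= prob_observed}) / (n_perm + 1),
    with cell labels globally shuffled per permutation. Rows with zero observed
    probability have p_perm = 1 by construction.
    """
    if em.layer != LOGNORM:
        raise ValueError("communication_probability expects a lognorm matrix")
    if n_perm > 0 and seed is None:
        raise ValueError("seed is required when n_perm > 0")
    if 0 < n_perm < 100:
        log.warning("communication_probability: n_perm=%d is low; p-values are "
                    "coarse", n_perm)
    labels = np.asarray([str(x) for x in labels])
    means_df = group_means(em, labels)
    types = list(means_df.index)
    usable = _pair_indices(em, db)

    def prob_cube(means: np.ndarray) -> np.ndarray:
        # (n_pairs, n_types senders, n_types receivers)
        out = np.empty((len(usable), len(types), len(types)))
        for k, (_, lidx, ridx) in enumerate(usable):
            ls = _side_means(means, lidx)
            rr = _side_means(means, ridx)
            lr = np.outer(ls, rr)
            out[k] = lr / (kh + lr)
        return out

    obs = prob_cube(means_df.to_numpy())
    exceed = np.zeros_like(obs)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        types_arr = np.array(types)
        onehot_base = (labels[None, :] == types_arr[:, None]).astype(float)
        onehot_base /= onehot_base.sum(axis=1, keepdims=True)
        X = em.values.T  # cells x genes
        for _ in range(n_perm):
            perm = rng.permutation(em.n_obs)
            means_p = onehot_base @ X[perm]
            exceed += prob_cube(means_p) >= obs
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for k, (pid, _, _) in enumerate(usable):
        for i, s in enumerate(types):
            for j, r in enumerate(types):
                rows.append((s, r, pid, obs[k, i, j], p_perm[k, i, j]))
    table = pd.DataFrame(rows, columns=["sender", "receiver", "pair_id",
                                        "prob", "p_perm"])
    table["significant"] = table["p_perm"] < alpha
    log.info("communication_probability: %d rows, %d significant "
             "(n_perm=%d, kh=%g)", len(table), int(table["significant"].sum()),
             n_perm, kh)
    return table


def stcomm_filter(
    enr: pd.DataFrame,
    ccc: pd.DataFrame,
    net: ColocalizationNetwork,
) -> pd.DataFrame:
    """Final intersection: a directed (sender, receiver, pair) communication row
    is retained iff its unordered type pair is a colocalization edge, the pair
    is spatially enriched on that edge, and the permutation test is significant.

    Both directions of an unordered enriched edge are evaluated.
    """
    enriched_lut = {}
    if len(enr):
        for row in enr.itertuples(index=False):
            enriched_lut[(frozenset((row.type_a, row.type_b)), row.pair_id)] = (
                bool(row.enriched), row.q
            )
    out = ccc.copy()
    kept_edges = net.kept_edges
    edge_flags, enr_flags, enr_q = [], [], []
    for row in ccc.itertuples(index=False):
        key = frozenset((row.sender, row.receiver))
        edge_flags.append(key in kept_edges)
        flag, q = enriched_lut.get((key, row.pair_id), (False, np.nan))
        enr_flags.append(flag)
        enr_q.append(q)
    out["edge"] = edge_flags
    out["enriched"] = enr_flags
    out["enrichment_q"] = enr_q
    out["retained"] = out["edge"] & out["enriched"] & out["significant"]
    log.info("stcomm_filter: %d/%d rows retained", int(out["retained"].sum()),
             len(out))
    return out
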