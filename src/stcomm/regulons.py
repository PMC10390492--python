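"""Regulon activity, spatial specificity and co-activation structure.

- Activity per spot is the area under the gene-rank recovery curve of the
  regulon's target set (the AUCell statistic).
- Spatial specificity (RSS) compares a regulon's activity distribution over
  spots with a domain's normalized indicator via Jensen-Shannon divergence:
  RSS = 1 - sqrt(JSD), base-2 logs, so RSS = 1 exactly on an indicator match.
- The connection specificity index (CSI) of a regulon pair (A, B) is the
  fraction of all regulons whose correlation with both A and B falls below
  corr(A, B); modules come from Ward clustering of CSI rows and the
  co-activation network keeps edges with CSI strictly above a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon

from ._logging import get_logger
from .datatypes import ExpressionMatrix, RegulonActivityMatrix, SignatureCollection

log = get_logger(__name__)


def auc_recovery_score(
    em: ExpressionMatrix,
    gene_set,
    top_frac: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-observation area under the gene-rank recovery curve of a gene set.

    For each observation, genes are ranked by descending expression (ties
    broken by one seeded random permutation shared across observations); the
    recovery curve counts set genes among the top ranks up to
    ``max_rank = ceil(top_frac * n_genes)`` and the score is the area under
    that step curve normalized by its maximum possible area. Scores are
    invariant to any strictly monotone transform of the expression values.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    in_set = np.array([g in gene_set for g in em.gene_ids])
    n_set = int(in_set.sum())
    if n_set == 0:
        name = getattr(gene_set, "name", None) or sorted(gene_set)[:5]
        raise ValueError(f"gene set has no genes in the matrix: {name}")
    n_genes = em.n_genes
    max_rank = math.ceil(top_frac * n_genes)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n_genes)
    # lexsort: primary descending expression, secondary the seeded shuffle
    order = np.lexsort((tiebreak[:, None].repeat(em.n_obs, axis=1),
                        -em.values), axis=0)
    hits = in_set[order[:max_rank, :]]        # max_rank x n_obs
    cum = np.cumsum(hits, axis=0)
    auc = cum.sum(axis=0).astype(float)
    ks = np.arange(1, max_rank + 1)
    max_auc = np.minimum(ks, n_set).sum()
    return auc / max_auc


def ras_matrix(
    em: ExpressionMatrix,
    regulons: SignatureCollection,
    top_frac: float = 0.05,
    seed: int = 0,
) -> RegulonActivityMatrix:
    """Recovery-AUC activity of every regulon in a collection (spots x regulons)."""
    coll, flagged = regulons.intersect(em.gene_ids)
    if flagged:
        log.warning("ras_matrix: sets with no genes in matrix dropped: %s", flagged)
    if not len(coll):
        raise ValueError("no regulon has genes in the matrix")
    cols = [auc_recovery_score(em, set(coll[name]), top_frac, seed)
            for name in coll.names]
    return RegulonActivityMatrix(np.column_stack(cols), list(em.obs_ids), coll.names)


def jensen_shannon_divergence(p, q) -> float:
    """Jensen-Shannon divergence with base-2 logs (in [0, 1]).

    Inputs must be same-length probability vectors (non-negative, summing
    to 1 within 1e-9).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} does not sum to 1 (got {v.sum()!r})")
    return float(jensenshannon(p, q, base=2) ** 2)


def regulon_specificity_scores(
    ras: RegulonActivityMatrix,
    domains,
) -> pd.DataFrame:
    """Regulons x domains specificity matrix: RSS = 1 - sqrt(JSD) between the
    regulon's activity normalized over spots and the domain's normalized
    indicator. RSS is invariant to positive scaling of an activity column and
    equals 1 exactly when activity is the domain indicator.
    """
    domains = np.asarray([str(d) for d in domains])
    if domains.shape[0] != ras.n_spots:
        raise ValueError("domains must have one label per spot")
    domain_names = sorted(np.unique(domains))
    colsums = ras.values.sum(axis=0)
    zero_cols = [n for n, s in zip(ras.regulon_names, colsums) if s == 0]
    if zero_cols:
        log.warning("regulon_specificity_scores: zero-sum columns give NaN: %s",
                    zero_cols)
    out = np.full((len(ras.regulon_names), len(domain_names)), np.nan)
    for j, dom in enumerate(domain_names):
        ind = (domains == dom).astype(float)
        p_d = ind / ind.sum()
        for i in range(len(ras.regulon_names)):
            if colsums[i] == 0:
                continue
            p_r = ras.values[:, i] / colsums[i]
            out[i, j] = 1.0 - float(jensenshannon(p_r, p_d, base=2))
    return pd.DataFrame(out, index=ras.regulon_names, columns=domain_names)


def connection_specificity_index(
    ras: RegulonActivityMatrix,
    margin: float = 0.0,
) -> pd.DataFrame:
    """Connection specificity index over all regulon pairs.

    With P the pairwise Pearson correlation matrix of activity columns,
    CSI(A, B) counts the regulons C with P(A,C) < P(A,B) - margin and
    P(B,C) < P(A,B) - margin, divided by the number of regulons N. A and B
    themselves never count because P(A,A) = P(B,B) = 1. Diagonal defined as 1.
    Constant activity columns are excluded (logged).
    """
    sd = ras.values.std(axis=0)
    usable = sd > 0
    dropped = [n for n, u in zip(ras.regulon_names, usable) if not u]
    if dropped:
        log.warning("connection_specificity_index: constant columns dropped: %s",
                    dropped)
    names = [n for n, u in zip(ras.regulon_names, usable) if u]
    if len(names) < 3:
        raise ValueError("need at least 3 regulons with non-constant activity")
    P = np.corrcoef(ras.values[:, usable], rowvar=False)
    n = len(names)
    csi = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cut = P[i, j] - margin
            count = int(np.sum((P[i] < cut) & (P[j] < cut)))
            csi[i, j] = csi[j, i] = count / n
    return pd.DataFrame(csi, index=names, columns=names)


@dataclass
class ModuleAssignment:
    """Partition of regulons into co-activation modules with per-spot mean
    activity of each module."""

    modules: dict[str, int]
    mean_activity: pd.DataFrame  # spots x modules

    def members(self, module_id: int) -> list[str]:
        return [r for r, m in self.modules.items() if m == module_id]


def regulon_modules(
    csi: pd.DataFrame,
    ras: RegulonActivityMatrix,
    n_modules: int = 7,
    method: str = "ward",
) -> ModuleAssignment:
    """Cut the hierarchical clustering of CSI rows (Euclidean distance, Ward
    linkage by default) into ``n_modules`` regulon modules; a module's mean
    activity per spot is the arithmetic mean of its members' activity columns.
    """
    names = list(csi.index)
    if not 2 <= n_modules <= len(names) - 1:
        raise ValueError("n_modules must be in [2, n_regulons - 1]")
    Z = linkage(csi.to_numpy(), method=method, metric="euclidean")
    assignment = fcluster(Z, t=n_modules, criterion="maxclust")
    modules = {name: int(m) for name, m in zip(names, assignment)}
    ras_df = ras.to_dataframe()
    means = {}
    for mod in sorted(set(assignment)):
        members = [n for n in names if modules[n] == mod]
        means[f"module_{mod}"] = ras_df[members].mean(axis=1)
    log.info("regulon_modules: %d modules over %d regulons (%s linkage)",
             len(means), len(names), method)
    return ModuleAssignment(modules=modules, mean_activity=pd.DataFrame(means))


def csi_network_edges(csi: pd.DataFrame, threshold: float = 0.85) -> pd.DataFrame:
    """Co-activation network edge list: unordered regulon pairs with CSI
    strictly above the threshold."""
    names = list(csi.index)
    rows = []
    vals = csi.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if vals[i, j] > threshold:
                rows.append((names[i], names[j], vals[i, j]))
    edges = pd.DataFrame(rows, columns=["regulon_a", "regulon_b", "csi"])
    log.info("csi_network_edges: %d edges at CSI > %g", len(edges), threshold)
    return edges
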