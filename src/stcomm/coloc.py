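"""Spot-level cell-type colocalization from deconvolution weights.

Two cell types colocalize when their per-spot weight columns correlate: the
colocalization network keeps the unordered pairs with Pearson correlation
strictly above ``min_pcc`` and BH-adjusted p strictly below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._logging import get_logger
from ._stats import bh_adjust, pearson_with_pvalues
from .datatypes import CellTypeWeights

log = get_logger(__name__)


@dataclass
class BooleanOccupancy:
    """Spots x cell-types boolean presence calls."""

    values: np.ndarray
    obs_ids: list[str]
    type_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.obs_ids), len(self.type_names)):
            raise ValueError("occupancy shape must be (n_spots, n_types)")

    def column(self, type_name: str) -> np.ndarray:
        return self.values[:, self.type_names.index(type_name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.type_names)


@dataclass
class ColocalizationNetwork:
    """Edge table over unordered cell-type pairs plus the full PCC matrix."""

    edges: pd.DataFrame  # type_a, type_b, pcc, p, q, kept
    pcc: pd.DataFrame    # symmetric type x type matrix

    @property
    def kept_edges(self) -> set[frozenset]:
        kept = self.edges[self.edges["kept"]]
        return {frozenset((a, b)) for a, b in zip(kept["type_a"], kept["type_b"])}

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.kept_edges


def pairwise_pcc(w: CellTypeWeights) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of cell-type weight columns over all spots,
    with two-sided t-test p-values (df = n - 2).

    Zero-variance columns give NaN correlation and are excluded from testing.
    """
    r, p = pearson_with_pvalues(w.weights)
    nan_cols = [t for t, ok in zip(w.type_names, np.isfinite(np.diag(r))) if not ok]
    if nan_cols:
        log.warning("pairwise_pcc: zero-variance cell types excluded: %s", nan_cols)
    idx = w.type_names
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def colocalization_network(
    pcc: pd.DataFrame,
    p: pd.DataFrame,
    min_pcc: float = 0.06,
    alpha: float = 0.05,
) -> ColocalizationNetwork:
    """Build the colocalization edge table.

    BH adjustment runs over the family of all unordered type pairs with finite
    correlation; an edge is kept iff pcc > min_pcc and q < alpha (both strict).
    """
    types = list(pcc.columns)
    rows = []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            rows.append((types[i], types[j], pcc.iat[i, j], p.iat[i, j]))
    edges = pd.DataFrame(rows, columns=["type_a", "type_b", "pcc", "p"])
    finite = np.isfinite(edges["pcc"].to_numpy())
    edges = edges[finite].reset_index(drop=True)
    edges["q"] = bh_adjust(edges["p"].to_numpy())
    edges["kept"] = (edges["pcc"] > min_pcc) & (edges["q"] < alpha)
    log.info(
        "colocalization_network: %d/%d pairs kept (min_pcc=%g, alpha=%g)",
        int(edges["kept"].sum()), len(edges), min_pcc, alpha,
    )
    return ColocalizationNetwork(edges=edges, pcc=pcc)


def binarize_weights(
    w: CellTypeWeights,
    threshold: float | None = 0.1,
    external: pd.DataFrame | None = None,
) -> BooleanOccupancy:
    """Binarize deconvolution weights into presence calls.

    Either threshold at ``weight >= threshold`` or pass through an external
    boolean table (e.g. upstream confident calls), aligned by spot and type ids.
    """
    if external is not None:
        missing_obs = set(w.obs_ids) - set(external.index.astype(str))
        missing_types = set(w.type_names) - set(external.columns.astype(str))
        if missing_obs or missing_types:
            raise ValueError(
                f"external boolean table id mismatch: missing spots "
                f"{sorted(missing_obs)[:5]}, missing types {sorted(missing_types)[:5]}"
            )
        aligned = external.loc[w.obs_ids, w.type_names].to_numpy(bool)
        return BooleanOccupancy(aligned, list(w.obs_ids), list(w.type_names))
    if threshold is None or not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    occ = w.weights >= threshold
    log.info("binarize_weights: threshold=%g, occupancy rate=%.3f",
             threshold, occ.mean())
    return BooleanOccupancy(occ, list(w.obs_ids), list(w.type_names))
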