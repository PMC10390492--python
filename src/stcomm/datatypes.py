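"""Core domain containers for spot-based spatial transcriptomics analysis.

All matrices are oriented genes x observations internally; tabular outputs are
long-format keyed by identifiers, never positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"

_VALID_LAYERS = (RAW_COUNTS, LOGNORM)
_VALID_MODES = ("secreted", "contact", "ecm")


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x observations expression values.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_obs)
        Non-negative expression values. Integer counts when ``layer`` is
        ``"raw_counts"``; natural-log normalized values when ``"lognorm"``.
    gene_ids, obs_ids : sequences of unique strings.
    layer : {"raw_counts", "lognorm"}
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    layer: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.obs_ids = [str(o).strip() for o in self.obs_ids]
        if self.layer not in _VALID_LAYERS:
            raise ValueError(f"layer must be one of {_VALID_LAYERS}, got {self.layer!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x observations matrix")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.obs_ids, "obs_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if self.layer == RAW_COUNTS and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValueError("raw_counts layer requires integer values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([lut[g] for g in genes], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)


@dataclass
class SpotAnnotations:
    """Per-spot metadata: section of origin, array coordinates, optional domain
    label and optional externally supplied pseudo-space ordering."""

    obs_ids: list[str]
    section_index: np.ndarray
    array_x: np.ndarray
    array_y: np.ndarray
    domain: list[str] | None = None
    pseudo_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.obs_ids = [str(o).strip() for o in self.obs_ids]
        _check_unique(self.obs_ids, "obs_ids")
        n = len(self.obs_ids)
        self.section_index = np.asarray(self.section_index, dtype=int)
        self.array_x = np.asarray(self.array_x, dtype=float)
        self.array_y = np.asarray(self.array_y, dtype=float)
        for name, arr in (
            ("section_index", self.section_index),
            ("array_x", self.array_x),
            ("array_y", self.array_y),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per spot")
        if np.any(self.section_index < 1):
            raise ValueError("section_index must be >= 1")
        secs = np.unique(self.section_index)
        if not np.array_equal(secs, np.arange(secs.min(), secs.max() + 1)):
            raise ValueError("section_index values must form a contiguous range")
        if self.domain is not None and len(self.domain) != n:
            raise ValueError("domain must have one entry per spot")
        if self.pseudo_order is not None:
            self.pseudo_order = np.asarray(self.pseudo_order, dtype=float)
            if self.pseudo_order.shape != (n,):
                raise ValueError("pseudo_order must have one entry per spot")

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "obs_id": self.obs_ids,
                "section_index": self.section_index,
                "array_x": self.array_x,
                "array_y": self.array_y,
            }
        )
        if self.domain is not None:
            df["domain"] = self.domain
        if self.pseudo_order is not None:
            df["pseudo_order"] = self.pseudo_order
        return df


@dataclass
class CellTypeWeights:
    """Spots x cell-types deconvolution weights on the probability simplex
    (row sums at most 1)."""

    weights: np.ndarray
    obs_ids: list[str]
    type_names: list[str]

    _ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.obs_ids = [str(o).strip() for o in self.obs_ids]
        self.type_names = [str(t).strip() for t in self.type_names]
        if self.weights.shape != (len(self.obs_ids), len(self.type_names)):
            raise ValueError("weights shape must be (n_spots, n_types)")
        if len(self.type_names) < 2:
            raise ValueError("need at least 2 cell types")
        _check_unique(self.obs_ids, "obs_ids")
        _check_unique(self.type_names, "type_names")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if np.any(self.weights.sum(axis=1) > 1 + self._ROW_SUM_TOL):
            raise ValueError("weight row sums must not exceed 1")

    @property
    def n_spots(self) -> int:
        return self.weights.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.obs_ids, columns=self.type_names)


@dataclass
class LRPair:
    """One ligand-receptor record; multi-subunit sides are gene-id lists."""

    pair_id: str
    ligand_subunits: list[str]
    receptor_subunits: list[str]
    pathway: str = ""
    mode: str = "secreted"

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError(f"pair {self.pair_id!r}: empty subunit list")
        if any(not g for g in self.ligand_subunits + self.receptor_subunits):
            raise ValueError(f"pair {self.pair_id!r}: empty subunit gene id")
        if self.mode not in _VALID_MODES:
            raise ValueError(
                f"pair {self.pair_id!r}: mode {self.mode!r} not in {_VALID_MODES}"
            )
        both = set(self.ligand_subunits) & set(self.receptor_subunits)
        if both:
            raise ValueError(
                f"pair {self.pair_id!r}: genes on both sides: {sorted(both)}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.ligand_subunits) + list(self.receptor_subunits)


@dataclass
class LRDatabase:
    """Curated ligand-receptor pair collection."""

    pairs: list[LRPair]

    def __post_init__(self) -> None:
        _check_unique([p.pair_id for p in self.pairs], "pair_ids")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def subset(self, genes) -> "LRDatabase":
        """Pairs whose subunits are all contained in ``genes``."""
        gset = set(genes)
        return LRDatabase([p for p in self.pairs if set(p.genes) <= gset])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in self.pairs],
                "ligand": ["_".join(p.ligand_subunits) for p in self.pairs],
                "receptor": ["_".join(p.receptor_subunits) for p in self.pairs],
                "pathway": [p.pathway for p in self.pairs],
                "mode": [p.mode for p in self.pairs],
            }
        )


@dataclass
class SignatureCollection:
    """Named gene sets (regulons, axis marker sets, signaling signatures)."""

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def intersect(self, genes) -> tuple["SignatureCollection", list[str]]:
        """Restrict every set to ``genes``; returns (collection, flagged names)
        where flagged sets became empty and were dropped."""
        gset = set(genes)
        kept, flagged = {}, []
        for name, gs in self.sets.items():
            inter = [g for g in gs if g in gset]
            if inter:
                kept[name] = inter
            else:
                flagged.append(name)
        return (
            SignatureCollection(kept, {n: c for n, c in self.categories.items() if n in kept}),
            flagged,
        )


@dataclass
class RegulonActivityMatrix:
    """Spots x regulons activity scores in [0, 1] (recovery-curve AUC)."""

    values: np.ndarray
    obs_ids: list[str]
    regulon_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.obs_ids), len(self.regulon_names)):
            raise ValueError("values shape must be (n_spots, n_regulons)")
        _check_unique(self.obs_ids, "obs_ids")
        _check_unique(self.regulon_names, "regulon_names")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0) or np.any(finite > 1):
            raise ValueError("activity values must lie in [0, 1]")
        if np.any(np.all(~np.isfinite(self.values), axis=0)):
            raise ValueError("all-NaN regulon column")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.regulon_names)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic atlas."""

    planted_coloc_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_lr: list[tuple[str, str, str]] = field(default_factory=list)
    planted_gradient_genes: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_domain_regulons: dict[str, str] = field(default_factory=dict)
    decoy_lr: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
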