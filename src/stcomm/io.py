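"""Readers, writers and normalization for the standard on-disk formats.

Count matrices come in as 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv, optionally gzipped) or dense TSV; gene sets as
GMT; ligand-receptor pairs, weights and annotations as TSV.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._logging import get_logger
from .datatypes import (
    LOGNORM,
    RAW_COUNTS,
    CellTypeWeights,
    ExpressionMatrix,
    LRDatabase,
    LRPair,
    SignatureCollection,
    SpotAnnotations,
)

log = get_logger(__name__)


def _find_triplet_file(d: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        for ext in (".mtx", ".tsv", ".txt", ".csv"):
            p = d / f"{stem}{ext}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"no {stem} file found in {d}")


def _read_id_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # 10x features files carry (id, symbol, type); prefer the symbol column
    if rows and len(rows[0]) >= 2:
        return [r[1] for r in rows]
    return [r[0] for r in rows]


def make_unique(ids) -> list[str]:
    """Disambiguate duplicates deterministically with ``.1``, ``.2``, ... suffixes."""
    counts: dict[str, int] = {}
    out = []
    for i in ids:
        if i in counts:
            counts[i] += 1
            out.append(f"{i}.{counts[i]}")
        else:
            counts[i] = 0
            out.append(i)
    return out


def read_count_matrix(path) -> ExpressionMatrix:
    """Read raw counts from an MTX triplet directory or a dense genes x obs TSV."""
    path = Path(path)
    if path.is_dir():
        mtx_path = _find_triplet_file(path, "matrix")
        feat_path = _find_triplet_file(path, "features")
        bc_path = _find_triplet_file(path, "barcodes")
        mat = scipy.io.mmread(str(mtx_path))
        genes = _read_id_column(feat_path)
        barcodes = _read_id_column(bc_path)
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{feat_path.name} has {len(genes)} rows but matrix header "
                f"declares {mat.shape[0]} rows"
            )
        if mat.shape[1] != len(barcodes):
            raise ValueError(
                f"{bc_path.name} has {len(barcodes)} rows but matrix header "
                f"declares {mat.shape[1]} columns"
            )
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        genes = make_unique(genes)
        barcodes = make_unique(barcodes)
        em = ExpressionMatrix(values, genes, barcodes, layer=RAW_COUNTS)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        em = ExpressionMatrix(
            df.to_numpy(),
            make_unique(df.index.astype(str)),
            make_unique(df.columns.astype(str)),
            layer=RAW_COUNTS,
        )
    log.info("read_count_matrix: %d genes x %d observations from %s",
             em.n_genes, em.n_obs, path)
    return em


def write_count_matrix(em: ExpressionMatrix, path, fmt: str = "mtx") -> None:
    """Write an expression matrix as an MTX triplet directory or dense TSV."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(em.values)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp)
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in em.gene_ids)
        )
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in em.obs_ids))
    elif fmt == "tsv":
        em.to_dataframe().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def lognormalize(em: ExpressionMatrix, scale_factor: float = 10000.0) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform raw counts.

    Each value becomes ``ln(1 + count / obs_total * scale_factor)``.
    """
    if em.layer != RAW_COUNTS:
        raise ValueError("lognormalize expects a raw_counts matrix")
    totals = em.values.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        bad = [em.obs_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"observations with zero total counts: {bad[:10]}")
    vals = np.log1p(em.values / totals * scale_factor)
    log.info("lognormalize: scale_factor=%g on %d x %d", scale_factor,
             em.n_genes, em.n_obs)
    return ExpressionMatrix(vals, list(em.gene_ids), list(em.obs_ids), layer=LOGNORM)


def qc_filter_spots(
    em: ExpressionMatrix,
    min_genes: int = 1000,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "mt-",
) -> ExpressionMatrix:
    """Optional spot QC: minimum detected genes and maximum mitochondrial
    count fraction (mitochondrial genes matched by id prefix, case-insensitive)."""
    if em.layer != RAW_COUNTS:
        raise ValueError("qc_filter_spots expects raw counts")
    detected = (em.values > 0).sum(axis=0)
    mito = np.array([g.lower().startswith(mito_prefix) for g in em.gene_ids])
    totals = em.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, em.values[mito].sum(axis=0) / totals, 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    log.info("qc_filter_spots: kept %d / %d spots", int(keep.sum()), em.n_obs)
    return ExpressionMatrix(
        em.values[:, keep],
        list(em.gene_ids),
        [o for o, k in zip(em.obs_ids, keep) if k],
        layer=RAW_COUNTS,
    )


def read_lr_database(path) -> LRDatabase:
    """Read ligand-receptor pairs from TSV with columns
    pair_id, ligand, receptor, pathway, mode (subunits '_'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"pair_id", "ligand", "receptor", "pathway", "mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ligand-receptor TSV missing columns: {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            LRPair(
                pair_id=row.pair_id.strip(),
                ligand_subunits=[g.strip() for g in row.ligand.split("_")],
                receptor_subunits=[g.strip() for g in row.receptor.split("_")],
                pathway=row.pathway.strip(),
                mode=row.mode.strip(),
            )
        )
    db = LRDatabase(pairs)
    log.info("read_lr_database: %d pairs from %s", len(db), path)
    return db


def write_lr_database(db: LRDatabase, path) -> None:
    db.to_dataframe().to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> SignatureCollection:
    """Read gene sets from standard GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
            if desc:
                categories[name] = desc
    coll = SignatureCollection(sets, categories)
    log.info("read_gene_sets: %d sets from %s", len(coll), path)
    return coll


def write_gene_sets(coll: SignatureCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.categories.get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def read_weights(path) -> CellTypeWeights:
    """Spots x cell-types weights from TSV (index column = obs ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellTypeWeights(
        df.to_numpy(float), list(df.index.astype(str)), list(df.columns.astype(str))
    )


def write_weights(w: CellTypeWeights, path) -> None:
    w.to_dataframe().to_csv(path, sep="\t")


def read_annotations(path) -> SpotAnnotations:
    df = pd.read_csv(path, sep="\t")
    if "obs_id" not in df.columns:
        raise ValueError("annotations TSV needs an obs_id column")
    return SpotAnnotations(
        obs_ids=list(df["obs_id"].astype(str)),
        section_index=df["section_index"].to_numpy(int),
        array_x=df["array_x"].to_numpy(float),
        array_y=df["array_y"].to_numpy(float),
        domain=list(df["domain"].astype(str)) if "domain" in df.columns else None,
        pseudo_order=(
            df["pseudo_order"].to_numpy(float) if "pseudo_order" in df.columns else None
        ),
    )


def write_annotations(ann: SpotAnnotations, path) -> None:
    ann.to_dataframe().to_csv(path, sep="\t", index=False)


def read_labels(path) -> tuple[list[str], list[str]]:
    """Two-column TSV (obs_id, label) -> (obs_ids, labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return list(df[cols[0]]), list(df[cols[1]])
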