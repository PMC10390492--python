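"""Synthetic spatial atlases with planted ground truth.

The generator emulates the structure the downstream stages are designed to
detect: spatial domains spanning sections in which a planted pair of cell
types shares elevated deconvolution weight, ligand/receptor genes elevated
where the sender/receiver weight is high, monotone gradient genes along the
section axis, and domain-specific regulon activity. Counts are
negative-binomial (overdispersed) and weights Dirichlet (simplex-valued), so
calibration tests run under realistic variance. All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._logging import get_logger
from .datatypes import (
    CellTypeWeights,
    ExpressionMatrix,
    LRDatabase,
    LRPair,
    RegulonActivityMatrix,
    SignatureCollection,
    SpotAnnotations,
    SyntheticTruth,
)

log = get_logger(__name__)

# Gains translating effect_size into planted signal strength. Fixed design
# constants of the generator, not tunables: weight boost on the Dirichlet
# concentration of a planted pair inside its domain, expression gain tying
# ligand/receptor means to the matching weight, reference-cell elevation, and
# the gradient ramp amplitude.
WEIGHT_BOOST = 10.0
EXPRESSION_GAIN = 10.0
REFERENCE_GAIN = 4.0
GRADIENT_GAIN = 8.0

PLANTED_LR_BASE_MEAN = 0.2
DECOY_LR_BASE_MEAN = 2.0
BACKGROUND = "background"


@dataclass
class SyntheticAtlas:
    """Bundle returned by :func:`simulate_spatial_atlas`: the four planted
    objects plus the ligand-receptor database the generator planted and the
    per-gene baseline means needed to simulate matched reference cells."""

    expression: ExpressionMatrix
    annotations: SpotAnnotations
    weights: CellTypeWeights
    truth: SyntheticTruth
    lr_db: LRDatabase
    base_means: dict[str, float]
    effect_size: float


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean matrix and shape
    ``dispersion`` (variance = mean + mean^2 / dispersion)."""
    p = dispersion / (dispersion + np.maximum(mean, 1e-12))
    return rng.negative_binomial(dispersion, p)


def simulate_spatial_atlas(
    n_sections: int = 3,
    grid: tuple[int, int] = (12, 12),
    n_types: int = 6,
    n_genes: int = 120,
    effect_size: float = 1.5,
    noise_sd: float = 0.25,
    dispersion: float = 10.0,
    n_coloc_pairs: int = 2,
    n_lr_per_pair: int = 2,
    n_decoy_lr: int = 16,
    n_gradient_per_interval: int = 0,
    seed: int = 0,
) -> SyntheticAtlas:
    """Simulate a sectioned spot atlas with planted colocalization and
    ligand-receptor signal.

    Each planted cell-type pair owns a vertical domain band spanning all
    sections; inside the band the Dirichlet concentration of both types is
    boosted by a shared per-spot intensity so their weights co-vary
    positively. Ligand genes of planted pairs are elevated multiplicatively
    with the sender's weight and receptor genes with the receiver's, on low
    log-normal baselines, so co-expression concentrates in colocalized spots.
    Optional gradient genes ramp monotonically across every contiguous
    section interval. ``effect_size = 0`` yields a null atlas in which
    planted and decoy structure are indistinguishable.
    """
    nx, ny = grid
    if n_types < 4:
        raise ValueError("need at least 4 cell types")
    if nx * ny < 50:
        raise ValueError("grid must yield at least 50 spots per section")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if 2 * n_coloc_pairs > n_types:
        raise ValueError(
            f"cannot plant {n_coloc_pairs} disjoint pairs with {n_types} types"
        )
    rng = np.random.default_rng(seed)
    type_names = [f"type_{i + 1}" for i in range(n_types)]
    planted_pairs = [
        (type_names[2 * k], type_names[2 * k + 1]) for k in range(n_coloc_pairs)
    ]

    # --- spots, sections, domains (equal-width vertical bands) -------------
    n_spots = n_sections * nx * ny
    section_index, xs, ys, obs_ids, domain = [], [], [], [], []
    n_bands = n_coloc_pairs + 1
    for s in range(1, n_sections + 1):
        for ix in range(nx):
            band = min(ix * n_bands // nx, n_bands - 1)
            for iy in range(ny):
                obs_ids.append(f"s{s}_x{ix}_y{iy}")
                section_index.append(s)
                xs.append(float(ix))
                ys.append(float(iy))
                domain.append(
                    f"domain_{band + 1}" if band < n_coloc_pairs else BACKGROUND
                )
    section_index = np.array(section_index)
    domain = np.array(domain)

    # --- weights: Dirichlet with shared-intensity boosts in planted domains -
    alphas = np.ones((n_spots, n_types))
    for k, (a, b) in enumerate(planted_pairs):
        in_dom = domain == f"domain_{k + 1}"
        intensity = rng.uniform(0.5, 1.5, size=int(in_dom.sum()))
        boost = WEIGHT_BOOST * effect_size * intensity
        ia, ib = type_names.index(a), type_names.index(b)
        alphas[in_dom, ia] += boost
        alphas[in_dom, ib] += boost
    gammas = rng.standard_gamma(alphas)
    weights = gammas / gammas.sum(axis=1, keepdims=True)

    # --- genes ---------------------------------------------------------------
    gene_ids: list[str] = []
    base_means: dict[str, float] = {}
    planted_lr: list[tuple[str, str, str]] = []
    lr_pairs: list[LRPair] = []
    modes = ("secreted", "contact", "ecm")
    idx = 0
    lr_effect: list[tuple[str, str, str]] = []  # gene, role, type
    for k, (a, b) in enumerate(planted_pairs):
        for j in range(n_lr_per_pair):
            lig, rec = f"LigP{idx}", f"RecP{idx}"
            idx += 1
            pair_id = f"{lig}_{rec}"
            lr_pairs.append(LRPair(pair_id, [lig], [rec], "synthetic",
                                   modes[idx % 2]))
            planted_lr.append((a, b, pair_id))
            gene_ids += [lig, rec]
            base_means[lig] = base_means[rec] = PLANTED_LR_BASE_MEAN
            lr_effect += [(lig, "ligand", a), (rec, "receptor", b)]
    decoy_lr_ids = []
    for j in range(n_decoy_lr):
        lig, rec = f"LigD{j}", f"RecD{j}"
        pair_id = f"{lig}_{rec}"
        lr_pairs.append(LRPair(pair_id, [lig], [rec], "synthetic", modes[j % 2]))
        decoy_lr_ids.append(pair_id)
        gene_ids += [lig, rec]
        base_means[lig] = base_means[rec] = DECOY_LR_BASE_MEAN

    gradient_genes: dict[str, tuple[int, int]] = {}
    if n_gradient_per_interval > 0:
        for start in range(1, n_sections + 1):
            for end in range(start + 1, min(start + n_sections - 1, n_sections) + 1):
                if end - start + 1 > n_sections - 1:
                    continue
                for c in range(n_gradient_per_interval):
                    g = f"Grad_{start}_{end}_{c}"
                    gradient_genes[g] = (start, end)
                    gene_ids.append(g)
                    base_means[g] = 1.0

    n_filler = n_genes - len(gene_ids)
    if n_filler < 1:
        raise ValueError(
            f"n_genes={n_genes} too small for {len(gene_ids)} planted genes"
        )
    filler = [f"gene_{i}" for i in range(n_filler)]
    filler_means = np.exp(rng.normal(0.0, 1.0, size=n_filler))
    filler_means[0] = 50.0  # housekeeping anchor keeps every spot total > 0
    for g, m in zip(filler, filler_means):
        base_means[g] = float(m)
    gene_ids += filler

    # --- per-spot means and counts ------------------------------------------
    base = np.array([base_means[g] for g in gene_ids])
    mu = base[:, None] * np.exp(rng.normal(0.0, noise_sd, size=(len(gene_ids),
                                                                n_spots)))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for gene, role, typ in lr_effect:
        w = weights[:, type_names.index(typ)]
        mu[gpos[gene]] *= 1.0 + EXPRESSION_GAIN * effect_size * w
    for gene, (start, end) in gradient_genes.items():
        length = end - start + 1
        ramp = np.ones(n_spots)
        inside = (section_index >= start) & (section_index <= end)
        rel = (section_index[inside] - start + 1) / length
        ramp[inside] = 1.0 + GRADIENT_GAIN * effect_size * rel
        mu[gpos[gene]] *= ramp

    counts = _nb_counts(rng, mu, dispersion)

    order = np.lexsort((np.array(xs), np.array(ys), section_index))
    pseudo_order = np.empty(n_spots)
    pseudo_order[order] = np.arange(n_spots, dtype=float)

    expression = ExpressionMatrix(counts, gene_ids, obs_ids, layer="raw_counts")
    annotations = SpotAnnotations(
        obs_ids=list(obs_ids),
        section_index=section_index,
        array_x=np.array(xs),
        array_y=np.array(ys),
        domain=list(domain),
        pseudo_order=pseudo_order,
    )
    truth = SyntheticTruth(
        planted_coloc_pairs=planted_pairs,
        planted_lr=planted_lr,
        planted_gradient_genes=gradient_genes,
        decoy_lr=decoy_lr_ids,
        decoy_genes=filler,
    )
    log.info("simulate_spatial_atlas: %d spots x %d genes, %d types, "
             "effect_size=%g, seed=%d", n_spots, len(gene_ids), n_types,
             effect_size, seed)
    return SyntheticAtlas(
        expression=expression,
        annotations=annotations,
        weights=CellTypeWeights(weights, list(obs_ids), type_names),
        truth=truth,
        lr_db=LRDatabase(lr_pairs),
        base_means=base_means,
        effect_size=effect_size,
    )


def simulate_reference_cells(
    atlas: SyntheticAtlas,
    n_cells_per_type: int = 50,
    dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Reference single cells matched to an atlas: per-type negative-binomial
    counts on the atlas gene baselines, with each planted ligand elevated in
    its sender type and each planted receptor in its receiver type."""
    rng = np.random.default_rng(seed)
    gene_ids = list(atlas.expression.gene_ids)
    type_names = list(atlas.weights.type_names)
    base = np.array([atlas.base_means[g] for g in gene_ids])
    means = np.tile(base[:, None], (1, len(type_names)))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    lut = {p.pair_id: p for p in atlas.lr_db}
    mult = 1.0 + REFERENCE_GAIN * atlas.effect_size
    for sender, receiver, pair_id in atlas.truth.planted_lr:
        pair = lut[pair_id]
        for g in pair.ligand_subunits:
            means[gpos[g], type_names.index(sender)] = atlas.base_means[g] * mult
        for g in pair.receptor_subunits:
            means[gpos[g], type_names.index(receiver)] = atlas.base_means[g] * mult
    cols, labels, obs_ids = [], [], []
    for t, typ in enumerate(type_names):
        mu = np.tile(means[:, [t]], (1, n_cells_per_type))
        cols.append(_nb_counts(rng, mu, dispersion))
        labels += [typ] * n_cells_per_type
        obs_ids += [f"{typ}_cell_{i}" for i in range(n_cells_per_type)]
    counts = np.concatenate(cols, axis=1)
    # guarantee positive totals for log-normalization
    counts[0, counts.sum(axis=0) == 0] = 1
    em = ExpressionMatrix(counts, gene_ids, obs_ids, layer="raw_counts")
    return em, labels


def simulate_regulon_activity(
    n_regulons: int,
    domains,
    specificity: float,
    seed: int = 0,
    noise_sd: float = 0.05,
    baseline: float = 0.0,
) -> tuple[RegulonActivityMatrix, SyntheticTruth]:
    """Regulon activity with one planted regulon per non-background domain.

    Planted activity is ``baseline + specificity`` inside the domain and
    ``baseline`` outside, plus Gaussian noise, clipped to [0, 1]; remaining
    regulons are pure-noise decoys. ``specificity = 1`` with ``noise_sd = 0``
    and zero baseline gives the exact domain indicator, and ``specificity = 0``
    has no domain preference.
    """
    if not 0 <= specificity <= 1:
        raise ValueError("specificity must be in [0, 1]")
    domains = np.asarray([str(d) for d in domains])
    planted_domains = sorted(d for d in np.unique(domains) if d != BACKGROUND)
    if n_regulons < len(planted_domains):
        raise ValueError(
            f"need at least {len(planted_domains)} regulons to plant "
            f"{len(planted_domains)} domains"
        )
    rng = np.random.default_rng(seed)
    n_spots = len(domains)
    names, cols = [], []
    mapping = {}
    for dom in planted_domains:
        name = f"Reg_{dom}"
        ind = (domains == dom).astype(float)
        act = baseline + specificity * ind
        if noise_sd > 0:
            act = act + rng.normal(0.0, noise_sd, size=n_spots)
        names.append(name)
        cols.append(np.clip(act, 0.0, 1.0))
        mapping[name] = dom
    for i in range(n_regulons - len(planted_domains)):
        act = np.full(n_spots, baseline)
        if noise_sd > 0:
            act = act + rng.normal(0.0, noise_sd, size=n_spots)
        names.append(f"Reg_decoy_{i}")
        cols.append(np.clip(act, 0.0, 1.0))
    ras = RegulonActivityMatrix(
        np.column_stack(cols), [f"spot_{i}" for i in range(n_spots)], names
    )
    truth = SyntheticTruth(planted_domain_regulons=mapping,
                           decoy_genes=[n for n in names if n not in mapping])
    return ras, truth


def simulate_gradient_regulons(
    pseudo_order,
    n_planted: int = 5,
    n_decoy: int = 45,
    amplitude: float = 0.8,
    noise_sd: float = 0.03,
    decoy_level: float = 0.05,
    seed: int = 0,
) -> tuple[RegulonActivityMatrix, list[str]]:
    """Monotone-gradient regulons along a pseudo-space ordering among flat
    decoys (signs alternate between planted regulons)."""
    order = np.asarray(pseudo_order, dtype=float)
    t = (order.argsort().argsort()) / max(len(order) - 1, 1)
    rng = np.random.default_rng(seed)
    names, cols = [], []
    for i in range(n_planted):
        ramp = t if i % 2 == 0 else 1.0 - t
        act = amplitude * ramp + rng.normal(0.0, noise_sd, size=len(order))
        names.append(f"Reg_grad_{i}")
        cols.append(np.clip(act, 0.0, 1.0))
    for i in range(n_decoy):
        act = decoy_level + rng.normal(0.0, noise_sd, size=len(order))
        names.append(f"Reg_flat_{i}")
        cols.append(np.clip(act, 0.0, 1.0))
    ras = RegulonActivityMatrix(
        np.column_stack(cols), [f"spot_{i}" for i in range(len(order))], names
    )
    return ras, names[:n_planted]


def simulate_regulon_blocks(
    n_per_block: int = 5,
    n_spots: int = 300,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[RegulonActivityMatrix, dict[str, int]]:
    """Two blocks of mutually co-activated regulons driven by independent
    latent factors; the planted partition is the ground truth for module
    recovery."""
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0.1, 0.9, size=n_spots)
    f2 = rng.uniform(0.1, 0.9, size=n_spots)
    names, cols, truth = [], [], {}
    for b, f in enumerate((f1, f2), start=1):
        for i in range(n_per_block):
            name = f"Reg_b{b}_{i}"
            names.append(name)
            truth[name] = b
            cols.append(np.clip(f + rng.normal(0.0, noise_sd, n_spots), 0, 1))
    ras = RegulonActivityMatrix(
        np.column_stack(cols), [f"spot_{i}" for i in range(n_spots)], names
    )
    return ras, truth


def simulate_dmv_cord(
    n_spots_per_band: int = 80,
    n_genes: int = 300,
    genes_per_set: int = 15,
    effect: float = 8.0,
    noise_sd: float = 0.2,
    dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], SignatureCollection]:
    """Synthetic spinal-cord cross-section with dorsal / middle / ventral
    marker bands: each region's marker set is elevated ``(1 + effect)``-fold
    inside its band. Returns raw counts, per-spot band labels and the three
    marker gene sets."""
    rng = np.random.default_rng(seed)
    bands = ["D", "M", "V"]
    labels = sum(([b] * n_spots_per_band for b in bands), [])
    n_spots = len(labels)
    n_markers = genes_per_set * 3
    if n_genes <= n_markers:
        raise ValueError("n_genes must exceed the total marker count")
    gene_ids, sets = [], {}
    for b in bands:
        sets[b] = [f"{b}_marker_{i}" for i in range(genes_per_set)]
        gene_ids += sets[b]
    gene_ids += [f"gene_{i}" for i in range(n_genes - n_markers)]
    base = np.concatenate([
        np.full(n_markers, 1.0),
        np.exp(rng.normal(0.0, 0.5, size=n_genes - n_markers)),
    ])
    mu = base[:, None] * np.exp(rng.normal(0.0, noise_sd, size=(n_genes, n_spots)))
    labels_arr = np.array(labels)
    for bi, b in enumerate(bands):
        in_band = labels_arr == b
        rows = slice(bi * genes_per_set, (bi + 1) * genes_per_set)
        mu[rows, :][:, in_band] *= 1.0 + effect
    counts = _nb_counts(rng, mu, dispersion)
    counts[0, counts.sum(axis=0) == 0] = 1
    em = ExpressionMatrix(
        counts, gene_ids, [f"spot_{i}" for i in range(n_spots)], layer="raw_counts"
    )
    return em, labels, SignatureCollection(sets, {b: "region" for b in bands})


PRESETS = ("coloc-demo", "null", "gradient")


def simulate_preset(preset: str, seed: int = 0) -> SyntheticAtlas:
    """Named study conditions: ``coloc-demo`` (planted colocalization and
    ligand-receptor signal), ``null`` (same structure, zero effect) and
    ``gradient`` (nine sections with two monotone genes per contiguous
    section interval among flat decoys)."""
    if preset == "coloc-demo":
        return simulate_spatial_atlas(seed=seed)
    if preset == "null":
        return simulate_spatial_atlas(effect_size=0.0, seed=seed)
    if preset == "gradient":
        return simulate_spatial_atlas(
            n_sections=9,
            grid=(10, 10),
            n_genes=400,
            n_coloc_pairs=2,
            n_lr_per_pair=2,
            n_decoy_lr=16,
            n_gradient_per_interval=2,
            seed=seed,
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def write_fixture_set(atlas: SyntheticAtlas, out_dir) -> None:
    """Write a full fixture set in the standard on-disk formats."""
    from . import io as stio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stio.write_count_matrix(atlas.expression, out / "matrix", fmt="mtx")
    stio.write_annotations(atlas.annotations, out / "spots.tsv")
    stio.write_weights(atlas.weights, out / "weights.tsv")
    stio.write_lr_database(atlas.lr_db, out / "lr_pairs.tsv")
    truth = {
        "planted_coloc_pairs": [list(p) for p in atlas.truth.planted_coloc_pairs],
        "planted_lr": [list(t) for t in atlas.truth.planted_lr],
        "planted_gradient_genes": {
            g: list(v) for g, v in atlas.truth.planted_gradient_genes.items()
        },
        "decoy_lr": atlas.truth.decoy_lr,
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
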