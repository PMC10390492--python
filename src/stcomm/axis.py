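"""Body-axis patterning statistics for a sectioned spatial atlas.

Anterior-posterior (A-P) structure is screened by correlating gene expression
against every contiguous run of sections ("section patterns") and taking the
union of the top-k genes per pattern. Dorsal-ventral (D-V) structure uses
gene-set recovery-AUC scores per region band, z-score or bimodal binarization,
and rank-sum differential tests. Axis-related regulons are selected from their
activity's correlation with a supplied pseudo-space ordering (|PCC| above a
multiple of the PCC spread) combined with a minimum peak activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logging import get_logger
from ._stats import bh_adjust
from .datatypes import (
    LOGNORM,
    ExpressionMatrix,
    RegulonActivityMatrix,
    SignatureCollection,
    SpotAnnotations,
)
from .regulons import auc_recovery_score

log = get_logger(__name__)


@dataclass
class SectionPattern:
    """One contiguous run of sections along the ordered section list."""

    start: int   # 0-based position in the ordered section list
    length: int
    mask: np.ndarray  # boolean over ordered sections

    @property
    def pattern_id(self) -> str:
        return f"S{self.start + 1}-{self.start + self.length}"


def enumerate_section_patterns(
    n_sections: int,
    min_len: int = 2,
    max_len: int | None = None,
) -> list[SectionPattern]:
    """All contiguous section runs with length in [min_len, max_len]
    (default bounds [2, n_sections - 1]), ordered by (start, length).

    The count is sum over lengths of (n_sections - length + 1); nine ordered
    sections with default bounds give 35 patterns.
    """
    if n_sections < 3:
        raise ValueError("need at least 3 sections")
    if max_len is None:
        max_len = n_sections - 1
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    patterns = []
    for start in range(n_sections):
        for length in range(min_len, max_len + 1):
            if start + length > n_sections:
                break
            mask = np.zeros(n_sections, dtype=bool)
            mask[start:start + length] = True
            patterns.append(SectionPattern(start=start, length=length, mask=mask))
    patterns.sort(key=lambda p: (p.start, p.length))
    return patterns


@dataclass
class AxisGeneTable:
    """Long-format gene x pattern correlations with selection flags."""

    table: pd.DataFrame  # gene, pattern_id, pcc, rank, selected

    @property
    def selected_genes(self) -> set[str]:
        sel = self.table[self.table["selected"]]
        return set(sel["gene"])


def ap_pattern_genes(
    em: ExpressionMatrix,
    ann: SpotAnnotations,
    candidate_genes,
    top_k: int = 20,
    min_len: int = 2,
    max_len: int | None = None,
) -> AxisGeneTable:
    """Correlate candidate genes against contiguous section patterns and select
    the union of the top-k PCC genes per pattern.

    The pattern indicator is broadcast to spots (every spot of a section gets
    the section's 0/1 value). Genes constant over the region are skipped.
    """
    if em.obs_ids != ann.obs_ids:
        raise ValueError("expression and annotation spot ids differ")
    sections = np.unique(ann.section_index)
    counts = {s: int(np.sum(ann.section_index == s)) for s in sections}
    small = [s for s, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"sections with fewer than 3 spots: {small}")
    patterns = enumerate_section_patterns(len(sections), min_len, max_len)
    sec_pos = {s: i for i, s in enumerate(sections)}
    spot_pos = np.array([sec_pos[s] for s in ann.section_index])

    candidate_genes = list(candidate_genes)
    idx = em.gene_index(candidate_genes)
    X = em.values[idx, :].astype(float)  # genes x spots
    sd = X.std(axis=1)
    usable = sd > 0
    skipped = [g for g, u in zip(candidate_genes, usable) if not u]
    if skipped:
        log.warning("ap_pattern_genes: constant genes skipped: %s", skipped[:10])
    genes = [g for g, u in zip(candidate_genes, usable) if u]
    X = X[usable]
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    ind = np.stack([p.mask[spot_pos].astype(float) for p in patterns])  # pat x spots
    ind_z = (ind - ind.mean(axis=1, keepdims=True)) / ind.std(axis=1, keepdims=True)
    pcc = Xz @ ind_z.T / em.n_obs  # genes x patterns

    k = min(top_k, len(genes))
    rows = []
    for j, pat in enumerate(patterns):
        # stable deterministic ranking: by descending pcc then gene name
        order = sorted(range(len(genes)), key=lambda g: (-pcc[g, j], genes[g]))
        for rank, g in enumerate(order, start=1):
            rows.append((genes[g], pat.pattern_id, pcc[g, j], rank, rank <= k))
    table = pd.DataFrame(rows, columns=["gene", "pattern_id", "pcc", "rank",
                                        "selected"])
    n_sel = table[table["selected"]]["gene"].nunique()
    log.info("ap_pattern_genes: %d genes selected from %d candidates over %d "
             "patterns (top_k=%d)", n_sel, len(genes), len(patterns), top_k)
    return AxisGeneTable(table)


def region_activity_scores(
    em: ExpressionMatrix,
    sigs: SignatureCollection,
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery-AUC activity of each region gene set per spot (spots x regions)."""
    coll, flagged = sigs.intersect(em.gene_ids)
    if flagged:
        raise ValueError(f"region sets with no genes in the matrix: {flagged}")
    scores = {name: auc_recovery_score(em, set(coll[name]), top_frac, seed)
              for name in coll.names}
    return pd.DataFrame(scores, index=em.obs_ids)


def binarize_scores(
    scores: pd.DataFrame,
    method: str = "zscore",
    z_min: float = 2.5,
) -> pd.DataFrame:
    """Zero out low region scores.

    ``"zscore"`` zeroes entries whose column z-score falls below ``z_min``.
    ``"bimodal"`` splits each column into two groups at the split minimizing
    within-group variance and zeroes entries below the midpoint of the two
    group means; a degenerate column (no valid split) is passed through with a
    warning.
    """
    out = scores.copy()
    for col in scores.columns:
        v = scores[col].to_numpy(float)
        if method == "zscore":
            sd = v.std()
            if sd == 0:
                raise ValueError(f"zero-variance score column {col!r}")
            z = (v - v.mean()) / sd
            out[col] = np.where(z < z_min, 0.0, v)
        elif method == "bimodal":
            thr = _bimodal_threshold(v)
            if thr is None:
                warnings.warn(f"column {col!r} has no bimodal split; passed through")
                continue
            out[col] = np.where(v < thr, 0.0, v)
        else:
            raise ValueError(f"unknown binarization method {method!r}")
    return out


def _bimodal_threshold(v: np.ndarray) -> float | None:
    """Midpoint between the two group means of the 1-D split minimizing total
    within-group sum of squares (a binary-assignment surrogate)."""
    s = np.sort(v)
    n = len(s)
    if n < 2 or s[0] == s[-1]:
        return None
    csum = np.cumsum(s)
    total = csum[-1]
    best, best_cut = np.inf, None
    for i in range(1, n):  # lower group = s[:i]
        if s[i - 1] == s[i]:
            continue
        m1 = csum[i - 1] / i
        m2 = (total - csum[i - 1]) / (n - i)
        ss = (np.sum((s[:i] - m1) ** 2) + np.sum((s[i:] - m2) ** 2))
        if ss < best:
            best, best_cut = ss, (m1 + m2) / 2.0
    return best_cut


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided"):
    """Rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 12 with no
    ties; otherwise the normal approximation with tie and continuity
    correction. Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        # all values identical: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def dv_domain_genes(
    em: ExpressionMatrix,
    dmv_labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest rank-sum differential expression across the D/M/V region
    labels with BH correction pooled over all (gene, region) tests.

    Returns a long table (gene, region, U, p, q, significant); genes with
    q < alpha in some region are axis-related.
    """
    labels = np.asarray([str(x) for x in dmv_labels])
    if labels.shape[0] != em.n_obs:
        raise ValueError("labels must have one entry per spot")
    regions = sorted(np.unique(labels))
    for reg in regions:
        if np.sum(labels == reg) < 3:
            raise ValueError(f"region {reg!r} has fewer than 3 spots")
    rows = []
    for reg in regions:
        mask = labels == reg
        for gi, gene in enumerate(em.gene_ids):
            u, p = wilcoxon_rank_sum(em.values[gi, mask], em.values[gi, ~mask])
            rows.append((gene, reg, u, p))
    table = pd.DataFrame(rows, columns=["gene", "region", "U", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table


def ap_regulon_selection(
    ras: RegulonActivityMatrix,
    pseudo_order,
    sd_mult: float = 1.5,
    min_max_ras: float = 0.2,
) -> pd.DataFrame:
    """Select regulons patterned along the pseudo-space ordering.

    A regulon is selected when |PCC(activity, pseudo_order)| exceeds
    ``sd_mult`` times the SD of all regulons' PCCs and its maximum activity
    strictly exceeds ``min_max_ras``.
    """
    order = np.asarray(pseudo_order, dtype=float)
    if order.shape[0] != ras.n_spots:
        raise ValueError("pseudo_order must have one value per spot")
    if np.any(~np.isfinite(order)):
        raise ValueError("pseudo_order contains non-finite values")
    oz = (order - order.mean()) / order.std()
    pccs = []
    for i in range(len(ras.regulon_names)):
        v = ras.values[:, i]
        sd = v.std()
        pccs.append(np.nan if sd == 0 else float(np.mean((v - v.mean()) / sd * oz)))
    pccs = np.asarray(pccs)
    spread = np.nanstd(pccs)
    max_ras = ras.values.max(axis=0)
    selected = (np.abs(pccs) > sd_mult * spread) & (max_ras > min_max_ras)
    selected &= np.isfinite(pccs)
    table = pd.DataFrame(
        {"regulon": ras.regulon_names, "pcc": pccs, "max_ras": max_ras,
         "selected": selected}
    )
    log.info("ap_regulon_selection: %d/%d regulons selected "
             "(|pcc| > %g x SD=%g, max_ras > %g)", int(selected.sum()),
             len(table), sd_mult, spread, min_max_ras)
    return table


def dv_regulon_selection(
    ras: RegulonActivityMatrix,
    dmv_labels,
    min_max_ras: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select regulons differentially active across D/M/V region labels.

    One-vs-rest rank-sum per region on activity columns, BH pooled over all
    tests; a regulon is selected when any region is significant and its
    maximum activity strictly exceeds ``min_max_ras``.
    """
    labels = np.asarray([str(x) for x in dmv_labels])
    regions = sorted(np.unique(labels))
    for reg in regions:
        if np.sum(labels == reg) < 3:
            raise ValueError(f"region {reg!r} has fewer than 3 spots")
    rows = []
    for reg in regions:
        mask = labels == reg
        for i, name in enumerate(ras.regulon_names):
            u, p = wilcoxon_rank_sum(ras.values[mask, i], ras.values[~mask, i])
            rows.append((name, reg, u, p))
    table = pd.DataFrame(rows, columns=["regulon", "region", "U", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    max_ras = dict(zip(ras.regulon_names, ras.values.max(axis=0)))
    table["max_ras"] = table["regulon"].map(max_ras)
    table["selected"] = table["significant"] & (table["max_ras"] > min_max_ras)
    return table


def module_score(
    em: ExpressionMatrix,
    signature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Signature score per spot: mean signature expression minus the mean of an
    expression-matched control gene set.

    Genes are binned into ``n_bins`` equal-size bins by average expression
    across spots; for every signature gene, ``n_ctrl`` control genes are
    sampled with replacement from its bin (seeded) and the pooled unique
    control set is averaged. When a bin contains only the signature genes the
    control set coincides with the signature and the score is 0.
    """
    if em.layer != LOGNORM:
        raise ValueError("module_score expects a lognorm matrix")
    if n_bins > em.n_genes:
        raise ValueError("n_bins exceeds the number of genes")
    sig = [g for g in signature if g in set(em.gene_ids)]
    if not sig:
        raise ValueError("signature has no genes in the matrix")
    avg = em.values.mean(axis=1)
    order = np.argsort(np.argsort(avg, kind="stable"), kind="stable")
    bins = np.floor(order * n_bins / em.n_genes).astype(int)
    rng = np.random.default_rng(seed)
    sig_idx = em.gene_index(sig)
    control: set[int] = set()
    for gi in sig_idx:
        bin_members = np.flatnonzero(bins == bins[gi])
        control.update(rng.choice(bin_members, size=n_ctrl, replace=True).tolist())
    ctrl_idx = np.array(sorted(control))
    return em.values[sig_idx].mean(axis=0) - em.values[ctrl_idx].mean(axis=0)


def cell_cycle_phase(
    em: ExpressionMatrix,
    s_genes,
    g2m_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """S and G2M module scores per spot with the standard phase call:
    G1 when both scores are <= 0, otherwise the larger score's phase."""
    s_score = module_score(em, s_genes, n_bins, n_ctrl, seed)
    g2m_score = module_score(em, g2m_genes, n_bins, n_ctrl, seed)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0), "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=em.obs_ids,
    )
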