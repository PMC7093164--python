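"""Statistical core of the coordination analysis.

High-expression filtering against the reference group, within-group pairwise
Pearson correlation, transcriptome-wide correlation profiles per seed gene,
the composite correlation Pc between a seed's reference and condition
profiles, Pc ranking, and correlated-set extraction.

Undefined statistics (constant vectors, too-small backgrounds) are explicit:
``None`` for scalars, NaN plus a mask for matrix entries — never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from genecoord.io import AnalysisConfig, ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson R among a gene set within one group.

    Entries involving a zero-variance gene are undefined and stored as NaN;
    ``defined`` exposes the mask. Diagonal is exactly 1 for genes with
    nonzero variance.
    """

    gene_ids: list[str]
    values: np.ndarray
    group: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def offdiagonal(self) -> np.ndarray:
        """Defined off-diagonal entries (each unordered pair once)."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]


@dataclass
class CorrelationProfile:
    """One seed gene's Pearson R against the shared transcriptome background."""

    seed_gene: str
    group: str
    background_gene_ids: list[str]
    r_values: np.ndarray  # NaN marks undefined entries


@dataclass
class ProfilePair:
    """Index-aligned reference/condition profiles for one seed gene."""

    seed_gene: str
    ref: CorrelationProfile
    cond: CorrelationProfile


@dataclass
class PcRecord:
    """A seed gene's composite correlation between its two group profiles."""

    seed_gene: str
    pc: float | None
    n_common_background: int

    @property
    def defined(self) -> bool:
        return self.pc is not None


@dataclass
class PcRanking:
    """Seed genes sorted by ascending Pc; undefined records listed last."""

    records: list[PcRecord]
    bottom: list[PcRecord] = field(default_factory=list)
    top: list[PcRecord] = field(default_factory=list)


class GeneSet:
    """Genes whose R with a seed gene exceeds the cutoff within one group."""

    def __init__(self, seed_gene: str, group: str,
                 gene_ids: Sequence[str], r_values: Sequence[float]):
        self.seed_gene = seed_gene
        self.group = group
        self.gene_ids = list(gene_ids)
        self.r_values = [float(r) for r in r_values]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def as_set(self) -> set[str]:
        return set(self.gene_ids)


# ---------------------------------------------------------------------------
# transforms and low-level correlation
# ---------------------------------------------------------------------------


def apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    """Apply the configured expression transform to a genes x samples array.

    ``cpm_log1p`` scales each sample to counts-per-million before log1p, so
    library-size differences cannot drive correlations.
    """
    if transform == "none":
        return np.asarray(values, dtype=np.float64)
    if transform == "log1p":
        return np.log1p(values)
    if transform == "cpm_log1p":
        totals = values.sum(axis=0, keepdims=True)
        totals = np.where(totals > 0, totals, 1.0)
        return np.log1p(values / totals * 1e6)
    raise ValueError(f"unknown transform {transform!r}")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; ``None`` if either vector is constant.

    Requires equal lengths of at least 3.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1-D with length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.dot(xc, yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (standardized, valid mask)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered * centered, axis=1))
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    return centered / safe[:, None], valid


def _group_column_indices(matrix: ExpressionMatrix, design: SampleDesign,
                          group: str) -> np.ndarray:
    sample_idx = matrix.sample_index()
    missing = [s for s in design.samples(group) if s not in sample_idx]
    if missing:
        raise ValueError(
            f"group {group!r} samples missing from the matrix: {missing[:5]}"
        )
    return np.array([sample_idx[s] for s in design.samples(group)], dtype=int)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def filter_high_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: AnalysisConfig,
) -> list[str]:
    """Genes whose aggregated reference-group value is at least ``min_reads``.

    Aggregation over the reference samples is ``config.read_aggregation``
    (mean by default). The threshold is inclusive. Gene order is preserved.
    """
    cols = _group_column_indices(matrix, design, design.reference_label)
    sub = matrix.values[:, cols]
    if config.read_aggregation == "mean":
        agg = sub.mean(axis=1)
    elif config.read_aggregation == "min":
        agg = sub.min(axis=1)
    else:
        agg = sub.sum(axis=1)
    keep = agg >= config.min_reads
    selected = [g for g, k in zip(matrix.gene_ids, keep) if k]
    logger.info(
        "high-expression filter (%s >= %g in %s): %d of %d genes pass",
        config.read_aggregation, config.min_reads, design.reference_label,
        len(selected), matrix.n_genes,
    )
    if not selected:
        logger.warning("no gene passes the high-expression filter")
    return selected


def pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    design: SampleDesign,
    group: str,
    config: AnalysisConfig,
) -> CorrelationMatrix:
    """Symmetric Pearson correlation among ``genes`` over one group's samples."""
    gene_idx = matrix.gene_index()
    unknown = [g for g in genes if g not in gene_idx]
    if unknown:
        raise KeyError(f"unknown gene identifiers: {unknown[:5]}")
    cols = _group_column_indices(matrix, design, group)
    transformed = apply_transform(matrix.values[:, cols], config.transform)
    rows = np.array([gene_idx[g] for g in genes], dtype=int)
    std, valid = _standardize_rows(transformed[rows])
    corr = std @ std.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("%d zero-variance genes in group %s flagged undefined",
                    n_invalid, group)
    return CorrelationMatrix(gene_ids=list(genes), values=corr, group=group)


@dataclass
class CoherenceSummary:
    """Aggregate statistics over a correlation matrix's defined off-diagonal."""

    mean_r: float
    mean_abs_r: float
    _offdiag: np.ndarray

    def fraction_above(self, tau: float) -> float:
        return float(np.mean(self._offdiag > tau))


def coherence_summary(cm: CorrelationMatrix) -> CoherenceSummary:
    """Mean R, mean |R| and exceedance fractions over defined off-diagonal pairs."""
    off = cm.offdiagonal()
    if off.size == 0:
        raise ValueError(
            f"correlation matrix for group {cm.group!r} has no defined "
            "off-diagonal entries"
        )
    return CoherenceSummary(
        mean_r=float(off.mean()),
        mean_abs_r=float(np.abs(off).mean()),
        _offdiag=off,
    )


def transcriptome_profiles(
    matrix: ExpressionMatrix,
    seed_genes: Sequence[str],
    design: SampleDesign,
    config: AnalysisConfig,
) -> dict[str, ProfilePair]:
    """Per-seed correlation profiles against the whole transcriptome, per group.

    The background for every seed is the full gene list minus the seed itself
    minus genes with zero variance in either group, so the two groups' profiles
    are index-aligned over one shared background. A seed that is itself
    constant in a group gets an all-undefined profile there (its Pc will be
    undefined downstream).
    """
    gene_idx = matrix.gene_index()
    unknown = [g for g in seed_genes if g not in gene_idx]
    if unknown:
        raise KeyError(f"unknown seed gene identifiers: {unknown[:5]}")
    seeds: list[str] = []
    for g in seed_genes:
        if g in seeds:
            logger.warning("duplicate seed gene %r ignored", g)
        else:
            seeds.append(g)

    groups = {
        "ref": design.reference_label,
        "cond": design.condition_label,
    }
    transformed: dict[str, np.ndarray] = {}
    std: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for key, label in groups.items():
        cols = _group_column_indices(matrix, design, label)
        transformed[key] = apply_transform(matrix.values[:, cols], config.transform)
        std[key], valid[key] = _standardize_rows(transformed[key])

    shared_valid = valid["ref"] & valid["cond"]
    n_dropped = int((~shared_valid).sum())
    if n_dropped:
        logger.info(
            "excluding %d genes constant in at least one group from all "
            "profile backgrounds", n_dropped,
        )

    seed_rows = np.array([gene_idx[g] for g in seeds], dtype=int)
    # R[seed, gene] per group; rows for invalid genes are zero-padded in std,
    # masked below.
    r_by_group = {key: std[key][seed_rows] @ std[key].T for key in groups}
    for key in groups:
        np.clip(r_by_group[key], -1.0, 1.0, out=r_by_group[key])

    out: dict[str, ProfilePair] = {}
    for i, seed in enumerate(seeds):
        bg_mask = shared_valid.copy()
        bg_mask[gene_idx[seed]] = False
        bg_ids = [g for g, m in zip(matrix.gene_ids, bg_mask) if m]
        profiles = {}
        for key, label in groups.items():
            r = r_by_group[key][i, bg_mask]
            if not valid[key][gene_idx[seed]]:
                r = np.full(len(bg_ids), np.nan)
            profiles[key] = CorrelationProfile(
                seed_gene=seed, group=label,
                background_gene_ids=bg_ids, r_values=np.asarray(r, dtype=np.float64),
            )
        out[seed] = ProfilePair(seed_gene=seed, ref=profiles["ref"],
                                cond=profiles["cond"])
    return out


def composite_correlation(
    profile_ref: CorrelationProfile,
    profile_cond: CorrelationProfile,
    config: AnalysisConfig,
) -> PcRecord:
    """Pc: correlation between a seed's two group profiles.

    Computed (Pearson by default, Spearman optionally) over background
    positions where both profiles are defined; undefined when fewer than 3
    such positions remain or either restricted profile is constant.
    """
    if profile_ref.seed_gene != profile_cond.seed_gene:
        raise ValueError(
            f"mismatched seeds: {profile_ref.seed_gene!r} vs "
            f"{profile_cond.seed_gene!r}"
        )
    if profile_ref.background_gene_ids != profile_cond.background_gene_ids:
        raise ValueError("profiles have different backgrounds; not index-aligned")
    x = profile_ref.r_values
    y = profile_cond.r_values
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return PcRecord(profile_ref.seed_gene, None, n)
    xv, yv = x[mask], y[mask]
    if config.pc_method == "spearman":
        xv, yv = rankdata(xv), rankdata(yv)
    pc = pearson_r(xv, yv)
    return PcRecord(profile_ref.seed_gene, pc, n)


def rank_by_pc(records: Sequence[PcRecord], config: AnalysisConfig) -> PcRanking:
    """Ascending Pc ranking (lost coordination first) with bottom/top selections.

    Ties break lexicographically by seed gene; undefined records sort last and
    are never selected.
    """
    defined = sorted(
        (r for r in records if r.defined), key=lambda r: (r.pc, r.seed_gene)
    )
    undefined = sorted(
        (r for r in records if not r.defined), key=lambda r: r.seed_gene
    )
    if not defined:
        raise ValueError("all Pc records are undefined; nothing to rank")
    bottom = defined[: config.bottom_k]
    top = list(reversed(defined[-config.top_k:]))
    return PcRanking(records=defined + undefined, bottom=bottom, top=top)


def extract_correlated_set(
    profile: CorrelationProfile,
    config: AnalysisConfig,
) -> GeneSet:
    """Background genes with defined R strictly greater than the cutoff."""
    keep = np.isfinite(profile.r_values) & (profile.r_values > config.r_cutoff)
    gene_ids = [g for g, k in zip(profile.background_gene_ids, keep) if k]
    r_values = profile.r_values[keep]
    if not gene_ids:
        logger.info(
            "seed %s, group %s: empty correlated set at R > %g",
            profile.seed_gene, profile.group, config.r_cutoff,
        )
    return GeneSet(profile.seed_gene, profile.group, gene_ids, r_values)
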