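"""Marker-region selection via one-vs-rest moderated linear models.

For each level of a categorical phenotype, expression at every region is
regressed on an intercept and a 0/1 level indicator; variances are shrunk
by empirical Bayes (see :mod:`.moderation`) and the n regions with the
smallest moderated-t p-values per level form the predictor's region set.
Tests are two-sided: a marker may be under- or over-expressed in a level.

Genome-scale inputs that arrive in chunks (e.g. one file per chromosome)
are handled by :func:`filter_regions` + :func:`merge_input`: per-region
statistics are chunk-independent, and each chunk carries the sufficient
moments of its log variances so the merged pool reproduces the global
empirical-Bayes fit before the final re-ranking. Chunk ``n_keep`` must be
at least the final per-level ``n`` for the merged selection to match
unchunked selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .moderation import (
    LogVarianceMoments,
    VariancePrior,
    log_variance_moments,
    moderated_t_pvalues,
    prior_from_moments,
    squeeze_variances,
)
from .phenotypes import PhenotypeTable
from .regions import Region

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class OneVsRestDesign:
    """0/1 indicator design contrasting one phenotype level vs all others.

    Built over usable samples only (missing / non-meaningful phenotype
    values are excluded). Optional covariate columns may be appended; by
    default none are, so the selected markers generalize across datasets.
    """

    level: str
    samples: list[str]
    indicator: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=float)
        n_one = int(np.sum(self.indicator == 1))
        n_zero = int(np.sum(self.indicator == 0))
        if n_one < 2 or n_zero < 2:
            raise ValueError(
                f"degenerate design for level {self.level!r}: "
                f"{n_one} in-level and {n_zero} out-of-level samples "
                "(need at least 2 of each)"
            )

    def matrix(self) -> np.ndarray:
        cols = [np.ones_like(self.indicator), self.indicator]
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if cov.shape[0] != len(self.samples):
                cov = cov.T
            cols.extend(cov.T)
        return np.column_stack(cols)


def build_onevsrest_design(
    pheno: PhenotypeTable, column: str, level: str, covariates=None
) -> OneVsRestDesign:
    """Build the one-vs-rest design for ``level`` of categorical ``column``."""
    levels = pheno.levels(column)
    if level not in levels:
        raise ValueError(f"level {level!r} is not a level of column {column!r}: {levels}")
    usable = pheno.usable_mask(column)
    samples = [s for s, u in zip(pheno.samples, usable) if u]
    values = pheno.values(column)[usable]
    indicator = (values == level).astype(float)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[usable]
    return OneVsRestDesign(level=level, samples=samples, indicator=indicator, covariates=cov)


# ---------------------------------------------------------------------------
# moderated fits
# ---------------------------------------------------------------------------

@dataclass
class ModeratedFit:
    """Per-region moderated statistics for one one-vs-rest contrast."""

    level: str
    regions: list[Region]
    coef: np.ndarray          # level effect per region
    intercept: np.ndarray
    s2: np.ndarray            # residual sample variances
    df: float                 # residual df (shared: same design for all regions)
    stdev_unscaled: float     # design-dependent SE scale of the level effect
    prior: VariancePrior
    s2_post: np.ndarray
    t: np.ndarray
    p: np.ndarray
    moments: LogVarianceMoments
    zero_variance: np.ndarray  # mask: constant rows, forced to p = 1

    def ranking(self) -> np.ndarray:
        """Region order: ascending p, then |t| descending, then index."""
        return rank_regions(self.p, self.t)


def rank_regions(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    order = sorted(range(len(p)), key=lambda i: (p[i], -abs(t[i]), i))
    return np.asarray(order, dtype=int)


def fit_moderated_models(
    m: ExpressionMatrix,
    design: OneVsRestDesign,
    prior: VariancePrior | None = None,
) -> ModeratedFit:
    """OLS of each region's expression on the design, with EB moderation.

    All regions share one design, so the fits are vectorized: coefficients
    come from a single pseudoinverse application, and the residual df and
    standard-error scale are scalars. Regions with zero variance across the
    design samples get t = 0, p = 1 and are never selected.

    ``prior`` overrides empirical-Bayes estimation of (d0, s0^2) — used for
    closed-form verification and by :func:`merge_input`.
    """
    pos = {s: i for i, s in enumerate(m.samples)}
    missing = [s for s in design.samples if s not in pos]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:10]}")
    cols = [pos[s] for s in design.samples]
    E = m.values[:, cols]
    X = design.matrix()
    n, p_cols = X.shape
    if n < p_cols + 1:
        raise ValueError(
            f"need at least {p_cols + 1} usable samples for residual df >= 1, got {n}"
        )
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("design matrix is rank deficient (constant indicator?)")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = E @ X @ xtx_inv.T          # (regions, p_cols)
    resid = E - beta @ X.T
    df = float(n - p_cols)
    s2 = np.einsum("ij,ij->i", resid, resid) / df
    s2 = np.maximum(s2, 0.0)
    row_var = np.var(E, axis=1)
    zero_var = row_var == 0.0
    if np.all(zero_var):
        raise ValueError("all regions are constant across design samples")
    s2 = np.where(zero_var, 0.0, s2)
    stdev_unscaled = float(np.sqrt(xtx_inv[1, 1]))

    moments = log_variance_moments(s2, df)
    if prior is None:
        used_prior = prior_from_moments(moments)
    else:
        used_prior = prior
    s2_post, used_prior = squeeze_variances(s2, df, prior=used_prior)

    coef = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.where(zero_var | ~np.isfinite(t), 0.0, t)
    pvals = moderated_t_pvalues(t, df, used_prior.df)
    pvals = np.where(zero_var, 1.0, pvals)

    return ModeratedFit(
        level=design.level,
        regions=list(m.regions),
        coef=coef,
        intercept=beta[:, 0],
        s2=s2,
        df=df,
        stdev_unscaled=stdev_unscaled,
        prior=used_prior,
        s2_post=s2_post,
        t=t,
        p=pvals,
        moments=moments,
        zero_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# top-n selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedRegionSet:
    """Per-level top-n marker regions and their deduplicated union.

    The union can hold up to n x L regions; overlap between per-level lists
    shrinks it. ``provenance`` records which levels selected each region.
    """

    phenotype: str
    levels: list[str]
    n_requested: int
    per_level: dict[str, list[Region]]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def union(self) -> list[Region]:
        seen: dict[Region, None] = {}
        for level in self.levels:
            for r in self.per_level.get(level, []):
                seen.setdefault(r, None)
        return list(seen)

    @property
    def provenance(self) -> dict[Region, list[str]]:
        out: dict[Region, list[str]] = {}
        for level in self.levels:
            for r in self.per_level.get(level, []):
                out.setdefault(r, []).append(level)
        return out

    def __len__(self) -> int:
        return len(self.union)


def select_top_regions(
    fits: dict[str, ModeratedFit], n: int, phenotype: str = ""
) -> SelectedRegionSet:
    """Pick the n most significant regions per level and pool them.

    Regions forced to p = 1 (zero variance) are excluded even when n
    exceeds the number of informative regions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    levels = list(fits)
    per_level: dict[str, list[Region]] = {}
    stat_rows = []
    for level in levels:
        fit = fits[level]
        order = fit.ranking()
        usable = [i for i in order if not fit.zero_variance[i]]
        if n > len(usable):
            logger.warning(
                "level %r: requested %d regions but only %d informative regions "
                "are available; selecting all of them", level, n, len(usable),
            )
        top = usable[:n]
        per_level[level] = [fit.regions[i] for i in top]
        for rank, i in enumerate(top):
            r = fit.regions[i]
            stat_rows.append(
                {
                    "region_id": r.id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "level": level,
                    "coef": fit.coef[i],
                    "t": fit.t[i],
                    "p": fit.p[i],
                    "rank": rank + 1,
                }
            )
    stats = pd.DataFrame(stat_rows)
    return SelectedRegionSet(
        phenotype=phenotype, levels=levels, n_requested=n, per_level=per_level, stats=stats
    )


# ---------------------------------------------------------------------------
# chunked filter / merge
# ---------------------------------------------------------------------------

@dataclass
class FilteredChunk:
    """Output of :func:`filter_regions` on one chunk of regions.

    Keeps, per level, the chunk-level top-``n_keep`` regions with their raw
    per-region statistics (coefficient and sample variance — reusable
    because fits are region-independent) and the chunk's log-variance
    moments over *all* fitted regions, which :func:`merge_input` pools to
    reproduce the global moderation prior.
    """

    samples: list[str]
    selection: SelectedRegionSet
    matrix: ExpressionMatrix | None
    level_stats: dict[str, pd.DataFrame]
    level_moments: dict[str, LogVarianceMoments]
    df: float | None
    stdev_unscaled: dict[str, float]


def filter_regions(
    m_chunk: ExpressionMatrix,
    pheno: PhenotypeTable,
    column: str,
    n_keep: int,
    levels: list[str] | None = None,
) -> FilteredChunk:
    """Run moderated selection within one chunk, keeping top ``n_keep`` per level."""
    if levels is None:
        levels = pheno.levels(column)
    if len(m_chunk.regions) == 0:
        empty = SelectedRegionSet(column, list(levels), n_keep, {lev: [] for lev in levels})
        return FilteredChunk(
            samples=list(m_chunk.samples),
            selection=empty,
            matrix=None,
            level_stats={lev: pd.DataFrame() for lev in levels},
            level_moments={
                lev: LogVarianceMoments(0, 0.0, 0.0, 0.0) for lev in levels
            },
            df=None,
            stdev_unscaled={},
        )
    fits = {}
    for level in levels:
        design = build_onevsrest_design(pheno, column, level)
        fits[level] = fit_moderated_models(m_chunk, design)
    selection = select_top_regions(fits, n_keep, phenotype=column)
    level_stats = {}
    for level in levels:
        fit = fits[level]
        idx = {r: i for i, r in enumerate(fit.regions)}
        rows = [idx[r] for r in selection.per_level[level]]
        level_stats[level] = pd.DataFrame(
            {
                "region_id": [fit.regions[i].id for i in rows],
                "coef": fit.coef[rows],
                "s2": fit.s2[rows],
                "zero_variance": fit.zero_variance[rows],
            }
        )
    sub = m_chunk.subset_regions(selection.union) if len(selection) else None
    return FilteredChunk(
        samples=list(m_chunk.samples),
        selection=selection,
        matrix=sub,
        level_stats=level_stats,
        level_moments={lev: fits[lev].moments for lev in levels},
        df=fits[levels[0]].df,
        stdev_unscaled={lev: fits[lev].stdev_unscaled for lev in levels},
    )


def merge_input(
    chunks: list[FilteredChunk], n: int | None = None
) -> tuple[ExpressionMatrix, SelectedRegionSet]:
    """Pool filtered chunks and re-rank the selection globally.

    The pooled log-variance moments reproduce the exact global
    empirical-Bayes prior; p-values of the retained regions are then
    recomputed under that prior and the top-``n`` per level re-taken over
    the merged pool. When ``n`` is None the chunk ``n_keep`` is reused.
    """
    if not chunks:
        raise ValueError("no chunks to merge")
    nonempty = [c for c in chunks if c.matrix is not None]
    if not nonempty:
        raise ValueError("all chunks are empty")
    samples = nonempty[0].samples
    for c in nonempty[1:]:
        if c.samples != samples:
            raise ValueError("chunks do not share the same sample order")
    dfs = {c.df for c in nonempty}
    if len(dfs) != 1:
        raise ValueError("chunks were fitted with different residual df")
    df = nonempty[0].df

    levels = nonempty[0].selection.levels
    phenotype = nonempty[0].selection.phenotype
    if n is None:
        n = nonempty[0].selection.n_requested

    seen: set[Region] = set()
    merged_regions: list[Region] = []
    blocks = []
    for c in nonempty:
        for r in c.matrix.regions:
            if r in seen:
                raise ValueError(f"region {r.id} duplicated across chunks")
            seen.add(r)
        merged_regions.extend(c.matrix.regions)
        blocks.append(c.matrix.values)
    merged = ExpressionMatrix(
        merged_regions, samples, np.vstack(blocks), nonempty[0].matrix.transformed
    )

    per_level: dict[str, list[Region]] = {}
    stat_rows = []
    for level in levels:
        moments = nonempty[0].level_moments[level]
        for c in nonempty[1:]:
            moments = moments.pooled_with(c.level_moments[level])
        prior = prior_from_moments(moments)
        stdev = nonempty[0].stdev_unscaled[level]

        stats = pd.concat(
            [c.level_stats[level] for c in nonempty if len(c.level_stats[level])],
            ignore_index=True,
        )
        s2_post, _ = squeeze_variances(
            stats["s2"].to_numpy(), df, prior=prior
        )
        coef = stats["coef"].to_numpy()
        zero = stats["zero_variance"].to_numpy(dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / (np.sqrt(s2_post) * stdev)
        t = np.where(zero | ~np.isfinite(t), 0.0, t)
        p = moderated_t_pvalues(t, df, prior.df)
        p = np.where(zero, 1.0, p)
        order = rank_regions(p, t)
        usable = [i for i in order if not zero[i]]
        top = usable[:n]
        regions_by_id = {r.id: r for r in merged_regions}
        per_level[level] = [regions_by_id[stats["region_id"].iloc[i]] for i in top]
        for rank, i in enumerate(top):
            rid = stats["region_id"].iloc[i]
            r = regions_by_id[rid]
            stat_rows.append(
                {
                    "region_id": rid,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "level": level,
                    "coef": coef[i],
                    "t": t[i],
                    "p": p[i],
                    "rank": rank + 1,
                }
            )
    selection = SelectedRegionSet(
        phenotype=phenotype,
        levels=levels,
        n_requested=n,
        per_level=per_level,
        stats=pd.DataFrame(stat_rows),
    )
    return merged, selection


def select_regions(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    column: str,
    n: int,
    levels: list[str] | None = None,
) -> SelectedRegionSet:
    """Unchunked selection: one-vs-rest moderated fit per level, top-n union."""
    if levels is None:
        levels = pheno.levels(column)
    fits = {}
    for level in levels:
        design = build_onevsrest_design(pheno, column, level)
        fits[level] = fit_moderated_models(m, design)
    return select_top_regions(fits, n, phenotype=column)
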