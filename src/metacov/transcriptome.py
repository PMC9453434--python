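"""Gene expression versus regional metabolism, with empirical-null calibration.

Each gene's cortical expression profile is correlated (Pearson) with the
group-mean SUVR profile over the shared ROIs. Two layers of inference are
reported per gene:

* a conventional two-tailed P from the exact t transform
  ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom, and
* a calibration against the whole-transcriptome empirical null: the
  distribution of the same correlation over ALL genes, summarised by its
  mean and SD; a gene's ``z = (r - mean) / sd`` and the effective one-tailed
  ``p_e`` is the standard-normal upper tail of |z|.

The null mean is not assumed zero — spatially structured transcriptomes can
be slightly off-centre — and the normal tail is used rather than the
empirical percentile because the null is bell-shaped by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .atlas import RoiAtlas
from .community import Partition
from .exceptions import SampleSizeError, ValidationError
from .io import GeneExpressionTable, SuvrTable

logger = logging.getLogger("metacov")

#: Significance-star cut-offs for the two-tailed correlation P.
STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def significance_stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p <= level:
            return mark
    return ""


@dataclass(frozen=True)
class MetabolismProfile:
    """Per-ROI mean SUVR of one participant group."""

    roi_names: tuple[str, ...]
    mean_suvr: np.ndarray
    group: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "mean_suvr", np.asarray(self.mean_suvr, dtype=float)
        )
        if len(self.roi_names) != self.mean_suvr.size:
            raise ValidationError("profile length does not match roi_names")
        if (self.mean_suvr <= 0).any():
            raise ValidationError("mean SUVR must be strictly positive")

    def restrict(self, rois: Sequence[str]) -> "MetabolismProfile":
        lookup = {n: i for i, n in enumerate(self.roi_names)}
        missing = [r for r in rois if r not in lookup]
        if missing:
            raise ValidationError(f"profile lacks ROI(s): {missing}")
        idx = [lookup[r] for r in rois]
        return MetabolismProfile(tuple(rois), self.mean_suvr[idx], self.group)


def mean_metabolism_profile(
    table: SuvrTable, rois: Sequence[str] | None = None
) -> MetabolismProfile:
    """Arithmetic per-ROI mean over subjects, optionally on an ROI subset."""
    if table.n_subjects < 1:
        raise ValidationError("need at least one subject")
    group_labels = set(table.group)
    group = group_labels.pop() if len(group_labels) == 1 else "combined"
    profile = MetabolismProfile(
        tuple(table.roi_names), table.values.mean(axis=0), group
    )
    if rois is not None:
        if len(list(rois)) == 0:
            raise ValidationError("ROI subset must not be empty")
        profile = profile.restrict(list(rois))
    return profile


@dataclass(frozen=True)
class GeneCorrelationResult:
    """Per-gene association with regional metabolism."""

    gene_symbol: str
    r: float
    p_two_tailed: float
    n_rois: int
    z: float | None = None
    p_e: float | None = None
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return "" if self.degenerate else significance_stars(self.p_two_tailed)


def _pearson_rows(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Pearson r of each matrix row against ``vector``; NaN for flat rows."""
    x = matrix - matrix.mean(axis=1, keepdims=True)
    y = vector - vector.mean()
    xnorm = np.sqrt((x * x).sum(axis=1))
    ynorm = np.sqrt((y * y).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ y) / (xnorm * ynorm)
    return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed P via the exact t transform with n - 2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def gene_metabolism_correlation(
    genes: GeneExpressionTable, profile: MetabolismProfile
) -> list[GeneCorrelationResult]:
    """Pearson r and two-tailed P per gene over the shared ROIs.

    Zero-variance (flat) genes are returned flagged ``degenerate`` with NaN
    statistics rather than silently dropped.
    """
    shared = [r for r in genes.roi_names if r in set(profile.roi_names)]
    if len(shared) < 3:
        raise SampleSizeError(
            f"only {len(shared)} shared ROI(s) between genes and profile; need >=3"
        )
    gene_idx = [genes.roi_names.index(r) for r in shared]
    expr = genes.expression[:, gene_idx]
    prof = profile.restrict(shared).mean_suvr
    r = _pearson_rows(expr, prof)
    p = _p_from_r(r, len(shared))
    out = []
    for g, ri, pi in zip(genes.gene_symbols, r, p):
        if np.isnan(ri):
            out.append(
                GeneCorrelationResult(g, float("nan"), float("nan"),
                                      len(shared), degenerate=True)
            )
        else:
            out.append(GeneCorrelationResult(g, float(ri), float(pi), len(shared)))
    return out


@dataclass(frozen=True)
class NullDistribution:
    """Whole-transcriptome distribution of gene-metabolism correlations."""

    r_values: np.ndarray
    mean: float
    sd: float
    n_genes: int
    n_degenerate: int = 0

    def histogram(self, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        counts, edges = np.histogram(self.r_values, bins=n_bins)
        return counts, edges


def transcriptome_null(
    genes_all: GeneExpressionTable, profile: MetabolismProfile
) -> NullDistribution:
    """Correlate EVERY transcriptome gene with the profile; summarise r.

    The SD uses the n - 1 convention. Degenerate (flat) genes are excluded
    from the summary with a logged count.
    """
    results = gene_metabolism_correlation(genes_all, profile)
    r = np.array([res.r for res in results if not res.degenerate])
    n_degenerate = sum(res.degenerate for res in results)
    if n_degenerate:
        logger.info("null distribution: excluded %d degenerate gene(s)", n_degenerate)
    if r.size < 2:
        raise SampleSizeError("need >=2 non-degenerate genes for a null distribution")
    sd = float(r.std(ddof=1))
    if sd == 0:
        raise ValidationError("null distribution has zero spread")
    return NullDistribution(
        r_values=r, mean=float(r.mean()), sd=sd,
        n_genes=int(r.size), n_degenerate=n_degenerate,
    )


def p_e_from_z(z: float) -> float:
    """Effective one-tailed P: standard-normal upper tail of |z|."""
    return float(stats.norm.sf(abs(z)))


def calibrate_against_null(
    result: GeneCorrelationResult, null: NullDistribution
) -> GeneCorrelationResult:
    """Fill in z and p_e by standardising r against the empirical null."""
    if null.sd <= 0:
        raise ValidationError("null distribution sd must be positive")
    if result.degenerate:
        return result
    z = (result.r - null.mean) / null.sd
    return replace(result, z=float(z), p_e=p_e_from_z(z))


@dataclass(frozen=True)
class ModuleCorrelation:
    """Per-module gene-metabolism correlations on cortical ROIs only.

    ``defined`` is False (results None) when the module intersects fewer
    than 3 cortical ROIs covered by the gene table.
    """

    module: int
    roi_names: tuple[str, ...]
    results: tuple[GeneCorrelationResult, ...] | None

    @property
    def defined(self) -> bool:
        return self.results is not None


def module_wise_correlation(
    genes: GeneExpressionTable,
    profile: MetabolismProfile,
    partition: Partition,
    atlas: RoiAtlas,
) -> list[ModuleCorrelation]:
    """Correlations restricted to each module's cortical ROIs.

    The partition is over the full atlas (cortex plus subcortex), but
    expression exists for cortex only, so each module is intersected with
    the cortical ROIs present in the gene table before correlating.
    """
    if partition.n_nodes != atlas.n_rois:
        raise ValidationError("partition does not cover the atlas")
    covered = set(genes.roi_names) & set(profile.roi_names)
    out = []
    for label in range(1, partition.n_modules + 1):
        rois = [
            atlas.names[i]
            for i in partition.members(label)
            if atlas.is_cortical[i] and atlas.names[i] in covered
        ]
        if len(rois) < 3:
            out.append(ModuleCorrelation(label, tuple(rois), None))
            continue
        sub_idx = [genes.roi_names.index(r) for r in rois]
        sub = GeneExpressionTable(
            gene_symbols=list(genes.gene_symbols),
            roi_names=rois,
            expression=genes.expression[:, sub_idx],
            consistency=genes.consistency,
        )
        results = gene_metabolism_correlation(sub, profile.restrict(rois))
        out.append(ModuleCorrelation(label, tuple(rois), tuple(results)))
    return out
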