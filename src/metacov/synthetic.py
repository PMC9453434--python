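"""Synthetic cohorts and transcriptomes with planted ground truth.

The SUVR generator draws subjects from a multivariate normal whose
correlation matrix has a planted block (module) structure — a Gaussian
copula is sufficient because every downstream statistic is second-order
(Pearson based). The transcriptome generator plants genes at chosen target
correlations with a metabolism profile among a sea of background genes, so
both pipeline stages can be scored against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atlas import RoiAtlas, default_atlas
from .community import Partition
from .exceptions import ConfigError, ValidationError
from .io import GeneExpressionTable, SuvrTable
from .transcriptome import MetabolismProfile

logger = logging.getLogger("metacov")


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    """Planted block-correlation cohort.

    Defaults mirror a pons-normalised SUVR scale (baseline 1.5, residual SD
    0.15) and a three-module organisation over the 72-ROI atlas.
    """

    module_sizes: tuple[int, ...] = (30, 24, 18)
    rho_within: float = 0.7
    rho_between: float = 0.1
    n_subjects: int = 100
    baseline: float = 1.5
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(int(m) for m in self.module_sizes))
        if any(m < 1 for m in self.module_sizes):
            raise ConfigError("module sizes must be positive")
        if not 0.0 <= self.rho_between < self.rho_within < 1.0:
            raise ConfigError(
                "require 0 <= rho_between < rho_within < 1, got "
                f"rho_between={self.rho_between}, rho_within={self.rho_within}"
            )
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if self.noise_sd <= 0 or self.baseline <= 0:
            raise ConfigError("baseline and noise_sd must be positive")

    @property
    def n_rois(self) -> int:
        return sum(self.module_sizes)

    def correlation_matrix(self) -> np.ndarray:
        """Block correlation matrix; positive definiteness is validated."""
        n = self.n_rois
        corr = np.full((n, n), self.rho_between)
        start = 0
        for size in self.module_sizes:
            corr[start : start + size, start : start + size] = self.rho_within
            start += size
        np.fill_diagonal(corr, 1.0)
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ConfigError("planted correlation matrix is not positive definite")
        return corr

    def planted_partition(self) -> Partition:
        labels = np.repeat(np.arange(1, len(self.module_sizes) + 1), self.module_sizes)
        return Partition(labels)


#: Qualitative group presets: progression toward dementia weakens
#: between-module coupling (raising modularity); values are illustrative
#: conditions, not estimates of any cohort.
GROUP_PRESETS: dict[str, SyntheticNetworkConfig] = {
    "CN-to-CN": SyntheticNetworkConfig(rho_between=0.45, n_subjects=81),
    "CN-to-MCI": SyntheticNetworkConfig(rho_between=0.35, n_subjects=21),
    "CN-to-AD": SyntheticNetworkConfig(rho_between=0.25, n_subjects=15),
    "AD": SyntheticNetworkConfig(rho_between=0.10, n_subjects=150),
}


def simulate_suvr_table(
    config: SyntheticNetworkConfig,
    atlas: RoiAtlas | None = None,
    group: str = "synthetic",
) -> tuple[SuvrTable, Partition]:
    """Draw a cohort with planted modular covariance; return the truth too.

    Values are ``baseline + noise_sd * z`` with z from the planted-block
    multivariate normal; the rare draw at or below zero is clipped to a
    small positive floor (count logged) to honour the SUVR positivity
    invariant.
    """
    atlas = atlas or default_atlas()
    if atlas.n_rois != config.n_rois:
        raise ConfigError(
            f"module sizes sum to {config.n_rois} but atlas has {atlas.n_rois} ROIs"
        )
    corr = config.correlation_matrix()
    rng = np.random.default_rng(config.seed)
    z = rng.multivariate_normal(
        np.zeros(config.n_rois), corr, size=config.n_subjects, method="cholesky"
    )
    values = config.baseline + config.noise_sd * z
    floor = 1e-3
    n_clipped = int((values < floor).sum())
    if n_clipped:
        logger.info("clipped %d non-positive synthetic SUVR cell(s)", n_clipped)
        values = np.clip(values, floor, None)
    width = len(str(config.n_subjects))
    table = SuvrTable(
        subject_ids=[f"S{i + 1:0{width}d}" for i in range(config.n_subjects)],
        roi_names=list(atlas.names),
        values=values,
        group=np.array([group] * config.n_subjects, dtype=object),
        sex=np.array(
            ["women" if i % 2 == 0 else "men" for i in range(config.n_subjects)],
            dtype=object,
        ),
    )
    return table, config.planted_partition()


@dataclass(frozen=True)
class SyntheticTranscriptomeConfig:
    """Background transcriptome plus genes planted at target correlations.

    ``planted`` maps gene labels to target correlations r_true with the
    metabolism profile. Background genes are pure noise by default; a
    positive ``background_corr_sd`` gives each background gene a random
    shared-profile loading, widening the null r distribution the way a
    spatially structured transcriptome does.
    """

    n_background_genes: int = 5000
    planted: tuple[tuple[str, float], ...] = ()
    n_rois: int = 68
    consistency_range: tuple[float, float] = (0.0, 1.0)
    background_corr_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted", tuple((str(g), float(r)) for g, r in self.planted))
        labels = [g for g, _ in self.planted]
        if len(set(labels)) != len(labels):
            raise ConfigError("planted gene labels must be unique")
        if any(abs(r) >= 1.0 for _, r in self.planted):
            raise ConfigError("planted |r_true| must be < 1")
        lo, hi = self.consistency_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("consistency_range must be within [0, 1]")
        if self.n_background_genes < 0 or self.n_rois < 3:
            raise ConfigError("need n_background_genes >= 0 and n_rois >= 3")
        if self.background_corr_sd < 0:
            raise ConfigError("background_corr_sd must be >= 0")


def simulate_transcriptome(
    config: SyntheticTranscriptomeConfig, profile: MetabolismProfile
) -> GeneExpressionTable:
    """Planted gene g = r_true * standardised(profile) + sqrt(1-r^2) * noise.

    Background genes are unit-variance noise (optionally with a random
    profile loading of SD ``background_corr_sd``); expression is shifted to
    a log-intensity-like level of 6 arbitrary units. Planted genes come
    first, in config order, followed by labelled background genes.
    """
    if len(profile.roi_names) != config.n_rois:
        raise ValidationError(
            f"profile has {len(profile.roi_names)} ROIs, config expects {config.n_rois}"
        )
    rng = np.random.default_rng(config.seed)
    p = profile.mean_suvr
    p_std = (p - p.mean()) / p.std()
    rows, labels = [], []
    for gene, r_true in config.planted:
        noise = rng.standard_normal(config.n_rois)
        rows.append(r_true * p_std + np.sqrt(1.0 - r_true**2) * noise)
        labels.append(gene)
    for i in range(config.n_background_genes):
        noise = rng.standard_normal(config.n_rois)
        if config.background_corr_sd > 0:
            b = rng.normal(0.0, config.background_corr_sd)
            noise = b * p_std + noise
        rows.append(noise)
        labels.append(f"GENE{i + 1:05d}")
    lo, hi = config.consistency_range
    consistency = rng.uniform(lo, hi, size=len(rows))
    expression = 6.0 + np.asarray(rows)
    return GeneExpressionTable(
        gene_symbols=labels,
        roi_names=list(profile.roi_names),
        expression=expression,
        consistency=consistency,
    )
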