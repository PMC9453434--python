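"""Model/Results front-end over the functional pipeline.

`MetabolicCovarianceModel` wraps one participant group's SUVR table: the
exogenous structure is the ROI atlas, the "fit" is signed-Louvain consensus
clustering of the cross-subject correlation network, and the results object
carries the stable partition, its modularity decomposition and descriptive
diagnostics.

`GeneMetabolismModel` wraps a gene-expression table against the same group's
mean metabolism profile; its results carry per-gene correlation estimates
with two layers of inference (exact-t two-tailed P, and z / p_e against the
whole-transcriptome empirical null).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .atlas import RoiAtlas, default_atlas
from .community import (
    ConsensusResult,
    ModularityResult,
    Partition,
    consensus_cluster,
)
from .exceptions import ValidationError
from .io import (
    DEFAULT_CONSISTENCY_THRESHOLD,
    GeneExpressionTable,
    SuvrTable,
    filter_genes_by_consistency,
    group_subset,
    read_suvr_table,
)
from .network import (
    NetworkSummary,
    SignedNetwork,
    build_correlation_network,
    network_summary,
)
from .transcriptome import (
    GeneCorrelationResult,
    MetabolismProfile,
    NullDistribution,
    calibrate_against_null,
    gene_metabolism_correlation,
    mean_metabolism_profile,
    module_wise_correlation,
    transcriptome_null,
)


def partition_similarity(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions (1 = identical)."""
    if a.n_nodes != b.n_nodes:
        raise ValidationError("partitions cover different node sets")
    return float(adjusted_rand_score(a.assignment, b.assignment))


class MetabolicCovarianceModel:
    """Metabolic covariance network of one participant group."""

    def __init__(self, table: SuvrTable, atlas: RoiAtlas | None = None):
        self.table = table
        self.atlas = atlas or default_atlas()
        self._network: SignedNetwork | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, atlas: RoiAtlas | None = None,
                       group: str | None = None, sex: str | None = None):
        import tempfile
        from pathlib import Path

        atlas = atlas or default_atlas()
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "suvr.csv"
            df.to_csv(path, index=False)
            table = read_suvr_table(path, atlas)
        if group is not None:
            table = group_subset(table, group, sex)
        return cls(table, atlas)

    @classmethod
    def from_file(cls, path, atlas: RoiAtlas | None = None,
                  group: str | None = None, sex: str | None = None):
        atlas = atlas or default_atlas()
        table = read_suvr_table(path, atlas)
        if group is not None:
            table = group_subset(table, group, sex)
        return cls(table, atlas)

    @property
    def network(self) -> SignedNetwork:
        if self._network is None:
            self._network = build_correlation_network(self.table)
        return self._network

    def fit(self, n_runs: int = 100, seed: int = 0, max_iter: int = 50,
            tau: float = 0.0) -> "ConsensusClusteringResults":
        consensus = consensus_cluster(
            self.network, n_runs=n_runs, seed=seed, max_iter=max_iter, tau=tau
        )
        return ConsensusClusteringResults(self, consensus)


class ConsensusClusteringResults:
    """Stable modular decomposition of a metabolic covariance network."""

    def __init__(self, model: MetabolicCovarianceModel, consensus: ConsensusResult):
        self.model = model
        self.network = model.network
        self.consensus = consensus
        self.partition: Partition = consensus.partition
        self.modularity: ModularityResult = consensus.modularity
        self.iterations: int = consensus.iterations

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules

    def module_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_name": self.network.roi_names,
                "module_id": self.partition.assignment,
            }
        )

    def network_summary(self) -> NetworkSummary:
        return network_summary(self.network)

    def ari(self, reference: Partition) -> float:
        return partition_similarity(self.partition, reference)

    def summary(self) -> str:
        mod = self.modularity
        summ = self.network_summary()
        lines = [
            "Metabolic covariance network: consensus clustering",
            "=" * 58,
            f"Nodes (ROIs):            {self.network.n_nodes}",
            f"Subjects:                {self.model.table.n_subjects}",
            f"Mean edge weight:        {summ.mean_weight: .4f}",
            f"Negative edge fraction:  {summ.frac_negative: .4f}",
            "-" * 58,
            f"Modularity M:            {mod.M: .4f}",
            f"  positive part M+:      {mod.M_pos: .4f}",
            f"  negative part M-:      {mod.M_neg: .4f}",
            f"  negative weight ratio: {mod.neg_weight_ratio: .4f}",
            f"Consensus iterations:    {self.iterations}",
            f"Louvain runs/iteration:  {self.consensus.n_runs}",
            f"Seed:                    {self.consensus.seed}",
            "-" * 58,
            f"Modules:                 {self.n_modules}",
        ]
        for label in range(1, self.n_modules + 1):
            members = self.partition.members(label)
            lines.append(f"  module {label}: {members.size} ROI(s)")
        return "\n".join(lines)


class GeneMetabolismModel:
    """Regional gene expression against a group's mean metabolism.

    ``genes`` is the full transcriptome table: it supplies both the
    empirical null and (after the consistency filter and optional panel
    restriction) the genes that are reported.
    """

    def __init__(
        self,
        genes: GeneExpressionTable,
        metabolism: SuvrTable | MetabolismProfile,
        atlas: RoiAtlas | None = None,
        consistency_threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
        panel: Sequence[str] | None = None,
    ):
        self.atlas = atlas or default_atlas()
        genes.validate_against_atlas(self.atlas)
        self.genes = genes
        if isinstance(metabolism, SuvrTable):
            metabolism = mean_metabolism_profile(metabolism)
        # expression exists on cortex only; restrict the profile accordingly
        shared = [r for r in genes.roi_names if r in set(metabolism.roi_names)]
        self.profile = metabolism.restrict(shared)
        self.consistency_threshold = consistency_threshold
        self.panel = tuple(panel) if panel is not None else None

    def fit(self) -> "GeneCorrelationResults":
        null = transcriptome_null(self.genes, self.profile)
        reported = filter_genes_by_consistency(self.genes, self.consistency_threshold)
        if self.panel is not None:
            reported = reported.select(self.panel)
        results = [
            calibrate_against_null(res, null)
            for res in gene_metabolism_correlation(reported, self.profile)
        ]
        results.sort(key=lambda res: -np.inf if np.isnan(res.r) else res.r,
                     reverse=True)
        return GeneCorrelationResults(self, tuple(results), null, reported)


class GeneCorrelationResults:
    """Per-gene correlation estimates with null-calibrated significance."""

    def __init__(
        self,
        model: GeneMetabolismModel,
        results: tuple[GeneCorrelationResult, ...],
        null: NullDistribution,
        reported_genes: GeneExpressionTable,
    ):
        self.model = model
        self.results = results
        self.null = null
        self._reported_genes = reported_genes

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [res.gene_symbol for res in self.results],
                "n_rois": [res.n_rois for res in self.results],
                "r": [res.r for res in self.results],
                "p_two_tailed": [res.p_two_tailed for res in self.results],
                "z": [res.z for res in self.results],
                "p_e": [res.p_e for res in self.results],
                "stars": [res.stars for res in self.results],
            }
        )

    def module_wise(self, partition: Partition) -> pd.DataFrame:
        """Correlations per module (cortical ROIs only); NaN when undefined."""
        modules = module_wise_correlation(
            self._reported_genes, self.model.profile, partition, self.model.atlas
        )
        rows = []
        for mod in modules:
            if not mod.defined:
                rows.append(
                    {"module": mod.module, "gene": None, "n_rois": len(mod.roi_names),
                     "r": np.nan, "p_two_tailed": np.nan, "stars": "undefined"}
                )
                continue
            for res in mod.results:
                rows.append(
                    {"module": mod.module, "gene": res.gene_symbol,
                     "n_rois": res.n_rois, "r": res.r,
                     "p_two_tailed": res.p_two_tailed, "stars": res.stars}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Gene expression vs regional metabolism",
            "=" * 66,
            f"Group profile:        {self.model.profile.group or '(unlabelled)'}",
            f"Cortical ROIs used:   {len(self.model.profile.roi_names)}",
            f"Null genes:           {self.null.n_genes} "
            f"(mean r {self.null.mean: .4f}, sd {self.null.sd:.4f})",
            f"Consistency filter:   > {self.model.consistency_threshold}",
            "-" * 66,
            f"{'gene':<10}{'r':>9}{'P(2-tail)':>12}{'z':>9}{'p_e':>9}  stars",
        ]
        for res in self.results:
            lines.append(
                f"{res.gene_symbol:<10}{res.r:>9.3f}{res.p_two_tailed:>12.2e}"
                f"{res.z:>9.3f}{res.p_e:>9.4f}  {res.stars}"
            )
        return "\n".join(lines)
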