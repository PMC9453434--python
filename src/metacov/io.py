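"""Tabular ingestion, validation, filters and normalisations.

All tables travel as delimited text (comma for ``.csv``, tab for ``.tsv``).
The SUVR table holds one subject per row: ``subject_id``, ``group``, optional
``sex``, then one column per atlas ROI. The gene-expression table holds one
gene per row: ``gene_symbol``, ``consistency``, then the 68 cortical ROI
columns. Validation is strict: missing cells and non-positive SUVR are
rejected rather than imputed, mirroring a QC policy of discarding bad scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, default_atlas
from .exceptions import (
    DegenerateInputError,
    ParseError,
    SampleSizeError,
    SchemaError,
    UnknownLabelError,
    ValidationError,
)

logger = logging.getLogger("metacov")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _parse_numeric_column(series: pd.Series, column: str, row_ids) -> np.ndarray:
    """Exact (round-trip) float parsing with a located error on bad cells.

    ``Series.astype(float)`` uses Python's correctly rounded parser, unlike
    the lossy fast path of ``pd.to_numeric``, so written tables re-read
    bit-identically.
    """
    bad = np.flatnonzero(series.isna().to_numpy())
    if not bad.size:
        try:
            return series.astype(float).to_numpy()
        except (ValueError, TypeError):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = np.flatnonzero(coerced.isna().to_numpy())
    raise ParseError(
        f"non-numeric or missing value at row {bad[0] + 1} "
        f"({row_ids[bad[0]]!r}), column {column!r}"
    )


# ---------------------------------------------------------------------------
# SUVR tables
# ---------------------------------------------------------------------------


@dataclass
class SuvrTable:
    """Subjects x ROIs matrix of pons-normalised mean SUVR with labels."""

    subject_ids: list[str]
    roi_names: list[str]
    values: np.ndarray
    group: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=object)
        n_subj, n_roi = self.values.shape
        if len(self.subject_ids) != n_subj:
            raise ValidationError("subject_ids length does not match value rows")
        if len(self.roi_names) != n_roi:
            raise ValidationError("roi_names length does not match value columns")
        if len(set(self.subject_ids)) != n_subj:
            dupes = sorted(
                {s for s in self.subject_ids if self.subject_ids.count(s) > 1}
            )
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        if len(self.group) != n_subj:
            raise ValidationError("group length does not match value rows")
        if self.sex is not None and len(self.sex) != n_subj:
            raise ValidationError("sex length does not match value rows")
        if np.isnan(self.values).any():
            raise ValidationError("SUVR matrix contains missing values")
        if (self.values <= 0).any():
            raise ValidationError("SUVR values must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group))

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {"subject_id": self.subject_ids, "group": self.group}
        if self.sex is not None:
            data["sex"] = self.sex
        frame = pd.DataFrame(data)
        return pd.concat(
            [frame, pd.DataFrame(self.values, columns=self.roi_names)], axis=1
        )


def read_suvr_table(
    path: str | Path,
    atlas: RoiAtlas | None = None,
    aliases: Mapping[str, str] | None = None,
) -> SuvrTable:
    """Load and validate a delimited SUVR table, reordered to atlas order.

    ``aliases`` maps foreign column names onto atlas ROI names so other
    naming dialects can be ingested without editing files.
    """
    atlas = atlas or default_atlas()
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if aliases:
        df = df.rename(columns=dict(aliases))
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"SUVR table missing column {col!r}")
    missing = [n for n in atlas.names if n not in df.columns]
    if missing:
        raise SchemaError(f"SUVR table missing ROI column(s): {missing}")

    subject_ids = df["subject_id"].astype(str).tolist()
    values = np.empty((len(df), atlas.n_rois), dtype=float)
    for j, roi in enumerate(atlas.names):
        values[:, j] = _parse_numeric_column(df[roi], roi, subject_ids)
    sex = df["sex"].to_numpy() if "sex" in df.columns else None
    return SuvrTable(
        subject_ids=subject_ids,
        roi_names=list(atlas.names),
        values=values,
        group=df["group"].to_numpy(),
        sex=sex,
    )


def write_suvr_table(table: SuvrTable, path: str | Path) -> None:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index=False)


def normalize_suv_to_suvr(suv_values, pons_mean) -> np.ndarray:
    """Divide each subject's regional SUV by that subject's mean pons SUV."""
    suv = np.asarray(suv_values, dtype=float)
    pons = np.atleast_1d(np.asarray(pons_mean, dtype=float))
    if (pons <= 0).any() or np.isnan(pons).any():
        raise DegenerateInputError("pons mean SUV must be strictly positive")
    if suv.ndim == 1:
        suv = suv[np.newaxis, :]
    if pons.shape[0] != suv.shape[0]:
        raise ValidationError("one pons mean per subject row is required")
    return suv / pons[:, np.newaxis]


def group_subset(table: SuvrTable, group: str, sex: str | None = None) -> SuvrTable:
    """Subjects of one risk group (optionally one sex); needs >=3 subjects."""
    if group not in set(table.group):
        raise UnknownLabelError(f"unknown group label {group!r}")
    mask = table.group == group
    if sex is not None:
        if table.sex is None:
            raise UnknownLabelError("table has no sex column")
        if sex not in set(table.sex):
            raise UnknownLabelError(f"unknown sex label {sex!r}")
        mask &= table.sex == sex
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise SampleSizeError(
            f"group {group!r}" + (f" sex {sex!r}" if sex else "") +
            f" has {idx.size} subject(s); correlation needs at least 3"
        )
    return SuvrTable(
        subject_ids=[table.subject_ids[i] for i in idx],
        roi_names=list(table.roi_names),
        values=table.values[idx],
        group=table.group[idx],
        sex=None if table.sex is None else table.sex[idx],
    )


# ---------------------------------------------------------------------------
# Amyloid positivity
# ---------------------------------------------------------------------------

#: SUVR positivity thresholds by (tracer, reference region).
AMYLOID_THRESHOLDS: dict[tuple[str, str | None], float] = {
    ("florbetapir", "whole-cerebellum"): 1.11,
    ("florbetapir", "composite"): 0.79,
    ("pib", None): 1.50,
}


@dataclass(frozen=True)
class AmyloidRecord:
    """One amyloid-PET score: tracer, optional reference region, mean SUVR."""

    tracer: str
    score: float
    reference: str | None = None

    def __post_init__(self):
        if self.tracer not in {"florbetapir", "pib"}:
            raise ValidationError(f"unknown tracer {self.tracer!r}")
        if self.score <= 0:
            raise ValidationError("amyloid SUVR score must be positive")
        if self.tracer == "florbetapir":
            if self.reference not in {"whole-cerebellum", "composite"}:
                raise ValidationError(
                    "florbetapir requires reference 'whole-cerebellum' or 'composite'"
                )
        elif self.reference is not None:
            raise ValidationError("PIB records carry no reference region")

    @property
    def threshold(self) -> float:
        return AMYLOID_THRESHOLDS[(self.tracer, self.reference)]


def amyloid_positive(records: Sequence[AmyloidRecord]) -> bool | None:
    """True if ANY record scores strictly above its tracer threshold.

    Returns ``None`` (indeterminate) for an empty record list: participants
    without usable amyloid PET are excluded from positivity ratios, not
    counted negative.
    """
    if not records:
        return None
    return any(rec.score > rec.threshold for rec in records)


# ---------------------------------------------------------------------------
# Gene expression tables
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionTable:
    """Genes x cortical-ROI median expression with per-gene consistency."""

    gene_symbols: list[str]
    roi_names: list[str]
    expression: np.ndarray
    consistency: np.ndarray

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.consistency = np.asarray(self.consistency, dtype=float)
        n_genes, n_rois = self.expression.shape
        if len(self.gene_symbols) != n_genes:
            raise ValidationError("gene_symbols length mismatch")
        if len(set(self.gene_symbols)) != n_genes:
            raise ValidationError("gene symbols must be unique")
        if len(self.roi_names) != n_rois:
            raise ValidationError("roi_names length mismatch")
        if len(self.consistency) != n_genes:
            raise ValidationError("consistency length mismatch")
        if np.isnan(self.expression).any():
            raise ValidationError("expression matrix contains missing values")
        if ((self.consistency < 0) | (self.consistency > 1)).any():
            raise ValidationError("consistency scores must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    def validate_against_atlas(self, atlas: RoiAtlas) -> None:
        """Expression is cortical-only; refuse subcortical or unknown ROIs."""
        cortical = set(atlas.cortical_names)
        subcortical = set(atlas.subcortical_names)
        bad_sub = [n for n in self.roi_names if n in subcortical]
        if bad_sub:
            raise ValidationError(
                f"gene table contains subcortical ROI column(s): {bad_sub}; "
                "regional expression is defined on cortex only"
            )
        unknown = [n for n in self.roi_names if n not in cortical]
        if unknown:
            raise SchemaError(f"gene table ROI column(s) not in atlas: {unknown}")

    def select(self, symbols: Sequence[str]) -> "GeneExpressionTable":
        present = {g: i for i, g in enumerate(self.gene_symbols)}
        idx = [present[s] for s in symbols if s in present]
        skipped = [s for s in symbols if s not in present]
        if skipped:
            logger.warning("panel gene(s) absent from table, skipped: %s", skipped)
        return GeneExpressionTable(
            gene_symbols=[self.gene_symbols[i] for i in idx],
            roi_names=list(self.roi_names),
            expression=self.expression[idx],
            consistency=self.consistency[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"gene_symbol": self.gene_symbols, "consistency": self.consistency}
        )
        return pd.concat(
            [frame, pd.DataFrame(self.expression, columns=self.roi_names)], axis=1
        )


def read_gene_table(
    path: str | Path, atlas: RoiAtlas | None = None
) -> GeneExpressionTable:
    atlas = atlas or default_atlas()
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("gene_symbol", "consistency"):
        if col not in df.columns:
            raise SchemaError(f"gene table missing column {col!r}")
    roi_cols = [c for c in df.columns if c not in ("gene_symbol", "consistency")]
    genes = df["gene_symbol"].astype(str).tolist()
    consistency = _parse_numeric_column(df["consistency"], "consistency", genes)
    expr = np.empty((len(df), len(roi_cols)), dtype=float)
    for j, roi in enumerate(roi_cols):
        expr[:, j] = _parse_numeric_column(df[roi], roi, genes)
    table = GeneExpressionTable(
        gene_symbols=genes,
        roi_names=roi_cols,
        expression=expr,
        consistency=consistency,
    )
    table.validate_against_atlas(atlas)
    return table


def write_gene_table(table: GeneExpressionTable, path: str | Path) -> None:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index=False)


#: Default consistency cut-off for donor-representative expression profiles.
DEFAULT_CONSISTENCY_THRESHOLD = 0.446

#: Alzheimer-risk gene panel that survives the default consistency filter.
DEFAULT_RISK_PANEL: tuple[str, ...] = (
    "APOE",
    "BIN1",
    "CD33",
    "CLU",
    "CELF1",
    "MAPT",
    "MEF2C",
    "FERMT2",
    "SORL1",
    "TREM2",
)


def filter_genes_by_consistency(
    table: GeneExpressionTable,
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> GeneExpressionTable:
    """Keep genes whose consistency is STRICTLY above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("consistency threshold must lie in [0, 1]")
    keep = np.flatnonzero(table.consistency > threshold)
    logger.info(
        "consistency filter (> %.3f): kept %d of %d genes",
        threshold, keep.size, table.n_genes,
    )
    return GeneExpressionTable(
        gene_symbols=[table.gene_symbols[i] for i in keep],
        roi_names=list(table.roi_names),
        expression=table.expression[keep],
        consistency=table.consistency[keep],
    )
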