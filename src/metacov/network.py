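"""Group-level metabolic covariance networks.

Edges are Pearson correlations of regional SUVR computed ACROSS subjects
(metabolic co-activation), not across time. The dense signed matrix is kept
as-is — no thresholding or sparsification — and decomposed into positive and
negative parts, the substrate for signed-modularity clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    SampleSizeError,
    SchemaError,
    ValidationError,
)
from .io import SuvrTable, _sep_for


class SignedNetwork:
    """Symmetric weighted network split into positive and negative parts.

    ``w_pos`` holds the positive weights, ``w_neg`` the magnitudes of the
    negative weights, so ``weights = w_pos - w_neg`` with at most one of the
    two nonzero per cell. Node strengths ``s_pos``/``s_neg`` and totals
    ``v_pos``/``v_neg`` follow the convention that each undirected connection
    is counted twice in the totals (full-matrix sums).
    """

    def __init__(self, roi_names, weights):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValidationError("weights must be a square matrix")
        if len(roi_names) != weights.shape[0]:
            raise ValidationError("roi_names length does not match matrix size")
        if not np.array_equal(weights, weights.T):
            raise ValidationError("weight matrix must be exactly symmetric")
        if np.diagonal(weights).any():
            raise ValidationError("diagonal must be zero (no self-loops)")
        self.roi_names = list(roi_names)
        self.weights = weights
        self.w_pos = np.where(weights > 0, weights, 0.0)
        self.w_neg = np.where(weights < 0, -weights, 0.0)
        self.s_pos = self.w_pos.sum(axis=1)
        self.s_neg = self.w_neg.sum(axis=1)
        self.v_pos = float(self.s_pos.sum())
        self.v_neg = float(self.s_neg.sum())

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __repr__(self) -> str:
        return (
            f"SignedNetwork(n_nodes={self.n_nodes}, "
            f"v_pos={self.v_pos:.4g}, v_neg={self.v_neg:.4g})"
        )


def build_correlation_network(table: SuvrTable) -> SignedNetwork:
    """Pairwise Pearson correlation of ROI SUVR across subjects.

    The self-correlation diagonal is zeroed before clustering so the totals
    v+/v- carry no self-loop mass.
    """
    if table.n_subjects < 3:
        raise SampleSizeError(
            f"correlation network needs >=3 subjects, got {table.n_subjects}"
        )
    sd = table.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [table.roi_names[i] for i in flat]
        raise DegenerateInputError(
            f"zero-variance ROI column(s) across subjects: {names}"
        )
    corr = np.corrcoef(table.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 0.0)
    return SignedNetwork(table.roi_names, corr)


@dataclass(frozen=True)
class NetworkSummary:
    """Descriptive statistics of the off-diagonal (undirected) edge weights."""

    n_nodes: int
    n_edges: int
    mean_weight: float
    min_weight: float
    max_weight: float
    n_negative: int
    frac_negative: float


def network_summary(net: SignedNetwork) -> NetworkSummary:
    iu = np.triu_indices(net.n_nodes, k=1)
    w = net.weights[iu]
    n_neg = int((w < 0).sum())
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=w.size,
        mean_weight=float(w.mean()),
        min_weight=float(w.min()),
        max_weight=float(w.max()),
        n_negative=n_neg,
        frac_negative=n_neg / w.size if w.size else 0.0,
    )


# ---------------------------------------------------------------------------
# Delimited import/export
# ---------------------------------------------------------------------------


def write_matrix(net: SignedNetwork, path: str | Path) -> None:
    """Square delimited matrix with ROI names as header row and column."""
    path = Path(path)
    pd.DataFrame(net.weights, index=net.roi_names, columns=net.roi_names).to_csv(
        path, sep=_sep_for(path)
    )


def read_matrix(path: str | Path) -> SignedNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("matrix file row and column ROI names differ")
    return SignedNetwork(list(df.columns), df.to_numpy(dtype=float))


def write_edge_list(net: SignedNetwork, path: str | Path) -> None:
    """Three-column upper-triangle edge list (roi_a, roi_b, weight)."""
    path = Path(path)
    ii, jj = np.triu_indices(net.n_nodes, k=1)
    pd.DataFrame(
        {
            "roi_a": [net.roi_names[i] for i in ii],
            "roi_b": [net.roi_names[j] for j in jj],
            "weight": net.weights[ii, jj],
        }
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_edge_list(path: str | Path) -> SignedNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("roi_a", "roi_b", "weight"):
        if col not in df.columns:
            raise SchemaError(f"edge list missing column {col!r}")
    names: list[str] = []
    seen = set()
    for col in ("roi_a", "roi_b"):
        for n in df[col].astype(str):
            if n not in seen:
                seen.add(n)
                names.append(n)
    idx = {n: i for i, n in enumerate(names)}
    weights = np.zeros((len(names), len(names)))
    for a, b, w in zip(df["roi_a"], df["roi_b"], df["weight"]):
        i, j = idx[str(a)], idx[str(b)]
        weights[i, j] = weights[j, i] = float(w)
    np.fill_diagonal(weights, 0.0)
    return SignedNetwork(names, weights)
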