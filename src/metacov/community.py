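"""Signed modularity, seeded Louvain, and consensus clustering.

Correlation networks carry negative edges, so partition quality is scored
with a signed modularity: the positive part M+ rewards positive weight
concentrated within modules against a strength-product null, the negative
part M- rewards negative weight expelled between modules, and the two are
combined as

    M = M+ + [v- / (v+ + v-)] * M-

so negative connections play only an auxiliary role whose influence grows
with the negative weight fraction. Sums run over all ordered node pairs
including i = j (zero self-weights at the original level), and each
undirected connection is counted twice in v+/v-.

The Louvain pass returned here is the LOWEST hierarchical level: the greedy
single-node move phase on the original nodes, iterated to convergence. Later
aggregation levels only coarsen that assignment and cannot change it, so the
first-level partition is what consensus clustering aggregates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, DegenerateInputError, ValidationError
from .io import _sep_for
from .network import SignedNetwork

logger = logging.getLogger("metacov")

#: Moves with modularity gain below this are treated as zero (no livelock).
GAIN_TOL = 1e-12


class Partition:
    """Module assignment sigma for each node, canonicalised to labels 1..k.

    Labels are relabelled by first appearance so two partitions are equal iff
    they agree up to a permutation of module labels.
    """

    def __init__(self, labels: Sequence[int]):
        raw = np.asarray(labels)
        if raw.ndim != 1 or raw.size == 0:
            raise ValidationError("partition labels must be a non-empty 1-D sequence")
        canonical = np.empty(raw.size, dtype=int)
        mapping: dict = {}
        for i, lab in enumerate(raw):
            key = lab.item() if hasattr(lab, "item") else lab
            if key not in mapping:
                mapping[key] = len(mapping) + 1
            canonical[i] = mapping[key]
        self.assignment = canonical
        self.assignment.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)

    def same_module_matrix(self) -> np.ndarray:
        a = self.assignment
        return a[:, None] == a[None, :]

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and np.array_equal(
            self.assignment, other.assignment
        )

    def __hash__(self) -> int:
        return hash(self.assignment.tobytes())

    def __repr__(self) -> str:
        return f"Partition(n_nodes={self.n_nodes}, n_modules={self.n_modules})"


@dataclass(frozen=True)
class ModularityResult:
    """Signed modularity and its decomposition."""

    M: float
    M_pos: float
    M_neg: float
    neg_weight_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {
            "M": self.M,
            "M_pos": self.M_pos,
            "M_neg": self.M_neg,
            "neg_weight_ratio": self.neg_weight_ratio,
        }


def signed_modularity(net: SignedNetwork, partition: Partition) -> ModularityResult:
    """Evaluate the signed modularity of ``partition`` on ``net``.

    A sign whose total weight v is zero contributes a zero term by
    definition; an entirely empty network is degenerate.
    """
    if partition.n_nodes != net.n_nodes:
        raise ValidationError("partition does not cover the network's nodes")
    if net.v_pos == 0 and net.v_neg == 0:
        raise DegenerateInputError("network has no edges of either sign")
    delta = partition.same_module_matrix()
    if net.v_pos > 0:
        expected = np.outer(net.s_pos, net.s_pos) / net.v_pos
        m_pos = float(((net.w_pos - expected) * delta).sum() / net.v_pos)
    else:
        m_pos = 0.0
    if net.v_neg > 0:
        expected = np.outer(net.s_neg, net.s_neg) / net.v_neg
        m_neg = float(-((net.w_neg - expected) * delta).sum() / net.v_neg)
    else:
        m_neg = 0.0
    ratio = net.v_neg / (net.v_pos + net.v_neg)
    return ModularityResult(
        M=m_pos + ratio * m_neg, M_pos=m_pos, M_neg=m_neg, neg_weight_ratio=ratio
    )


def _phase_one(w_pos, w_neg, v_pos, v_neg, rng, record=None):
    """Greedy single-node moves on one (possibly aggregated) graph.

    Each sweep visits the nodes in a seeded random order and moves each node
    to the module with the largest positive gain (ties broken toward the
    smallest canonical label); sweeps repeat until no move improves M by
    more than ``GAIN_TOL``. Self-loop terms are module-invariant and cancel
    from every gain, so aggregated graphs need no special casing. Returns
    the label array and whether any move happened.
    """
    n = w_pos.shape[0]
    sp = w_pos.sum(axis=1)
    sn = w_neg.sum(axis=1)
    ivp = 1.0 / v_pos if v_pos > 0 else 0.0
    ivn = 1.0 / v_neg if v_neg > 0 else 0.0
    cp = ivp                          # coefficient of the positive term in M
    cn = 1.0 / (v_pos + v_neg)        # coefficient of the negative term in M

    comm = np.arange(n)
    sizes = np.ones(n, dtype=int)
    comm_sp = sp.copy()
    comm_sn = sn.copy()
    all_labels = np.arange(n)
    moved_any = False

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = comm[i]
            sizes[a] -= 1
            comm_sp[a] -= sp[i]
            comm_sn[a] -= sn[i]
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            k_pos = np.bincount(comm[mask], weights=w_pos[i, mask], minlength=n)
            k_neg = np.bincount(comm[mask], weights=w_neg[i, mask], minlength=n)
            gains = 2.0 * (
                cp * (k_pos - sp[i] * comm_sp * ivp)
                - cn * (k_neg - sn[i] * comm_sn * ivn)
            )
            candidates = all_labels[(sizes > 0) | (all_labels == a)]
            cand_gains = gains[candidates]
            best = candidates[cand_gains >= cand_gains.max() - GAIN_TOL][0]
            if best != a and gains[best] - gains[a] > GAIN_TOL:
                target = int(best)
                improved = True
                moved_any = True
            else:
                target = a
            comm[i] = target
            sizes[target] += 1
            comm_sp[target] += sp[i]
            comm_sn[target] += sn[i]
        if record is not None:
            record(comm)
    return comm, moved_any


def louvain(
    net: SignedNetwork,
    seed: int = 0,
    level: str = "lowest",
    return_history: bool = False,
) -> Partition | tuple[Partition, list[float]]:
    """Greedy two-phase signed-modularity maximisation.

    Phase 1 moves single nodes between modules until no move improves M;
    phase 2 aggregates modules into super-nodes (positive and negative
    weights summed separately, self-loops kept) and phase 1 repeats on the
    coarser graph, building a hierarchy of partitions.

    ``level="lowest"`` (default) returns the finest partition — the
    assignment after the first level's convergence. This is the convention
    used to build consensus agreement matrices: later aggregation levels
    can only merge its modules, and on benchmark networks the finest level
    tracks planted structure better than the coarsest. ``level="final"``
    returns the coarsest partition, the hierarchy's M-maximising endpoint.

    With ``return_history`` the modularity of the (original-node) partition
    after each sweep is also returned; it is non-decreasing.
    """
    if level not in ("lowest", "final"):
        raise ValidationError(f"level must be 'lowest' or 'final', got {level!r}")
    if net.v_pos == 0 and net.v_neg == 0:
        raise DegenerateInputError("network has no edges of either sign")
    rng = np.random.default_rng(seed)
    v_pos, v_neg = net.v_pos, net.v_neg  # totals are level-invariant
    w_pos, w_neg = net.w_pos, net.w_neg
    mapping = np.arange(net.n_nodes)
    history: list[float] = []
    lowest_labels: np.ndarray | None = None

    def record(comm):
        history.append(
            signed_modularity(net, Partition(comm[mapping])).M
        )

    while True:
        labels, _ = _phase_one(
            w_pos, w_neg, v_pos, v_neg, rng,
            record=record if return_history else None,
        )
        _, compact = np.unique(labels, return_inverse=True)
        composed = compact[mapping]
        if lowest_labels is None:
            lowest_labels = composed.copy()
            if level == "lowest":
                break
        n_modules = int(compact.max()) + 1
        if n_modules == w_pos.shape[0]:  # nothing merged: hierarchy converged
            break
        onehot = np.eye(n_modules)[compact]
        w_pos = onehot.T @ w_pos @ onehot
        w_neg = onehot.T @ w_neg @ onehot
        mapping = compact[mapping]

    partition = Partition(lowest_labels if level == "lowest" else composed)
    if return_history:
        return partition, history
    return partition


@dataclass(frozen=True)
class AgreementMatrix:
    """Co-assignment frequencies across clustering runs (zero diagonal)."""

    values: np.ndarray
    n_runs: int

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


def agreement_matrix(partitions: Sequence[Partition]) -> AgreementMatrix:
    """Fraction of partitions placing each node pair in the same module.

    The diagonal is set to zero so the matrix can be reused directly as an
    all-positive network by the consensus loop.
    """
    if not partitions:
        raise ValidationError("need at least one partition")
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValidationError("partitions are over different node sets")
    acc = np.zeros((n, n))
    for p in partitions:
        acc += p.same_module_matrix()
    acc /= len(partitions)
    np.fill_diagonal(acc, 0.0)
    return AgreementMatrix(values=acc, n_runs=len(partitions))


@dataclass(frozen=True)
class ConsensusResult:
    """Stable partition with its modularity on the ORIGINAL network.

    ``modularity_on_agreement`` records the same partition scored on the last
    re-clustered agreement network (None when the first batch already
    agreed), since either convention could be meant by "the modularity of the
    stable partition".
    """

    partition: Partition
    modularity: ModularityResult
    iterations: int
    n_runs: int
    seed: int
    modularity_on_agreement: ModularityResult | None = None


def consensus_cluster(
    net: SignedNetwork,
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 50,
    tau: float = 0.0,
    level: str = "lowest",
) -> ConsensusResult:
    """Stabilise Louvain by iteratively re-clustering the agreement matrix.

    Each iteration runs Louvain ``n_runs`` times (seeds ``seed + run``),
    declares convergence when all runs return the same partition up to label
    permutation, and otherwise re-clusters the agreement matrix (entries at
    or below ``tau`` zeroed; default 0 keeps the raw frequencies) as a new
    all-positive network. ``level`` selects the Louvain hierarchy level fed
    into the agreement matrix (the finest by default).
    """
    if n_runs < 2:
        raise ValidationError("consensus clustering needs n_runs >= 2")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    current = net
    agreement: AgreementMatrix | None = None
    for iteration in range(1, max_iter + 1):
        parts = [
            louvain(current, seed=seed + run, level=level) for run in range(n_runs)
        ]
        if all(p == parts[0] for p in parts[1:]):
            stable = parts[0]
            on_agreement = (
                signed_modularity(current, stable) if iteration > 1 else None
            )
            logger.info(
                "consensus converged in %d iteration(s): %d module(s)",
                iteration, stable.n_modules,
            )
            return ConsensusResult(
                partition=stable,
                modularity=signed_modularity(net, stable),
                iterations=iteration,
                n_runs=n_runs,
                seed=seed,
                modularity_on_agreement=on_agreement,
            )
        agreement = agreement_matrix(parts)
        values = agreement.values.copy()
        if tau > 0:
            values[values <= tau] = 0.0
        current = SignedNetwork(net.roi_names, values)
    raise ConvergenceError(
        f"consensus clustering did not converge within {max_iter} iterations",
        agreement=agreement,
    )


# ---------------------------------------------------------------------------
# Delimited import/export
# ---------------------------------------------------------------------------


def write_partition(
    partition: Partition, roi_names: Sequence[str], path: str | Path
) -> None:
    path = Path(path)
    if len(roi_names) != partition.n_nodes:
        raise ValidationError("roi_names length does not match partition")
    pd.DataFrame(
        {"roi_name": list(roi_names), "module_id": partition.assignment}
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_partition(path: str | Path) -> tuple[Partition, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("roi_name", "module_id"):
        if col not in df.columns:
            raise ValidationError(f"partition file missing column {col!r}")
    return Partition(df["module_id"].to_numpy()), df["roi_name"].astype(str).tolist()
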