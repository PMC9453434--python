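"""Independent oracles used by the test suite.

Everything here is deliberately naive — direct double-loop summation of the
modularity definition, brute-force enumeration of set partitions — so it
shares no code path with the package implementation it checks.
"""

import numpy as np
from sympy.utilities.iterables import multiset_partitions

import metacov as mc


def random_signed_network(rng, n):
    """Dense symmetric signed network with weights in [-1, 1], zero diagonal."""
    w = rng.uniform(-1.0, 1.0, size=(n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    return mc.SignedNetwork([f"n{i}" for i in range(n)], w)


def naive_signed_modularity(weights, labels):
    """Direct double-loop evaluation of the signed quality function."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    w_pos = np.where(w > 0, w, 0.0)
    w_neg = np.where(w < 0, -w, 0.0)
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    v_pos = s_pos.sum()
    v_neg = s_neg.sum()
    m_pos = 0.0
    m_neg = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if v_pos > 0:
                m_pos += (w_pos[i, j] - s_pos[i] * s_pos[j] / v_pos) / v_pos
            if v_neg > 0:
                m_neg -= (w_neg[i, j] - s_neg[i] * s_neg[j] / v_neg) / v_neg
    ratio = v_neg / (v_pos + v_neg)
    return m_pos + ratio * m_neg


def all_partitions(n):
    """Every set partition of range(n), as label arrays."""
    for blocks in multiset_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for module_id, block in enumerate(blocks, start=1):
            for node in block:
                labels[node] = module_id
        yield labels


def _vectorised_quality(net, labels):
    """Direct full-matrix evaluation of the quality function (test-local)."""
    delta = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    q = 0.0
    if net.v_pos > 0:
        q += ((net.w_pos - np.outer(net.s_pos, net.s_pos) / net.v_pos) * delta
              ).sum() / net.v_pos
    if net.v_neg > 0:
        q -= ((net.w_neg - np.outer(net.s_neg, net.s_neg) / net.v_neg) * delta
              ).sum() / (net.v_pos + net.v_neg)
    return q


def exhaustive_maximum(net):
    """Globally best quality and an argmax labelling by full enumeration."""
    best_q, best_labels = -np.inf, None
    for labels in all_partitions(net.n_nodes):
        q = _vectorised_quality(net, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
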