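"""Chance-corrected clustering agreement metrics.

Both the adjusted Rand index and adjusted mutual information are computed
from the r x c contingency table of two labelings, implemented directly
from their combinatorial definitions:

* ARI = (RI - E[RI]) / (max RI - E[RI]), all terms expressed through
  pair counts sum_ij C(n_ij, 2) and their marginal analogues, with the
  expectation under the permutation (hypergeometric) model.
* AMI = (MI - E[MI]) / (mean(H_a, H_b) - E[MI]); the expected mutual
  information is the exact hypergeometric sum over admissible cell counts,
  evaluated with log-gamma factorials. The arithmetic mean of the two
  entropies is used as the normalizer (the most common convention; the
  "max" normalizer is available via ``average_method``).

Both metrics are symmetric and invariant to relabeling either argument.
When both labelings are constant (a single cluster each) the partitions
agree completely and both metrics return 1.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["contingency_table", "adjusted_rand_index", "adjusted_mutual_info"]


def _validate_pair(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least two observations")
    return a, b


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """r x c matrix of co-occurrence counts between two labelings."""
    a, b = _validate_pair(labels_a, labels_b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.int64)
    return m * (m - 1) // 2


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index in [-1, 1]; 1 iff identical partitions, 0 in
    expectation for independent labelings."""
    table = contingency_table(labels_a, labels_b)
    n = int(table.sum())
    sum_cells = int(_comb2(table).sum())
    sum_a = int(_comb2(table.sum(axis=1)).sum())
    sum_b = int(_comb2(table.sum(axis=0)).sum())
    total = _comb2(np.int64(n))
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (each a single cluster)
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray, n: int) -> float:
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * np.log(n * nij / (a[i] * b[j]))
    return mi


def expected_mutual_information(a_counts: np.ndarray, b_counts: np.ndarray, n: int) -> float:
    """Exact E[MI] under the hypergeometric model of random tables with
    fixed marginals: for each cell, sum the MI contribution weighted by the
    hypergeometric probability of each admissible count."""
    gln = gammaln
    emi = 0.0
    log_n_fact = gln(n + 1)
    for ai in a_counts:
        for bj in b_counts:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_p = (
                    gln(ai + 1) + gln(bj + 1) + gln(n - ai + 1) + gln(n - bj + 1)
                    - log_n_fact - gln(nij + 1) - gln(ai - nij + 1)
                    - gln(bj - nij + 1) - gln(n - ai - bj + nij + 1)
                )
                emi += np.exp(log_p) * (nij / n) * np.log(n * nij / (ai * bj))
    return float(emi)


def adjusted_mutual_info(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Adjusted mutual information; <= 1, equal to 1 iff the labelings are
    identical up to relabeling, ~0 for independent labelings."""
    table = contingency_table(labels_a, labels_b)
    n = int(table.sum())
    a_counts = table.sum(axis=1)
    b_counts = table.sum(axis=0)
    h_a = _entropy(a_counts, n)
    h_b = _entropy(b_counts, n)
    if h_a == 0.0 and h_b == 0.0:  # both constant: complete agreement
        return 1.0
    mi = _mutual_information(table, n)
    emi = expected_mutual_information(a_counts, b_counts, n)
    if average_method == "arithmetic":
        denom = 0.5 * (h_a + h_b) - emi
    elif average_method == "max":
        denom = max(h_a, h_b) - emi
    else:
        raise ValueError(f"unknown average_method {average_method!r}")
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return float((mi - emi) / denom)
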