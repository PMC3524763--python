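"""Shared fixtures and independent oracle implementations.

The oracles here recompute entropies, mutual information and adjusted
residuals by explicit enumeration over contingency tables, independently of
the library code paths they are used to check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from siteclust.interdependency import RedundancyMatrix
from siteclust.msa_io import Alignment, DEFAULT_ALPHABET


def make_alignment(rows, labels=None, ids=None, alphabet=None):
    """Build an Alignment from a list of equal-length strings.

    The alphabet is widened to whatever symbols the rows use, so tests can
    work with abstract symbol columns, not just residues.
    """
    sym = np.array([list(r) for r in rows], dtype="<U1")
    n = sym.shape[1]
    if alphabet is None:
        alphabet = DEFAULT_ALPHABET | {str(c) for c in np.unique(sym)}
    return Alignment(
        ids=tuple(ids) if ids else tuple(f"seq{i+1}" for i in range(len(rows))),
        symbols=sym,
        site_labels=tuple(labels) if labels else tuple(range(1, n + 1)),
        alphabet=frozenset(alphabet),
    )


def rmat_from_R(R, labels=None, n=100):
    """A RedundancyMatrix wrapping an explicit R array (for clustering and
    tree tests that do not touch I or H)."""
    R = np.asarray(R, dtype=float)
    N = R.shape[0]
    labels = tuple(labels) if labels else tuple(range(1, N + 1))
    H = np.ones_like(R)
    return RedundancyMatrix(
        labels=labels,
        n=n,
        R=R,
        I=R * H,
        H=H,
        observed_alphabet_sizes=tuple([2] * N),
    )


# ---------------------------------------------------------------- oracles


def oracle_joint_entropy(col_i, col_j) -> float:
    """Explicit sum over the observed contingency table, natural log."""
    n = len(col_i)
    counts = Counter(zip(col_i, col_j))
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def oracle_entropy(col) -> float:
    n = len(col)
    return -sum((c / n) * math.log(c / n) for c in Counter(col).values())


def oracle_mutual_information(col_i, col_j) -> float:
    """Direct plug-in double sum over the contingency table."""
    n = len(col_i)
    joint = Counter(zip(col_i, col_j))
    pa = Counter(col_i)
    pb = Counter(col_j)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((pa[x] / n) * (pb[y] / n)))
    return total


def oracle_redundancy(col_i, col_j) -> float:
    h = oracle_joint_entropy(col_i, col_j)
    return 0.0 if h == 0.0 else oracle_mutual_information(col_i, col_j) / h


def oracle_two_way_adjusted_residual(col_i, col_j, a: str, b: str) -> float:
    """Haberman adjusted residual of cell (a, b) of the 2-way table."""
    n = len(col_i)
    o = sum(1 for x, y in zip(col_i, col_j) if x == a and y == b)
    p_row = sum(1 for x in col_i if x == a) / n
    p_col = sum(1 for y in col_j if y == b) / n
    e = n * p_row * p_col
    return (o - e) / math.sqrt(e * (1 - p_row) * (1 - p_col))


def random_column_pair(rng, n=None, alphabet="ACDE", dependent_prob=0.5):
    """A random pair of small symbol columns, sometimes coupled."""
    if n is None:
        n = int(rng.integers(4, 30))
    letters = list(alphabet)
    a = rng.choice(letters, size=n)
    if rng.random() < dependent_prob:
        mapping = {x: y for x, y in zip(letters, rng.permutation(letters))}
        noise = rng.random(n) < 0.3
        b = np.where(noise, rng.choice(letters, size=n), [mapping[x] for x in a])
    else:
        b = rng.choice(letters, size=n)
    return list(a), list(b)


@pytest.fixture
def toy_alignment():
    """Five sequences over five sites with visible structure."""
    return make_alignment(
        [
            "ACDEA",
            "ACDEA",
            "AGHEC",
            "TGHKC",
            "TCDKA",
        ]
    )
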