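"""Pairwise interdependency between aligned sites.

Each aligned site is a categorical random variable over the residue
alphabet.  For two sites X_i and X_i' with plug-in (maximum-likelihood)
probabilities estimated from the alignment rows,

    R_ii' = I(X_i, X_i') / H(X_i, X_i')

is the *interdependency redundancy*: mutual information normalized by joint
entropy.  R is 1 for perfectly dependent columns (one is a bijective
relabeling of the other), 0 for columns whose empirical joint distribution
factorizes exactly, and base-free (I and H scale together under a change of
logarithm base).  Because 2 n I(X_i, X_i') is the G-statistic for
independence, a chi-square test on R decides whether two sites are
dependent:  X_i and X_i' are dependent when

    R_ii' >= chi2_{(G_i - 1)(G_i' - 1)}(1 - alpha) / (2 n H(X_i, X_i')),

equivalently 2 n I >= the chi-square quantile.  Natural logarithms are used
internally so this equivalence holds on the nat scale the G-statistic
requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from siteclust.msa_io import Alignment

#: Minimum number of non-redundant sequences below which the dependency
#: statistics are unreliable.
MIN_SEQUENCES = 5


def _joint_counts(col_i: Sequence, col_j: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contingency counts and the two marginal count vectors."""
    a = np.asarray(col_i)
    b = np.asarray(col_j)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"columns must be 1-D and of equal length, got {a.shape} and {b.shape}"
        )
    if a.size == 0:
        raise ValueError("columns must be non-empty")
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    nb = ib.max() + 1
    joint = np.bincount(ia * nb + ib, minlength=(ia.max() + 1) * nb)
    joint = joint[joint > 0]
    return joint, np.bincount(ia), np.bincount(ib)


def _entropy(counts: np.ndarray, base: float | None) -> float:
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        h /= np.log(base)
    return h


def joint_entropy(col_i: Sequence, col_j: Sequence, base: float | None = None) -> float:
    """Joint entropy H(X_i, X_i') of two symbol columns, in nats.

    Plug-in relative frequencies over the observed joint symbols; 0 when a
    single joint symbol is observed.  ``base`` switches the logarithm base
    (``None`` means natural log).
    """
    joint, _, _ = _joint_counts(col_i, col_j)
    return _entropy(joint, base)


def marginal_entropy(col: Sequence, base: float | None = None) -> float:
    """Entropy of a single symbol column (plug-in estimate)."""
    _, counts = np.unique(np.asarray(col), return_counts=True)
    return _entropy(counts, base)


def mutual_information(col_i: Sequence, col_j: Sequence, base: float | None = None) -> float:
    """Mutual information I(X_i, X_i') of two symbol columns, in nats.

    Computed by the direct double sum over observed joint symbols,
    I = sum p(x,y) log[p(x,y) / (p(x) p(y))]; equal to
    H_i + H_j - H_ij up to floating point.  Never negative (clipped at 0).
    """
    a = np.asarray(col_i)
    b = np.asarray(col_j)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"columns must be 1-D and of equal length, got {a.shape} and {b.shape}"
        )
    if a.size == 0:
        raise ValueError("columns must be non-empty")
    n = a.size
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    nb = ib.max() + 1
    code = ia * nb + ib
    uniq, counts = np.unique(code, return_counts=True)
    pa = np.bincount(ia) / n
    pb = np.bincount(ib) / n
    pj = counts / n
    terms = pj * np.log(pj / (pa[uniq // nb] * pb[uniq % nb]))
    i = float(terms.sum())
    if base is not None:
        i /= np.log(base)
    return max(i, 0.0)


def redundancy(col_i: Sequence, col_j: Sequence, base: float | None = None) -> float:
    """Normalized interdependency redundancy R = I / H in [0, 1].

    When both columns are constant the joint entropy is 0 and R is defined
    as 0: a pair with no variation carries no interdependency signal.
    """
    h = joint_entropy(col_i, col_j, base)
    if h == 0.0:
        return 0.0
    r = mutual_information(col_i, col_j, base) / h
    return min(max(r, 0.0), 1.0)


@dataclass(frozen=True)
class RedundancyMatrix:
    """All pairwise interdependency statistics of an alignment.

    ``R``, ``I`` and ``H`` are symmetric N x N arrays.  The diagonal of
    ``H`` (and of ``I``) holds the marginal entropies; the diagonal of
    ``R`` is 1 for variable sites and 0 for constant (uninformative) ones.
    ``observed_alphabet_sizes`` gives G_i, the number of distinct symbols
    observed at each site, used for the degrees of freedom of the
    dependency test.
    """

    labels: tuple[int, ...]
    n: int
    R: np.ndarray
    I: np.ndarray
    H: np.ndarray
    observed_alphabet_sizes: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def index(self, label: int) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no site labelled {label}") from None

    def r(self, label_i: int, label_j: int) -> float:
        return float(self.R[self.index(label_i), self.index(label_j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="site", float_format="%.10g")


def redundancy_matrix(aln: Alignment) -> RedundancyMatrix:
    """Compute R, I and H for every pair of sites of an alignment.

    Warns when fewer than five unique rows are available (below the minimum
    for statistically meaningful dependency estimates).
    """
    n_sites = aln.n_sites
    if n_sites < 2:
        raise ValueError("need at least 2 columns to compute pairwise statistics")
    uniq_rows = len({"".join(r) for r in aln.symbols})
    if uniq_rows < MIN_SEQUENCES:
        warnings.warn(
            f"only {uniq_rows} unique sequences; at least {MIN_SEQUENCES} are "
            "needed for statistically significant results",
            stacklevel=2,
        )
    n = aln.n_rows
    R = np.zeros((n_sites, n_sites))
    I = np.zeros((n_sites, n_sites))
    H = np.zeros((n_sites, n_sites))
    sizes = []
    cols = [aln.symbols[:, j] for j in range(n_sites)]
    marg = [marginal_entropy(c) for c in cols]
    for j, c in enumerate(cols):
        sizes.append(int(np.unique(c).size))
        H[j, j] = marg[j]
        I[j, j] = marg[j]
        R[j, j] = 1.0 if marg[j] > 0 else 0.0
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            h = joint_entropy(cols[i], cols[j])
            mi = min(mutual_information(cols[i], cols[j]), h)
            r = 0.0 if h == 0.0 else mi / h
            H[i, j] = H[j, i] = h
            I[i, j] = I[j, i] = mi
            R[i, j] = R[j, i] = r
    return RedundancyMatrix(
        labels=tuple(aln.site_labels),
        n=n,
        R=R,
        I=I,
        H=H,
        observed_alphabet_sizes=tuple(sizes),
    )


@dataclass(frozen=True)
class DependencyResult:
    """Outcome of the chi-square dependency test for one site pair."""

    dependent: bool | None  #: None when the pair is not testable (df = 0)
    threshold: float  #: critical value on the R scale
    statistic: float  #: 2 n I, the G-statistic
    quantile: float  #: chi-square quantile at 1 - alpha
    df: int


def dependency_test(
    pair: tuple[int, int],
    rmat: RedundancyMatrix,
    alpha: float = 0.05,
    *,
    df_mode: str = "observed",
) -> DependencyResult:
    """Chi-square test of dependence between two sites.

    The decision compares R_ii' with chi2_df(1 - alpha) / (2 n H); since
    R = I / H this is exactly the G-test 2 n I >= chi2 quantile.  Degrees
    of freedom are (G_i - 1)(G_j - 1) with G the *observed* distinct symbol
    count at each site by default (``df_mode="full"`` uses the fixed
    21-letter alphabet instead).  A pair involving a constant column has
    df = 0 and is reported as not testable (``dependent=None``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    i = rmat.index(pair[0])
    j = rmat.index(pair[1])
    if df_mode == "observed":
        gi = rmat.observed_alphabet_sizes[i]
        gj = rmat.observed_alphabet_sizes[j]
    elif df_mode == "full":
        gi = gj = 21
    else:
        raise ValueError(f"unknown df_mode: {df_mode!r}")
    df = (gi - 1) * (gj - 1)
    statistic = 2.0 * rmat.n * rmat.I[i, j]
    if df < 1:
        return DependencyResult(None, np.inf, statistic, np.inf, df)
    quantile = float(stats.chi2.ppf(1.0 - alpha, df))
    h = rmat.H[i, j]
    if h <= 0.0:
        return DependencyResult(None, np.inf, statistic, quantile, df)
    threshold = quantile / (2.0 * rmat.n * h)
    dependent = bool(rmat.R[i, j] >= threshold)
    return DependencyResult(dependent, threshold, statistic, quantile, df)


def sr_sum(site: int, site_set: Iterable[int], rmat: RedundancyMatrix) -> float:
    """SR(i): the sum of R between one site and every other site of a set.

    The site itself is excluded from the sum, so a singleton set gives 0.
    """
    i = rmat.index(site)
    total = 0.0
    for other in site_set:
        if other == site:
            continue
        total += float(rmat.R[i, rmat.index(other)])
    return total


def pair_report(rmat: RedundancyMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair table of I, H, R, df, test threshold and decision."""
    rows = []
    for a in range(rmat.n_sites):
        for b in range(a + 1, rmat.n_sites):
            li, lj = rmat.labels[a], rmat.labels[b]
            res = dependency_test((li, lj), rmat, alpha)
            rows.append(
                {
                    "site_i": li,
                    "site_j": lj,
                    "I": rmat.I[a, b],
                    "H": rmat.H[a, b],
                    "R": rmat.R[a, b],
                    "df": res.df,
                    "threshold": res.threshold,
                    "dependent": res.dependent,
                }
            )
    return pd.DataFrame(rows)
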