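"""Pattern discovery: significant amino-acid compound events within a cluster.

A *compound event* is a joint assignment of one symbol per site over a set
of aligned sites, e.g. (N, K, E) on sites 60, 63, 64.  Under the null that
the sites carry no pattern, the expected count of an event is the product
of its marginal site frequencies scaled by the number of rows,
e = n * prod_j p_j.  The residual is d = o - e and the *adjusted residual*

    gamma = (o - e) / sqrt(e * prod_j (1 - p_j))

standardizes it by the variance of d under independence — the Haberman
adjusted residual of a contingency-table cell, generalized from two-way
tables to order-m events (for m = 2 it reduces exactly to the classical
formula).  gamma is asymptotically standard normal, so a cutoff of 2.58
corresponds to 99% two-sided confidence and 3.29 to 99.9%.

The normal approximation breaks down for events whose expected count is
tiny (a single observation of a rare residue combination can produce a huge
gamma that means nothing); events with e below ``min_expected`` (default 5,
the classical rule of thumb for residual-based tests in sparse tables) are
therefore reported as not testable and excluded from significance calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from siteclust.msa_io import GAP, Alignment

#: Expected-count floor below which the normal approximation to the
#: adjusted residual is not trusted.
DEFAULT_MIN_EXPECTED = 5.0


def confidence_to_cutoff(confidence: float) -> float:
    """Two-sided standard-normal critical value for a confidence level.

    confidence 0.99 -> 2.58, 0.999 -> 3.29 (to 2 decimal places).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be strictly between 0 and 1")
    return float(stats.norm.ppf((1.0 + confidence) / 2.0))


@dataclass(frozen=True)
class Pattern:
    """A compound event with its occurrence statistics.

    ``adjusted_residual`` is the standardized deviation of the observed
    count from independence; ``order`` is the number of sites spanned.
    """

    sites: tuple[int, ...]
    symbols: tuple[str, ...]
    observed: int
    expected: float
    residual: float
    variance: float
    adjusted_residual: float
    order: int

    def __str__(self) -> str:
        ev = "".join(self.symbols)
        at = ",".join(str(s) for s in self.sites)
        return (
            f"{ev} @ sites {at}: o={self.observed}, e={self.expected:.3f}, "
            f"gamma={self.adjusted_residual:.2f}"
        )


def adjusted_residual(
    event: tuple[Sequence[int], Sequence[str]], aln: Alignment
) -> Pattern:
    """Observed/expected statistics of one compound event.

    ``event`` is ``(site_labels, symbols)`` with one symbol per site.  Every
    symbol must occur marginally at its site (p_j > 0), otherwise the event
    is impossible under the independence model and an error is raised.
    """
    sites, symbols = event
    sites = tuple(int(s) for s in sites)
    symbols = tuple(str(a) for a in symbols)
    if len(sites) != len(symbols):
        raise ValueError("one symbol per site required")
    if len(sites) < 2:
        raise ValueError("a compound event spans at least 2 sites")
    sub = aln.columns(sites)
    n = aln.n_rows
    probs = []
    hit = np.ones(n, dtype=bool)
    for j, sym in enumerate(symbols):
        col = sub[:, j]
        p = float(np.mean(col == sym))
        if p == 0.0:
            raise ValueError(
                f"symbol {sym!r} never observed at site {sites[j]}"
            )
        probs.append(p)
        hit &= col == sym
    observed = int(hit.sum())
    probs_arr = np.array(probs)
    expected = n * float(np.prod(probs_arr))
    variance = expected * float(np.prod(1.0 - probs_arr))
    resid = observed - expected
    gamma = resid / np.sqrt(variance) if variance > 0 else 0.0
    return Pattern(
        sites=sites,
        symbols=symbols,
        observed=observed,
        expected=expected,
        residual=resid,
        variance=variance,
        adjusted_residual=float(gamma),
        order=len(sites),
    )


def _candidate_events(
    sites: tuple[int, ...], aln: Alignment, allow_gaps: bool
) -> Iterable[tuple[str, ...]]:
    """Distinct row projections onto the sites, in first-appearance order."""
    sub = aln.columns(sites)
    seen = {}
    for row in sub:
        key = tuple(row)
        if key not in seen:
            seen[key] = True
    for ev in seen:
        if not allow_gaps and GAP in ev:
            continue
        yield ev


def enumerate_patterns(
    cluster: Iterable[int],
    aln: Alignment,
    cutoff: float = 3.29,
    *,
    span: str = "full",
    allow_gaps: bool = True,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> list[Pattern]:
    """All significant patterns within a cluster of sites.

    Candidates are the residue combinations actually observed in the
    alignment rows restricted to the cluster's sites — the search space is
    the set of distinct row projections, not the full alphabet lattice.
    With ``span="full"`` (default) events span every site of the cluster;
    ``span="sub"`` also enumerates every sub-order event over >= 2 sites.
    An event is reported when its expected count is at least
    ``min_expected`` (set 0 to disable the validity screen) and its
    adjusted residual strictly exceeds ``cutoff``.  Results are sorted by
    adjusted residual, descending.
    """
    sites = tuple(sorted(int(s) for s in set(cluster)))
    if len(sites) < 2:
        raise ValueError("a cluster needs at least 2 sites for patterns")
    if span == "full":
        site_sets = [sites]
    elif span == "sub":
        site_sets = [
            combo
            for m in range(2, len(sites) + 1)
            for combo in itertools.combinations(sites, m)
        ]
    else:
        raise ValueError(f"unknown span: {span!r}")

    found: list[Pattern] = []
    for ss in site_sets:
        for ev in _candidate_events(ss, aln, allow_gaps):
            pat = adjusted_residual((ss, ev), aln)
            if pat.expected < min_expected:
                continue
            if pat.adjusted_residual > cutoff:
                found.append(pat)
    found.sort(
        key=lambda p: (-p.adjusted_residual, p.sites, p.symbols)
    )
    return found


def patterns_to_frame(patterns: Sequence[Pattern]) -> pd.DataFrame:
    """Tabular report of discovered patterns."""
    return pd.DataFrame(
        [
            {
                "sites": ",".join(str(s) for s in p.sites),
                "symbols": "".join(p.symbols),
                "order": p.order,
                "observed": p.observed,
                "expected": p.expected,
                "residual": p.residual,
                "adjusted_residual": p.adjusted_residual,
            }
            for p in patterns
        ],
        columns=[
            "sites",
            "symbols",
            "order",
            "observed",
            "expected",
            "residual",
            "adjusted_residual",
        ],
    )
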