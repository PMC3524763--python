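"""k-modes attribute clustering of aligned sites.

Sites are partitioned into k clusters by an iterative scheme analogous to
k-medoids, with two substitutions: the similarity measure is the
interdependency redundancy R between sites, and the cluster centre is the
*mode* — the member whose summed redundancy SR(i) to the other members is
highest.  One run: (1) pick k distinct sites at random as candidate modes;
(2) assign every remaining site to the mode with the highest R; (3)
recompute each cluster's mode; repeat (2)-(3) until no site changes cluster.
The k-sweep runs this for every k from N-1 down to 2 so that the nested
cluster structure can later be assembled into a cluster tree.

Cluster quality is summarized by SR(mode)/N*, the mode's summed redundancy
divided by the number of attribute pairs involving the mode (cluster size
minus one), which for a pair equals its R and is always in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from siteclust.interdependency import RedundancyMatrix


@dataclass(frozen=True)
class ClusterConfiguration:
    """A partition of all sites into k clusters at one value of k.

    ``clusters`` are frozensets of site labels; ``modes[c]`` is the mode of
    ``clusters[c]`` and ``sr_mode[c]`` its normalized SR(mode) value.
    """

    k: int
    clusters: tuple[frozenset[int], ...]
    modes: tuple[int, ...]
    sr_mode: tuple[float, ...]
    iterations: int
    seed: int | None
    converged: bool
    objective: float

    def labels_for(self, site_order: tuple[int, ...]) -> np.ndarray:
        """Integer cluster labels in the given site order (for e.g. ARI)."""
        lookup = {}
        for c, members in enumerate(self.clusters):
            for s in members:
                lookup[s] = c
        return np.array([lookup[s] for s in site_order])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c,
                "mode": self.modes[c],
                "sr_mode": self.sr_mode[c],
                "order": len(members),
                "sites": ",".join(str(s) for s in sorted(members)),
            }
            for c, members in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows)


def compute_mode(cluster, rmat: RedundancyMatrix) -> int:
    """The cluster member with maximal SR within the cluster.

    SR(i) sums R between i and every other member; ties are broken by the
    lowest site label.  A singleton's mode is its only member.
    """
    members = sorted(cluster)
    if not members:
        raise ValueError("cluster must be non-empty")
    idx = [rmat.index(s) for s in members]
    sub = rmat.R[np.ix_(idx, idx)]
    sr = sub.sum(axis=1) - np.diag(sub)
    best = int(np.argmax(sr))  # argmax takes the first (lowest label) on ties
    return members[best]


def sr_mode_value(
    cluster, rmat: RedundancyMatrix, *, normalization: str = "mode_pairs"
) -> float:
    """SR(mode) of a cluster, normalized to [0, 1].

    ``normalization="mode_pairs"`` (default) divides SR(mode) by the number
    of pairs involving the mode, i.e. cluster size minus one, so that a
    pair's value equals its R.  ``"all_pairs"`` divides by C(size, 2)
    instead.  Singletons score 0.
    """
    members = sorted(cluster)
    size = len(members)
    if size <= 1:
        return 0.0
    mode = compute_mode(cluster, rmat)
    mi = rmat.index(mode)
    sr = sum(
        float(rmat.R[mi, rmat.index(s)]) for s in members if s != mode
    )
    if normalization == "mode_pairs":
        denom = size - 1
    elif normalization == "all_pairs":
        denom = math.comb(size, 2)
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    return sr / denom


def _objective(assign: np.ndarray, modes: np.ndarray, R: np.ndarray) -> float:
    """Total within-cluster redundancy to the mode (higher is better)."""
    total = 0.0
    for c, m in enumerate(modes):
        members = np.flatnonzero(assign == c)
        total += R[m, members].sum() - R[m, m] * (m in members)
    return float(total)


def run_kmodes(
    rmat: RedundancyMatrix,
    k: int,
    seed: int | None = None,
    max_iter: int = 100,
    *,
    init_modes=None,
) -> ClusterConfiguration:
    """One k-modes run on a redundancy matrix.

    Deterministic given ``seed``.  Assignment ties keep the current cluster
    when it is among the best, otherwise pick the mode with the lowest site
    label.  A cluster emptied by reassignment is reseeded with the site
    worst served by the current modes (lowest maximal R to any mode).
    Terminates when no site changes cluster, or at ``max_iter`` with
    ``converged=False`` and a warning.
    """
    N = rmat.n_sites
    if not 2 <= k <= N:
        raise ValueError(f"k must be in [2, {N}], got {k}")
    R = rmat.R
    rng = np.random.default_rng(seed)
    if init_modes is None:
        modes = np.sort(rng.choice(N, size=k, replace=False))
    else:
        modes = np.asarray([rmat.index(s) for s in init_modes])
        if len(set(modes.tolist())) != k:
            raise ValueError("init_modes must name k distinct sites")

    assign = np.full(N, -1)
    for c, m in enumerate(modes):
        assign[m] = c

    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        prev = assign.copy()
        # Step 2: assign every non-mode site to its best mode.
        new_assign = np.full(N, -1)
        for c, m in enumerate(modes):
            new_assign[m] = c
        mode_set = set(modes.tolist())
        for i in range(N):
            if i in mode_set:
                continue
            r_to_modes = R[i, modes]
            best = r_to_modes.max()
            candidates = np.flatnonzero(r_to_modes == best)
            if prev[i] in candidates:
                choice = prev[i]
            else:
                # lowest mode label among the tied best
                choice = int(candidates[np.argmin(modes[candidates])])
            new_assign[i] = choice
        # Reseed any emptied cluster with the worst-served site.
        for c in range(k):
            if not np.any(new_assign == c):
                fit = R[:, modes].max(axis=1)
                movable = [
                    i
                    for i in range(N)
                    if i not in mode_set and np.sum(new_assign == new_assign[i]) > 1
                ]
                worst = min(movable, key=lambda i: (fit[i], i))
                new_assign[worst] = c
                modes[c] = worst
                mode_set = set(modes.tolist())
        assign = new_assign
        # Step 3: recompute modes.
        new_modes = modes.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            sub = R[np.ix_(members, members)]
            sr = sub.sum(axis=1) - np.diag(sub)
            new_modes[c] = members[int(np.argmax(sr))]
        modes = new_modes
        if np.array_equal(assign, prev):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"k-modes did not converge in {max_iter} iterations (k={k})",
            stacklevel=2,
        )

    clusters = []
    out_modes = []
    srv = []
    order = np.argsort([rmat.labels[m] for m in modes])
    for c in order:
        members = frozenset(rmat.labels[i] for i in np.flatnonzero(assign == c))
        clusters.append(members)
        out_modes.append(compute_mode(members, rmat))
        srv.append(sr_mode_value(members, rmat))
    return ClusterConfiguration(
        k=k,
        clusters=tuple(clusters),
        modes=tuple(out_modes),
        sr_mode=tuple(srv),
        iterations=t,
        seed=seed,
        converged=converged,
        objective=_objective(assign, modes, R),
    )


def sweep_k(
    rmat: RedundancyMatrix,
    *,
    k_max: int | None = None,
    k_min: int = 2,
    seed: int | None = None,
    restarts: int = 1,
    max_iter: int = 100,
) -> list[ClusterConfiguration]:
    """Run k-modes for every k from ``k_max`` (default N-1) down to ``k_min``.

    For each k the best of ``restarts`` runs (by total within-cluster
    redundancy to the mode) is kept.  Restart seeds are derived
    deterministically from ``seed``, so identical arguments give an
    identical sweep.
    """
    N = rmat.n_sites
    if k_max is None:
        k_max = N - 1
    if not 2 <= k_min <= k_max <= N:
        raise ValueError(f"need 2 <= k_min <= k_max <= {N}")
    configs = []
    for k in range(k_max, k_min - 1, -1):
        best = None
        for r in range(restarts):
            sub_seed = (
                None
                if seed is None
                else int(np.random.SeedSequence([seed, k, r]).generate_state(1)[0] % (2**31))
            )
            cfg = run_kmodes(rmat, k, seed=sub_seed, max_iter=max_iter)
            if best is None or cfg.objective > best.objective:
                best = cfg
        configs.append(best)
    return configs
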