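"""Seeded synthetic alignments with planted dependency structure.

The generator emulates the column statistics the pipeline is built to
detect, without simulating evolution along a phylogeny.  Sites belong
either to the i.i.d. uniform background or to a *block* of mutually
dependent sites: each block carries a latent symbol stream (one uniform
draw per row) and every member site copies the latent symbol through a
site-specific bijective relabeling with probability rho, or draws uniform
noise otherwise.  This latent-stream copy model makes within-block mutual
information monotone in rho (rho = 1 gives pairwise redundancy R = 1 up to
relabeling, rho = 0 gives independent columns) and keeps the blocks
analytically transparent.  On top of the blocks, a *merge schedule* couples
groups of blocks weakly through a second-level latent stream, planting a
nested hierarchy for the cluster tree to recover, and explicit amino-acid
*patterns* overwrite chosen sites in a chosen fraction of rows.  Gaps are
injected per column at a fixed rate kept below the 20% filtering threshold
so the planted columns survive preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from siteclust.msa_io import AMINO_ACIDS, GAP, Alignment, DEFAULT_ALPHABET


@dataclass(frozen=True)
class Block:
    """A set of mutually dependent sites with coupling strength rho."""

    sites: tuple[int, ...]  #: 1-based site labels
    rho: float = 0.8


@dataclass(frozen=True)
class PlantedPattern:
    """A specific residue combination planted at a target row frequency."""

    sites: tuple[int, ...]
    symbols: tuple[str, ...]
    frequency: float


@dataclass(frozen=True)
class Merge:
    """Second-level coupling of several blocks (by index into ``blocks``)."""

    block_indices: tuple[int, ...]
    rho: float = 0.5


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: partition, patterns and hierarchy edges."""

    site_labels: tuple[int, ...]
    partition: tuple[int, ...]  #: per-site block id; -1 for background
    blocks: tuple[Block, ...]
    patterns: tuple[PlantedPattern, ...]
    merges: tuple[Merge, ...]

    def partition_labels(self) -> np.ndarray:
        """Per-site integer labels with background sites as singletons."""
        out = []
        next_free = len(self.blocks)
        for p in self.partition:
            if p >= 0:
                out.append(p)
            else:
                out.append(next_free)
                next_free += 1
        return np.array(out)

    def hierarchy_edges(self) -> list[tuple[frozenset[int], frozenset[int]]]:
        """Planted (child sites, parent sites) nesting relations."""
        edges = []
        for merge in self.merges:
            parent = frozenset(
                s for b in merge.block_indices for s in self.blocks[b].sites
            )
            for b in merge.block_indices:
                edges.append((frozenset(self.blocks[b].sites), parent))
        return edges


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic alignment.

    Defaults give 200 rows over 12 sites in three rho = 0.8 blocks of
    four sites — enough signal for the clustering to recover the planted
    partition, with coupling well short of perfect copies.
    """

    n_rows: int = 200
    n_sites: int = 12
    blocks: tuple[Block, ...] = (
        Block(sites=(1, 2, 3, 4), rho=0.8),
        Block(sites=(5, 6, 7, 8), rho=0.8),
        Block(sites=(9, 10, 11, 12), rho=0.8),
    )
    patterns: tuple[PlantedPattern, ...] = ()
    merges: tuple[Merge, ...] = ()
    gap_rate: float = 0.0
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_sites < 1:
            raise ValueError("n_rows and n_sites must be positive")
        seen: set[int] = set()
        for blk in self.blocks:
            if not 0.0 <= blk.rho <= 1.0:
                raise ValueError("block rho must be in [0, 1]")
            for s in blk.sites:
                if not 1 <= s <= self.n_sites:
                    raise ValueError(f"block site {s} outside 1..{self.n_sites}")
                if s in seen:
                    raise ValueError(f"site {s} appears in two blocks")
                seen.add(s)
        for merge in self.merges:
            if not 0.0 <= merge.rho <= 1.0:
                raise ValueError("merge rho must be in [0, 1]")
            for b in merge.block_indices:
                if not 0 <= b < len(self.blocks):
                    raise ValueError(f"merge references unknown block {b}")
        # Patterns sharing a site must sit on the identical site tuple and
        # leave room for each other; anything else is infeasible.
        by_sites: dict[tuple[int, ...], float] = {}
        claimed: dict[int, tuple[int, ...]] = {}
        for pat in self.patterns:
            if len(pat.sites) != len(pat.symbols):
                raise ValueError("pattern needs one symbol per site")
            if not 0.0 < pat.frequency < 1.0:
                raise ValueError("pattern frequency must be in (0, 1)")
            key = tuple(pat.sites)
            for s in pat.sites:
                if not 1 <= s <= self.n_sites:
                    raise ValueError(f"pattern site {s} outside 1..{self.n_sites}")
                if s in claimed and claimed[s] != key:
                    raise ValueError(
                        f"site {s} shared by patterns on different site sets"
                    )
                claimed[s] = key
            by_sites[key] = by_sites.get(key, 0.0) + pat.frequency
        for key, total in by_sites.items():
            if total >= 1.0:
                raise ValueError(
                    f"pattern frequencies on sites {key} sum to {total} >= 1"
                )
        if not 0.0 <= self.gap_rate < 0.2:
            raise ValueError("gap_rate must be in [0, 0.2) to survive filtering")
        bad = set(self.alphabet) - (DEFAULT_ALPHABET - {GAP})
        if bad or len(self.alphabet) < 2:
            raise ValueError("alphabet must be >= 2 standard residues")


def generate(spec: PlantSpec) -> tuple[Alignment, GroundTruth]:
    """Generate one alignment and its ground truth, deterministically.

    Layering order: background noise, merge-level latent streams, block
    latent streams, member-site emission, planted patterns, gaps.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.alphabet))
    a = len(letters)
    n, N = spec.n_rows, spec.n_sites

    sym = letters[rng.integers(0, a, size=(n, N))]

    merge_stream: dict[int, np.ndarray] = {}
    block_merge_rho: dict[int, float] = {}
    for merge in spec.merges:
        stream = rng.integers(0, a, size=n)
        for b in merge.block_indices:
            # per-block bijective relabeling of the shared stream
            perm = rng.permutation(a)
            merge_stream[b] = perm[stream]
            block_merge_rho[b] = merge.rho

    partition = [-1] * N
    for b, blk in enumerate(spec.blocks):
        latent = rng.integers(0, a, size=n)
        if b in merge_stream:
            take = rng.random(n) < block_merge_rho[b]
            latent = np.where(take, merge_stream[b], latent)
        for s in blk.sites:
            partition[s - 1] = b
            perm = rng.permutation(a)
            copy = rng.random(n) < blk.rho
            noise = rng.integers(0, a, size=n)
            sym[:, s - 1] = np.where(copy, letters[perm[latent]], letters[noise])

    # Patterns grouped by site tuple share one uniform draw so their row
    # sets are disjoint.
    groups: dict[tuple[int, ...], list[PlantedPattern]] = {}
    for pat in spec.patterns:
        groups.setdefault(tuple(pat.sites), []).append(pat)
    for key, pats in groups.items():
        u = rng.random(n)
        lo = 0.0
        for pat in pats:
            rows = (u >= lo) & (u < lo + pat.frequency)
            lo += pat.frequency
            for s, sm in zip(pat.sites, pat.symbols):
                sym[rows, s - 1] = sm

    if spec.gap_rate > 0.0:
        n_gaps = int(np.floor(spec.gap_rate * n))
        if n_gaps / n >= 0.2:  # defensive; validate() already bounds the rate
            raise ValueError("gap_rate too high for the 20% column filter")
        for j in range(N):
            rows = rng.choice(n, size=n_gaps, replace=False)
            sym[rows, j] = GAP

    aln = Alignment(
        ids=tuple(f"synth_{i + 1}" for i in range(n)),
        symbols=sym,
        site_labels=tuple(range(1, N + 1)),
    )
    truth = GroundTruth(
        site_labels=aln.site_labels,
        partition=tuple(partition),
        blocks=tuple(spec.blocks),
        patterns=tuple(spec.patterns),
        merges=tuple(spec.merges),
    )
    return aln, truth
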