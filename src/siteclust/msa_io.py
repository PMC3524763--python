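"""Reading, preprocessing and writing of multiple sequence alignments.

An :class:`Alignment` is an M x N array of single-character symbols (the 20
amino acids plus a gap symbol) together with per-column *site labels* that
carry the reference numbering of the protein family (e.g. ubiquitin sites
6-74).  Preprocessing follows the standard protocol for alignment-column
statistics: drop insert-state columns, drop columns with too many gaps,
collapse duplicate sequences, and relabel the retained columns so that every
downstream report speaks in reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
#: Ambiguity / non-standard residue codes (Asx, Glx, unknown, Sec, Pyl).
AMBIGUOUS: frozenset[str] = frozenset("BZXUO")

DEFAULT_ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | {GAP}


class AlignmentFormatError(ValueError):
    """Raised when an input file cannot be interpreted as an alignment."""


@dataclass(frozen=True)
class Alignment:
    """An aligned block of sequences over a fixed symbol alphabet.

    Parameters
    ----------
    ids:
        One identifier per row, order preserved from the input file.
    symbols:
        ``(M, N)`` array of single-character symbols.
    site_labels:
        N strictly increasing integer labels giving the reference numbering
        of each retained column.
    alphabet:
        The admissible symbol set (20 amino acids plus the gap symbol by
        default).
    """

    ids: tuple[str, ...]
    symbols: np.ndarray
    site_labels: tuple[int, ...]
    alphabet: frozenset[str] = field(default=DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype="<U1")
        object.__setattr__(self, "symbols", sym)
        if sym.ndim != 2:
            raise ValueError("symbols must be a 2-D array of single characters")
        m, n = sym.shape
        if len(self.ids) != m:
            raise ValueError(f"{len(self.ids)} ids for {m} rows")
        if len(self.site_labels) != n:
            raise ValueError(
                f"{len(self.site_labels)} site labels for {n} columns"
            )
        labels = np.asarray(self.site_labels)
        if n > 1 and not np.all(np.diff(labels) > 0):
            raise ValueError("site_labels must be strictly increasing")
        present = set(np.unique(sym))
        unknown = present - set(self.alphabet)
        if unknown:
            raise ValueError(f"symbols outside alphabet: {sorted(unknown)}")

    @property
    def n_rows(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_sites(self) -> int:
        return self.symbols.shape[1]

    def column(self, label: int) -> np.ndarray:
        """Return the symbol column for a reference site label."""
        try:
            j = self.site_labels.index(label)
        except ValueError:
            raise KeyError(f"no site labelled {label}") from None
        return self.symbols[:, j]

    def columns(self, labels: Iterable[int]) -> np.ndarray:
        """Return the ``(M, len(labels))`` sub-array for the given labels."""
        idx = [self.site_labels.index(lab) for lab in labels]
        return self.symbols[:, idx]

    def gap_fractions(self) -> np.ndarray:
        """Per-column fraction of gap symbols."""
        return (self.symbols == GAP).mean(axis=0)


def _normalize_symbol(ch: str, keep_ambiguous: bool) -> str:
    """Map a raw character to the internal alphabet.

    Both ``-`` and ``.`` count as gaps (the Stockholm dialect uses both);
    residues are upper-cased; ambiguity codes collapse to gap unless kept.
    """
    if ch in "-.":
        return GAP
    up = ch.upper()
    if up in AMBIGUOUS and not keep_ambiguous:
        return GAP
    return up


def _is_insert_column(raw_column: Sequence[str]) -> bool:
    # Pfam marks insert states with lowercase residues and "." gaps.
    return any(c == "." or c.islower() for c in raw_column)


def read_alignment(
    path,
    fmt: str = "fasta",
    *,
    drop_insert_columns: bool | None = None,
    keep_ambiguous: bool = False,
    first_label: int = 1,
) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Parameters
    ----------
    path:
        Input file path.
    fmt:
        ``"fasta"`` (aligned FASTA) or ``"stockholm"``.
    drop_insert_columns:
        Remove columns containing lowercase residues or ``.`` gaps before
        any other processing.  Defaults to ``True`` for Stockholm input
        (where these mark insert states) and ``False`` for FASTA.
    keep_ambiguous:
        Keep B/Z/X/U/O as extra symbols instead of mapping them to gap.
    first_label:
        Label given to the first column; columns are numbered consecutively.

    Raises
    ------
    AlignmentFormatError
        On an empty file, ragged rows (the offending record is named), or
        an unknown residue character.
    """
    fmt = fmt.lower()
    if fmt not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported format: {fmt!r}")
    if drop_insert_columns is None:
        drop_insert_columns = fmt == "stockholm"

    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise AlignmentFormatError(str(exc)) from exc
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")

    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )

    raw = np.array([list(str(rec.seq)) for rec in records], dtype="<U1")
    if drop_insert_columns:
        keep = [j for j in range(raw.shape[1]) if not _is_insert_column(raw[:, j])]
        raw = raw[:, keep]
    if raw.shape[1] == 0:
        raise AlignmentFormatError("no columns left after insert-state removal")

    alphabet = set(DEFAULT_ALPHABET)
    if keep_ambiguous:
        alphabet |= AMBIGUOUS
    norm = np.empty_like(raw)
    for (i, j), ch in np.ndenumerate(raw):
        sym = _normalize_symbol(ch, keep_ambiguous)
        if sym not in alphabet:
            raise AlignmentFormatError(
                f"record {records[i].id!r} contains unknown symbol {ch!r}"
            )
        norm[i, j] = sym

    labels = tuple(range(first_label, first_label + norm.shape[1]))
    return Alignment(
        ids=tuple(rec.id for rec in records),
        symbols=norm,
        site_labels=labels,
        alphabet=frozenset(alphabet),
    )


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as aligned FASTA (row order preserved)."""
    with open(path, "w") as fh:
        for ident, row in zip(aln.ids, aln.symbols):
            fh.write(f">{ident}\n{''.join(row)}\n")


def filter_gapped_columns(
    aln: Alignment, max_gap_fraction: float = 0.20
) -> Alignment:
    """Retain columns whose gap fraction is strictly below the threshold.

    A column exactly at the threshold is removed (a 5-row column with one
    gap, fraction 0.20, does not survive the default 0.20 cutoff).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    frac = aln.gap_fractions()
    keep = np.flatnonzero(frac < max_gap_fraction)
    if keep.size == 0:
        raise ValueError(
            "all columns exceed the gap threshold; raise max_gap_fraction"
        )
    return replace(
        aln,
        symbols=aln.symbols[:, keep],
        site_labels=tuple(aln.site_labels[j] for j in keep),
    )


def deduplicate_sequences(aln: Alignment) -> tuple[Alignment, int]:
    """Collapse rows with identical symbol strings to their first occurrence.

    Returns the deduplicated alignment and the number of rows removed.
    Row order among survivors is preserved.
    """
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, row in enumerate(aln.symbols):
        key = "".join(row)
        if key not in seen:
            seen[key] = i
            keep.append(i)
    removed = aln.n_rows - len(keep)
    out = replace(
        aln,
        ids=tuple(aln.ids[i] for i in keep),
        symbols=aln.symbols[keep, :],
    )
    return out, removed


def relabel_sites(aln: Alignment, offset_or_map) -> Alignment:
    """Replace site labels with an integer offset or an explicit list.

    With an integer ``d``, column ``j`` (0-based) gets label ``j + 1 + d``,
    so ``relabel_sites(aln, 5)`` maps a 69-column alignment onto reference
    sites 6..74.  An explicit list is used verbatim and must be strictly
    increasing with one label per column.
    """
    if isinstance(offset_or_map, (int, np.integer)):
        labels = tuple(
            int(j + 1 + offset_or_map) for j in range(aln.n_sites)
        )
    else:
        labels = tuple(int(x) for x in offset_or_map)
        if len(labels) != aln.n_sites:
            raise ValueError(
                f"{len(labels)} labels given for {aln.n_sites} columns"
            )
    return replace(aln, site_labels=labels)


def preprocess(
    aln: Alignment,
    *,
    max_gap_fraction: float = 0.20,
    deduplicate: bool = True,
) -> tuple[Alignment, dict]:
    """Column filtering followed by deduplication, with a JSON-able report.

    Gapped-column removal runs first so duplicate detection sees only the
    retained columns (two sequences differing solely inside removed columns
    collapse to one).
    """
    report: dict = {
        "rows_in": aln.n_rows,
        "columns_in": aln.n_sites,
        "gap_fraction_per_column": {
            str(lab): float(f)
            for lab, f in zip(aln.site_labels, aln.gap_fractions())
        },
        "max_gap_fraction": max_gap_fraction,
    }
    out = filter_gapped_columns(aln, max_gap_fraction)
    removed = 0
    if deduplicate:
        out, removed = deduplicate_sequences(out)
    report.update(
        rows_out=out.n_rows,
        columns_out=out.n_sites,
        duplicate_rows_removed=removed,
        retained_site_labels=list(out.site_labels),
    )
    return out, report
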