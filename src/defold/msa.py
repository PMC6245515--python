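"""Multiple sequence alignment handling: reading, trimming, and reweighting.

Coupling inference is only as good as the alignment behind it.  This module
reads family alignments (FASTA / A3M / Stockholm), trims them by gap content
-- columns with more than 50% gaps are dropped, sequences with more than 30%
gaps over the query columns are deleted -- and down-weights redundant
sequences so that near-duplicate cluster members do not dominate the site
statistics.

The alignment alphabet is the 20 standard amino acids plus the gap symbol
``-`` (21 states total); unknown or non-standard letters are mapped to gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  #: 21-state alphabet; gap is the last state
Q = len(ALPHABET)

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


class MsaFormatError(ValueError):
    """Raised when an alignment file cannot be parsed into equal-length rows."""


class DegenerateAlignmentError(ValueError):
    """Raised when trimming removes every column."""


@dataclass
class Msa:
    """An aligned protein family.

    Attributes
    ----------
    sequences:
        Equal-length uppercase strings over the 21-letter alphabet.
    query_index:
        Row index of the query sequence (default 0).
    column_map:
        For each current column, the index of the original alignment column
        it came from; strictly increasing.  Starts as ``range(n_cols)`` and
        shrinks under column trimming.
    """

    sequences: list[str]
    query_index: int = 0
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MsaFormatError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise MsaFormatError(f"rows have unequal lengths: {sorted(lengths)}")
        if not self.column_map:
            self.column_map = list(range(len(self.sequences[0])))
        if len(self.column_map) != len(self.sequences[0]):
            raise MsaFormatError("column_map length does not match row length")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise MsaFormatError("column_map must be strictly increasing")
        if not 0 <= self.query_index < len(self.sequences):
            raise IndexError("query_index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def to_array(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_rows, n_cols), gap = 20."""
        arr = np.empty((self.n_rows, self.n_cols), dtype=np.int8)
        for r, seq in enumerate(self.sequences):
            arr[r] = [_AA_INDEX.get(c, Q - 1) for c in seq]
        return arr

    def gap_fractions_per_column(self) -> np.ndarray:
        return (self.to_array() == Q - 1).mean(axis=0)

    def gap_fractions_per_row(self) -> np.ndarray:
        return (self.to_array() == Q - 1).mean(axis=1)


@dataclass
class SeqWeights:
    """Per-sequence weights from identity-based down-weighting.

    ``weights[s] = 1 / |{t : identity(s, t) >= identity_threshold}|`` (the
    set includes ``s`` itself), so a sequence with no near-duplicates keeps
    weight 1 and an n-fold repeated sequence is counted once in total.
    """

    weights: np.ndarray
    identity_threshold: float

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


def _normalize_row(seq: str) -> str:
    return "".join(c.upper() if c != "." else GAP for c in seq)


def _read_a3m(path: Path) -> list[tuple[str, str]]:
    # A3M: lowercase letters are insertions relative to the query and are
    # simply removed; '.' gap-inserts likewise.
    records = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if len(line) > 1 else "", []
            else:
                chunks.append("".join(c for c in line if not (c.islower() or c == ".")))
        if name is not None:
            records.append((name, "".join(chunks)))
    return records


def read_msa(path: str | Path, format: str = "fasta", query_index: int = 0) -> Msa:
    """Read an alignment from ``path`` in ``fasta``, ``a3m`` or ``stockholm`` format.

    A3M insert states (lowercase and ``.``) are removed so every row aligns
    to the query columns.  Raises :class:`MsaFormatError` on ragged rows and
    on empty files.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "a3m":
        pairs = _read_a3m(path)
        rows = [seq for _, seq in pairs]
    elif fmt == "fasta":
        rows = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    elif fmt == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise MsaFormatError(f"cannot parse {path} as stockholm: {exc}") from exc
        rows = [str(rec.seq) for rec in aln]
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    if not rows:
        raise MsaFormatError(f"no sequences found in {path}")
    rows = [_normalize_row(r) for r in rows]
    return Msa(sequences=rows, query_index=query_index)


def filter_columns(msa: Msa, max_gap_fraction: float = 0.5) -> Msa:
    """Drop columns whose gap count strictly exceeds ``max_gap_fraction`` of rows.

    Boundary columns (gap fraction exactly at the threshold) are kept: the
    rule is strictly "more than".
    """
    if not 0 < max_gap_fraction < 1:
        raise ValueError("max_gap_fraction must be in (0, 1)")
    gap_frac = msa.gap_fractions_per_column()
    keep = np.nonzero(gap_frac <= max_gap_fraction)[0]
    if keep.size == 0:
        raise DegenerateAlignmentError("column filtering removed every column")
    seqs = ["".join(s[i] for i in keep) for s in msa.sequences]
    col_map = [msa.column_map[i] for i in keep]
    return Msa(sequences=seqs, query_index=msa.query_index, column_map=col_map)


def filter_sequences(msa: Msa, max_gap_fraction: float = 0.3) -> Msa:
    """Delete non-query rows whose gap fraction strictly exceeds ``max_gap_fraction``.

    Gap content is measured over the current (query) columns.  The query row
    is always retained.  Rows exactly at the threshold are kept, mirroring
    the strictly-greater column rule.
    """
    gap_frac = msa.gap_fractions_per_row()
    keep = [
        r
        for r in range(msa.n_rows)
        if r == msa.query_index or gap_frac[r] <= max_gap_fraction
    ]
    if len(keep) < 2:
        warnings.warn(
            "fewer than 2 sequences remain after gap filtering; "
            "coupling estimates will be meaningless",
            stacklevel=2,
        )
    new_query = keep.index(msa.query_index)
    return Msa(
        sequences=[msa.sequences[r] for r in keep],
        query_index=new_query,
        column_map=list(msa.column_map),
    )


def compute_weights(msa: Msa, identity_threshold: float = 0.8) -> SeqWeights:
    """Identity-based sequence reweighting.

    The weight of a sequence is the reciprocal of the number of sequences
    (itself included) whose fractional identity to it is at least
    ``identity_threshold``.  ``identity_threshold=1.0`` collapses exact
    duplicates only; passing ``None`` disables reweighting (all weights 1).
    """
    if identity_threshold is None:
        return SeqWeights(np.ones(msa.n_rows), identity_threshold=1.0 + 1e-9)
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    arr = msa.to_array()
    n, L = arr.shape
    counts = np.zeros(n, dtype=np.int64)
    # Blocked pairwise identity; O(n^2 L) but memory-bounded.
    block = max(1, int(2e7) // max(1, n * L))
    for start in range(0, n, block):
        sub = arr[start : start + block]
        ident = (sub[:, None, :] == arr[None, :, :]).mean(axis=2)
        counts[start : start + block] = (ident >= identity_threshold).sum(axis=1)
    return SeqWeights(1.0 / counts, identity_threshold=identity_threshold)


def write_msa_fasta(msa: Msa, path: str | Path, names: list[str] | None = None) -> None:
    """Write the (trimmed) alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for i, seq in enumerate(msa.sequences):
            name = names[i] if names else f"seq{i}" + ("|query" if i == msa.query_index else "")
            fh.write(f">{name}\n{seq}\n")


def write_trimming_report(
    original: Msa, trimmed: Msa, path: str | Path
) -> None:
    """TSV report: per original column kept/dropped, then per-row gap fractions."""
    kept = set(trimmed.column_map)
    row_gaps = original.gap_fractions_per_row()
    with open(path, "w") as fh:
        fh.write("record\tindex\tvalue\n")
        for c in original.column_map:
            fh.write(f"column\t{c}\t{'kept' if c in kept else 'dropped'}\n")
        for r, g in enumerate(row_gaps):
            fh.write(f"sequence_gap_fraction\t{r}\t{g:.4f}\n")
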