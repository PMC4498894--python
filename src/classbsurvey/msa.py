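"""Alignment ingestion, Rossmann-anchored core trimming, gap editing, identity.

The survey works on a multiple sequence alignment of candidate Class B
monooxygenases.  Before tree building the alignment is reduced to its
comparable core: the N- and C-terminal regions flanking the two Rossmann
motifs are excluded, and columns containing gaps are removed.  Pairwise
percent identity (pairwise deletion over shared non-gap columns) feeds both
the identity histogram of the curated dataset and the distance matrices used
for tree inference.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import AMBIGUITY_AA, STANDARD_AA, DegeneratePattern, scan_sequence

__all__ = [
    "Msa",
    "IdentityMatrix",
    "MsaError",
    "map_position_to_column",
    "trim_to_core",
    "drop_gap_columns",
    "pairwise_identity",
    "identity_histogram",
]

GAP = "-"
_ROW_ALPHABET = set(STANDARD_AA + AMBIGUITY_AA + GAP)


class MsaError(ValueError):
    """Invalid alignment or alignment operation."""


@dataclass(frozen=True)
class Msa:
    """Equal-length gapped rows over uniquely named sequences."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise MsaError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise MsaError("duplicate sequence ids")
        if self.rows:
            ncol = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise MsaError(f"row {sid!r} has length {len(row)}, expected {ncol}")
                bad = set(row) - _ROW_ALPHABET
                if bad:
                    raise MsaError(f"row {sid!r} contains invalid characters {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def select_columns(self, columns: np.ndarray | list[int]) -> "Msa":
        """New alignment keeping the given 0-based columns, order preserved."""
        idx = np.asarray(columns)
        arr = self.to_array()[:, idx]
        return Msa(self.ids, tuple("".join(r) for r in arr.astype(str)))

    def to_array(self) -> np.ndarray:
        """(n_rows, n_columns) array of single characters."""
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_rows, self.n_columns
        )

    @classmethod
    def from_records(cls, records) -> "Msa":
        ids, rows = zip(*records) if records else ((), ())
        return cls(tuple(ids), tuple(rows))

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        from Bio import SeqIO

        return cls.from_records(
            [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def map_position_to_column(msa: Msa, seq_id: str, ungapped_pos: int) -> int:
    """Alignment column (1-based) holding residue ``ungapped_pos`` (1-based) of a row."""
    row = msa.row(seq_id)
    if ungapped_pos < 1:
        raise IndexError(f"ungapped position must be >= 1, got {ungapped_pos}")
    seen = 0
    for col, c in enumerate(row, start=1):
        if c != GAP:
            seen += 1
            if seen == ungapped_pos:
                return col
    raise IndexError(
        f"position {ungapped_pos} beyond ungapped length {seen} of row {seq_id!r}"
    )


def trim_to_core(
    msa: Msa,
    registry: dict[str, DegeneratePattern],
    min_voting_fraction: float = 0.5,
) -> Msa:
    """Excise the alignment regions flanking the two Rossmann motifs.

    Each row holding at least two Rossmann occurrences in its ungapped
    sequence votes with the column of the first residue of its first hit and
    the column of the last residue of its last hit; the retained range is the
    median of the start votes through the median of the end votes (low/high
    median so the cut sits on an actual vote).  Rows without two hits do not
    vote but are trimmed to the same columns, with a warning.  Refuses when
    fewer than ``min_voting_fraction`` of rows qualify.
    """
    rossmann = registry["rossmann"]
    start_votes, end_votes, silent = [], [], []
    for sid in msa.ids:
        hits = scan_sequence(msa.ungapped(sid), rossmann, sid)
        if len(hits) >= 2:
            start_votes.append(map_position_to_column(msa, sid, hits[0].start))
            end_votes.append(map_position_to_column(msa, sid, hits[-1].end))
        else:
            silent.append(sid)
    if len(start_votes) < min_voting_fraction * msa.n_rows:
        raise MsaError(
            f"only {len(start_votes)}/{msa.n_rows} rows contain two Rossmann motifs "
            f"(need >= {min_voting_fraction:.0%}); refusing to trim"
        )
    if silent:
        warnings.warn(
            f"{len(silent)} row(s) lack two Rossmann motifs and did not vote: "
            f"{', '.join(silent[:5])}{'...' if len(silent) > 5 else ''}",
            stacklevel=2,
        )
    start = statistics.median_low(start_votes)
    end = statistics.median_high(end_votes)
    return msa.select_columns(np.arange(start - 1, end))


def drop_gap_columns(msa: Msa, max_gap_fraction: float = 0.0) -> Msa:
    """Remove every column whose gap fraction exceeds ``max_gap_fraction``.

    The default 0.0 removes any column containing a gap, the strictest
    reading of manual gap elimination.  Idempotent at any fixed threshold.
    """
    arr = msa.to_array()
    gap_frac = (arr == GAP.encode()).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    if keep.size == 0:
        raise MsaError("gap elimination removed every column")
    return msa.select_columns(keep)


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over alignment rows (diagonal 100)."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="seq_id")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.taxa), k=1)
        return self.values[iu]


def _identity_from_array(arr: np.ndarray) -> np.ndarray:
    nongap = arr != GAP.encode()
    shared = nongap[:, None, :] & nongap[None, :, :]
    same = (arr[:, None, :] == arr[None, :, :]) & shared
    denom = shared.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * same.sum(axis=-1) / denom
    pct[denom == 0] = 0.0
    np.fill_diagonal(pct, 100.0)
    return pct


def pairwise_identity(msa: Msa) -> IdentityMatrix:
    """Percent identity per pair over shared non-gap columns (pairwise deletion).

    Pairs with no shared non-gap column get identity 0 with a warning.
    """
    if msa.n_rows < 2:
        raise MsaError("pairwise identity needs at least two rows")
    arr = msa.to_array()
    nongap = arr != GAP.encode()
    denom = (nongap[:, None, :] & nongap[None, :, :]).sum(axis=-1)
    if np.any(denom[np.triu_indices(msa.n_rows, k=1)] == 0):
        warnings.warn("some pairs share no non-gap columns; identity set to 0", stacklevel=2)
    return IdentityMatrix(msa.ids, _identity_from_array(arr))


def identity_histogram(matrix: IdentityMatrix, bin_width: int = 10) -> pd.DataFrame:
    """Off-diagonal identities binned into [0,w), [w,2w), ..., [100-w,100].

    Returns a table of bin bounds, pair counts and percentages (summing
    to 100) — the standard way to display the identity distribution of a
    curated dataset.
    """
    pairs = matrix.off_diagonal()
    if pairs.size == 0:
        raise MsaError("no off-diagonal pairs to bin")
    edges = np.arange(0, 100 + bin_width, bin_width, dtype=float)
    edges[-1] = 100.0
    counts, _ = np.histogram(pairs, bins=edges)  # last bin right-inclusive
    pct = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "percent": pct,
        }
    )
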