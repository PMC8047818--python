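"""Alignment containers, FASTA I/O and the alignment utilities used upstream
of every analysis stage.

The central object is :class:`Alignment`, an ordered, validated collection of
equal-length amino-acid sequences (with ``-`` gaps).  :class:`SequenceSet`
holds ungapped sequences where no column structure is implied.  Utilities
cover column filtering by gap occupancy (a deliberately simple stand-in for
block-selection tools such as Gblocks), greedy identity-based deduplication
(CD-HIT-style representative selection at a 92% default identity threshold),
and i.i.d. random-sequence baselines used to put observed identities on a
floor of chance expectation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
_VALID_ALIGNED = frozenset(AA_LETTERS + GAP)
_VALID_UNGAPPED = frozenset(AA_LETTERS)


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate or empty identifiers, bad residues)."""


class EmptyAlignmentError(ValueError):
    """An operation produced or received an alignment with no usable columns."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length amino-acid sequences with gaps.

    Parameters
    ----------
    records
        Ordered ``(identifier, sequence)`` pairs.  Sequences must share one
        length and use only the 20 amino-acid letters plus ``-``.
    """

    records: tuple[tuple[str, str], ...]

    def __init__(self, records: Iterable[tuple[str, str]]):
        object.__setattr__(self, "records", tuple((i, s) for i, s in records))
        self._validate()

    def _validate(self) -> None:
        if not self.records:
            raise EmptyAlignmentError("alignment must contain at least one record")
        seen: set[str] = set()
        length = len(self.records[0][1])
        if length < 1:
            raise FastaFormatError("alignment columns must number >= 1")
        for ident, seq in self.records:
            if not ident:
                raise FastaFormatError("empty sequence identifier")
            if ident in seen:
                raise FastaFormatError(f"duplicate identifier {ident!r}")
            seen.add(ident)
            if len(seq) != length:
                raise FastaFormatError(
                    f"record {ident!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - _VALID_ALIGNED
            if bad:
                raise FastaFormatError(
                    f"record {ident!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    def sequence(self, identifier: str) -> str:
        for ident, seq in self.records:
            if ident == identifier:
                return seq
        raise KeyError(f"no record with identifier {identifier!r}")

    def subset(self, identifiers: Sequence[str]) -> "Alignment":
        """Row subset in the requested order (identifiers must exist)."""
        missing = [i for i in identifiers if i not in set(self.identifiers)]
        if missing:
            raise KeyError(f"identifiers not in alignment: {missing}")
        lookup = dict(self.records)
        return Alignment([(i, lookup[i]) for i in identifiers])

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, length), dtype '<U1'."""
        return np.array([list(s) for _, s in self.records])


@dataclass(frozen=True)
class SequenceSet:
    """Ungapped sequences with unique identifiers; no column structure."""

    records: tuple[tuple[str, str], ...]

    def __init__(self, records: Iterable[tuple[str, str]]):
        object.__setattr__(self, "records", tuple((i, s) for i, s in records))
        seen: set[str] = set()
        for ident, seq in self.records:
            if not ident:
                raise FastaFormatError("empty sequence identifier")
            if ident in seen:
                raise FastaFormatError(f"duplicate identifier {ident!r}")
            seen.add(ident)
            if not seq:
                raise FastaFormatError(f"record {ident!r} has empty sequence")
            bad = set(seq) - _VALID_UNGAPPED
            if bad:
                raise FastaFormatError(
                    f"record {ident!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)


def read_fasta(path: str | os.PathLike, as_alignment: bool = True):
    """Read a FASTA file, normalising residues to upper case.

    Returns an :class:`Alignment` when ``as_alignment`` is true (all records
    must then share one length) and a :class:`SequenceSet` of ungapped
    sequences otherwise (gaps are stripped).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    if as_alignment:
        return Alignment(records)
    return SequenceSet([(i, s.replace(GAP, "")) for i, s in records])


def write_fasta(records, path: str | os.PathLike, wrap: int = 60) -> None:
    """Write records (an Alignment/SequenceSet or (id, seq) iterable) as FASTA.

    Output is deterministic, with sequence lines wrapped at ``wrap`` columns.
    """
    if hasattr(records, "records"):
        records = records.records
    with open(path, "w") as out:
        for ident, seq in records:
            out.write(f">{ident}\n")
            for start in range(0, len(seq), wrap):
                out.write(seq[start : start + wrap] + "\n")


def filter_columns(
    alignment: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Keep columns whose gap fraction does not exceed ``max_gap_fraction``.

    Returns the filtered alignment and the kept column indices in the original
    0-based coordinate system.  Raises :class:`EmptyAlignmentError` if nothing
    survives.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError(f"max_gap_fraction must be in [0, 1], got {max_gap_fraction}")
    mat = alignment.to_array()
    gap_fraction = (mat == GAP).mean(axis=0)
    kept = np.nonzero(gap_fraction <= max_gap_fraction)[0]
    if kept.size == 0:
        raise EmptyAlignmentError(
            f"no column has gap fraction <= {max_gap_fraction}"
        )
    sub = mat[:, kept]
    filtered = Alignment(
        [(ident, "".join(row)) for (ident, _), row in zip(alignment.records, sub)]
    )
    return filtered, [int(i) for i in kept]


def write_kept_columns(kept: Sequence[int], path: str | os.PathLike) -> None:
    """Write kept column indices, one 1-based index per line."""
    with open(path, "w") as out:
        for idx in kept:
            out.write(f"{idx + 1}\n")


def _identity_equal_length(a: str, b: str) -> float:
    """Identity over columns where not both are gaps; gap-vs-residue counts
    as a comparable mismatch here (CD-HIT-style global identity)."""
    comparable = 0
    matches = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        return 0.0
    return matches / comparable


def dedup_by_identity(sequences, threshold: float = 0.92):
    """Greedy longest-first representative selection.

    A sequence is dropped iff its identity to an already-kept representative
    exceeds ``threshold``.  Inputs must be pre-aligned (equal length) or
    literally identical when lengths differ; ungapped unequal-length inputs
    are compared only for exact equality (a documented limitation — no
    alignment is attempted here).  Output preserves the input order of the
    representatives.  Works on :class:`Alignment`, :class:`SequenceSet` or an
    (id, seq) iterable; returns a :class:`SequenceSet` of ungapped
    representatives.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if hasattr(sequences, "records"):
        sequences = sequences.records
    records = list(sequences)
    if not records:
        return SequenceSet([])
    # cluster longest-first (ungapped length), stable for ties
    order = sorted(
        range(len(records)),
        key=lambda i: (-len(records[i][1].replace(GAP, "")), i),
    )
    kept_indices: list[int] = []
    for i in order:
        _, seq = records[i]
        redundant = False
        for j in kept_indices:
            rep = records[j][1]
            if len(rep) == len(seq):
                ident = _identity_equal_length(seq, rep)
            else:
                ident = 1.0 if seq.replace(GAP, "") == rep.replace(GAP, "") else 0.0
            if ident > threshold:
                redundant = True
                break
        if not redundant:
            kept_indices.append(i)
    kept_indices.sort()
    return SequenceSet(
        [(records[i][0], records[i][1].replace(GAP, "")) for i in kept_indices]
    )


def random_sequences(
    n: int,
    length: int,
    frequencies: Sequence[float] | None = None,
    seed: int | None = None,
) -> SequenceSet:
    """Generate ``n`` i.i.d. random amino-acid sequences of a given length.

    ``frequencies`` are per-residue probabilities over ``AA_LETTERS`` (uniform
    by default).  The expected pairwise identity of two such sequences is
    sum(f_i^2) — 1/20 = 0.05 under uniform frequencies — which is the chance
    floor these baselines are used to estimate.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if frequencies is None:
        frequencies = np.full(20, 1.0 / 20)
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.shape != (20,):
        raise ValueError("frequencies must have 20 entries")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {freqs.sum()!r}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_LETTERS))
    records = []
    for k in range(n):
        draw = rng.choice(20, size=length, p=freqs)
        records.append((f"random_{k + 1}", "".join(letters[draw])))
    return SequenceSet(records)
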