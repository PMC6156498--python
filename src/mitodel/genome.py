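"""Mitochondrial reference genome, deletion coordinates and junctional direct repeats.

All coordinates are 1-based, closed intervals on the plus strand, matching NCBI
numbering of the *C. elegans* mitochondrial genome (the coordinate system in
which deletion breakpoints are conventionally reported).  A deletion is the
closed interval ``[b5, b3]`` of removed bases; the molecule retains
``...(b5-1)`` joined to ``(b3+1)...``.

A junctional direct repeat (DR) is a sequence present at both breakpoints such
that the deleted molecule keeps exactly one copy.  Because of the standard
representation ambiguity of junctional repeats, a repeat of length ``r`` can be
anchored at either end of the deletion:

* start-anchored: ``ref[b5 .. b5+r-1] == ref[b3+1 .. b3+r]``
  (the repeat copy at the start of the deleted segment equals the segment just
  past the deletion end), or
* end-anchored: ``ref[b5-r .. b5-1] == ref[b3-r+1 .. b3]``
  (the segment just before the deletion equals the copy at the deletion end).

Both placements are scanned and the maximal exact match is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

__all__ = [
    "MtReference",
    "Deletion",
    "RepeatHit",
    "load_reference",
    "deletion_length",
    "find_flanking_direct_repeat",
    "load_deletions_tsv",
    "write_deletions_tsv",
    "deletions_to_bed",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MtReference:
    """A (typically circular) mitochondrial reference sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise ValueError("reference sequence is empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"reference contains non-nucleotide characters: {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``, wrapping when circular.

        Returns the empty string for out-of-range positions on a linear
        reference (so window comparisons simply fail instead of raising).
        """
        n = self.length
        if self.circular:
            return self.sequence[(pos - 1) % n]
        if 1 <= pos <= n:
            return self.sequence[pos - 1]
        return ""

    def window(self, start: int, length: int) -> Optional[str]:
        """Sequence of ``length`` bases starting at 1-based ``start``.

        Wraps around the origin when circular; returns None if the window
        leaves a linear reference.
        """
        n = self.length
        if length < 0:
            raise ValueError("window length must be >= 0")
        if self.circular:
            idx = [(start - 1 + k) % n for k in range(length)]
            return "".join(self.sequence[i] for i in idx)
        if start < 1 or start + length - 1 > n:
            return None
        return self.sequence[start - 1 : start - 1 + length]


@dataclass(frozen=True, order=True)
class Deletion:
    """Breakpoints of a deletion: ``b5`` first and ``b3`` last removed base."""

    b5: int
    b3: int

    def __post_init__(self):
        if self.b5 < 1:
            raise ValueError(f"b5 must be >= 1, got {self.b5}")
        if self.b5 > self.b3:
            raise ValueError(f"b5 ({self.b5}) must not exceed b3 ({self.b3})")

    @property
    def length(self) -> int:
        return self.b3 - self.b5 + 1

    def validate(self, ref: MtReference) -> "Deletion":
        if self.b3 > ref.length:
            raise ValueError(
                f"deletion [{self.b5}, {self.b3}] exceeds reference length {ref.length}"
            )
        return self


@dataclass(frozen=True)
class RepeatHit:
    """A perfect direct repeat flanking a deletion junction."""

    length: int
    side: str  # "start-anchored" | "end-anchored"
    seq: str

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("repeat length must be >= 1")
        if len(self.seq) != self.length:
            raise ValueError("repeat sequence length mismatch")
        if self.side not in ("start-anchored", "end-anchored"):
            raise ValueError(f"invalid side {self.side!r}")


def load_reference(fasta_path, circular: bool = True) -> MtReference:
    """Read the first record of a FASTA file as the mitochondrial reference.

    Sequence is upper-cased; only A/C/G/T/N are accepted.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"FASTA file {path} contains no records") from None
    return MtReference(id=record.id, sequence=str(record.seq), circular=circular)


def deletion_length(d: Deletion) -> int:
    """Number of removed bases, ``b3 - b5 + 1`` (closed interval)."""
    return d.length


def find_flanking_direct_repeat(
    ref: MtReference,
    d: Deletion,
    min_len: int = 1,
    max_len: int = 30,
) -> Optional[RepeatHit]:
    """Maximal perfect direct repeat flanking a deletion junction.

    Scans repeat lengths ``r`` in ``[min_len, max_len]`` at both canonical
    placements (see module docstring) and returns the longest hit, ties broken
    toward the start-anchored placement.  Returns None when no placement
    matches at ``min_len`` or above.  Windows that would leave a linear
    (non-circular) reference simply do not match.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    d.validate(ref)
    best: Optional[RepeatHit] = None
    for r in range(min_len, max_len + 1):
        start_a = ref.window(d.b5, r)
        start_b = ref.window(d.b3 + 1, r)
        if start_a is not None and start_a == start_b:
            best = RepeatHit(length=r, side="start-anchored", seq=start_a)
            continue
        end_a = ref.window(d.b5 - r, r)
        end_b = ref.window(d.b3 - r + 1, r)
        if end_a is not None and end_a == end_b:
            best = RepeatHit(length=r, side="end-anchored", seq=end_a)
            continue
        # no placement matches at r; longer r cannot match a prefix-extendable
        # placement that already failed at r only if matches were nested, which
        # they are (a length-r+1 match implies a length-r match on the same
        # placement), so stop once both placements fail.
        break
    if best is not None and best.length >= min_len:
        return best
    return None


def load_deletions_tsv(path) -> list[Deletion]:
    """Read deletions from a TSV with columns id, b5, b3 (1-based inclusive)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("b5", "b3"):
        if col not in df.columns:
            raise ValueError(f"deletions TSV missing column {col!r}")
    return [Deletion(int(r.b5), int(r.b3)) for r in df.itertuples()]


def write_deletions_tsv(deletions, path, ids=None) -> None:
    import pandas as pd

    ids = ids if ids is not None else [f"del{i+1}" for i in range(len(deletions))]
    pd.DataFrame(
        {"id": ids, "b5": [d.b5 for d in deletions], "b3": [d.b3 for d in deletions]}
    ).to_csv(path, sep="\t", index=False)


def deletions_to_bed(deletions, ref: MtReference):
    """0-based half-open BED rows (chrom, start, end) for a list of deletions."""
    return [(ref.id, d.b5 - 1, d.b3) for d in deletions]
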