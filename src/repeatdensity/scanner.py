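"""Detection of maximal (perfect/intact) mononucleotide runs.

A run is maximal: the bases flanking it (when inside the chromosome)
differ from the run base, so a 15-mer inside a 30-mer is never counted
separately. The default length window is 13–27 bp inclusive; runs longer
than the maximum are excluded entirely, never clipped, because lengths of
whole runs are what get summed downstream.

Run boundaries are found with numpy on the byte array of the sequence,
deliberately not with regular expressions: the test suite uses a regex
maximal-run matcher as an independent oracle.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .errors import RepeatDensityError, ValidationError
from .io import VALID_ALPHABET, GenomeSequence

DEFAULT_MIN_LEN = 13
DEFAULT_MAX_LEN = 27
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class RepeatRun:
    """One maximal homopolymer run. ``chrom`` is None for chrom-less scans."""

    base: str
    start: int
    length: int
    chrom: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


def _run_arrays(seq: str, base: str) -> tuple[np.ndarray, np.ndarray]:
    """(starts, lengths) of all maximal runs of ``base`` in ``seq``, sorted."""
    if not seq:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = arr == ord(base)
    # boundaries: prepend/append False so edge runs are closed
    padded = np.empty(mask.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = mask
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return starts.astype(np.int64), (ends - starts).astype(np.int64)


def _seed_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of all maximal runs of ``base`` with length >= min_len.

    Seed-and-extend on ``str.find``: runs this long are rare in real and
    simulated sequence, so locating seeds in C and extending by hand beats
    materialising every length-1 run of a whole chromosome.
    """
    seed = base * min_len
    n = len(seq)
    out = []
    i = seq.find(seed)
    while i != -1:
        s = i
        while s > 0 and seq[s - 1] == base:
            s -= 1
        e = i + min_len
        while e < n and seq[e] == base:
            e += 1
        out.append((s, e - s))
        i = seq.find(seed, e + 1)
    return out


def _validate_seq(seq: str) -> None:
    if set(seq) - VALID_ALPHABET:
        bad = sorted(set(seq) - VALID_ALPHABET)
        raise ValidationError(f"sequence contains illegal characters {bad}")


def find_runs(seq: str, base: str, chrom: str | None = None) -> list[RepeatRun]:
    """All maximal runs of ``base`` in ``seq`` (every length >= 1), by start.

    N and sequence ends terminate runs; a run touching a sequence end is
    maximal by construction and still counts.
    """
    if base not in ("A", "C", "G", "T"):
        raise ValidationError(f"base must be one of A/C/G/T, got {base!r}")
    _validate_seq(seq)
    starts, lengths = _run_arrays(seq, base)
    return [
        RepeatRun(base=base, start=int(s), length=int(l), chrom=chrom)
        for s, l in zip(starts, lengths)
    ]


def filter_runs(runs: list[RepeatRun], min_len: int, max_len: int) -> list[RepeatRun]:
    """Keep runs with min_len <= length <= max_len (inclusive both ends)."""
    if min_len < 1:
        raise ValidationError(f"min_len must be >= 1, got {min_len}")
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} exceeds max_len {max_len}")
    return [r for r in runs if min_len <= r.length <= max_len]


@dataclass
class RepeatIndex:
    """Per-chromosome, per-base sorted runs with the scan parameters recorded.

    Runs of one base never overlap (maximality), so both starts and ends
    are sorted and interval queries reduce to two binary searches.
    """

    min_len: int
    max_len: int
    bases: tuple[str, ...]
    runs: dict[str, dict[str, list[RepeatRun]]] = field(default_factory=dict)
    _starts: dict = field(default_factory=dict, repr=False)
    _ends: dict = field(default_factory=dict, repr=False)

    def add_chromosome(self, chrom: str, by_base: dict[str, list[RepeatRun]]) -> None:
        self.runs[chrom] = by_base
        for base, rs in by_base.items():
            self._starts[(chrom, base)] = [r.start for r in rs]
            self._ends[(chrom, base)] = [r.end for r in rs]

    @property
    def chroms(self) -> list[str]:
        return list(self.runs)

    def all_runs(self) -> list[RepeatRun]:
        """All runs, chromosome blocks in insertion order, merged-sorted by start."""
        out = []
        for chrom, by_base in self.runs.items():
            merged = sorted(
                (r for rs in by_base.values() for r in rs),
                key=lambda r: (r.start, r.base),
            )
            out.extend(merged)
        return out

    def query(self, chrom: str, base: str, start: int, end: int) -> list[RepeatRun]:
        """Runs of ``base`` on ``chrom`` overlapping [start, end)."""
        if chrom not in self.runs:
            raise RepeatDensityError(f"chromosome {chrom!r} absent from repeat index")
        if base not in self.runs[chrom]:
            return []
        starts = self._starts[(chrom, base)]
        ends = self._ends[(chrom, base)]
        lo = bisect_right(ends, start)  # first run with end > start
        hi = bisect_left(starts, end)  # first run with start >= end
        return self.runs[chrom][base][lo:hi]


def scan_genome(
    genome: GenomeSequence,
    bases: tuple[str, ...] = ("A", "T"),
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> RepeatIndex:
    """Scan every chromosome for maximal runs of each base, length-filtered.

    Chromosomes are scanned independently, so runs never merge across
    records. The length filter is applied on array form before any run
    objects are built, which keeps whole-genome scans cheap.
    """
    if min_len < 1:
        raise ValidationError(f"min_len must be >= 1, got {min_len}")
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} exceeds max_len {max_len}")
    index = RepeatIndex(min_len=min_len, max_len=max_len, bases=tuple(bases))
    for chrom, seq in genome.records.items():
        by_base: dict[str, list[RepeatRun]] = {}
        for base in bases:
            by_base[base] = [
                RepeatRun(base=base, start=s, length=l, chrom=chrom)
                for s, l in _seed_runs(seq, base, min_len)
                if l <= max_len
            ]
        index.add_chromosome(chrom, by_base)
    return index


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
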