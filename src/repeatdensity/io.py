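"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based, half-open throughout the package; BED is the
native interval dialect. Genome sequences are held as plain uppercase
strings over the alphabet {A, C, G, T, N}; anything else is rejected at
load time with the offending record and offset named in the error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import LoadError, ValidationError

VALID_ALPHABET = frozenset("ACGTN")
_ILLEGAL = re.compile(r"[^ACGTN]")

STRANDS = ("+", "-")


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered map of chromosome name -> sequence.

    Sequences are uppercase strings over {A, C, G, T, N}. Record order is
    the file order.
    """

    records: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def chrom_length(self, chrom: str) -> int:
        return len(self.records[chrom])


@dataclass(frozen=True)
class GeneRecord:
    """One gene anchored by a single TSS.

    ``tss`` is a 0-based reference position; ``gene_end`` is the 0-based
    exclusive end of the gene body in transcription direction (for a
    minus-strand gene it therefore lies 5' of the TSS in reference
    coordinates). ``gene_end`` is carried for validation and reporting
    only; windows are built purely from the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_end: int

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise LoadError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples log-intensity matrix with a test/control grouping.

    ``values`` is indexed by gene_id with one column per sample. Every
    sample belongs to exactly one of the groups 'test' or 'control', and
    each group has at least two replicate columns — with fewer the
    per-gene two-sample t-test is undefined.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    @property
    def test_samples(self) -> list[str]:
        return self.samples_in("test")

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in("control")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased. Raises :class:`LoadError` for malformed
    headers, empty or duplicate records, or characters outside
    {A, C, G, T, N} (the error names the record and 0-based offset).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"FASTA file not found: {path}")
    records: dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # e.g. text before the first '>'
        raise LoadError(f"malformed FASTA {path}: {exc}") from exc
    if not parsed and path.stat().st_size > 0:
        raise LoadError(f"malformed FASTA {path}: no records parsed")
    for rec in parsed:
        name = rec.id
        if not name:
            raise LoadError(f"{path}: record with empty header")
        if name in records:
            raise LoadError(f"{path}: duplicate record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise LoadError(f"{path}: record {name!r} has empty sequence")
        bad = _ILLEGAL.search(seq)
        if bad:
            raise LoadError(
                f"{path}: record {name!r} has illegal character "
                f"{bad.group()!r} at offset {bad.start()}"
            )
        records[name] = seq
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation


_TSV_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_end"]


def read_annotation(
    path: str | Path,
    dialect: str = "tsv",
    genome: GenomeSequence | None = None,
) -> list[GeneRecord]:
    """Read a gene annotation as a list of :class:`GeneRecord`.

    ``dialect='tsv'`` expects a header with columns gene_id, chrom, strand,
    tss, gene_end. ``dialect='bed'`` expects 6-column BED where the TSS is
    the strand-aware 5' end: start for '+', end-1 for '-'.

    Duplicate gene_ids are rejected. If ``genome`` is given, every gene's
    chromosome must exist in it and the TSS must lie within bounds.
    """
    path = Path(path)
    if dialect == "tsv":
        genes = _read_annotation_tsv(path)
    elif dialect == "bed":
        genes = _read_annotation_bed(path)
    else:
        raise LoadError(f"unknown annotation dialect {dialect!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise LoadError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    if genome is not None:
        validate_annotation(genes, genome)
    return genes


def _read_annotation_tsv(path: Path) -> list[GeneRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    except Exception as exc:
        raise LoadError(f"cannot parse annotation TSV {path}: {exc}") from exc
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing annotation columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                gene_end=int(row.gene_end),
            )
        )
    return genes


def _read_annotation_bed(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise LoadError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand == "+":
                tss, gene_end = start, end
            elif strand == "-":
                # 5' end of a minus-strand feature; gene body runs leftward,
                # exclusive end in transcription direction is start-1.
                tss, gene_end = end - 1, start - 1
            else:
                raise LoadError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            genes.append(GeneRecord(name, chrom, strand, tss, gene_end))
    return genes


def validate_annotation(genes: Iterable[GeneRecord], genome: GenomeSequence) -> None:
    for g in genes:
        if g.chrom not in genome:
            raise ValidationError(
                f"gene {g.gene_id!r}: chromosome {g.chrom!r} absent from genome"
            )
        if not 0 <= g.tss < genome.chrom_length(g.chrom):
            raise ValidationError(
                f"gene {g.gene_id!r}: tss {g.tss} outside chromosome "
                f"{g.chrom!r} (length {genome.chrom_length(g.chrom)})"
            )


def write_annotation_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.gene_end) for g in genes],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | Path, groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene id).

    ``groups`` maps every sample id to 'test' or 'control'. The file's
    samples and the map's keys must coincide, every cell must be numeric
    with no missing values, and each group needs at least 2 replicates —
    otherwise the per-gene t-test is undefined.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise LoadError(f"cannot parse expression TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate gene_ids {dups[:5]}")
    file_samples = set(df.columns)
    map_samples = set(groups)
    if file_samples != map_samples:
        only_file = sorted(file_samples - map_samples)
        only_map = sorted(map_samples - file_samples)
        raise ValidationError(
            f"{path}: sample/group mismatch — in file only: {only_file}; "
            f"in group map only: {only_map}"
        )
    bad_groups = {s: g for s, g in groups.items() if g not in ("test", "control")}
    if bad_groups:
        raise ValidationError(f"{path}: groups must be 'test'/'control', got {bad_groups}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise LoadError(f"{path}: non-numeric cell in expression matrix: {exc}") from exc
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise LoadError(f"{path}: missing value (gene {gene!r})")
    matrix = ExpressionMatrix(values=values, group_of=dict(groups))
    for group in ("test", "control"):
        n = len(matrix.samples_in(group))
        if n < 2:
            raise ValidationError(
                f"{path}: group {group!r} has {n} sample(s); at least 2 "
                "replicates required for the two-sample t-test"
            )
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Repeat runs as BED


def write_repeats_bed(runs, path: str | Path) -> None:
    """Write repeat runs as BED6: name is base+length (e.g. 'A15'), score = length.

    Input must be sorted: chromosome blocks contiguous, starts ascending
    within each block. Unsorted input is an error — the caller must sort.
    """
    prev_chrom = None
    prev_start = -1
    seen_chroms: set[str] = set()
    with open(path, "w") as fh:
        for run in runs:
            if run.chrom is None:
                raise ValidationError("run without chromosome cannot be written to BED")
            if run.chrom != prev_chrom:
                if run.chrom in seen_chroms:
                    raise ValidationError(
                        f"runs not sorted: chromosome {run.chrom!r} appears twice"
                    )
                seen_chroms.add(run.chrom)
                prev_chrom, prev_start = run.chrom, -1
            if run.start < prev_start:
                raise ValidationError(
                    f"runs not sorted by start on {run.chrom!r} "
                    f"({run.start} after {prev_start})"
                )
            prev_start = run.start
            fh.write(
                f"{run.chrom}\t{run.start}\t{run.start + run.length}\t"
                f"{run.base}{run.length}\t{run.length}\t.\n"
            )


def read_repeats_bed(path: str | Path):
    """Read BED produced by :func:`write_repeats_bed` back into RepeatRun objects."""
    from .scanner import RepeatRun

    runs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise LoadError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            start, end = int(start_s), int(end_s)
            base = name[0]
            if base not in ("A", "C", "G", "T"):
                raise LoadError(f"{path}:{lineno}: cannot parse base from name {name!r}")
            runs.append(RepeatRun(chrom=chrom, base=base, start=start, length=end - start))
    return runs
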