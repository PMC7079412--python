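"""Flat-file plumbing: FASTQ/FASTA/BED readers and writers, wgsim-style
read-name parsing, UMI extraction, and the compressed per-read
evaluation-record format.

All FASTQ/FASTA paths transparently handle gzip by ``.gz`` extension.
Coordinates follow the conventions of each format: FASTQ/FASTA are
positional, wgsim names are 1-based, BED is 0-based half-open.
"""
from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

PLACEHOLDER_QUALITY = "I"  # Phred+33 score 40; evaluation never reads qualities


class FastqParseError(ValueError):
    """A FASTQ record violates the 4-line grammar or its invariants."""


class FastaFormatError(ValueError):
    pass


class BedFormatError(ValueError):
    pass


class WgsimNameError(ValueError):
    """Read name does not follow the wgsim origin-encoding grammar."""


class EvalRecordFormatError(ValueError):
    """Evaluation-record line has the wrong shape."""


@dataclass
class Read:
    """A named nucleotide sequence with optional per-base qualities.

    ``description`` keeps the full FASTQ title line (including the name)
    when the header carried more than the bare identifier, so that
    header-embedded UMI tokens survive a round trip.
    """

    name: str
    sequence: str
    qualities: Optional[str] = None
    mate: Optional[int] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.name!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OriginInfo:
    """Genomic origin encoded in a wgsim-style read name.

    ``pos1``/``pos2`` are the 1-based outer coordinates of the simulated
    fragment (mate-1 end and mate-2 end). ``err1``/``err2`` are the two
    per-mate ``subs:indels:?`` annotation tokens, preserved verbatim;
    ``counter`` is the trailing pair-index token, also verbatim.
    """

    chrom: str
    pos1: int
    pos2: int
    mate: int
    counter: str
    err1: str = "0:0:0"
    err2: str = "0:0:0"


@dataclass
class EvalRecord:
    """Per-read base-classification counts.

    ``tn`` is carried in memory for dataset totals but is not part of the
    compressed record format (None when parsed back from file).
    """

    read_name: str
    length: int
    tp: int = 0
    fn: int = 0
    fn_wrong: int = 0
    fp: int = 0
    fp_indel: int = 0
    fp_trim: int = 0
    tp_trim: int = 0
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        for f in ("length", "tp", "fn", "fn_wrong", "fp", "fp_indel", "fp_trim", "tp_trim"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def event_count(self) -> int:
        """Number of TP/FP/FN-family events; records with zero events are
        omitted from the compressed file."""
        return (
            self.tp + self.fn + self.fn_wrong + self.fp
            + self.fp_indel + self.fp_trim + self.tp_trim
        )


@dataclass(frozen=True)
class CategoryInterval:
    """Half-open 0-based genomic interval labelled with a category."""

    chrom: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


_MATE_SUFFIX = re.compile(r"/([12])$")


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield reads from a (possibly gzipped) 4-line-per-record FASTQ file.

    The read name is the title up to the first whitespace; a trailing
    ``/1`` or ``/2`` sets ``mate``. Malformed records raise
    :class:`FastqParseError` naming the 0-based record index.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record #{index}: {exc}"
                ) from exc
            name = title.split()[0] if title.split() else title
            m = _MATE_SUFFIX.search(name)
            try:
                yield Read(
                    name=name,
                    sequence=seq.upper(),
                    qualities=qual,
                    mate=int(m.group(1)) if m else None,
                    description=title if title != name else None,
                )
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record #{index}: {exc}"
                ) from exc
            index += 1


def write_fastq(reads: Iterable[Read], path: PathLike) -> int:
    """Write reads as FASTQ; returns the number of records written.

    Reads without qualities get a constant placeholder quality string
    ('I' = Phred 40), which downstream evaluation ignores.
    """
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = read.qualities or PLACEHOLDER_QUALITY * len(read.sequence)
            if len(qual) != len(read.sequence):
                raise ValueError(f"read {read.name!r}: quality/sequence length mismatch")
            title = read.description if read.description else read.name
            fh.write(f"@{title}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


_ERR_TOKEN = re.compile(r"^\d+:\d+:\d+$")


def parse_wgsim_name(name: str) -> OriginInfo:
    """Parse a wgsim-style read name, e.g. ``1_22_238_1:0:0_3:0:0_0/1``.

    Chromosome names may themselves contain underscores, so the six
    structural tokens are taken from the right.
    """
    core, sep, mate_s = name.rpartition("/")
    if sep != "/" or mate_s not in ("1", "2"):
        raise WgsimNameError(f"unparseable origin (no /1 or /2 mate suffix): {name!r}")
    parts = core.rsplit("_", 5)
    if len(parts) != 6:
        raise WgsimNameError(f"unparseable origin (too few '_' fields): {name!r}")
    chrom, pos1_s, pos2_s, err1, err2, counter = parts
    if not chrom:
        raise WgsimNameError(f"unparseable origin (empty chromosome): {name!r}")
    if not (pos1_s.isdigit() and pos2_s.isdigit()):
        raise WgsimNameError(f"unparseable origin (non-integer coordinates): {name!r}")
    if not (_ERR_TOKEN.match(err1) and _ERR_TOKEN.match(err2)):
        raise WgsimNameError(f"unparseable origin (bad error-count tokens): {name!r}")
    pos1, pos2 = int(pos1_s), int(pos2_s)
    if pos1 < 1 or pos2 < pos1:
        raise WgsimNameError(f"unparseable origin (coordinates out of order): {name!r}")
    return OriginInfo(
        chrom=chrom, pos1=pos1, pos2=pos2, mate=int(mate_s),
        counter=counter, err1=err1, err2=err2,
    )


def format_wgsim_name(origin: OriginInfo) -> str:
    """Inverse of :func:`parse_wgsim_name` over the documented grammar."""
    return (
        f"{origin.chrom}_{origin.pos1}_{origin.pos2}_"
        f"{origin.err1}_{origin.err2}_{origin.counter}/{origin.mate}"
    )


def extract_umi(read: Read, spec: str) -> Optional[tuple[str, Read]]:
    """Extract a UMI according to a location descriptor.

    ``spec`` is ``"prefix:K"`` (UMI = first K bases, removed from the
    payload) or ``"header:REGEX"`` (REGEX with one capture group searched
    in the full header; payload unchanged). Returns ``None`` (with a
    warning) when the read cannot yield a UMI under the spec.
    """
    kind, _, arg = spec.partition(":")
    if kind == "prefix":
        k = int(arg)
        if k < 1:
            raise ValueError("prefix UMI length must be >= 1")
        if len(read.sequence) <= k:
            warnings.warn(
                f"read {read.name!r} shorter than UMI prefix {k}; skipped",
                stacklevel=2,
            )
            return None
        payload = Read(
            name=read.name,
            sequence=read.sequence[k:],
            qualities=read.qualities[k:] if read.qualities else None,
            mate=read.mate,
            description=read.description,
        )
        return read.sequence[:k], payload
    if kind == "header":
        header = read.description if read.description else read.name
        m = re.search(arg, header)
        if m is None or not m.groups():
            warnings.warn(
                f"read {read.name!r}: header matches no UMI under {arg!r}; skipped",
                stacklevel=2,
            )
            return None
        return m.group(1), read
    raise ValueError(f"unknown UMI spec kind {kind!r} (expected prefix: or header:)")


EVAL_RECORD_HEADER = "#read_name,length,TP,FN,FN_WRONG,FP,FP_INDEL,FP_TRIM,TP_TRIM"


def write_eval_records(records: Iterable[EvalRecord], path: PathLike) -> int:
    """Write the compressed evaluation-record CSV.

    Field order: read_name, length, TP, FN, FN_WRONG, FP, FP_INDEL,
    FP_TRIM, TP_TRIM. Only reads with at least one TP/FP/FN-family event
    are written; all-TN reads are represented solely in dataset totals.
    Returns the number of data lines written.
    """
    n = 0
    with _open_text(path, "wt") as fh:
        fh.write(EVAL_RECORD_HEADER + "\n")
        for rec in records:
            if rec.event_count < 1:
                continue
            fh.write(
                f"{rec.read_name},{rec.length},{rec.tp},{rec.fn},{rec.fn_wrong},"
                f"{rec.fp},{rec.fp_indel},{rec.fp_trim},{rec.tp_trim}\n"
            )
            n += 1
    return n


def parse_eval_record(line: str, lineno: Optional[int] = None) -> EvalRecord:
    """Parse one evaluation-record CSV line (exact inverse of the writer)."""
    where = f" at line {lineno}" if lineno is not None else ""
    fields = line.rstrip("\n").split(",")
    if len(fields) != 9:
        raise EvalRecordFormatError(
            f"expected 9 comma-separated fields, got {len(fields)}{where}"
        )
    name = fields[0]
    try:
        nums = [int(x) for x in fields[1:]]
    except ValueError as exc:
        raise EvalRecordFormatError(f"non-integer count field{where}: {exc}") from exc
    length, tp, fn, fn_wrong, fp, fp_indel, fp_trim, tp_trim = nums
    return EvalRecord(
        read_name=name, length=length, tp=tp, fn=fn, fn_wrong=fn_wrong,
        fp=fp, fp_indel=fp_indel, fp_trim=fp_trim, tp_trim=tp_trim,
    )


def read_eval_records(path: PathLike) -> list[EvalRecord]:
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            records.append(parse_eval_record(line, lineno=lineno))
    return records


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Ordered (name, sequence) pairs; sequences uppercased; duplicate
    names are an error."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate FASTA name {rec.id!r}")
            seen.add(rec.id)
            out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike, width: int = 70) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
            n += 1
    return n


def read_bed(path: PathLike) -> list[CategoryInterval]:
    """Read a 4+-column BED (chrom, start, end, category), 0-based half-open."""
    out: list[CategoryInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise BedFormatError(
                    f"{path}:{lineno}: need >=4 columns (chrom start end category)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                out.append(CategoryInterval(fields[0], start, end, fields[3]))
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return out
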