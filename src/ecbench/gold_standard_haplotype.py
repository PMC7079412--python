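"""Error-free reads for mixed-haplotype (viral quasispecies) data.

Each read is placed on every candidate haplotype, both strands, by a
mismatch-only semi-global scan (the read lies fully inside the
haplotype; its ends are free on the haplotype) and assigned to the
placement with the fewest mismatches. The error-free copy of a read is
then simply the assigned haplotype window, so truth replacement is
purely positional. Two dataset editors support sensitivity studies:
error-rate titration (revert a random subset of sequencing errors to
the true base until a target dataset-wide rate is reached) and
haplotype-diversity reduction (move one haplotype toward another while
re-introducing any sequencing error the edit would have silently fixed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import edlib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _seq
from .io_formats import Read


@dataclass(frozen=True)
class Haplotype:
    name: str
    sequence: str


@dataclass(frozen=True)
class Assignment:
    """Best placement of a read on one haplotype.

    ``offset`` is the 0-based start of the read window on the haplotype;
    ``strand`` '-' means the read is the reverse complement of that
    window."""

    read_name: str
    haplotype: str
    offset: int
    strand: str
    mismatches: int


RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _mismatch_scan(read_arr: np.ndarray, hap_arr: np.ndarray) -> Optional[tuple[int, int]]:
    """(mismatches, offset) of the best placement; leftmost wins ties.
    None when the haplotype is shorter than the read."""
    m = read_arr.size
    if hap_arr.size < m:
        return None
    windows = sliding_window_view(hap_arr, m)
    mm = (windows != read_arr).sum(axis=1)
    off = int(mm.argmin())  # argmin -> first (leftmost) minimum
    return int(mm[off]), off


def assign_read(
    read: Read,
    haplotypes: Sequence[Haplotype],
    max_mismatch_frac: float = 0.1,
) -> Optional[Assignment]:
    """Assign a read to its minimum-mismatch haplotype placement.

    Ties are broken by haplotype input order, then leftmost offset, then
    '+' strand. Returns None (unmapped) when the best placement's
    mismatch fraction exceeds ``max_mismatch_frac``; reads needing indels
    to place well fall out this way and are dropped by callers.
    """
    if not haplotypes:
        raise ValueError("at least one haplotype required")
    fwd = _seq.encode(read.sequence)
    rev = _seq.complement_array(fwd)[::-1].copy()
    best: Optional[tuple[int, int, int, int]] = None  # (mm, hap_idx, offset, strand_rank)
    for hi, hap in enumerate(haplotypes):
        hap_arr = _seq.encode(hap.sequence)
        for strand_rank, arr in ((0, fwd), (1, rev)):
            got = _mismatch_scan(arr, hap_arr)
            if got is None:
                continue
            mm, off = got
            key = (mm, hi, off, strand_rank)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mm, hi, off, strand_rank = best
    if mm / len(read.sequence) > max_mismatch_frac:
        return None
    return Assignment(
        read_name=read.name,
        haplotype=haplotypes[hi].name,
        offset=off,
        strand="+" if strand_rank == 0 else "-",
        mismatches=mm,
    )


def make_error_free(
    read: Read, assignment: Assignment, haplotypes: Sequence[Haplotype]
) -> Read:
    """The error-free copy of a read: the assigned haplotype window,
    reverse-complemented for '-' strand placements. Name and qualities
    are preserved."""
    by_name = {h.name: h for h in haplotypes}
    hap = by_name[assignment.haplotype]
    window = hap.sequence[assignment.offset:assignment.offset + len(read.sequence)]
    if len(window) != len(read.sequence):
        raise ValueError(
            f"assignment of {read.name!r} overhangs haplotype {hap.name!r}"
        )
    seq = window if assignment.strand == "+" else _seq.reverse_complement(window)
    return Read(
        name=read.name, sequence=seq, qualities=read.qualities,
        mate=read.mate, description=read.description,
    )


def build_truth_set(
    reads: Iterable[Read],
    haplotypes: Sequence[Haplotype],
    max_mismatch_frac: float = 0.1,
) -> tuple[list[Read], list[Read], list[Assignment], int]:
    """Assign every read and emit matched (raw, true) sets.

    Unmapped reads are dropped. Returns (kept_raw, true_reads,
    assignments, n_dropped)."""
    kept: list[Read] = []
    truth: list[Read] = []
    assignments: list[Assignment] = []
    n_dropped = 0
    for read in reads:
        asg = assign_read(read, haplotypes, max_mismatch_frac=max_mismatch_frac)
        if asg is None:
            n_dropped += 1
            continue
        kept.append(read)
        truth.append(make_error_free(read, asg, haplotypes))
        assignments.append(asg)
    return kept, truth, assignments, n_dropped


def dataset_error_rate(raw_reads: Sequence[Read], true_reads: Sequence[Read]) -> float:
    """Fraction of erroneous bases over all bases in positionally paired
    (raw, true) reads."""
    errors = 0
    bases = 0
    for raw, true in zip(raw_reads, true_reads, strict=True):
        if len(raw) != len(true):
            raise ValueError(f"read {raw.name!r}: raw/true length mismatch")
        errors += int((_seq.encode(raw.sequence) != _seq.encode(true.sequence)).sum())
        bases += len(raw)
    return errors / bases if bases else 0.0


def titrate_error_rate(
    raw_reads: Sequence[Read],
    true_reads: Sequence[Read],
    target_rate: float,
    rng: RngLike,
) -> list[Read]:
    """Lower the dataset-wide error rate to ``target_rate`` by reverting a
    uniform random subset of error positions to the true base.

    Exactly round(target_rate * total_bases) error positions remain.
    Non-error bases are never touched and no new error is created.
    Raises when the target exceeds the current rate (errors cannot be
    added here)."""
    rng = _as_rng(rng)
    arrs = []
    error_index: list[tuple[int, int]] = []
    total_bases = 0
    for ri, (raw, true) in enumerate(zip(raw_reads, true_reads, strict=True)):
        if len(raw) != len(true):
            raise ValueError(f"read {raw.name!r}: raw/true length mismatch")
        arr = _seq.encode(raw.sequence)
        diff = np.flatnonzero(arr != _seq.encode(true.sequence))
        error_index.extend((ri, int(p)) for p in diff)
        arrs.append(arr)
        total_bases += len(raw)
    k_target = int(round(target_rate * total_bases))
    if k_target > len(error_index):
        raise ValueError(
            f"target rate {target_rate} exceeds current rate "
            f"{len(error_index) / total_bases if total_bases else 0.0:.6g}"
        )
    n_fix = len(error_index) - k_target
    chosen = rng.choice(len(error_index), size=n_fix, replace=False)
    for ci in chosen:
        ri, pos = error_index[int(ci)]
        arrs[ri][pos] = _seq.encode(true_reads[ri].sequence)[pos]
    return [
        Read(
            name=raw.name, sequence=_seq.decode(arr), qualities=raw.qualities,
            mate=raw.mate, description=raw.description,
        )
        for raw, arr in zip(raw_reads, arrs)
    ]


def hamming_fraction(a: str, b: str) -> float:
    """Fraction of differing positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming_fraction requires equal-length sequences")
    if not a:
        return 0.0
    return float((_seq.encode(a) != _seq.encode(b)).mean())


def reduce_haplotype_diversity(
    hap_a: Haplotype,
    hap_b: Haplotype,
    target_hamming: float,
    reads_with_assignments: Sequence[tuple[Read, Assignment]],
    rng: RngLike,
) -> tuple[Haplotype, list[Read]]:
    """Move ``hap_b`` toward ``hap_a`` until their Hamming fraction equals
    round(target_hamming * L) / L, editing hap_b-assigned reads in step.

    A uniform random subset of the differing columns is set in hap_b to
    hap_a's base. Reads assigned to hap_b receive the same replacement at
    covered positions — except that a read base that was a sequencing
    error before the edit must stay an error: it is re-drawn uniformly
    from the three bases different from the new truth. Per-read
    sequencing-error counts are therefore preserved exactly.
    """
    if len(hap_a.sequence) != len(hap_b.sequence):
        raise ValueError("haplotypes must have equal length (columnwise protocol)")
    rng = _as_rng(rng)
    L = len(hap_b.sequence)
    a_arr = _seq.encode(hap_a.sequence)
    b_old = _seq.encode(hap_b.sequence)
    diff = np.flatnonzero(a_arr != b_old)
    target_count = int(round(target_hamming * L))
    n_fix = diff.size - target_count
    if n_fix < 0:
        raise ValueError(
            f"target Hamming {target_hamming} exceeds current "
            f"{diff.size / L:.6g} (cannot add diversity)"
        )
    chosen = np.sort(diff[rng.choice(diff.size, size=n_fix, replace=False)]) \
        if n_fix else np.empty(0, dtype=int)
    b_new = b_old.copy()
    b_new[chosen] = a_arr[chosen]
    chosen_set = set(int(p) for p in chosen)
    out_reads: list[Read] = []
    for read, asg in reads_with_assignments:
        if asg.haplotype != hap_b.name:
            out_reads.append(read)
            continue
        arr = _seq.encode(read.sequence)
        m = len(read.sequence)
        for p in range(asg.offset, asg.offset + m):
            if p not in chosen_set:
                continue
            if asg.strand == "+":
                rp = p - asg.offset
                old_truth = b_old[p]
                new_truth = b_new[p]
            else:
                rp = (asg.offset + m - 1) - p
                old_truth = _seq.complement_array(b_old[p:p + 1])[0]
                new_truth = _seq.complement_array(b_new[p:p + 1])[0]
            if arr[rp] == old_truth:
                arr[rp] = new_truth
            else:
                # was a sequencing error; re-introduce it against the new truth
                arr[rp] = new_truth
                _seq.substitute(arr, np.array([rp]), rng)
        out_reads.append(
            Read(
                name=read.name, sequence=_seq.decode(arr),
                qualities=read.qualities, mate=read.mate,
                description=read.description,
            )
        )
    return Haplotype(hap_b.name, _seq.decode(b_new)), out_reads


def align_haplotypes(a: str, b: str) -> tuple[str, str]:
    """Unit-cost global alignment of two haplotypes (preparation step for
    the columnwise protocol when inputs differ in length). Returns the
    two gapped rows."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def aligned_hamming_fraction(a: str, b: str) -> float:
    """Hamming fraction after global alignment, with gap columns excluded
    from both numerator and denominator."""
    row_a, row_b = align_haplotypes(a, b)
    n = 0
    d = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        n += 1
        if x != y:
            d += 1
    return d / n if n else 0.0
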