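"""Base-resolution evaluation of corrected reads against a gold standard.

Every read is scored as a (true, raw, corrected) trio. The three
sequences are placed into one gapped three-row alignment and each column
is classified into one of eight outcomes:

    TN        correct base left alone
    TP        sequencing error correctly fixed (also: inserted base
              removed, or deleted base correctly restored)
    FP        correct base changed to a wrong base
    FP_INDEL  insertion/deletion introduced by the tool
    FN        sequencing error left untouched
    FN_WRONG  sequencing error changed to a different wrong base
    TP_TRIM   erroneous base removed in a terminal trim
    FP_TRIM   correct base removed in a terminal trim

The alignment is a deterministic two-stage global dynamic program:
true vs raw first, then the corrected sequence against the resulting
two-row column profile. Scoring is match +1 / mismatch -1 / gap -5 with
a fixed diagonal > up > left tie-break and an infinitesimal bias against
gap moves, so results are reproducible to the byte. The stiff gap
penalty matters: raw reads are positionally paired with their error-free
templates, so for equal-length substitution-only trios — the dominant
case for the gold standards built by this package — the optimal
alignment must be gap-free, and a mild penalty would let runs of
clustered errors buy spurious gap columns. With these weights a gap pair
only appears when the sequences genuinely differ in length (tool indels
or trimming) and the classification reduces to a positionwise comparison
otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from numba import njit

from . import _seq
from .io_formats import EvalRecord, PathLike, Read, read_fastq
from .metrics_report import ConfusionTotals

GAP = ord("-")


@dataclass(frozen=True)
class Scoring:
    """Alignment weights (applied in both DP stages)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -5.0


DEFAULT_SCORING = Scoring()


@dataclass
class TripleAlignment:
    """Three equal-length gapped rows: true, raw, corrected."""

    true_row: str
    raw_row: str
    corrected_row: str

    def __post_init__(self) -> None:
        if not (len(self.true_row) == len(self.raw_row) == len(self.corrected_row)):
            raise ValueError("alignment rows must have equal length")

    @property
    def columns(self) -> int:
        return len(self.true_row)


@njit(cache=True)
def _nw_pointers(S: np.ndarray, gap: float) -> np.ndarray:
    """Global-alignment pointer matrix over a precomputed score matrix
    S[i, j] = score of pairing row-symbol i with column-symbol j.
    Pointer codes: 0 diagonal, 1 up (consume row seq), 2 left (consume
    column seq); ties resolve diagonal > up > left. Gap moves carry an
    infinitesimal extra penalty (far below the 0.5 score granularity) so
    that an alignment tying a gap-free one never wins through gaps."""
    n, m = S.shape
    gap_eff = gap - 1e-9
    H = np.empty((n + 1, m + 1), np.float64)
    P = np.zeros((n + 1, m + 1), np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        H[0, j] = H[0, j - 1] + gap_eff
        P[0, j] = 2
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap_eff
        P[i, 0] = 1
        for j in range(1, m + 1):
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            u = H[i - 1, j] + gap_eff
            l = H[i, j - 1] + gap_eff
            best = d
            p = 0
            if u > best:
                best = u
                p = 1
            if l > best:
                best = l
                p = 2
            H[i, j] = best
            P[i, j] = p
    return P


def _traceback(P: np.ndarray) -> list[int]:
    """Pointer matrix -> list of ops from start to end (0/1/2)."""
    i, j = P.shape[0] - 1, P.shape[1] - 1
    ops: list[int] = []
    while i > 0 or j > 0:
        p = P[i, j]
        ops.append(int(p))
        if p == 0:
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()
    return ops


def _pair_score_matrix(a: np.ndarray, b: np.ndarray, sc: Scoring) -> np.ndarray:
    return np.where(a[:, None] == b[None, :], sc.match, sc.mismatch)


def align_trio(
    true_seq: str,
    raw_seq: str,
    corrected_seq: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> TripleAlignment:
    """Deterministic three-row alignment of a (true, raw, corrected) trio.

    Stage 1 globally aligns true against raw; stage 2 aligns corrected
    against the stage-1 column profile, scoring a corrected symbol
    against a column as the mean of its scores against the two member
    symbols (a gap member contributes the gap weight). Equal-length
    substitution-only trios produce a gap-free columnwise alignment.
    """
    if not (true_seq and raw_seq and corrected_seq):
        raise ValueError("all three sequences must be non-empty")
    t = _seq.encode(true_seq)
    r = _seq.encode(raw_seq)
    c = _seq.encode(corrected_seq)

    ops1 = _traceback(_nw_pointers(_pair_score_matrix(t, r, scoring), scoring.gap))
    n_cols = len(ops1)
    t_col = np.full(n_cols, GAP, dtype=np.uint8)
    r_col = np.full(n_cols, GAP, dtype=np.uint8)
    ti = ri = 0
    for k, op in enumerate(ops1):
        if op != 2:
            t_col[k] = t[ti]
            ti += 1
        if op != 1:
            r_col[k] = r[ri]
            ri += 1

    # corrected vs (true,raw) profile: mean member score per column
    def member_scores(row: np.ndarray) -> np.ndarray:
        s = np.where(row[:, None] == c[None, :], scoring.match, scoring.mismatch)
        s[row == GAP, :] = scoring.gap
        return s

    S2 = 0.5 * (member_scores(t_col) + member_scores(r_col))
    ops2 = _traceback(_nw_pointers(S2, scoring.gap))

    t_out = bytearray()
    r_out = bytearray()
    c_out = bytearray()
    pi = ci = 0
    for op in ops2:
        if op == 0:
            t_out.append(t_col[pi])
            r_out.append(r_col[pi])
            c_out.append(c[ci])
            pi += 1
            ci += 1
        elif op == 1:  # consume profile column, corrected gap
            t_out.append(t_col[pi])
            r_out.append(r_col[pi])
            c_out.append(GAP)
            pi += 1
        else:  # corrected insertion: new all-new column
            t_out.append(GAP)
            r_out.append(GAP)
            c_out.append(c[ci])
            ci += 1
    return TripleAlignment(
        true_row=t_out.decode("ascii"),
        raw_row=r_out.decode("ascii"),
        corrected_row=c_out.decode("ascii"),
    )


def align_trio_msa(
    true_seq: str, raw_seq: str, corrected_seq: str, exec_cmd: str
) -> TripleAlignment:
    """Align a trio with a user-supplied multiple-sequence-alignment
    executable instead of the built-in engine.

    ``exec_cmd`` is a shell-style command (e.g. ``"mafft --quiet"``); the
    path of a three-record FASTA (ids: true, raw, corrected) is appended
    and the program must print the aligned FASTA on stdout. Rows are
    uppercased; the adapter verifies that removing gaps reproduces the
    inputs."""
    import shlex
    import subprocess
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for name, seq in (("true", true_seq), ("raw", raw_seq),
                          ("corrected", corrected_seq)):
            fh.write(f">{name}\n{seq}\n")
        path = fh.name
    try:
        proc = subprocess.run(
            shlex.split(exec_cmd) + [path],
            capture_output=True, text=True, check=True,
        )
    finally:
        Path(path).unlink(missing_ok=True)
    rows: dict[str, list[str]] = {}
    current: Optional[str] = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            rows[current] = []
        elif current is not None:
            rows[current].append(line.strip())
    try:
        aligned = {k: "".join(rows[k]).upper() for k in ("true", "raw", "corrected")}
    except KeyError as exc:
        raise ValueError(f"MSA output missing row {exc.args[0]!r}") from exc
    for key, original in (("true", true_seq), ("raw", raw_seq),
                          ("corrected", corrected_seq)):
        if aligned[key].replace("-", "") != original.upper():
            raise ValueError(f"MSA {key} row does not reproduce the input sequence")
    return TripleAlignment(
        true_row=aligned["true"], raw_row=aligned["raw"],
        corrected_row=aligned["corrected"],
    )


def classify_column(t: str, r: str, c: str, in_terminal_trim: bool = False) -> Optional[str]:
    """Classify one alignment column (symbols over {A,C,G,T,N,-}).

    Returns one of TP/TN/FP/FP_INDEL/FN/FN_WRONG/TP_TRIM/FP_TRIM, or
    None for non-scoring columns (raw and corrected both gapped). N is an
    ordinary symbol that matches only itself, so an N written over a
    correct base counts as FP.
    """
    if t == "-" and r == "-" and c == "-":
        raise ValueError("all-gap column is not a valid alignment column")
    if r == "-" and c == "-":
        return None  # base absent from both raw and corrected; nothing to score
    if r != "-" and c == "-":
        if in_terminal_trim:
            return "TP_TRIM" if r != t else "FP_TRIM"
        if t == "-":
            return "TP"  # tool removed a base the truth never had
        return "FP_INDEL" if r == t else "FN_WRONG"
    if r == "-" and c != "-":
        return "TP" if c == t else "FP_INDEL"
    # r and c both bases
    if c == r:
        return "TN" if r == t else "FN"
    if c == t:
        return "TP"
    return "FP" if r == t else "FN_WRONG"


def _terminal_trim_mask(corrected_row: str) -> list[bool]:
    """True for columns inside the maximal leading/trailing gap runs of
    the corrected row."""
    n = len(corrected_row)
    mask = [False] * n
    i = 0
    while i < n and corrected_row[i] == "-":
        mask[i] = True
        i += 1
    j = n - 1
    while j >= 0 and corrected_row[j] == "-":
        mask[j] = True
        j -= 1
    return mask


def classify_alignment(alignment: TripleAlignment) -> dict[str, int]:
    """Column-label counts for a trio alignment."""
    counts = {
        k: 0
        for k in ("TP", "TN", "FP", "FP_INDEL", "FN", "FN_WRONG", "TP_TRIM", "FP_TRIM")
    }
    trim = _terminal_trim_mask(alignment.corrected_row)
    for t, r, c, is_trim in zip(
        alignment.true_row, alignment.raw_row, alignment.corrected_row, trim
    ):
        label = classify_column(t, r, c, in_terminal_trim=is_trim)
        if label is not None:
            counts[label] += 1
    return counts


def evaluate_read(
    true_read: Read,
    raw_read: Read,
    corrected_read: Read,
    scoring: Scoring = DEFAULT_SCORING,
    msa_exec: Optional[str] = None,
) -> EvalRecord:
    """Align one trio and return its per-read classification record.

    ``length`` is the raw read length; ``tn`` is carried in memory for
    dataset totals (it is not part of the compressed record format).
    ``msa_exec`` routes the alignment through an external MSA executable
    instead of the built-in engine."""
    if msa_exec is not None:
        alignment = align_trio_msa(
            true_read.sequence, raw_read.sequence, corrected_read.sequence, msa_exec
        )
    else:
        alignment = align_trio(
            true_read.sequence, raw_read.sequence, corrected_read.sequence, scoring
        )
    counts = classify_alignment(alignment)
    return EvalRecord(
        read_name=raw_read.name,
        length=len(raw_read.sequence),
        tp=counts["TP"],
        fn=counts["FN"],
        fn_wrong=counts["FN_WRONG"],
        fp=counts["FP"],
        fp_indel=counts["FP_INDEL"],
        fp_trim=counts["FP_TRIM"],
        tp_trim=counts["TP_TRIM"],
        tn=counts["TN"],
    )


def _as_trimmed_record(true_read: Read, raw_read: Read) -> EvalRecord:
    """Score a read the correction tool dropped entirely as fully trimmed:
    every erroneous raw base is TP_TRIM, every correct one FP_TRIM."""
    if len(true_read.sequence) == len(raw_read.sequence):
        t = _seq.encode(true_read.sequence)
        r = _seq.encode(raw_read.sequence)
        tp_trim = int((t != r).sum())
    else:  # rare: indel-bearing truth; align pairwise and count mismatch columns
        alignment = align_trio(true_read.sequence, raw_read.sequence, raw_read.sequence)
        tp_trim = sum(
            1
            for t_s, r_s in zip(alignment.true_row, alignment.raw_row)
            if r_s != "-" and t_s != r_s
        )
    return EvalRecord(
        read_name=raw_read.name,
        length=len(raw_read.sequence),
        tp_trim=tp_trim,
        fp_trim=len(raw_read.sequence) - tp_trim,
        tn=0,
    )


@dataclass
class EvaluationResult:
    records: list[EvalRecord]
    totals: ConfusionTotals
    n_evaluated: int = 0
    n_missing: int = 0
    skipped_names: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.skipped_names is None:
            self.skipped_names = []


ReadsInput = Union[PathLike, Iterable[Read]]


def _load_reads(source: ReadsInput) -> dict[str, Read]:
    if isinstance(source, (str, Path)):
        reads: Iterable[Read] = read_fastq(source)
    else:
        reads = source
    out: dict[str, Read] = {}
    for read in reads:
        if read.name in out:
            raise ValueError(f"duplicate read name {read.name!r}")
        out[read.name] = read
    return out


def evaluate_dataset(
    true_source: ReadsInput,
    raw_source: ReadsInput,
    corrected_source: ReadsInput,
    scoring: Scoring = DEFAULT_SCORING,
    missing_policy: str = "skip",
    msa_exec: Optional[str] = None,
) -> EvaluationResult:
    """Evaluate a whole corrected read set against its gold standard.

    Reads are matched by name; paired-end data is evaluated per mate (a
    mate's ``/1``/``/2`` suffix makes its name unique, so pairing is
    effectively ignored). The true and raw sets must contain the same
    names; the corrected set may be a subset — missing reads are either
    skipped (``missing_policy='skip'``, counted in the result) or scored
    as fully trimmed (``'as-trimmed'``). A corrected name absent from the
    truth set is an error. Totals accumulate the eight classes plus TN
    and total bases (sum of raw lengths over evaluated reads); output is
    sorted by name, so it is invariant to input order.
    """
    if missing_policy not in ("skip", "as-trimmed"):
        raise ValueError("missing_policy must be 'skip' or 'as-trimmed'")
    true_reads = _load_reads(true_source)
    raw_reads = _load_reads(raw_source)
    corrected_reads = _load_reads(corrected_source)
    if set(true_reads) != set(raw_reads):
        raise ValueError("true and raw read sets must contain the same read names")
    invented = set(corrected_reads) - set(true_reads)
    if invented:
        some = ", ".join(sorted(invented)[:3])
        raise ValueError(
            f"{len(invented)} corrected read(s) absent from the truth set "
            f"(e.g. {some})"
        )
    result = EvaluationResult(records=[], totals=ConfusionTotals())
    for name in sorted(true_reads):
        true_read = true_reads[name]
        raw_read = raw_reads[name]
        corrected = corrected_reads.get(name)
        if corrected is None:
            if missing_policy == "skip":
                result.n_missing += 1
                result.skipped_names.append(name)
                continue
            record = _as_trimmed_record(true_read, raw_read)
        else:
            record = evaluate_read(true_read, raw_read, corrected, scoring,
                                   msa_exec=msa_exec)
        result.records.append(record)
        result.totals.add_record(record)
        result.n_evaluated += 1
    return result
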