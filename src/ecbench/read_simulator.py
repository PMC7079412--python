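"""wgsim-style paired-end read simulation with matched ground truth.

The simulator draws fragments from a reference, emits mate 1 from the
fragment's left end and mate 2 as the reverse complement of its right
end, then injects independent per-base substitution errors. Both the
erroneous ("raw") and error-free ("true") copies of every read are
reported, with origin and per-mate error counts encoded wgsim-style in
the read names — the matched files are the gold standard that the
evaluation modules consume.

Also hosts the synthetic fixture generators for the other two
gold-standard protocols: UMI-tagged amplicon clusters and reads drawn
from a mixture of diverged haplotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from . import _seq
from .io_formats import Read, OriginInfo, format_wgsim_name


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Simulation settings.

    coverage   fold coverage per reference sequence (> 0)
    read_len   read length in bases
    frag_mean  mean fragment length in bases
    frag_std   fragment-length standard deviation; defaults to 10% of
               frag_mean when unset
    err_rate   per-base substitution-error probability in [0, 1)
    mut_rate   per-base template-mutation probability in [0, 1); mutations
               are genuine variants, present in both true and raw reads,
               never scored as errors
    seed       RNG seed (identical seed => byte-identical output)
    """

    coverage: float
    read_len: int = 100
    frag_mean: int = 200
    frag_std: Optional[float] = None
    err_rate: float = 0.01
    mut_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.read_len > self.frag_mean:
            raise ValueError("read_len must be <= frag_mean")
        if not 0 <= self.err_rate < 1:
            raise ValueError("err_rate must be in [0, 1)")
        if not 0 <= self.mut_rate < 1:
            raise ValueError("mut_rate must be in [0, 1)")
        if self.frag_std is None:
            self.frag_std = 0.1 * self.frag_mean
        if self.frag_std < 0:
            raise ValueError("frag_std must be >= 0")


class SimulatedReads(NamedTuple):
    raw1: list[Read]
    raw2: list[Read]
    true1: list[Read]
    true2: list[Read]


def apply_substitution_errors(
    sequence: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Substitute each A/C/G/T base independently with probability ``rate``
    (N bases are never touched). The substituted base is uniform over the
    three alternatives, so every returned position genuinely differs.
    Returns (mutated sequence, sorted 0-based error positions)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    arr = _seq.encode(sequence)
    mask = rng.random(arr.size) < rate
    mask &= arr != ord("N")
    positions = np.flatnonzero(mask)
    _seq.substitute(arr, positions, rng)
    return _seq.decode(arr), positions.tolist()


def _draw_fragment_length(rng: np.random.Generator, params: SimParams, seq_len: int) -> int:
    lo, hi = params.read_len, seq_len
    for _ in range(1000):
        flen = int(round(rng.normal(params.frag_mean, params.frag_std)))
        if lo <= flen <= hi:
            return flen
    return min(max(lo, params.frag_mean), hi)


def simulate_reads(
    reference: Sequence[tuple[str, str]], params: SimParams
) -> SimulatedReads:
    """Simulate paired-end reads from every reference sequence.

    Pairs per sequence = round(L * coverage / (2 * read_len)). Fragment
    starts are uniform; lengths follow a rounded normal truncated to
    [read_len, L]. Fragments containing N are redrawn (up to 100 starts,
    then an error). Read names follow the wgsim grammar with the realized
    per-mate substitution-error counts and a global decimal pair counter.
    """
    rng = np.random.default_rng(params.seed)
    raw1, raw2, true1, true2 = [], [], [], []
    counter = 0
    qual = None  # written as constant placeholder by write_fastq
    for ref_name, ref_seq in reference:
        L = len(ref_seq)
        if L < params.read_len:
            raise SimulationError(
                f"reference {ref_name!r} (length {L}) shorter than read length "
                f"{params.read_len}"
            )
        ref_arr = _seq.encode(ref_seq)
        has_n = bool(np.any(ref_arr == ord("N")))
        n_pairs = int(round(L * params.coverage / (2 * params.read_len)))
        for _ in range(n_pairs):
            flen = _draw_fragment_length(rng, params, L)
            frag = None
            for _attempt in range(100):
                start = int(rng.integers(0, L - flen + 1))
                frag = ref_arr[start:start + flen]
                if not has_n or not np.any(frag == ord("N")):
                    break
            else:
                raise SimulationError(
                    f"reference {ref_name!r}: could not draw an N-free fragment "
                    f"in 100 attempts"
                )
            template = frag.copy()
            if params.mut_rate > 0:
                mut_mask = rng.random(template.size) < params.mut_rate
                _seq.substitute(template, np.flatnonzero(mut_mask), rng)
            t1 = template[: params.read_len]
            t2 = _seq.complement_array(template[-params.read_len:])[::-1]
            s1, e1 = apply_substitution_errors(_seq.decode(t1), params.err_rate, rng)
            s2, e2 = apply_substitution_errors(_seq.decode(t2), params.err_rate, rng)
            pos1 = start + 1             # 1-based leftmost mate-1 coordinate
            pos2 = start + flen          # 1-based mate-2 fragment-end coordinate
            base = OriginInfo(
                chrom=ref_name, pos1=pos1, pos2=pos2, mate=1, counter=str(counter),
                err1=f"{len(e1)}:0:0", err2=f"{len(e2)}:0:0",
            )
            name1 = format_wgsim_name(base)
            name2 = format_wgsim_name(
                OriginInfo(**{**base.__dict__, "mate": 2})  # type: ignore[arg-type]
            )
            raw1.append(Read(name1, s1, qual, mate=1))
            raw2.append(Read(name2, s2, qual, mate=2))
            true1.append(Read(name1, _seq.decode(t1), qual, mate=1))
            true2.append(Read(name2, _seq.decode(t2), qual, mate=2))
            counter += 1
    return SimulatedReads(raw1, raw2, true1, true2)


def simulate_tcr_like_panel(
    n_transcripts: int, transcript_len: int, seed: int
) -> list[tuple[str, str]]:
    """Deterministic synthetic transcript panel standing in for a T cell
    receptor transcript set, usable as a simulate_reads reference. Total
    length = n_transcripts * transcript_len."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_transcripts))
    return [
        (f"tcr_transcript_{i + 1:0{width}d}", _seq.random_sequence(transcript_len, rng))
        for i in range(n_transcripts)
    ]


def simulate_umi_tagged_reads(
    n_clusters: int,
    cluster_size: int,
    read_len: int = 100,
    umi_len: int = 12,
    err_rate: float = 0.01,
    seed: int = 1,
) -> tuple[list[Read], dict[str, str]]:
    """Synthetic UMI-tagged amplicon reads: ``n_clusters`` molecules, each
    amplified into ``cluster_size`` copies carrying the same UMI prefix
    and independent per-base substitution errors at ``err_rate``.

    Returns (reads, truth) where truth maps UMI -> error-free template
    (the payload without the UMI). Read sequences are UMI + payload.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth: dict[str, str] = {}
    umis: set[str] = set()
    for ci in range(n_clusters):
        while True:
            umi = _seq.random_sequence(umi_len, rng)
            if umi not in umis:
                umis.add(umi)
                break
        template = _seq.random_sequence(read_len, rng)
        truth[umi] = template
        for ri in range(cluster_size):
            payload, _ = apply_substitution_errors(template, err_rate, rng)
            reads.append(Read(f"mol{ci:05d}_copy{ri:03d}", umi + payload))
    return reads, truth


@dataclass(frozen=True)
class ReadOrigin:
    """Ground truth for one read drawn from a haplotype mixture."""

    haplotype: str
    offset: int
    strand: str
    true_sequence: str
    error_positions: tuple[int, ...]


def simulate_haplotype_mixture(
    hap_len: int = 9000,
    divergence: float = 0.01,
    n_reads: int = 1000,
    read_len: int = 250,
    err_rate: float = 0.0144,
    proportions: Sequence[float] = (0.5, 0.5),
    seed: int = 1,
) -> tuple[list[tuple[str, str]], list[Read], list[ReadOrigin]]:
    """Reads from a two-haplotype mixture at a stated Hamming divergence.

    Haplotype B is haplotype A with round(divergence * hap_len) uniform
    substitutions. Reads are drawn from each haplotype in the given
    proportions, from both strands, with substitution errors at
    ``err_rate``. Returns (haplotypes, reads, origins); origins record
    the source haplotype, placement, strand and error-free sequence.
    """
    if len(proportions) != 2:
        raise ValueError("exactly two mixture proportions expected")
    rng = np.random.default_rng(seed)
    hap_a = _seq.random_sequence(hap_len, rng)
    arr_b = _seq.encode(hap_a)
    n_diff = int(round(divergence * hap_len))
    diff_pos = rng.choice(hap_len, size=n_diff, replace=False)
    _seq.substitute(arr_b, np.sort(diff_pos), rng)
    hap_b = _seq.decode(arr_b)
    haps = [("hapA", hap_a), ("hapB", hap_b)]
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    reads: list[Read] = []
    origins: list[ReadOrigin] = []
    for i in range(n_reads):
        hi = int(rng.choice(2, p=p))
        hap_name, hap_seq = haps[hi]
        offset = int(rng.integers(0, hap_len - read_len + 1))
        window = hap_seq[offset:offset + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        true_seq = window if strand == "+" else _seq.reverse_complement(window)
        raw_seq, errs = apply_substitution_errors(true_seq, err_rate, rng)
        name = f"mix_read_{i:06d}"
        reads.append(Read(name, raw_seq))
        origins.append(ReadOrigin(hap_name, offset, strand, true_seq, tuple(errs)))
    return haps, reads, origins
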