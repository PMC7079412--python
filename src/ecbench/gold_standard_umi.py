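"""Error-free reads from UMI-tagged data by per-cluster majority consensus.

Reads sharing a unique molecular identifier derive from one template
molecule, so within a UMI cluster the modal base at each position is the
template base and minority bases are amplification/sequencing errors.
A consensus base requires a configurable supermajority (default 80%);
if any position lacks that support the whole cluster is discarded, which
protects genuine low-frequency variants from being voted away.
"""
from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from . import _seq
from .io_formats import Read, extract_umi


@dataclass
class UmiCluster:
    umi: str
    members: list[Read]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a UMI cluster needs at least one member")


@dataclass
class ConsensusResult:
    """Outcome of consensus calling on one cluster.

    status              "accepted" or "discarded"
    consensus           consensus sequence (accepted clusters only)
    per_position_support max base fraction per position (empty when the
                        cluster was discarded before voting)
    n_members_used      members of the modal length that voted
    n_dropped_length    members dropped for having a non-modal length
    reason              why a cluster was discarded ("too_small" or
                        "low_support"), None when accepted
    """

    status: str
    consensus: Optional[str] = None
    per_position_support: list[float] = field(default_factory=list)
    n_members_used: int = 0
    n_dropped_length: int = 0
    reason: Optional[str] = None


def cluster_by_umi(
    reads: Iterable[Read],
    spec: str,
    on_skip: Optional[Callable[[Read], None]] = None,
) -> list[UmiCluster]:
    """Group reads into clusters keyed by exact UMI match.

    Cluster members are the UMI-stripped payloads. Reads that yield no
    UMI under ``spec`` are skipped (``on_skip`` callback if given, else a
    summary warning). Clusters are sorted by UMI and members by name, so
    the result is independent of input order.
    """
    groups: dict[str, list[Read]] = defaultdict(list)
    n_skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-read skip warnings summarized below
        for read in reads:
            got = extract_umi(read, spec)
            if got is None:
                n_skipped += 1
                if on_skip is not None:
                    on_skip(read)
                continue
            umi, payload = got
            groups[umi].append(payload)
    if n_skipped and on_skip is None:
        warnings.warn(f"{n_skipped} read(s) yielded no UMI and were skipped", stacklevel=2)
    return [
        UmiCluster(umi, sorted(groups[umi], key=lambda r: (r.name, r.sequence)))
        for umi in sorted(groups)
    ]


def _modal_length_members(members: list[Read]) -> tuple[list[Read], int]:
    lengths = Counter(len(m) for m in members)
    top = max(lengths.values())
    modal = min(l for l, c in lengths.items() if c == top)  # tie -> shorter
    used = [m for m in members if len(m) == modal]
    return used, len(members) - len(used)


def consensus_cluster(
    cluster: UmiCluster, threshold: float = 0.8, min_size: int = 3
) -> ConsensusResult:
    """Call a majority consensus for one cluster.

    At each position the modal base is accepted iff its fraction of the
    voting members is >= ``threshold``; a single failing position
    discards the whole cluster. Members whose length differs from the
    cluster's modal length are dropped from the vote (counted in the
    result); clusters with fewer than ``min_size`` voting members are
    discarded. ``threshold`` must exceed 0.5 so the winning base is
    unique. Qualities are ignored.
    """
    if not threshold > 0.5:
        raise ValueError("threshold must be > 0.5")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    used, n_dropped = _modal_length_members(cluster.members)
    if len(used) < min_size:
        return ConsensusResult(
            status="discarded", n_members_used=len(used),
            n_dropped_length=n_dropped, reason="too_small",
        )
    mat = np.stack([_seq.encode(m.sequence) for m in used])
    n, L = mat.shape
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGTN"])
    winner = counts.argmax(axis=0)
    support = counts.max(axis=0) / n
    if bool(np.any(support < threshold)):
        return ConsensusResult(
            status="discarded", per_position_support=support.tolist(),
            n_members_used=n, n_dropped_length=n_dropped, reason="low_support",
        )
    consensus = "".join("ACGTN"[i] for i in winner)
    return ConsensusResult(
        status="accepted", consensus=consensus,
        per_position_support=support.tolist(),
        n_members_used=n, n_dropped_length=n_dropped,
    )


def generate_umi_gold_standard(
    reads: Iterable[Read],
    spec: str,
    threshold: float = 0.8,
    min_size: int = 3,
    emit: str = "per-read",
) -> tuple[list[Read], list[Read], dict[str, int]]:
    """Build matched (true, raw) read sets from UMI-tagged reads.

    For every accepted cluster, ``per-read`` mode (default) emits one
    (raw payload, consensus) pair per voting member, so evaluation runs
    on the original raw reads; ``per-cluster`` mode deduplicates to a
    single pair per cluster (first member by name as the raw
    representative). Reads of discarded clusters appear in neither
    output. Returns (true_reads, raw_reads, report).
    """
    if emit not in ("per-read", "per-cluster"):
        raise ValueError("emit must be 'per-read' or 'per-cluster'")
    report = {
        "reads_in": 0,
        "reads_unparseable": 0,
        "clusters_total": 0,
        "clusters_accepted": 0,
        "clusters_discarded_low_support": 0,
        "clusters_discarded_too_small": 0,
        "members_dropped_length": 0,
        "reads_emitted": 0,
        "reads_discarded": 0,
    }
    reads = list(reads)
    report["reads_in"] = len(reads)
    clusters = cluster_by_umi(
        reads, spec, on_skip=lambda r: report.__setitem__(
            "reads_unparseable", report["reads_unparseable"] + 1
        ),
    )
    true_out: list[Read] = []
    raw_out: list[Read] = []
    for cluster in clusters:
        report["clusters_total"] += 1
        result = consensus_cluster(cluster, threshold=threshold, min_size=min_size)
        report["members_dropped_length"] += result.n_dropped_length
        if result.status != "accepted":
            key = (
                "clusters_discarded_low_support"
                if result.reason == "low_support"
                else "clusters_discarded_too_small"
            )
            report[key] += 1
            report["reads_discarded"] += len(cluster.members)
            continue
        report["clusters_accepted"] += 1
        used, _ = _modal_length_members(cluster.members)
        emitted = used if emit == "per-read" else used[:1]
        for member in emitted:
            raw_out.append(member)
            true_out.append(
                Read(name=member.name, sequence=result.consensus, mate=member.mate)
            )
        report["reads_emitted"] += len(emitted)
        report["reads_discarded"] += len(cluster.members) - len(emitted)
    return true_out, raw_out, report
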