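"""Accuracy metrics over base-classification totals, with optional
stratification by genomic category.

Conventions: FN in every formula means fn + fn_wrong (an error that was
ignored *or* changed to another wrong base); every zero-denominator case
returns 0. Gain is the headline metric: (TP - FP_all) / (TP + FN), 1.0
for a tool that fixed everything and broke nothing, 0 for a no-op,
negative when the tool did more harm than good.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import (
    CategoryInterval,
    EvalRecord,
    OriginInfo,
    WgsimNameError,
    parse_wgsim_name,
)


@dataclass
class ConfusionTotals:
    """Dataset-level base-classification counts.

    ``total_bases`` is the sum of raw-read lengths over evaluated reads;
    inserted-base events (FP_INDEL insertions) are not part of it.
    """

    tp: int = 0
    fp: int = 0
    fp_indel: int = 0
    fn: int = 0
    fn_wrong: int = 0
    tn: int = 0
    tp_trim: int = 0
    fp_trim: int = 0
    total_bases: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @property
    def fn_total(self) -> int:
        return self.fn + self.fn_wrong

    def add_record(self, record: EvalRecord) -> None:
        """Accumulate one per-read record. A record parsed back from the
        compressed format has no TN column; TN is then inferred as the
        raw-length remainder after all scored substitution and trim
        events."""
        self.tp += record.tp
        self.fp += record.fp
        self.fp_indel += record.fp_indel
        self.fn += record.fn
        self.fn_wrong += record.fn_wrong
        self.tp_trim += record.tp_trim
        self.fp_trim += record.fp_trim
        self.total_bases += record.length
        if record.tn is not None:
            self.tn += record.tn
        else:
            implied = record.length - (
                record.tp + record.fn + record.fn_wrong + record.fp
                + record.tp_trim + record.fp_trim
            )
            self.tn += max(implied, 0)

    def __add__(self, other: "ConfusionTotals") -> "ConfusionTotals":
        return ConfusionTotals(
            **{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)}
        )


def precision(t: ConfusionTotals) -> float:
    """Proportion of proper corrections among all corrections made."""
    denom = t.tp + t.fp + t.fp_indel
    return t.tp / denom if denom > 0 else 0.0


def sensitivity(t: ConfusionTotals) -> float:
    """Proportion of fixed errors among all errors present."""
    denom = t.tp + t.fn_total
    return t.tp / denom if denom > 0 else 0.0


def gain(t: ConfusionTotals) -> float:
    """Net benefit: corrections made minus corrections broken, over all
    errors. Bounded above by sensitivity (and by 1)."""
    denom = t.tp + t.fn_total
    return (t.tp - (t.fp + t.fp_indel)) / denom if denom > 0 else 0.0


def trim_percent(t: ConfusionTotals) -> float:
    """Proportion of bases trimmed out of all bases analyzed."""
    return (t.tp_trim + t.fp_trim) / t.total_bases if t.total_bases > 0 else 0.0


def trim_efficiency(t: ConfusionTotals) -> float:
    """Proportion of trimmed bases that removed a genuine error."""
    denom = t.tp_trim + t.fp_trim
    return t.tp_trim / denom if denom > 0 else 0.0


def f_score(t: ConfusionTotals) -> float:
    """Harmonic mean of precision and sensitivity (F1)."""
    p = precision(t)
    s = sensitivity(t)
    return 2 * p * s / (p + s) if (p + s) > 0 else 0.0


@dataclass(frozen=True)
class MetricSet:
    precision: float
    sensitivity: float
    gain: float
    f_score: float
    trim_percent: float
    trim_efficiency: float


def compute_metrics(t: ConfusionTotals) -> MetricSet:
    return MetricSet(
        precision=precision(t),
        sensitivity=sensitivity(t),
        gain=gain(t),
        f_score=f_score(t),
        trim_percent=trim_percent(t),
        trim_efficiency=trim_efficiency(t),
    )


OriginLookup = Mapping[str, tuple[str, int, int]]


def _record_origin(
    record: EvalRecord, origins: Optional[OriginLookup]
) -> Optional[tuple[str, int, int]]:
    """(chrom, start0, end0) half-open origin interval of a read, from a
    lookup table or its wgsim-style name. None when unparseable."""
    if origins is not None:
        return origins.get(record.read_name)
    try:
        info = parse_wgsim_name(record.read_name)
    except WgsimNameError:
        return None
    return info.chrom, info.pos1 - 1, info.pos2


def stratify_by_category(
    records: Iterable[EvalRecord],
    intervals: Sequence[CategoryInterval],
    origins: Optional[OriginLookup] = None,
    strict: bool = False,
) -> dict[str, ConfusionTotals]:
    """Aggregate per-read counts into genomic categories.

    A read belongs to every category whose interval overlaps its origin
    fragment (so category rows need not sum to the global totals); reads
    overlapping no interval fall into "normal". Origins come from a
    lookup table (name -> (chrom, start0, end0)) or, by default, from
    wgsim-style names. Unparseable origins raise under ``strict``,
    otherwise land in "unassigned".
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = iv.category
    out: dict[str, ConfusionTotals] = {}

    def bucket(name: str) -> ConfusionTotals:
        if name not in out:
            out[name] = ConfusionTotals()
        return out[name]

    for record in records:
        origin = _record_origin(record, origins)
        if origin is None:
            if strict:
                raise WgsimNameError(
                    f"cannot determine origin of read {record.read_name!r}"
                )
            bucket("unassigned").add_record(record)
            continue
        chrom, start, end = origin
        hits = trees[chrom][start:end] if chrom in trees else set()
        categories = sorted({hit.data for hit in hits}) or ["normal"]
        for category in categories:
            bucket(category).add_record(record)
    return out


SUMMARY_COLUMNS = [
    "stratum", "tp", "fp", "fp_indel", "fn", "fn_wrong", "tn", "tp_trim",
    "fp_trim", "total_bases", "precision", "sensitivity", "gain", "f_score",
    "trim_percent", "trim_efficiency",
]

_METRIC_COLUMNS = SUMMARY_COLUMNS[10:]


def summarize(
    totals: Union[ConfusionTotals, Mapping[str, ConfusionTotals]],
    round_to: Optional[int] = 4,
) -> pd.DataFrame:
    """One row per stratum: the nine raw counts plus the six metrics.

    Metric columns are rounded to ``round_to`` decimals for tabular
    output (pass None for full precision; :func:`summary_json` always
    keeps full precision)."""
    if isinstance(totals, ConfusionTotals):
        totals = {"all": totals}
    rows = []
    for stratum in sorted(totals):
        t = totals[stratum]
        m = compute_metrics(t)
        rows.append(
            {
                "stratum": stratum,
                "tp": t.tp, "fp": t.fp, "fp_indel": t.fp_indel, "fn": t.fn,
                "fn_wrong": t.fn_wrong, "tn": t.tn, "tp_trim": t.tp_trim,
                "fp_trim": t.fp_trim, "total_bases": t.total_bases,
                "precision": m.precision, "sensitivity": m.sensitivity,
                "gain": m.gain, "f_score": m.f_score,
                "trim_percent": m.trim_percent,
                "trim_efficiency": m.trim_efficiency,
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if round_to is not None and len(df):
        df[_METRIC_COLUMNS] = df[_METRIC_COLUMNS].round(round_to)
    return df


def summary_json(
    totals: Union[ConfusionTotals, Mapping[str, ConfusionTotals]]
) -> dict:
    """Full-precision JSON-ready summary, keyed by stratum."""
    df = summarize(totals, round_to=None)
    return {
        row["stratum"]: {k: row[k] for k in SUMMARY_COLUMNS if k != "stratum"}
        for row in df.to_dict(orient="records")
    }


def write_summary(
    totals: Union[ConfusionTotals, Mapping[str, ConfusionTotals]],
    csv_path=None,
    json_path=None,
) -> pd.DataFrame:
    df = summarize(totals)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary_json(totals), fh, indent=2)
            fh.write("\n")
    return df
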