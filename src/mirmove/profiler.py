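"""Small-RNA read preprocessing and isomiR index statistics.

Two bespoke per-miRNA statistics are computed from collapsed small-RNA reads:

* the anchored tailing/trimming estimate — 18–26-nt reads whose 5' end starts
  exactly at the annotated 5' position are partitioned into exact matches,
  shorter (3'-trimmed) and longer (3'-tailed) reads, and the log2 ratios
  shorter/exact (trim index) and longer/exact (tail index) are formed;
* the isoform (alternative-processing) estimate — perfectly templated reads of
  length mature +/- 1 nested in the locus enlarged by +/- 5 nt are counted,
  the exact mature count is subtracted to give "other" reads, and the log2
  ratio exact/other (isoform index) is formed for miRNAs passing a
  >=5-reads-in-every-replicate-of-some-genotype filter.

Undefined ratios (zero numerator or denominator) are reported as missing
(NaN) and excluded from summaries; an optional +1 pseudo-count mode exists
but is off by default.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reference import MatureAnnotation, ReferenceBundle, to_dna

logger = logging.getLogger(__name__)

ANCHOR_MIN_LEN = 18
ANCHOR_MAX_LEN = 26
ISO_FLANK = 5
ISO_LEN_TOL = 1
DEFAULT_MAX_LOCI = 500
REPLICATE_MIN_READS = 5


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass
class ClipStats:
    n_input: int = 0
    n_kept: int = 0
    n_no_adapter: int = 0
    n_too_short: int = 0


def clip_adapter(read: str, adapter: str, min_len: int = 15) -> str | None:
    """Remove the 3' adapter; return the insert or ``None`` for a discard.

    The insert is everything preceding the first occurrence of the full
    adapter. If the full adapter is absent, the longest adapter prefix of
    >= 8 nt terminating the read also counts (a partially sequenced adapter).
    Reads with no adapter occurrence, or inserts shorter than ``min_len``,
    are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = to_dna(read)
    adapter = to_dna(adapter)
    idx = read.find(adapter)
    if idx < 0:
        for k in range(min(len(adapter) - 1, len(read)), 7, -1):
            if read.endswith(adapter[:k]):
                idx = len(read) - k
                break
    if idx < 0:
        return None
    insert = read[:idx]
    if len(insert) < min_len:
        return None
    return insert


def clip_adapters(
    reads: Iterable[str], adapter: str, min_len: int = 15
) -> tuple[list[str], ClipStats]:
    """Clip a batch of reads; discards are counted, not raised."""
    stats = ClipStats()
    kept: list[str] = []
    for read in reads:
        stats.n_input += 1
        if not adapter:
            raise ValueError("adapter must be non-empty")
        insert = clip_adapter(read, adapter, min_len=min_len)
        if insert is None:
            # distinguish the two discard causes for the report
            raw = to_dna(read)
            found = raw.find(to_dna(adapter)) >= 0 or any(
                raw.endswith(to_dna(adapter)[:k])
                for k in range(min(len(adapter) - 1, len(raw)), 7, -1)
            )
            if found:
                stats.n_too_short += 1
            else:
                stats.n_no_adapter += 1
        else:
            stats.n_kept += 1
            kept.append(insert)
    if stats.n_kept < stats.n_input:
        logger.info(
            "adapter clipping discarded %d/%d reads (%d no adapter, %d too short)",
            stats.n_input - stats.n_kept, stats.n_input,
            stats.n_no_adapter, stats.n_too_short,
        )
    return kept, stats


def collapse(reads: Iterable[str]) -> list[CollapsedRead]:
    """Group identical reads; deterministic order (descending count, then
    lexicographic)."""
    counts = Counter(to_dna(r) for r in reads)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# anchored tailing / trimming estimate
# ---------------------------------------------------------------------------

@dataclass
class AnchoredCounts:
    mirna_id: str
    sample_id: str
    n_mature: int = 0
    n_shorter: int = 0
    n_longer: int = 0
    n_anomalous: int = 0

    @property
    def total(self) -> int:
        return self.n_mature + self.n_shorter + self.n_longer + self.n_anomalous


def classify_anchored(
    read: str,
    annotation: MatureAnnotation,
    ref: ReferenceBundle,
    max_templated_mismatch: int = 0,
) -> str:
    """Classify a read against one annotation.

    Returns one of ``exact | shorter | longer | anomalous | unanchored``. A
    read is anchored when its length is 18–26 nt and its 5' end coincides with
    the annotation's biological 5' position on the annotated strand: the read
    is compared base-by-base with the genomic template starting at that
    position, and positions beyond the annotated 3' end (possible
    non-templated tail) never count as mismatches. Anchored reads are exact
    iff identical to the mature sequence, shorter/longer by length, and
    anomalous when same-length but non-identical (only reachable with a
    mismatch allowance > 0).
    """
    read = to_dna(read)
    L = len(read)
    if not ANCHOR_MIN_LEN <= L <= ANCHOR_MAX_LEN:
        return "unanchored"
    window = ref.anchored_window(annotation, L)
    # mismatches are only assessed within the templated (annotated) span
    span = min(L, len(window), annotation.length)
    mismatches = sum(1 for a, b in zip(read[:span], window[:span]) if a != b)
    if mismatches > max_templated_mismatch:
        return "unanchored"
    if read == annotation.mature_seq:
        return "exact"
    if L < annotation.length:
        return "shorter"
    if L > annotation.length:
        return "longer"
    return "anomalous"


def anchored_counts(
    collapsed_reads: Sequence[CollapsedRead],
    ref: ReferenceBundle,
    sample_id: str,
    max_templated_mismatch: int = 0,
    max_loci: int = DEFAULT_MAX_LOCI,
) -> list[AnchoredCounts]:
    """Partition collapsed reads into per-locus anchored count records.

    A read anchoring at k loci contributes its count to all k; reads anchoring
    at more than ``max_loci`` loci are dropped (multi-mapping cap).
    """
    ref.validate()
    records = {a.id: AnchoredCounts(a.id, sample_id) for a in ref.annotations}
    field = {"exact": "n_mature", "shorter": "n_shorter",
             "longer": "n_longer", "anomalous": "n_anomalous"}
    for cr in collapsed_reads:
        hits = []
        for ann in ref.annotations:
            cls = classify_anchored(cr.sequence, ann, ref, max_templated_mismatch)
            if cls != "unanchored":
                hits.append((ann.id, cls))
        if not hits or len(hits) > max_loci:
            continue
        for ann_id, cls in hits:
            rec = records[ann_id]
            setattr(rec, field[cls], getattr(rec, field[cls]) + cr.count)
    return [records[a.id] for a in ref.annotations]


@dataclass
class IndexRecord:
    """Per-(miRNA, sample) log2 index values; NaN marks an undefined ratio."""

    mirna_id: str
    sample_id: str
    trim_index: float = math.nan
    tail_index: float = math.nan
    iso_index: float = math.nan


def _log_ratio(num: int, den: int, pseudocount: bool) -> float:
    if pseudocount:
        return math.log2((num + 1) / (den + 1))
    if num <= 0 or den <= 0:
        return math.nan
    return math.log2(num / den)


def trim_tail_index(
    counts: AnchoredCounts, pseudocount: bool = False
) -> IndexRecord:
    """Trim index = log2(shorter/exact); tail index = log2(longer/exact).

    Either index is undefined (NaN) when its numerator or the exact count is
    zero, unless ``pseudocount`` adds +1 to both.
    """
    return IndexRecord(
        counts.mirna_id,
        counts.sample_id,
        trim_index=_log_ratio(counts.n_shorter, counts.n_mature, pseudocount),
        tail_index=_log_ratio(counts.n_longer, counts.n_mature, pseudocount),
    )


# ---------------------------------------------------------------------------
# isoform (alternative processing) estimate
# ---------------------------------------------------------------------------

@dataclass
class IsoformCounts:
    mirna_id: str
    sample_id: str
    n_qualifying: int = 0
    n_exact: int = 0

    @property
    def n_other(self) -> int:
        return self.n_qualifying - self.n_exact


def isoform_counts(
    collapsed_reads: Sequence[CollapsedRead],
    ref: ReferenceBundle,
    sample_id: str,
) -> list[IsoformCounts]:
    """Count perfectly templated reads nested in each locus +/- 5 nt.

    A read qualifies for a locus iff it matches the strand-oriented genomic
    sequence perfectly (no mismatches or gaps) at some position fully inside
    the enlarged window and its length is within +/- 1 nt of the mature
    length. Exact matches to the annotated mature are counted separately;
    the remainder ("other") captures mis- or alternative processing.
    """
    ref.validate()
    out = []
    for ann in ref.annotations:
        window = ref.nested_window(ann, flank=ISO_FLANK)
        rec = IsoformCounts(ann.id, sample_id)
        for cr in collapsed_reads:
            seq = to_dna(cr.sequence)
            if abs(len(seq) - ann.length) > ISO_LEN_TOL:
                continue
            if seq not in window:
                continue
            rec.n_qualifying += cr.count
            if seq == ann.mature_seq:
                rec.n_exact += cr.count
        out.append(rec)
    return out


def isoform_index(
    iso_counts_by_sample: Mapping[str, Sequence[IsoformCounts]],
    design: Mapping[str, str],
    min_reads: int = REPLICATE_MIN_READS,
    pseudocount: bool = False,
) -> list[IndexRecord]:
    """Isoform index = log2(exact/other) per retained (miRNA, sample).

    ``design`` maps sample_id -> genotype. A miRNA is retained iff for at
    least one genotype every one of its samples has >= ``min_reads``
    qualifying reads. Samples present in the counts but absent from the
    design raise ``KeyError``.
    """
    for sample_id in iso_counts_by_sample:
        if sample_id not in design:
            raise KeyError(f"sample {sample_id!r} missing from design")
    # qualifying counts per miRNA per sample
    by_mirna: dict[str, dict[str, IsoformCounts]] = {}
    for sample_id, recs in iso_counts_by_sample.items():
        for rec in recs:
            by_mirna.setdefault(rec.mirna_id, {})[sample_id] = rec
    genotypes: dict[str, list[str]] = {}
    for sample_id in iso_counts_by_sample:
        genotypes.setdefault(design[sample_id], []).append(sample_id)

    out: list[IndexRecord] = []
    for mirna_id, per_sample in by_mirna.items():
        retained = any(
            all(
                sample in per_sample and per_sample[sample].n_qualifying >= min_reads
                for sample in samples
            )
            for samples in genotypes.values()
        )
        if not retained:
            continue
        for sample_id, rec in per_sample.items():
            out.append(
                IndexRecord(
                    mirna_id,
                    sample_id,
                    iso_index=_log_ratio(rec.n_exact, rec.n_other, pseudocount),
                )
            )
    return out


# ---------------------------------------------------------------------------
# distribution summaries (boxplot statistics)
# ---------------------------------------------------------------------------

def summarize_distribution(values: Iterable[float]) -> dict[str, float | int]:
    """Boxplot-style summary of a set of index values.

    Missing (NaN) values are excluded and counted. Quartiles use linear
    interpolation; whiskers extend to the most extreme data points within
    1.5 * IQR of the quartiles.
    """
    arr = np.asarray(list(values), dtype=float)
    missing = int(np.isnan(arr).sum())
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {
            "median": math.nan, "q1": math.nan, "q3": math.nan,
            "whisker_low": math.nan, "whisker_high": math.nan,
            "n_defined": 0, "n_missing": missing,
        }
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_lo = arr[arr >= lo_bound]
    in_hi = arr[arr <= hi_bound]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()) if in_lo.size else float(arr.min()),
        "whisker_high": float(in_hi.max()) if in_hi.size else float(arr.max()),
        "n_defined": int(arr.size),
        "n_missing": missing,
    }
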