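"""Pair merging, insert extraction and per-population counting.

Mirrors the screen's original read handling: paired amplicon reads are
overlap-merged (fastq-join-style defaults: minimum overlap 6, maximum
mismatch fraction 0.08), the variable insert is the substring strictly
between exact matches of the fixed flanks GGCGAAATCTAGA and AGATCTACTTC
(reverse complement searched when the forward strand fails), and distinct
inserts are tallied per population.  Flank matching is exact by default —
sequencing errors in a flank simply drop the read — and counting is per
merged read with no deduplication.

Identical read pairs are collapsed before merging; this is purely a speed
optimisation and cannot change any count.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import revcomp
from .countmatrix import CountMatrix
from .simulate import FLANK3, FLANK5

__all__ = [
    "MergedRead", "ExtractionReport",
    "merge_pair", "extract_insert", "count_inserts",
    "process_read_pairs", "process_fastq_pair", "build_count_matrix",
]

DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_FRACTION = 0.08


@dataclass(frozen=True)
class MergedRead:
    seq: str
    qual: str
    overlap: int
    mismatches: int


def merge_pair(seq1: str, qual1: str, seq2: str, qual2: str,
               min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
               ) -> MergedRead | None:
    """Overlap-merge a read pair, or return None when no overlap qualifies.

    Mate 2 is reverse-complemented first.  Candidate overlaps of at least
    ``min_overlap`` nt are scored by mismatch fraction; the lowest fraction
    wins and ties go to the longest overlap.  At conflicting overlap
    positions the higher-quality base wins (mate 1 on quality ties) and the
    consensus quality is the max of the two.
    """
    if len(seq1) != len(qual1) or len(seq2) != len(qual2):
        raise ValueError("sequence/quality length mismatch")
    rseq2 = revcomp(seq2)
    rqual2 = qual2[::-1]
    best: tuple[float, int, int] | None = None  # (frac, -overlap, mismatches)
    for olap in range(min(len(seq1), len(rseq2)), min_overlap - 1, -1):
        limit = int(max_mismatch_fraction * olap)
        mm = 0
        for a, b in zip(seq1[len(seq1) - olap:], rseq2[:olap]):
            if a != b:
                mm += 1
                if mm > limit:
                    break
        else:
            frac = mm / olap
            if best is None or frac < best[0]:
                best = (frac, olap, mm)
                if mm == 0:  # nothing can strictly beat a perfect overlap
                    break
    if best is None:
        return None
    _, olap, mm = best
    head_len = len(seq1) - olap
    seq = [seq1[:head_len]]
    qual = [qual1[:head_len]]
    for i in range(olap):
        b1, q1 = seq1[head_len + i], qual1[head_len + i]
        b2, q2 = rseq2[i], rqual2[i]
        if b1 == b2:
            seq.append(b1)
        else:
            seq.append(b2 if q2 > q1 else b1)
        qual.append(max(q1, q2))
    seq.append(rseq2[olap:])
    qual.append(rqual2[olap:])
    return MergedRead("".join(seq), "".join(qual), olap, mm)


def extract_insert(merged: str, flank5: str = FLANK5,
                   flank3: str = FLANK3) -> str | None:
    """Substring strictly between the first flank5 and the next flank3.

    Searches the forward strand first, then the reverse complement; returns
    None when no flank pair is found on either strand.  Adjacent flanks give
    the empty string (a zero-length insert, kept in raw counts).
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    for seq in (merged, revcomp(merged)):
        i = seq.find(flank5)
        if i >= 0:
            j = seq.find(flank3, i + len(flank5))
            if j >= 0:
                return seq[i + len(flank5):j]
    return None


@dataclass
class ExtractionReport:
    """Per-population accounting of where reads were lost."""

    population: str
    reads: int = 0
    merged: int = 0
    flank5_missing: int = 0
    flank3_missing: int = 0
    n_dropped: int = 0
    extracted: int = 0
    non_target_length: int = 0

    def as_dict(self) -> dict:
        return vars(self).copy()


def process_read_pairs(pairs, population: str,
                       flank5: str = FLANK5, flank3: str = FLANK3,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
                       ) -> tuple[Counter, ExtractionReport]:
    """Merge + extract an iterable of (seq1, qual1, seq2, qual2) tuples.

    Returns raw insert counts (all lengths, N-free) and the loss accounting.
    Identical pairs are collapsed and processed once.
    """
    report = ExtractionReport(population)
    unique: Counter = Counter()
    for pair in pairs:
        unique[tuple(pair)] += 1
        report.reads += 1
    inserts: Counter = Counter()
    for (s1, q1, s2, q2), n in unique.items():
        merged = merge_pair(s1, q1, s2, q2, min_overlap, max_mismatch_fraction)
        if merged is None:
            continue
        report.merged += n
        insert = extract_insert(merged.seq, flank5, flank3)
        if insert is None:
            # distinguish which flank failed, on the better strand
            fwd5 = merged.seq.find(flank5)
            rev5 = revcomp(merged.seq).find(flank5)
            if fwd5 < 0 and rev5 < 0:
                report.flank5_missing += n
            else:
                report.flank3_missing += n
            continue
        if "N" in insert:
            report.n_dropped += n
            continue
        report.extracted += n
        inserts[insert] += n
    return inserts, report


def _open_text(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def _pair_stream(r1_path, r2_path):
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield s1.upper(), q1, s2.upper(), q2


def process_fastq_pair(r1_path, r2_path, population: str,
                       **kwargs) -> tuple[Counter, ExtractionReport]:
    """Merge + extract one population's FASTQ pair (plain or gzip)."""
    return process_read_pairs(_pair_stream(r1_path, r2_path), population,
                              **kwargs)


def count_inserts(counters: dict[str, Counter], populations: pd.DataFrame,
                  length_filter: int | None = None,
                  metadata: dict | None = None,
                  ) -> tuple[CountMatrix, CountMatrix | None]:
    """Assemble per-population insert counters into count matrices.

    Returns ``(raw, filtered)`` where *raw* keeps every insert length and
    *filtered* applies the exact-length filter (None when no filter is set).
    Both tables are zero-filled for inserts absent from a population.
    """
    labels = list(populations["population"])
    if set(counters) != set(labels):
        raise ValueError("counters do not match the population table")
    all_inserts = sorted(set().union(*[c.keys() for c in counters.values()]))
    counts = pd.DataFrame(
        {lab: [counters[lab].get(s, 0) for s in all_inserts] for lab in labels},
        index=pd.Index(all_inserts, name="insert"), dtype="int64")
    meta = dict(metadata or {})
    raw = CountMatrix(counts, populations.copy(), meta)
    filtered = raw.filter_length(length_filter) if length_filter else None
    return raw, filtered


def build_count_matrix(samples: pd.DataFrame, length_filter: int | None = 11,
                       flank5: str = FLANK5, flank3: str = FLANK3,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
                       ) -> tuple[CountMatrix, CountMatrix | None, pd.DataFrame]:
    """FASTQ sample sheet → (raw counts, length-filtered counts, report).

    ``samples`` needs columns population/condition/replicate/r1/r2.  The
    report has one row per population with read-loss accounting, including
    how many extracted inserts were off the target length.
    """
    counters = {}
    reports = []
    for _, row in samples.iterrows():
        counter, report = process_fastq_pair(
            row["r1"], row["r2"], row["population"],
            flank5=flank5, flank3=flank3, min_overlap=min_overlap,
            max_mismatch_fraction=max_mismatch_fraction)
        if length_filter:
            report.non_target_length = sum(
                n for s, n in counter.items() if len(s) != length_filter)
        counters[row["population"]] = counter
        reports.append(report.as_dict())
    pops = samples[["population", "condition", "replicate"]].reset_index(drop=True)
    raw, filtered = count_inserts(
        counters, pops, length_filter,
        metadata={"flank5": flank5, "flank3": flank3,
                  "length_filter": length_filter})
    return raw, filtered, pd.DataFrame(reports)
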