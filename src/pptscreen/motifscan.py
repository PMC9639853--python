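"""Consensus/motif scanning in genomes and upstream of splice acceptors.

The screen's anomalous "G, no PPT" consensus (CCCAGUGUGGC) was looked for in
a reference genome and in the 50 nt immediately upstream of mapped
trans-splice acceptor sites.  "Related sequences" is operationalised as a
Hamming-neighbourhood search (substitutions only, configurable radius).

Coordinates are 0-based, half-open throughout.  An acceptor site stores the
0-based coordinate of the G of the AG dinucleotide; the upstream window is
the ``width`` bases ending immediately before the A (reverse-complemented
mirror for minus-strand sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import check_dna, revcomp
from .features import MIN_PPT_RUN, pyr_run_start

__all__ = [
    "AcceptorSite", "MotifHit", "WindowRecord",
    "load_fasta", "read_sites_bed", "upstream_windows",
    "find_matches", "cooccurrence_with_ppt", "hits_to_bed",
]


@dataclass(frozen=True)
class AcceptorSite:
    """A trans-splice acceptor: position is the 0-based G of the AG."""

    contig: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    """One (mismatched) motif occurrence; [start, end) in + coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched: str  # strand-oriented sequence at the hit


@dataclass(frozen=True)
class WindowRecord:
    """Upstream window sequence for one acceptor site."""

    site: AcceptorSite
    seq: str
    truncated: bool

    @property
    def name(self) -> str:
        return f"{self.site.contig}:{self.site.position}:{self.site.strand}"


def load_fasta(path) -> dict[str, str]:
    """Contig name → uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_sites_bed(path) -> list[AcceptorSite]:
    """BED intervals marking the AG dinucleotide → acceptor sites.

    For + strand sites the G is the last base of the interval (end-1); for
    - strand sites the AG read on the minus strand ends at the interval
    start, so the G is at ``start``.  A missing strand column means +.
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    sites = []
    for row in bed.itertuples(index=False):
        contig, start, end = str(row[0]), int(row[1]), int(row[2])
        strand = str(row[5]) if len(row) > 5 else "+"
        g = end - 1 if strand == "+" else start
        sites.append(AcceptorSite(contig, g, strand))
    return sites


def upstream_windows(sites, genome: dict[str, str],
                     width: int = 50) -> list[WindowRecord]:
    """The ``width`` bases 5' of each acceptor's A, strand-aware.

    Windows truncated by a contig edge are returned short and flagged.
    """
    out = []
    for site in sites:
        if site.contig not in genome:
            raise KeyError(f"contig {site.contig!r} not in genome FASTA")
        seq = genome[site.contig]
        if not 0 <= site.position < len(seq):
            raise ValueError(f"site {site} outside contig bounds")
        if site.strand == "+":
            end = site.position - 1  # immediately before the A of AG
            start = max(0, end - width)
            window = seq[max(0, start):max(0, end)]
        else:
            start = site.position + 2
            end = min(len(seq), start + width)
            window = revcomp(seq[start:end])
        out.append(WindowRecord(site, window, truncated=len(window) < width))
    return out


_ENC = np.full(256, 0, dtype=np.uint8)
for _b in b"ACGT":
    _ENC[_b] = _b


def _scan_one(seq: str, query: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every window within Hamming distance."""
    m = len(query)
    if len(seq) < m:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = sliding_window_view(arr, m)
    mm = (windows != q).sum(axis=1)
    idx = np.nonzero(mm <= max_mismatches)[0]
    return [(int(i), int(mm[i])) for i in idx]


def find_matches(targets, query: str, max_mismatches: int = 0,
                 both_strands: bool = True) -> list[MotifHit]:
    """All substitution-only matches of ``query`` in the target sequences.

    ``targets`` is a dict name→sequence (e.g. a genome or a window set), a
    single string, or an iterable of (name, sequence) pairs.  Minus-strand
    hits are reported in + coordinates with the strand-oriented matched
    sequence.  Positions containing N never match.
    """
    query = check_dna(query, allow_empty=False, what="query")
    if max_mismatches >= len(query):
        raise ValueError("max_mismatches must be < query length")
    if isinstance(targets, str):
        targets = {"seq": targets}
    elif not isinstance(targets, dict):
        targets = dict(targets)
    hits = []
    rquery = revcomp(query)
    for name, seq in targets.items():
        seq = seq.upper()
        for start, mm in _scan_one(seq, query, max_mismatches):
            hits.append(MotifHit(name, start, start + len(query), "+", mm,
                                 seq[start:start + len(query)]))
        if both_strands:
            for start, mm in _scan_one(seq, rquery, max_mismatches):
                hits.append(MotifHit(name, start, start + len(query), "-", mm,
                                     revcomp(seq[start:start + len(query)])))
    return hits


def cooccurrence_with_ppt(windows, hits, min_run: int = MIN_PPT_RUN,
                          ) -> pd.DataFrame:
    """Per window with >=1 motif hit: does a PPT co-occur, and in what order?

    ``windows`` maps window name → sequence (or is a list of
    :class:`WindowRecord`).  For each hit-bearing window the report gives the
    leftmost maximal pyrimidine run (if >= ``min_run``) and whether every
    motif hit lies 5' of that run's start.
    """
    if not isinstance(windows, dict):
        windows = {w.name: w.seq for w in windows}
    by_window: dict[str, list[MotifHit]] = {}
    for hit in hits:
        by_window.setdefault(hit.contig, []).append(hit)
    rows = []
    for name, whits in by_window.items():
        seq = windows[name]
        run, start = pyr_run_start(seq)
        has_ppt = run >= min_run
        upstream = None
        if has_ppt:
            upstream = all(h.start < start for h in whits)
        rows.append({
            "window": name,
            "n_hits": len(whits),
            "hit_starts": ",".join(str(h.start) for h in whits),
            "has_ppt": has_ppt,
            "ppt_start": start if has_ppt else None,
            "ppt_len": run if has_ppt else 0,
            "motif_upstream_of_ppt": upstream,
        })
    return pd.DataFrame(rows)


def hits_to_bed(hits) -> pd.DataFrame:
    """BED-compatible table: mismatch count in the score column."""
    return pd.DataFrame([
        {"chrom": h.contig, "start": h.start, "end": h.end,
         "name": h.matched, "score": h.mismatches, "strand": h.strand}
        for h in hits])
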