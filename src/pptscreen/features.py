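"""Pyrimidine-tract features, base compositions, frequency matrices and consensus.

The screen asks, for every selected 11-mer insert, whether it looks like a
polypyrimidine tract (PPT): a contiguous run of C/U upstream of the AG splice
acceptor.  This module computes the per-insert features used to stratify the
selected sets (longest pyrimidine run, base counts, the "G, no PPT" class),
and the position-wise statistics behind sequence logos: weighted position
frequency matrices, per-position information content in bits, and plurality
consensus strings.

Conventions
-----------
* Inputs accept T and U interchangeably; DNA (T) is canonical internally and
  RNA (U) is used for display (consensus strings, composition keys).
* A "PPT" is a maximal uninterrupted run of {C,T}; mixed C/U runs count the
  same as pure U runs.
* When several maximal runs tie for longest, the leftmost one is reported,
  so the run-start distribution reflects 5'-end concentration.
* Information content is ``2 + sum_b f_b log2 f_b`` with ``0·log 0 = 0`` and
  no small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import PYRIMIDINES, RNA_BASES, check_dna, to_rna

__all__ = [
    "FeatureRecord",
    "PositionFrequencyMatrix",
    "ConsensusResult",
    "longest_pyrimidine_run",
    "classify",
    "feature_table",
    "base_composition",
    "build_pfm",
    "consensus",
    "ppt_start_distribution",
    "plot_logo",
]

#: Default minimum run length for calling a PPT ("six contiguous pyrimidines").
MIN_PPT_RUN = 6


def _maximal_pyr_runs(seq: str) -> list[tuple[int, int]]:
    """All maximal pyrimidine runs as (start, length), left to right."""
    runs = []
    start = None
    for i, base in enumerate(seq):
        if base in PYRIMIDINES:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(seq) - start))
    return runs


def longest_pyrimidine_run(seq: str) -> int:
    """Length of the longest uninterrupted run of C/T (C/U) in ``seq``.

    Returns 0 for pyrimidine-free (or empty) sequences.
    """
    dna = check_dna(seq)
    runs = _maximal_pyr_runs(dna)
    return max((length for _, length in runs), default=0)


def pyr_run_start(seq: str) -> tuple[int, int | None]:
    """(longest run length, 0-based start of the leftmost longest run)."""
    dna = check_dna(seq)
    runs = _maximal_pyr_runs(dna)
    if not runs:
        return 0, None
    best = max(length for _, length in runs)
    start = next(s for s, length in runs if length == best)
    return best, start


@dataclass(frozen=True)
class FeatureRecord:
    """Per-insert pyrimidine-tract features.

    ``ppt6`` is True when the insert carries a PPT of at least
    :data:`MIN_PPT_RUN` contiguous pyrimidines; ``g_no_ppt`` marks the
    anomalous selected class (at least one G and no such PPT).
    """

    insert: str
    longest_pyr_run: int
    ppt_start: int | None
    pyr_count: int
    u_count: int
    c_count: int
    g_count: int
    a_count: int
    ppt6: bool
    g_no_ppt: bool


def classify(insert: str, min_ppt_run: int = MIN_PPT_RUN) -> FeatureRecord:
    """Compute all features for one insert (empty string allowed)."""
    dna = check_dna(insert, what="insert")
    run, start = pyr_run_start(dna)
    u = dna.count("T")
    c = dna.count("C")
    ppt = run >= min_ppt_run
    return FeatureRecord(
        insert=dna,
        longest_pyr_run=run,
        ppt_start=start,
        pyr_count=u + c,
        u_count=u,
        c_count=c,
        g_count=dna.count("G"),
        a_count=dna.count("A"),
        ppt6=ppt,
        g_no_ppt=(dna.count("G") >= 1 and not ppt),
    )


def feature_table(inserts, min_ppt_run: int = MIN_PPT_RUN) -> pd.DataFrame:
    """Feature records for many inserts as a DataFrame indexed by insert."""
    records = [classify(s, min_ppt_run) for s in inserts]
    df = pd.DataFrame([vars(r) for r in records]).set_index("insert")
    df["ppt_start"] = df["ppt_start"].astype("Int64")
    return df


def _as_weights(sequences: list[str], weights) -> np.ndarray:
    if weights is None:
        w = np.ones(len(sequences))
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(sequences):
            raise ValueError("weights and sequences differ in cardinality")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    if len(sequences) == 0:
        raise ValueError("no sequences given")
    if w.sum() == 0:
        raise ValueError("all weights are zero")
    return w


def _encoded(sequences) -> tuple[list[str], np.ndarray]:
    seqs = [check_dna(s, allow_empty=False) for s in sequences]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    # rows: sequences, cols: positions, values: base index into ACGT
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    mat = lut[np.frombuffer("".join(seqs).encode(), dtype=np.uint8)]
    return seqs, mat.reshape(len(seqs), length)


def base_composition(sequences, weights=None) -> dict[str, float]:
    """Overall A/C/G/U fractions, optionally weighting each sequence.

    Weighted mode multiplies each sequence's base counts by its weight before
    pooling — the screen's "multiplied by the enrichment factor" composition.
    Equal weights reproduce the unweighted composition exactly.
    """
    seqs, mat = _encoded(sequences)
    w = _as_weights(seqs, weights)
    counts = np.zeros(4)
    for b in range(4):
        counts[b] = ((mat == b).sum(axis=1) * w).sum()
    frac = counts / counts.sum()
    return dict(zip(RNA_BASES, frac))


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies (columns A, C, G, U) with IC in bits.

    ``n_eff`` is the total (possibly weighted) sequence mass behind each
    column.  ``freqs`` rows sum to 1.
    """

    freqs: np.ndarray  # shape (length, 4)
    n_eff: float

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def ic(self) -> np.ndarray:
        """Information content per position: 2 + sum f log2 f, in bits."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(RNA_BASES))
        df.insert(0, "position", np.arange(self.length))
        df["ic"] = self.ic
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PositionFrequencyMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(freqs=df[list(RNA_BASES)].to_numpy(), n_eff=float("nan"))


def build_pfm(sequences, weights=None) -> PositionFrequencyMatrix:
    """Weighted position frequency matrix over equal-length sequences."""
    seqs, mat = _encoded(sequences)
    w = _as_weights(seqs, weights)
    length = mat.shape[1]
    counts = np.zeros((length, 4))
    for b in range(4):
        counts[:, b] = ((mat == b) * w[:, None]).sum(axis=0)
    total = counts.sum(axis=1, keepdims=True)
    return PositionFrequencyMatrix(freqs=counts / total, n_eff=float(w.sum()))


@dataclass(frozen=True)
class ConsensusResult:
    """Plurality consensus in RNA display, with per-position tie flags."""

    sequence: str
    ties: tuple[bool, ...]


def consensus(pfm: PositionFrequencyMatrix) -> ConsensusResult:
    """Highest-fraction base per position; ties broken A<C<G<U and flagged."""
    best = pfm.freqs.argmax(axis=1)  # argmax returns the first (A<C<G<U) max
    tie = (pfm.freqs == pfm.freqs.max(axis=1, keepdims=True)).sum(axis=1) > 1
    seq = "".join(RNA_BASES[b] for b in best)
    return ConsensusResult(sequence=seq, ties=tuple(bool(t) for t in tie))


def ppt_start_distribution(inserts, min_run: int = MIN_PPT_RUN,
                           length: int | None = None) -> np.ndarray:
    """Histogram of leftmost-maximal-run start positions over PPT inserts.

    Only inserts whose longest pyrimidine run is at least ``min_run`` are
    counted.  Returns counts indexed by 0-based start position.
    """
    records = [classify(s, min_run) for s in inserts]
    if length is None:
        length = max((len(r.insert) for r in records), default=0)
    hist = np.zeros(length, dtype=int)
    for r in records:
        if r.ppt6 and r.ppt_start is not None:
            hist[r.ppt_start] += 1
    return hist


def plot_logo(pfm: PositionFrequencyMatrix, path, title: str = "") -> None:
    """Render an information-content logo (letters scaled to f·IC bits).

    Isolated from the math: nothing else depends on matplotlib state.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "U": "#e31a1c"}
    ic = pfm.ic
    fig, ax = plt.subplots(figsize=(max(4, pfm.length * 0.5), 3))
    for pos in range(pfm.length):
        stack = sorted(zip(RNA_BASES, pfm.freqs[pos]), key=lambda kv: kv[1])
        y = 0.0
        for base, frac in stack:
            h = frac * ic[pos]
            if h <= 0:
                continue
            ax.text(pos + 0.5, y + h / 2, base, ha="center", va="center",
                    fontsize=14, fontweight="bold", color=colors[base],
                    stretch="expanded")
            y += h
        ax.bar(pos + 0.5, ic[pos], width=0.9, color="none",
               edgecolor="0.85", linewidth=0.5)
    ax.set_xlim(0, pfm.length)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(pfm.length) + 0.5,
                  [str(i + 1) for i in range(pfm.length)])
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
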