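"""The inserts × populations read-count container used by every stage.

A screen has one starting ("initial") population and replicated populations
grown under two puromycin stringencies, labelled with the abstract conditions
``sel_1x`` and ``sel_5x``.  Counts are raw merged-read tallies per distinct
insert; normalisation lives in :mod:`pptscreen.enrichment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("initial", "sel_1x", "sel_5x")


@dataclass
class CountMatrix:
    """Integer read counts, inserts × populations, with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by insert sequence, one column per population
        label, non-negative integers.
    populations
        DataFrame with columns ``population``, ``condition``, ``replicate``;
        one row per counts column, in the same order.
    metadata
        Free-form provenance (flank sequences, length filter, import report).
    """

    counts: pd.DataFrame
    populations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = self.populations
        required = {"population", "condition", "replicate"}
        if not required.issubset(pops.columns):
            raise ValueError(f"populations table needs columns {sorted(required)}")
        labels = list(pops["population"])
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        if list(self.counts.columns) != labels:
            raise ValueError("counts columns do not match populations table")
        bad = set(pops["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s) {sorted(bad)}")
        if (pops["condition"] == "initial").sum() != 1:
            raise ValueError("exactly one 'initial' population is required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "insert"
        self.counts.columns.name = None

    # -- accessors ---------------------------------------------------------

    @property
    def initial_column(self) -> str:
        mask = self.populations["condition"] == "initial"
        return str(self.populations.loc[mask, "population"].iloc[0])

    def columns_for(self, condition: str) -> list[str]:
        mask = self.populations["condition"] == condition
        return list(self.populations.loc[mask, "population"])

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # -- transforms --------------------------------------------------------

    def filter_length(self, length: int) -> "CountMatrix":
        """Keep only inserts of exactly ``length`` nt (the 11-mer filter)."""
        keep = self.counts.index.str.len() == length
        meta = dict(self.metadata, length_filter=length)
        return CountMatrix(self.counts.loc[keep].copy(),
                           self.populations.copy(), meta)

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """One-file TSV: '#'-prefixed condition/replicate header, then counts."""
        with open(path, "w") as fh:
            fh.write("#condition\t" + "\t".join(self.populations["condition"]) + "\n")
            fh.write("#replicate\t"
                     + "\t".join(str(r) for r in self.populations["replicate"]) + "\n")
            self.counts.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        header: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *values = line[1:].rstrip("\n").split("\t")
                header[key] = values
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            counts = pd.read_csv(fh, sep="\t", index_col="insert",
                                 keep_default_na=False)
        if "condition" not in header:
            raise ValueError(f"{path}: missing '#condition' header line")
        pops = pd.DataFrame({
            "population": list(counts.columns),
            "condition": header["condition"],
            "replicate": [int(r) for r in header.get(
                "replicate", ["0"] * len(counts.columns))],
        })
        return cls(counts, pops)


def make_populations(n_replicates: int = 3) -> pd.DataFrame:
    """Standard population table: initial + n replicates per condition."""
    rows = [("initial", "initial", 0)]
    for cond, tag in (("sel_1x", "1x"), ("sel_5x", "5x")):
        for i in range(1, n_replicates + 1):
            rows.append((f"{tag}_r{i}", cond, i))
    return pd.DataFrame(rows, columns=["population", "condition", "replicate"])
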