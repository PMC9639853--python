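"""RPM normalisation, depletion/enrichment scores, and selected sets.

The screen's statistics are threshold rules, not hypothesis tests.  Counts
are normalised to reads per million (RPM) per population; then, with a +1
RPM pseudocount guaranteeing finite ratios,

* depletion  = rpm_initial / (median RPM over condition replicates + 1)
* enrichment = median RPM over condition replicates / (rpm_initial + 1)

The depleted set requires at least ``min_initial_reads`` raw starting reads
and at least ``fold_threshold``-fold depletion under *both* puromycin
stringencies.  Enriched sets are per condition; the intersection set
additionally requires the 5x median RPM to be at least the 1x median RPM
("at least as abundant" at the higher stringency).  The initial-read gate is
off for enrichment by default — sequences absent from the starting sample
were genuinely observed to enrich — with a config switch to apply it.
All comparisons are ``>=`` ("at least") at full floating precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

__all__ = [
    "ScreenConfig", "rpm_normalize", "depletion_score", "enrichment_score",
    "score_screen", "select_depleted", "select_enriched", "stronger_at_5x",
    "summarize_sets",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Threshold rules of the screen, defaulting to the study's values."""

    min_initial_reads: int = 10
    fold_threshold: float = 5.0
    ordering_rule_5x_ge_1x: bool = True
    pseudocount: float = 1.0
    apply_initial_filter_to_enriched: bool = False
    stronger_factor: float = 2.0
    stronger_universe: str = "either"  # either | both | all

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.stronger_universe not in ("either", "both", "all"):
            raise ValueError("stronger_universe must be either|both|all")


def rpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads-per-million matrix: count · 10^6 / column sum."""
    sums = cm.column_sums()
    empty = sums[sums == 0]
    if len(empty):
        raise ValueError(f"population(s) with zero reads: {list(empty.index)}")
    return cm.counts * 1e6 / sums


def depletion_score(rpm_initial, replicate_rpms, pseudocount: float = 1.0):
    """rpm_initial / (median over replicates + pseudocount); vectorised."""
    med = np.median(np.asarray(replicate_rpms, dtype=float), axis=-1)
    return np.asarray(rpm_initial, dtype=float) / (med + pseudocount)


def enrichment_score(rpm_initial, replicate_rpms, pseudocount: float = 1.0):
    """median over replicates / (rpm_initial + pseudocount); vectorised."""
    med = np.median(np.asarray(replicate_rpms, dtype=float), axis=-1)
    return med / (np.asarray(rpm_initial, dtype=float) + pseudocount)


def score_screen(cm: CountMatrix,
                 config: ScreenConfig | None = None) -> pd.DataFrame:
    """Per-insert score table with all ratios and selection flags.

    Columns: raw_initial, rpm_initial, median_rpm_1x, median_rpm_5x,
    depletion_1x/5x, enrichment_1x/5x and the boolean flags depleted_both,
    enriched_1x, enriched_5x, enriched_both_ordered, stronger_at_5x.
    Medians are taken over however many replicates exist (midpoint mean for
    even counts).
    """
    cfg = config or ScreenConfig()
    rpm = rpm_normalize(cm)
    init = cm.initial_column
    rec = pd.DataFrame(index=cm.counts.index.copy())
    rec["raw_initial"] = cm.counts[init]
    rec["rpm_initial"] = rpm[init]
    for cond, tag in (("sel_1x", "1x"), ("sel_5x", "5x")):
        cols = cm.columns_for(cond)
        if not cols:
            raise ValueError(f"no populations for condition {cond}")
        med = rpm[cols].median(axis=1)
        rec[f"median_rpm_{tag}"] = med
        rec[f"depletion_{tag}"] = rec["rpm_initial"] / (med + cfg.pseudocount)
        rec[f"enrichment_{tag}"] = med / (rec["rpm_initial"] + cfg.pseudocount)

    thr = cfg.fold_threshold
    rec["depleted_both"] = (
        (rec["raw_initial"] >= cfg.min_initial_reads)
        & (rec["depletion_1x"] >= thr) & (rec["depletion_5x"] >= thr))
    gate = (rec["raw_initial"] >= cfg.min_initial_reads) \
        if cfg.apply_initial_filter_to_enriched else True
    rec["enriched_1x"] = (rec["enrichment_1x"] >= thr) & gate
    rec["enriched_5x"] = (rec["enrichment_5x"] >= thr) & gate
    ordered = (rec["median_rpm_5x"] >= rec["median_rpm_1x"]) \
        if cfg.ordering_rule_5x_ge_1x else True
    rec["enriched_both_ordered"] = rec["enriched_1x"] & rec["enriched_5x"] & ordered
    universe = {
        "either": rec["enriched_1x"] | rec["enriched_5x"],
        "both": rec["enriched_1x"] & rec["enriched_5x"],
        "all": pd.Series(True, index=rec.index),
    }[cfg.stronger_universe]
    rec["stronger_at_5x"] = (
        (rec["enrichment_5x"] >= cfg.stronger_factor * rec["enrichment_1x"])
        & universe)
    return rec


def _inserts(records: pd.DataFrame, mask: pd.Series) -> list[str]:
    return list(records.index[mask])


def select_depleted(records: pd.DataFrame,
                    config: ScreenConfig | None = None) -> list[str]:
    """Inserts depleted >= fold under both conditions with enough start reads."""
    cfg = config or ScreenConfig()
    mask = ((records["raw_initial"] >= cfg.min_initial_reads)
            & (records["depletion_1x"] >= cfg.fold_threshold)
            & (records["depletion_5x"] >= cfg.fold_threshold))
    return _inserts(records, mask)


def select_enriched(records: pd.DataFrame,
                    config: ScreenConfig | None = None) -> dict[str, list[str]]:
    """Per-condition enriched sets and the ordered intersection set."""
    cfg = config or ScreenConfig()
    gate = (records["raw_initial"] >= cfg.min_initial_reads) \
        if cfg.apply_initial_filter_to_enriched else True
    e1 = (records["enrichment_1x"] >= cfg.fold_threshold) & gate
    e5 = (records["enrichment_5x"] >= cfg.fold_threshold) & gate
    ordered = (records["median_rpm_5x"] >= records["median_rpm_1x"]) \
        if cfg.ordering_rule_5x_ge_1x else True
    return {"1x": _inserts(records, e1),
            "5x": _inserts(records, e5),
            "both": _inserts(records, e1 & e5 & ordered)}


def stronger_at_5x(records: pd.DataFrame, factor: float = 2.0,
                   config: ScreenConfig | None = None) -> list[str]:
    """Inserts whose 5x enrichment is >= factor × their 1x enrichment."""
    cfg = config or ScreenConfig()
    sets = select_enriched(records, cfg)
    universe = {
        "either": set(sets["1x"]) | set(sets["5x"]),
        "both": set(sets["1x"]) & set(sets["5x"]),
        "all": set(records.index),
    }[cfg.stronger_universe]
    mask = (records["enrichment_5x"] >= factor * records["enrichment_1x"]) \
        & records.index.isin(universe)
    return _inserts(records, mask)


def summarize_sets(records: pd.DataFrame,
                   config: ScreenConfig | None = None) -> dict:
    """Headline counts of every selected set."""
    cfg = config or ScreenConfig()
    enriched = select_enriched(records, cfg)
    return {
        "n_inserts": int(len(records)),
        "n_depleted": len(select_depleted(records, cfg)),
        "n_enriched_1x": len(enriched["1x"]),
        "n_enriched_5x": len(enriched["5x"]),
        "n_enriched_both": len(enriched["both"]),
        "n_stronger_at_5x": len(stronger_at_5x(records, cfg.stronger_factor, cfg)),
    }
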