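"""End-to-end orchestration: config, stages, report bundle, run manifest.

Two entry points mirror how screen data arrives: raw paired FASTQ per
population (``samples`` mode) or an already-tabulated per-insert count table
(``count_table`` mode, the shape of the study's supplementary screen table).
Both converge on the same scoring/classification stages, so an error-free
simulation gives identical summaries through either path.

Every threshold (10 starting reads, 5-fold, 6-nt PPT, +1 pseudocount, 50-nt
scan window) is a named config key defaulting to the study's value.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .countmatrix import CountMatrix
from .enrichment import (ScreenConfig, score_screen, select_depleted,
                         select_enriched, stronger_at_5x, summarize_sets)
from .features import (MIN_PPT_RUN, base_composition, build_pfm, consensus,
                       feature_table, ppt_start_distribution)
from .readproc import (DEFAULT_MAX_MISMATCH_FRACTION, DEFAULT_MIN_OVERLAP,
                       build_count_matrix)
from .simulate import FLANK3, FLANK5

log = logging.getLogger("pptscreen")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "flank5": FLANK5,
    "flank3": FLANK3,
    "insert_length": 11,
    "merge": {
        "min_overlap": DEFAULT_MIN_OVERLAP,
        "max_mismatch_fraction": DEFAULT_MAX_MISMATCH_FRACTION,
    },
    "screen": {
        "min_initial_reads": 10,
        "fold_threshold": 5.0,
        "pseudocount": 1.0,
        "ordering_rule_5x_ge_1x": True,
        "apply_initial_filter_to_enriched": False,
        "stronger_factor": 2.0,
        "stronger_universe": "either",
    },
    "features": {"min_ppt_run": MIN_PPT_RUN},
    "scan": {"window": 50, "max_mismatches": 1},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by a YAML file, overlaid by explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def screen_config(cfg: dict) -> ScreenConfig:
    return ScreenConfig(**cfg["screen"])


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def import_supplementary_table(path, mapping: dict,
                               sheet=None) -> CountMatrix:
    """Load a published per-insert count spreadsheet/TSV as a CountMatrix.

    ``mapping`` names the columns: ``{"insert": col, "initial": col,
    "sel_1x": [cols...], "sel_5x": [cols...]}``.  Rows with non-ACGT inserts
    are dropped and logged; duplicate inserts are summed with a warning.
    Unmapped columns are reported in the matrix metadata.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet or 0)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for key in ("insert", "initial", "sel_1x", "sel_5x"):
        if key not in mapping:
            raise ValueError(f"mapping lacks required key {key!r}")
    needed = [mapping["insert"], mapping["initial"],
              *mapping["sel_1x"], *mapping["sel_5x"]]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing column(s) {missing}; table has {list(df.columns)}")
    unmapped = [c for c in df.columns if c not in needed]

    inserts = df[mapping["insert"]].astype(str).str.upper().str.replace("U", "T")
    valid = inserts.str.fullmatch("[ACGT]*").fillna(False) & (inserts != "")
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("dropping %d row(s) with non-ACGT inserts", n_bad)
    counts = df.loc[valid, needed[1:]].apply(pd.to_numeric)
    counts.index = pd.Index(inserts[valid], name="insert")
    if counts.index.has_duplicates:
        log.warning("summing %d duplicate insert row(s)",
                    int(counts.index.duplicated().sum()))
        counts = counts.groupby(level=0).sum()

    pops, conditions, replicates = [], [], []
    rename = {}
    for col, cond, rep in (
            [(mapping["initial"], "initial", 0)]
            + [(c, "sel_1x", i + 1) for i, c in enumerate(mapping["sel_1x"])]
            + [(c, "sel_5x", i + 1) for i, c in enumerate(mapping["sel_5x"])]):
        label = str(col)
        rename[col] = label
        pops.append(label)
        conditions.append(cond)
        replicates.append(rep)
    counts = counts.rename(columns=rename)[pops]
    populations = pd.DataFrame({"population": pops, "condition": conditions,
                                "replicate": replicates})
    return CountMatrix(counts, populations,
                       {"source": path, "unmapped_columns": unmapped,
                        "dropped_rows": n_bad})


def _write_set(path: Path, inserts) -> None:
    path.write_text("".join(f"{s}\n" for s in inserts))


def _set_analysis(inserts, records, min_ppt_run: int,
                  weight_col: str) -> dict:
    """Compositions (unweighted + enrichment-weighted) and feature counts."""
    if not inserts:
        return {"n": 0}
    feats = feature_table(inserts, min_ppt_run)
    weights = records.loc[inserts, weight_col]
    pfm = build_pfm(inserts)
    return {
        "n": len(inserts),
        "composition_unweighted": base_composition(inserts),
        "composition_weighted": base_composition(inserts, weights),
        "weight_column": weight_col,
        "n_ppt6": int(feats["ppt6"].sum()),
        "n_pyr_ge9": int((feats["pyr_count"] >= 9).sum()),
        "n_pyr_ge10": int((feats["pyr_count"] >= 10).sum()),
        "n_g_no_ppt": int(feats["g_no_ppt"].sum()),
        "consensus": consensus(pfm).sequence,
    }


def run_screen(config: dict, outdir,
               count_table=None, samples=None) -> dict:
    """Execute the full screen analysis and write the report bundle.

    Exactly one of ``count_table`` (CountMatrix or TSV path) and ``samples``
    (sample-sheet DataFrame or TSV path with population/condition/replicate/
    r1/r2) must be given.  Writes count/score/feature TSVs, selected-set
    lists, PFMs, a JSON summary and a YAML manifest; returns the summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    inputs: dict[str, str] = {}

    if (count_table is None) == (samples is None):
        raise ValueError("give exactly one of count_table and samples")

    if samples is not None:
        if not isinstance(samples, pd.DataFrame):
            inputs["samples"] = _sha256(samples)
            samples = pd.read_csv(samples, sep="\t")
        for p in pd.concat([samples["r1"], samples["r2"]]):
            inputs[str(p)] = _sha256(p)
        log.info("merging and extracting %d populations", len(samples))
        raw, cm, report = build_count_matrix(
            samples, length_filter=config["insert_length"],
            flank5=config["flank5"], flank3=config["flank3"],
            **config["merge"])
        raw.to_tsv(outdir / "counts_raw.tsv")
        report.to_csv(outdir / "extraction_report.tsv", sep="\t", index=False)
        stage_counts["reads"] = int(report["reads"].sum())
        stage_counts["merged"] = int(report["merged"].sum())
        stage_counts["inserts_raw"] = len(raw.counts)
    else:
        if not isinstance(count_table, CountMatrix):
            inputs["count_table"] = _sha256(count_table)
            count_table = CountMatrix.from_tsv(count_table)
        raw = count_table
        cm = raw.filter_length(config["insert_length"])
        raw.to_tsv(outdir / "counts_raw.tsv")
    cm.to_tsv(outdir / f"counts_{config['insert_length']}mer.tsv")
    stage_counts["inserts_target_length"] = len(cm.counts)

    cfg = screen_config(config)
    log.info("scoring %d inserts", len(cm.counts))
    records = score_screen(cm, cfg)
    records.to_csv(outdir / "enrichment_records.tsv", sep="\t")

    depleted = select_depleted(records, cfg)
    enriched = select_enriched(records, cfg)
    stronger = stronger_at_5x(records, cfg.stronger_factor, cfg)
    sets_dir = outdir / "sets"
    sets_dir.mkdir(exist_ok=True)
    _write_set(sets_dir / "depleted.txt", depleted)
    _write_set(sets_dir / "enriched_1x.txt", enriched["1x"])
    _write_set(sets_dir / "enriched_5x.txt", enriched["5x"])
    _write_set(sets_dir / "enriched_both.txt", enriched["both"])
    _write_set(sets_dir / "stronger_at_5x.txt", stronger)

    min_run = config["features"]["min_ppt_run"]
    feats = feature_table(cm.counts.index, min_run)
    feats.to_csv(outdir / "features.tsv", sep="\t")

    analyses = {
        "depleted": _set_analysis(depleted, records, min_run, "depletion_5x"),
        "enriched_1x": _set_analysis(enriched["1x"], records, min_run,
                                     "enrichment_1x"),
        "enriched_5x": _set_analysis(enriched["5x"], records, min_run,
                                     "enrichment_5x"),
        "enriched_both": _set_analysis(enriched["both"], records, min_run,
                                       "enrichment_5x"),
        "stronger_at_5x": _set_analysis(stronger, records, min_run,
                                        "enrichment_5x"),
    }
    for name, inserts in (("depleted", depleted),
                          ("enriched_both", enriched["both"])):
        if inserts:
            build_pfm(inserts).to_tsv(outdir / f"pfm_{name}.tsv")
    both_feats = feature_table(enriched["both"], min_run) if enriched["both"] \
        else None
    if both_feats is not None:
        g_no_ppt = list(both_feats.index[both_feats["g_no_ppt"]])
        if g_no_ppt:
            pfm = build_pfm(g_no_ppt)
            pfm.to_tsv(outdir / "pfm_g_no_ppt.tsv")
            analyses["g_no_ppt"] = {
                "n": len(g_no_ppt),
                "consensus": consensus(pfm).sequence,
            }
    if depleted:
        hist = ppt_start_distribution(depleted, min_run)
        analyses["depleted"]["ppt_start_histogram"] = [int(x) for x in hist]

    summary = {
        "pipeline_version": __version__,
        "config": config,
        **summarize_sets(records, cfg),
        "sets": analyses,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    outputs = sorted(str(p.relative_to(outdir))
                     for p in outdir.rglob("*")
                     if p.is_file() and p.name != "manifest.yaml")
    manifest = {
        "pipeline_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.get("seed"),
        "config": config,
        "inputs": inputs,
        "stage_counts": stage_counts,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return summary
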