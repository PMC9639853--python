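"""Synthetic PPT selection screens with known ground truth.

The real screen transfected a plasmid library carrying 11 random nucleotides
in the polypyrimidine-tract (PPT) position of a trans-splicing reporter,
selected survivors in two puromycin stringencies (three replicates each), and
amplicon-sequenced the insert region of every population.  This module
emulates that experiment end to end so the downstream stages can be tested
against a known truth:

1. a library of distinct random 11-mers with log-normally skewed initial
   abundances (real libraries are heavily bottlenecked by transformation and
   clone expansion; the study saw coverage spanning ~six orders of magnitude);
2. a logistic survival ("fitness") function of four insert features —
   longest pyrimidine run, pyrimidine count, U count and G count — whose
   default weights are anchored to the reporter's dose response: a (U)9
   tract behaves like the full-length tract while (U)3 is severely impaired;
3. discrete Wright–Fisher selection rounds: a multinomial bottleneck sample
   followed by reweighting each insert by ``fitness ** stringency``, with the
   5x condition given a higher stringency than 1x;
4. paired-end amplicon sequencing with a multinomial read allocation per
   population, uniform substitution errors and constant Phred qualities.

One named RNG stream is derived per (stage, population) from the master
seed, so adding populations never perturbs the others, and identical seeds
give byte-identical FASTQ output.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import check_dna, revcomp
from .countmatrix import CountMatrix, make_populations
from .features import longest_pyrimidine_run

__all__ = [
    "FLANK5", "FLANK3", "CONTEXT5", "CONTEXT3",
    "FitnessWeights", "SelectionSimParams", "TruthTable",
    "fitness", "generate_library", "simulate_selection",
    "simulate_counts", "simulate_sequencing", "amplicon",
]

#: Fixed flanks surrounding the randomised insert in the reporter amplicon.
FLANK5 = "GGCGAAATCTAGA"
FLANK3 = "AGATCTACTTC"

# Constant amplicon context outside the flanks.  Synthetic stand-ins for the
# reporter's surrounding plasmid sequence (the real amplicon context is not
# reproduced here); chosen free of internal flank matches.
CONTEXT5 = "GTTAACGCATGCCTCGAGACCTGCA"
CONTEXT3 = "GAATTCCATATGGTCGACCTGCAGC"


def amplicon(insert: str) -> str:
    """The constant amplicon context around one insert."""
    return CONTEXT5 + FLANK5 + insert + FLANK3 + CONTEXT3


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named generator: seeded from (master seed, crc32 of the label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class FitnessWeights:
    """Coefficients of the logistic survival function.

    ``fitness = sigmoid(intercept + w_run·run + w_pyr·pyr + w_u·U − w_g·G)``
    where *run* is the longest pyrimidine run, *pyr* the pyrimidine count,
    *U*/*G* the U and G counts of the insert.  Defaults are calibrated to the
    reporter's dose response — fitness((T)9 context) ≥ 0.9 × fitness((T)11)
    while fitness((T)3 context) ≤ 0.1 × fitness((T)11) — and frozen.
    """

    w_run: float = 0.3
    w_pyr: float = 0.3
    w_u: float = 0.2
    w_g: float = 0.3
    intercept: float = -5.0


def fitness(insert: str, weights: FitnessWeights | None = None) -> float:
    """Survival probability of one insert, strictly inside (0, 1)."""
    w = weights or FitnessWeights()
    dna = check_dna(insert, what="insert")
    run = longest_pyrimidine_run(dna)
    u = dna.count("T")
    c = dna.count("C")
    g = dna.count("G")
    score = (w.intercept + w.w_run * run + w.w_pyr * (u + c)
             + w.w_u * u - w.w_g * g)
    return 1.0 / (1.0 + math.exp(-score))


@dataclass(frozen=True)
class SelectionSimParams:
    """All knobs of the synthetic screen; defaults are the study conditions.

    ``stringency_*`` is the dimensionless selection exponent per condition
    (fitness is raised to it each round); ``bottleneck`` the number of cells
    resampled per round; ``depth`` the sequencing reads per population;
    ``error_rate`` the per-base substitution probability.
    """

    n_variants: int = 30_000
    insert_length: int = 11
    abundance_dispersion: float = 1.25
    fitness_weights: FitnessWeights = field(default_factory=FitnessWeights)
    stringency_1x: float = 0.75
    stringency_5x: float = 1.5
    n_replicates: int = 3
    bottleneck: int = 1_000_000
    rounds: int = 1
    depth: int = 1_000_000
    read_length: int = 75
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_variants > 4 ** self.insert_length:
            raise ValueError(
                f"impossible library: {self.n_variants} distinct "
                f"{self.insert_length}-mers do not exist")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")
        if self.stringency_1x < 0 or self.stringency_5x < 0:
            raise ValueError("stringency must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if min(self.depth, self.bottleneck, self.rounds) < 0 or \
                self.bottleneck < 1 or self.rounds < 1:
            raise ValueError("depth >= 0; bottleneck, rounds >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def populations(self) -> pd.DataFrame:
        return make_populations(self.n_replicates)

    def condition_stringency(self, condition: str) -> float:
        return {"sel_1x": self.stringency_1x,
                "sel_5x": self.stringency_5x}[condition]

    def check_read_geometry(self) -> None:
        span = len(amplicon("N" * self.insert_length))
        if self.read_length < len(CONTEXT5) + len(FLANK5) + \
                self.insert_length + len(FLANK3):
            raise ValueError(
                f"read_length {self.read_length} too short to span the "
                f"5' context, flanks and insert")
        if 2 * self.read_length < span:
            raise ValueError(
                f"read pairs of {self.read_length} nt cannot overlap on a "
                f"{span} nt amplicon")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class TruthTable:
    """Ground truth of a simulated screen.

    ``table`` is indexed by insert with columns ``fitness`` (once selection
    has run), ``freq_initial`` and one ``freq_<population>`` column per
    simulated population.  Every frequency column sums to 1.
    """

    table: pd.DataFrame

    def freq(self, population: str) -> pd.Series:
        return self.table[f"freq_{population}"]

    @property
    def inserts(self) -> list[str]:
        return list(self.table.index)

    def frequency_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("freq_")]

    def validate(self) -> None:
        for col in self.frequency_columns():
            total = float(self.table[col].sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{col} sums to {total}, not 1")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="insert",
                               keep_default_na=False))


def generate_library(params: SelectionSimParams) -> TruthTable:
    """Draw the insert library and its skewed initial frequencies.

    Inserts are distinct uppercase DNA ``insert_length``-mers; initial
    frequencies are log-normal with the configured log-scale SD, normalised
    to sum to 1.  Fully reproducible from the seed.
    """
    rng = _rng(params.seed, "library")
    n, length = params.n_variants, params.insert_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: dict[str, None] = {}
    while len(seen) < n:
        draw = bases[rng.integers(0, 4, size=(n - len(seen), length))]
        buf = draw.tobytes()
        for i in range(draw.shape[0]):
            seen.setdefault(buf[i * length:(i + 1) * length].decode(), None)
    inserts = list(seen)[:n]
    if params.abundance_dispersion > 0:
        raw = np.exp(rng.normal(0.0, params.abundance_dispersion, size=n))
    else:
        raw = np.ones(n)
    freqs = raw / raw.sum()
    table = pd.DataFrame({"freq_initial": freqs}, index=pd.Index(inserts, name="insert"))
    return TruthTable(table)


def simulate_selection(truth: TruthTable,
                       params: SelectionSimParams) -> TruthTable:
    """Run Wright–Fisher selection and add per-population frequencies.

    Per replicate population, ``rounds`` iterations of: multinomial
    bottleneck sample of ``bottleneck`` cells; reweight each insert by
    ``fitness ** stringency``; renormalise.  Replicates differ only by their
    RNG streams.  Stringency 0 reduces to pure drift.
    """
    table = truth.table.copy()
    if "freq_initial" not in table.columns:
        raise ValueError("truth table lacks initial frequencies")
    if "fitness" not in table.columns:
        table.insert(0, "fitness", [
            fitness(s, params.fitness_weights) for s in table.index])
    fit = table["fitness"].to_numpy()
    initial = table["freq_initial"].to_numpy()
    for _, row in params.populations().iterrows():
        pop, cond = row["population"], row["condition"]
        if cond == "initial":
            continue
        rng = _rng(params.seed, f"select:{pop}")
        strength = params.condition_stringency(cond)
        freq = initial
        for _ in range(params.rounds):
            cells = rng.multinomial(params.bottleneck, freq)
            weight = cells * fit ** strength
            total = weight.sum()
            if total == 0:  # pathological all-zero weights: keep drift only
                weight = cells
                total = weight.sum()
            freq = weight / total
        table[f"freq_{pop}"] = freq
    out = TruthTable(table)
    out.validate()
    return out


def _read_allocation(truth: TruthTable, params: SelectionSimParams,
                     population: str) -> np.ndarray:
    """Multinomial read allocation for one population.

    This is the *first* draw from the population's ``seq:`` RNG stream, so
    :func:`simulate_counts` reproduces exactly the allocation that
    :func:`simulate_sequencing` turns into FASTQ.
    """
    rng = _rng(params.seed, f"seq:{population}")
    return rng.multinomial(params.depth, truth.freq(population).to_numpy())


def simulate_counts(truth: TruthTable,
                    params: SelectionSimParams) -> CountMatrix:
    """Sequencing-depth multinomial counts per population (no reads).

    Identical to the per-insert read allocation underlying
    :func:`simulate_sequencing` with the same parameters and seed.
    """
    pops = params.populations()
    data = {row["population"]: _read_allocation(truth, params, row["population"])
            for _, row in pops.iterrows()}
    counts = pd.DataFrame(data, index=truth.table.index.copy())
    return CountMatrix(counts, pops, {
        "flank5": FLANK5, "flank3": FLANK3, "source": "simulate_counts",
        "seed": params.seed})


_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutated_lines(templates: np.ndarray, counts: np.ndarray,
                   error_rate: float, rng: np.random.Generator) -> list[str]:
    """Sequence lines for all reads; templates is (n_variants, L) uint8 codes."""
    reads = np.repeat(templates, counts, axis=0)
    if error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < error_rate
        nhit = int(mask.sum())
        if nhit:
            reads[mask] = (reads[mask] + rng.integers(1, 4, size=nhit)) % 4
    buf = _BASES[reads].tobytes()
    L = templates.shape[1]
    return [buf[i:i + L].decode() for i in range(0, len(buf), L)]


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate == 0 else min(40, round(-10 * math.log10(error_rate)))
    return chr(33 + q)


def _write_fastq(path: Path, pop: str, mate: int, lines: list[str],
                 qual: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        chunk = []
        for i, seq in enumerate(lines):
            chunk.append(f"@{pop}.{i}/{mate}\n{seq}\n+\n{qual}\n")
            if len(chunk) >= 20_000:
                fh.write("".join(chunk))
                chunk = []
        fh.write("".join(chunk))


def simulate_sequencing(truth: TruthTable, params: SelectionSimParams,
                        outdir, gzip_output: bool = False) -> dict:
    """Write paired FASTQ per population, the truth TSV and a run manifest.

    Read 1 covers the amplicon 5' end, read 2 is the reverse complement of
    the 3' end; with the default geometry the mates overlap over most of the
    amplicon.  Reads are grouped by insert within each file (order carries no
    information downstream).  Returns paths plus the sampled allocation as a
    :class:`CountMatrix`.
    """
    params.check_read_geometry()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pops = params.populations()
    L = params.read_length
    qual = _phred_char(params.error_rate) * L
    ext = ".fastq.gz" if gzip_output else ".fastq"

    inserts = truth.inserts
    amp = [amplicon(s) for s in inserts]
    t1 = np.vstack([_BASE_LUT[np.frombuffer(a[:L].encode(), np.uint8)]
                    for a in amp])
    t2 = np.vstack([_BASE_LUT[np.frombuffer(revcomp(a[-L:]).encode(), np.uint8)]
                    for a in amp])

    allocation = {}
    files = {}
    for _, row in pops.iterrows():
        pop = row["population"]
        rng = _rng(params.seed, f"seq:{pop}")
        counts = rng.multinomial(params.depth, truth.freq(pop).to_numpy())
        allocation[pop] = counts
        r1 = outdir / f"{pop}_R1{ext}"
        r2 = outdir / f"{pop}_R2{ext}"
        _write_fastq(r1, pop, 1,
                     _mutated_lines(t1, counts, params.error_rate, rng), qual)
        _write_fastq(r2, pop, 2,
                     _mutated_lines(t2, counts, params.error_rate, rng), qual)
        files[pop] = (str(r1), str(r2))

    truth_path = outdir / "truth.tsv"
    truth.to_tsv(truth_path)
    cm = CountMatrix(pd.DataFrame(allocation, index=truth.table.index.copy()),
                     pops, {"flank5": FLANK5, "flank3": FLANK3,
                            "source": "simulate_sequencing",
                            "seed": params.seed})
    manifest = {
        "params": params.to_dict(),
        "flank5": FLANK5, "flank3": FLANK3,
        "context5": CONTEXT5, "context3": CONTEXT3,
        "populations": {p: {"r1": files[p][0], "r2": files[p][1],
                            "reads": int(allocation[p].sum())}
                        for p in files},
        "truth": str(truth_path),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {"files": files, "truth_path": str(truth_path),
            "allocation": cm, "manifest": str(outdir / "manifest.yaml")}


def sample_sheet(sim_result: dict, params: SelectionSimParams) -> pd.DataFrame:
    """Sample sheet (population, condition, replicate, r1, r2) for a run."""
    pops = params.populations()
    rows = []
    for _, row in pops.iterrows():
        r1, r2 = sim_result["files"][row["population"]]
        rows.append((row["population"], row["condition"], row["replicate"],
                     r1, r2))
    return pd.DataFrame(rows, columns=["population", "condition",
                                       "replicate", "r1", "r2"])
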