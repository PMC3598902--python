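"""Synthetic MBD-capture experiments: genome, methylation, capture, sequencing.

The generator emulates the features the QC machinery keys on, at desk scale:

* a genome with CpG-island versus background dinucleotide structure
  (first-order Markov chain with an elevated C->G transition inside islands);
* a bimodal methylation landscape — heavily methylated background CpGs and a
  mixture of methylated/unmethylated islands;
* random ~200 bp fragmentation followed by affinity capture whose success
  probability grows with the number of methylated CpGs on the molecule,
  above a nonspecific floor:  p(m) = eps + (1 - eps) * (1 - (1 - q)^m);
* PCR/sampling duplicates via with-replacement resampling of the captured
  pool; and
* an RRBS-like observed methylation table with Poisson coverage and
  binomial sampling noise.

A "kit archetype" is the (eps, q) pair: eps is the methylation-independent
capture floor (inverse specificity), q the per-methylated-CpG binding
success (sensitivity).  All draws flow from one seeded generator per
experiment, so a (parameters, seed) pair reproduces bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from mbdqc.fragio import (
    MappedFragment,
    MethylationTable,
    ReferenceGenome,
    UNLIMITED_COVERAGE,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeModel:
    """Parameters of the island/background dinucleotide chain.

    ``cg_background`` and ``cg_island`` are the C->G transition
    probabilities P(G | C) outside and inside islands; genome-wide CpG
    depletion in mammals corresponds to a low background value.  Island
    lengths follow a gamma with the given mean (bp) and dispersion
    (coefficient of variation).
    """

    length: int = 200_000
    island_fraction: float = 0.10
    cg_background: float = 0.04
    cg_island: float = 0.25
    island_len_mean: float = 1_000.0
    island_len_dispersion: float = 0.5

    def __post_init__(self) -> None:
        for name in ("island_fraction", "cg_background", "cg_island"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.length <= 0:
            raise ValueError("genome length must be > 0")


@dataclass(frozen=True)
class MethylationModel:
    """Beta-distribution parameters of the methylation landscape.

    Background CpGs draw from ``background_beta`` (default Beta(9, 1), mean
    0.9 — most non-island CpGs methylated).  Islands are bimodal as units:
    each island independently is "methylated" with probability ``pi_m``.  A
    methylated island draws an island-level mean from ``island_high_beta``
    (default Beta(2, 1): graded, intermediate-to-full methylation), an
    unmethylated one from ``island_low_beta`` (default Beta(1, 9), mean
    0.1); individual CpG degrees then scatter around the island mean with
    concentration ``island_concentration``.  Methylation is therefore
    spatially coherent within an island — the all-or-none, regionally
    graded character that affinity capture keys on — rather than an
    independent draw per CpG.
    """

    background_beta: tuple[float, float] = (9.0, 1.0)
    island_high_beta: tuple[float, float] = (2.0, 1.0)
    island_low_beta: tuple[float, float] = (1.0, 9.0)
    pi_m: float = 0.3
    island_concentration: float = 20.0

    def __post_init__(self) -> None:
        for name in ("background_beta", "island_high_beta", "island_low_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} parameters must be > 0")
        if not 0.0 <= self.pi_m <= 1.0:
            raise ValueError("pi_m outside [0, 1]")
        if self.island_concentration <= 0:
            raise ValueError("island_concentration must be > 0")


@dataclass(frozen=True)
class KitArchetype:
    """A virtual capture kit: nonspecific floor eps and per-mCpG success q."""

    epsilon: float
    q: float
    label: str = "kit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0 or not 0.0 <= self.q <= 1.0:
            raise ValueError("epsilon and q must lie in [0, 1]")


def capture_probability(m: int | np.ndarray, kit: KitArchetype) -> float | np.ndarray:
    """p(m) = eps + (1 - eps) * (1 - (1 - q)^m) for m methylated CpGs.

    Each methylated CpG is an independent binding chance; p(0) = eps exactly
    and p saturates at 1 as m grows.
    """
    return kit.epsilon + (1.0 - kit.epsilon) * (1.0 - (1.0 - kit.q) ** np.asarray(m))


# ---------------------------------------------------------------------------
# genome


def _transition_matrix(base_probs: np.ndarray, cg_prob: float) -> np.ndarray:
    """Rows = current base, columns = next base; row C gets P(G) = cg_prob."""
    mat = np.tile(base_probs, (4, 1))
    c = _BASE_INDEX["C"]
    g = _BASE_INDEX["G"]
    row = base_probs.copy()
    others = row.sum() - row[g]
    row = row * (1.0 - cg_prob) / others
    row[g] = cg_prob
    mat[c] = row
    return mat / mat.sum(axis=1, keepdims=True)


def _draw_islands(model: GenomeModel, rng: np.random.Generator) -> list[tuple[int, int]]:
    if model.island_fraction <= 0.0:
        return []
    mean_gap = model.island_len_mean * (1.0 - model.island_fraction) / model.island_fraction
    shape = 1.0 / model.island_len_dispersion**2
    scale = model.island_len_mean / shape
    islands: list[tuple[int, int]] = []
    pos = 0
    while pos < model.length:
        pos += int(rng.exponential(mean_gap)) + 1
        if pos >= model.length:
            break
        ilen = max(int(rng.gamma(shape, scale)), 50)
        end = min(pos + ilen, model.length)
        islands.append((pos, end))
        pos = end
    return islands


def simulate_genome(
    model: GenomeModel, seed: int | np.random.Generator
) -> tuple[ReferenceGenome, list[tuple[int, int]]]:
    """Generate one chromosome ("sim1") plus its CpG-island intervals.

    The sequence is a first-order dinucleotide chain; inside islands the
    C->G transition (and GC content) is elevated.
    """
    rng = _rng(seed)
    bg_base = np.array([0.30, 0.20, 0.20, 0.30])  # AT-rich background
    isl_base = np.array([0.21, 0.29, 0.29, 0.21])  # GC-rich islands
    mat_bg = _transition_matrix(bg_base, model.cg_background)
    mat_isl = _transition_matrix(isl_base, model.cg_island)
    cum_bg = np.cumsum(mat_bg, axis=1)
    cum_isl = np.cumsum(mat_isl, axis=1)

    islands = _draw_islands(model, rng)
    in_island = np.zeros(model.length, dtype=bool)
    for s, e in islands:
        in_island[s:e] = True

    u = rng.random(model.length)
    out = np.empty(model.length, dtype=np.int8)
    state = int(rng.integers(4))
    for i in range(model.length):
        cum = cum_isl[state] if in_island[i] else cum_bg[state]
        state = int(np.searchsorted(cum, u[i], side="right"))
        if state > 3:  # guard against u == 1.0 edge
            state = 3
        out[i] = state
    seq = "".join(_BASES[b] for b in out)
    return ReferenceGenome({"sim1": seq}), islands


def find_cpgs(genome: ReferenceGenome, chrom: str = "sim1") -> np.ndarray:
    """0-based forward-strand C positions of every CpG on ``chrom``."""
    seq = genome[chrom].upper()
    positions = []
    start = 0
    while True:
        hit = seq.find("CG", start)
        if hit == -1:
            break
        positions.append(hit)
        start = hit + 1
    return np.asarray(positions, dtype=np.int64)


# ---------------------------------------------------------------------------
# methylation


def assign_methylation(
    genome: ReferenceGenome,
    islands: Sequence[tuple[int, int]],
    model: MethylationModel,
    seed: int | np.random.Generator,
    chrom: str = "sim1",
) -> MethylationTable:
    """Draw a true methylation degree for every CpG in the genome."""
    rng = _rng(seed)
    pos = find_cpgs(genome, chrom)
    if len(pos) == 0:
        raise ValueError("genome contains no CpG")
    island_id = np.full(genome.length(chrom), -1, dtype=np.int64)
    for k, (s, e) in enumerate(islands):
        island_id[s:e] = k
    cpg_island = island_id[pos]

    deg = np.empty(len(pos))
    background_cpg = cpg_island < 0
    a, b = model.background_beta
    deg[background_cpg] = rng.beta(a, b, size=int(background_cpg.sum()))
    # one methylated/unmethylated coin per island: islands are bimodal units,
    # with CpG degrees spatially coherent around an island-level mean
    island_high = rng.random(len(islands)) < model.pi_m
    ah, bh = model.island_high_beta
    al, bl = model.island_low_beta
    nu = model.island_concentration
    for k in range(len(islands)):
        members = cpg_island == k
        n = int(members.sum())
        mu = rng.beta(ah, bh) if island_high[k] else rng.beta(al, bl)
        if n == 0:
            continue
        deg[members] = rng.beta(nu * mu, nu * (1.0 - mu), size=n)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "degree": deg,
            "coverage": np.full(len(pos), UNLIMITED_COVERAGE, dtype=np.int64),
        }
    )
    return MethylationTable(df, source_kind="true")


# ---------------------------------------------------------------------------
# capture and sequencing


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_capture(
    genome: ReferenceGenome,
    true_methylation: MethylationTable,
    kit: KitArchetype,
    n_molecules: int,
    seed: int | np.random.Generator,
    fragment_len_mean: float = 200.0,
    fragment_len_sd: float = 50.0,
    fragment_len_bounds: tuple[float, float] = (50.0, 400.0),
    chrom: str = "sim1",
) -> list[MappedFragment]:
    """Fragment the genome and capture molecules by methylation affinity.

    Molecules get uniform random starts and truncated-normal lengths
    (default mean 200 bp, sd 50, bounds [50, 400], emulating sonication to
    ~200 bp).  Each molecule's methylated-CpG count m is re-sampled per
    molecule — Bernoulli(degree) per contained CpG, mimicking allelic and
    cellular heterogeneity — and the molecule is captured with probability
    p(m) = eps + (1 - eps) * (1 - (1 - q)^m).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    lo, hi = fragment_len_bounds
    if not 0 < lo <= hi:
        raise ValueError(f"invalid fragment length bounds ({lo}, {hi})")
    rng = _rng(seed)
    glen = genome.length(chrom)
    if glen <= lo:
        raise ValueError("genome shorter than the minimum fragment length")

    lengths = np.round(
        _truncated_normal(rng, n_molecules, fragment_len_mean, fragment_len_sd, lo, hi)
    ).astype(np.int64)
    lengths = np.clip(lengths, 1, glen)
    starts = rng.integers(0, glen - lengths + 1)
    ends = starts + lengths

    cdf = true_methylation.df
    pos = cdf.loc[cdf["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
    deg = cdf.loc[cdf["chrom"] == chrom, "degree"].to_numpy(dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, deg = pos[order], deg[order]

    los = np.searchsorted(pos, starts, side="left")
    his = np.searchsorted(pos, ends, side="left")
    captured: list[MappedFragment] = []
    for i in range(n_molecules):
        d = deg[los[i] : his[i]]
        m = int((rng.random(len(d)) < d).sum()) if len(d) else 0
        p = capture_probability(m, kit)
        if rng.random() < p:
            captured.append(MappedFragment(chrom, int(starts[i]), int(ends[i])))
    return captured


def simulate_sequencing(
    pool: Sequence[MappedFragment],
    n_reads: int,
    seed: int | np.random.Generator,
) -> list[MappedFragment]:
    """Sample the captured pool with replacement: PCR + flow-cell proxy.

    Small pools re-drawn many times produce high duplicate fractions, the
    low-yield/high-duplicate signature seen in yield accounting.  The
    returned fragments each have multiplicity 1; duplicate collapse is a
    downstream step.
    """
    if len(pool) == 0:
        raise ValueError("captured pool is empty")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = _rng(seed)
    idx = rng.integers(0, len(pool), size=n_reads)
    return [pool[i] for i in idx]


def expected_nonduplicate_fraction(pool_size: int, n_reads: int) -> float:
    """Occupancy closed form: E[distinct]/n for n draws on P equiprobable cells."""
    return pool_size * (1.0 - (1.0 - 1.0 / pool_size) ** n_reads) / n_reads


def nonduplicate_count_std(pool_size: int, n_reads: int) -> float:
    """Standard deviation of the distinct-cell count in the occupancy problem."""
    p, n = pool_size, n_reads
    e1 = (1.0 - 1.0 / p) ** n
    e2 = (1.0 - 2.0 / p) ** n if p > 1 else 0.0
    mean = p * (1.0 - e1)
    second = mean + p * (p - 1) * (1.0 - 2.0 * e1 + e2)
    return float(np.sqrt(max(second - mean**2, 0.0)))


# ---------------------------------------------------------------------------
# bisulfite observation


def simulate_bisulfite(
    true_methylation: MethylationTable,
    mean_coverage: float,
    seed: int | np.random.Generator,
) -> MethylationTable:
    """RRBS-like observation: Poisson coverage, binomial methylated counts.

    CpGs drawn with zero coverage are unobserved and omitted from the table.
    """
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be > 0")
    rng = _rng(seed)
    deg = true_methylation.df["degree"].to_numpy(dtype=float)
    cov = rng.poisson(mean_coverage, size=len(deg))
    meth = rng.binomial(cov, deg)
    seen = cov > 0
    df = pd.DataFrame(
        {
            "chrom": true_methylation.df["chrom"].to_numpy()[seen],
            "pos": true_methylation.df["pos"].to_numpy()[seen],
            "degree": meth[seen] / cov[seen],
            "coverage": cov[seen].astype(np.int64),
            "meth_count": meth[seen].astype(np.int64),
        }
    )
    return MethylationTable(df.reset_index(drop=True), source_kind="rrbs")


# ---------------------------------------------------------------------------
# whole experiment


@dataclass
class SimulatedExperiment:
    """One end-to-end virtual MBD-seq experiment plus its ground truth."""

    genome: ReferenceGenome
    islands: list[tuple[int, int]]
    true_methylation: MethylationTable
    captured_pool: list[MappedFragment]
    sequenced: list[MappedFragment]
    observed_rrbs: MethylationTable
    seed: int
    params: dict = field(default_factory=dict)


def simulate_experiment(
    seed: int,
    genome_model: GenomeModel = GenomeModel(),
    methylation_model: MethylationModel = MethylationModel(),
    kit: KitArchetype = KitArchetype(epsilon=0.02, q=0.25, label="kit"),
    n_molecules: int = 50_000,
    n_reads: int = 50_000,
    mean_coverage: float = 30.0,
    genome: ReferenceGenome | None = None,
    islands: Sequence[tuple[int, int]] | None = None,
) -> SimulatedExperiment:
    """Run the full generator chain from one seed.

    A pre-built (genome, islands) pair may be passed to share one genome
    across kit archetypes; methylation, capture, sequencing and bisulfite
    observation then still flow from the single seeded generator.
    """
    rng = np.random.default_rng(seed)
    if genome is None:
        genome, islands = simulate_genome(genome_model, rng)
    assert islands is not None
    true_meth = assign_methylation(genome, islands, methylation_model, rng)
    pool = simulate_capture(genome, true_meth, kit, n_molecules, rng)
    if len(pool) == 0:
        raise ValueError("capture produced an empty pool; raise epsilon, q or n_molecules")
    sequenced = simulate_sequencing(pool, n_reads, rng)
    observed = simulate_bisulfite(true_meth, mean_coverage, rng)
    params = {
        "genome_model": asdict(genome_model),
        "methylation_model": asdict(methylation_model),
        "kit": asdict(kit),
        "n_molecules": n_molecules,
        "n_reads": n_reads,
        "mean_coverage": mean_coverage,
    }
    return SimulatedExperiment(
        genome=genome,
        islands=list(islands),
        true_methylation=true_meth,
        captured_pool=pool,
        sequenced=sequenced,
        observed_rrbs=observed,
        seed=seed,
        params=params,
    )
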