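"""Forward Wright–Fisher simulation with recombination, plus perturbation
operators (missingness injection, locus/individual downsampling, Q-value
stratification, chromosome-map fragmentation).

Mating is random union of gametes in a monoecious diploid population
(selfing allowed with probability 1/N), the idealized model the LD
estimators are calibrated against.  Crossovers follow a Poisson process
along the genetic map (no interference), realized at the sampled loci as a
two-state Markov chain whose switch probability between adjacent loci is
the Haldane recombination fraction of their gap — exactly equivalent to
drawing a Poisson crossover count with uniform breakpoint positions.

Populations start from standing variation in linkage equilibrium at
Uniform(init_freq_low, init_freq_high) frequencies and accumulate LD over a
burn-in; there is no mutation during the run.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_seed, rng_from
from .errors import EmptySelectionError, InvalidConfigError, NeldError
from .ldcore import haldane_c
from .matrix import MISSING, GenotypeMatrix, LocusMap

log = logging.getLogger(__name__)

#: physical positions are synthesized at 1 cM = 1 Mb; bp carries order only
_BP_PER_MORGAN = 100_000_000


@dataclass
class SimConfig:
    """Configuration of one forward simulation.

    ``ne_trajectory`` is a list of ``(generation_index, N)`` breakpoints
    read as a step function forward in time: the population has size ``N``
    from that generation until the next breakpoint; simulation ends at the
    last breakpoint's generation.  ``burnin_generations=None`` selects the
    default ``min(4 * N_final, 500)``.
    """

    ne_trajectory: list[tuple[int, int]] = field(default_factory=lambda: [(0, 100)])
    n_demes: int = 1
    migration_rate: float = 0.0
    divergence_burnin: int = 0
    n_chromosomes: int = 4
    chrom_length_morgans: float = 1.0
    loci_per_chromosome: int = 200
    init_freq_low: float = 0.05
    init_freq_high: float = 0.95
    burnin_generations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ne_trajectory:
            raise InvalidConfigError("ne_trajectory must have at least one breakpoint")
        self.ne_trajectory = sorted((int(g), int(n)) for g, n in self.ne_trajectory)
        if self.ne_trajectory[0][0] != 0:
            raise InvalidConfigError("ne_trajectory must start at generation 0")
        if any(n < 2 for _, n in self.ne_trajectory):
            raise InvalidConfigError("all population sizes must be >= 2")
        if self.n_demes not in (1, 2):
            raise InvalidConfigError("n_demes must be 1 or 2")
        if not 0 <= self.migration_rate < 1:
            raise InvalidConfigError("migration_rate must be in [0, 1)")
        if self.n_demes == 1 and self.migration_rate != 0:
            raise InvalidConfigError("migration_rate must be 0 with a single deme")
        if self.divergence_burnin < 0:
            raise InvalidConfigError("divergence_burnin must be non-negative")
        if self.n_chromosomes < 1:
            raise InvalidConfigError("n_chromosomes must be positive")
        if self.chrom_length_morgans <= 0:
            raise InvalidConfigError("chrom_length_morgans must be positive")
        if self.loci_per_chromosome < 2:
            raise InvalidConfigError("loci_per_chromosome must be >= 2")
        if not (0 < self.init_freq_low < self.init_freq_high < 1):
            raise InvalidConfigError("init frequency bounds must satisfy 0 < low < high < 1")
        if self.burnin_generations is None:
            self.burnin_generations = min(4 * self.final_n, 500)
        if self.burnin_generations < 0:
            raise InvalidConfigError("burnin_generations must be non-negative")

    @property
    def final_n(self) -> int:
        return self.ne_trajectory[-1][1]

    @property
    def final_generation(self) -> int:
        return self.ne_trajectory[-1][0]

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def n_at(self, gen: int) -> int:
        n = self.ne_trajectory[0][1]
        for g, size in self.ne_trajectory:
            if g <= gen:
                n = size
        return n


@dataclass
class SimulatedPopulation:
    """Final-generation genotypes plus ground truth for recovery tests."""

    matrix: GenotypeMatrix
    true_ne_trajectory: list[tuple[int, int]]
    founder_freqs: np.ndarray
    seed: int
    config: SimConfig

    @property
    def q_values(self) -> np.ndarray:
        return self.matrix.q_values


def _build_map(config: SimConfig, rng: np.random.Generator) -> LocusMap:
    chrom_ids, bps, gpos = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        g = np.sort(rng.uniform(0.0, config.chrom_length_morgans, config.loci_per_chromosome))
        bp = np.floor(g * _BP_PER_MORGAN).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp)  # keep strictly increasing under ties
        bp += np.arange(bp.size)
        chrom_ids.append(np.full(g.size, c, dtype=np.int64))
        bps.append(bp)
        gpos.append(g)
    return LocusMap(
        chrom_id=np.concatenate(chrom_ids),
        bp=np.concatenate(bps),
        genetic_pos=np.concatenate(gpos),
        chrom_length={c: config.chrom_length_morgans for c in range(1, config.n_chromosomes + 1)},
    )


def _switch_probs(locus_map: LocusMap) -> np.ndarray:
    """Per-locus haplotype-switch probabilities for gamete formation.

    Entry l is the recombination fraction between locus l-1 and l; the first
    locus of each chromosome gets 0.5 (independent start, fair coin).
    """
    g = locus_map.genetic_pos
    chrom = locus_map.chrom_id
    c = np.empty(g.size)
    c[0] = 0.5
    gaps = g[1:] - g[:-1]
    same = chrom[1:] == chrom[:-1]
    c[1:] = np.where(same, haldane_c(np.abs(gaps)), 0.5)
    return c


def _gametes(
    hap: np.ndarray, parents: np.ndarray, cswitch: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per entry of ``parents`` from haplotype array ``hap``."""
    K, L = parents.size, cswitch.size
    switch = rng.random((K, L)) < cswitch
    anc = np.cumsum(switch, axis=1, dtype=np.int64) & 1
    return hap[parents[:, None], anc, np.arange(L)[None, :]]


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Run the forward simulation and return the final generation.

    Deterministic for a fixed config seed.  Burn-in runs on a single
    ancestral population; a two-deme run then splits it into demes A and B
    (each one Wright–Fisher generation drawn from the ancestral pool, with
    pedigree ancestry Q set to 1 and 0 at the split), evolves them
    separately for ``divergence_burnin`` generations, and finally applies
    ``migration_rate`` per parent draw over the trajectory phase.
    Offspring inherit the mean parental Q.
    """
    rng = rng_from(config.seed, "simulate")
    locus_map = _build_map(config, rng)
    cswitch = _switch_probs(locus_map)
    L = locus_map.n_loci
    n0 = config.ne_trajectory[0][1]

    freqs = rng.uniform(config.init_freq_low, config.init_freq_high, L)
    hap0 = (rng.random((n0, 2, L)) < freqs).astype(np.uint8)
    demes: list[dict] = [{"hap": hap0, "q": np.ones(n0)}]
    founder_freqs = hap0.sum(axis=(0, 1)) / (2 * n0)

    def step(sizes_next: list[int], m: float) -> None:
        offsets = np.cumsum([0] + [d["hap"].shape[0] for d in demes])
        hap_all = np.concatenate([d["hap"] for d in demes], axis=0)
        q_all = np.concatenate([d["q"] for d in demes])
        new = []
        for d_idx, size in enumerate(sizes_next):
            parent_idx = []
            for _ in range(2):  # mother, father draws
                src = np.full(size, d_idx)
                if len(demes) == 2 and m > 0:
                    mig = rng.random(size) < m
                    src = np.where(mig, 1 - d_idx, src)
                counts = np.array([demes[s]["hap"].shape[0] for s in src])
                parent_idx.append(offsets[src] + rng.integers(0, counts))
            mothers, fathers = parent_idx
            gam_m = _gametes(hap_all, mothers, cswitch, rng)
            gam_f = _gametes(hap_all, fathers, cswitch, rng)
            new.append(
                {
                    "hap": np.stack([gam_m, gam_f], axis=1),
                    "q": 0.5 * (q_all[mothers] + q_all[fathers]),
                }
            )
        for d_idx, nd in enumerate(new):
            demes[d_idx] = nd

    # phase 1: burn-in of the single ancestral population
    for _ in range(config.burnin_generations):
        step([n0], 0.0)
    if config.n_demes == 2:
        # split: each deme is one WF generation drawn from the ancestral pool
        ancestral = demes[0]
        split = []
        for d_idx in range(2):
            mothers = rng.integers(0, n0, size=n0)
            fathers = rng.integers(0, n0, size=n0)
            gam_m = _gametes(ancestral["hap"], mothers, cswitch, rng)
            gam_f = _gametes(ancestral["hap"], fathers, cswitch, rng)
            split.append(
                {
                    "hap": np.stack([gam_m, gam_f], axis=1),
                    "q": np.full(n0, 1.0 if d_idx == 0 else 0.0),
                }
            )
        demes = split
        # phase 2: divergence, demes evolve separately
        for _ in range(config.divergence_burnin):
            step([n0, n0], 0.0)
    # phase 3: the Ne trajectory with migration active
    realized: list[tuple[int, int]] = [(0, n0)]
    for gen in range(1, config.final_generation + 1):
        n_gen = config.n_at(gen)
        step([n_gen] * config.n_demes, config.migration_rate)
        realized.append((gen, n_gen))

    dosages = np.concatenate([d["hap"].sum(axis=1) for d in demes], axis=0).astype(np.int8)
    q = np.concatenate([d["q"] for d in demes])
    labels = np.concatenate(
        [np.full(demes[i]["hap"].shape[0], "A" if i == 0 else "B", dtype=object) for i in range(len(demes))]
    )
    ids = [f"{lab}{i + 1}" for i, lab in enumerate(labels)]
    matrix = GenotypeMatrix(
        dosages=dosages, map=locus_map, individual_ids=ids, deme_labels=labels, q_values=q
    )
    n_fixed = int(matrix.monomorphic_mask().sum())
    if n_fixed == matrix.n_loci:
        warnings.warn("all loci fixed after burn-in; nothing left for LD", stacklevel=2)
    elif n_fixed:
        log.info("%d of %d loci monomorphic after simulation (flagged)", n_fixed, L)
    return SimulatedPopulation(
        matrix=matrix,
        true_ne_trajectory=realized,
        founder_freqs=founder_freqs,
        seed=config.seed,
        config=config,
    )


# ---------------------------------------------------------------------------
# perturbation operators (all non-mutating)


def _as_matrix(pop_or_matrix) -> GenotypeMatrix:
    if isinstance(pop_or_matrix, SimulatedPopulation):
        return pop_or_matrix.matrix
    return pop_or_matrix


def sample_individuals(pop_or_matrix, n: int, seed: int = 0) -> GenotypeMatrix:
    """``n`` distinct individuals, drawn without replacement, metadata kept."""
    G = _as_matrix(pop_or_matrix)
    if not 1 <= n <= G.n_individuals:
        raise NeldError(
            f"cannot sample {n} individuals from {G.n_individuals} available"
        )
    rng = rng_from(seed, "sample-individuals")
    idx = np.sort(rng.choice(G.n_individuals, size=n, replace=False))
    return G.subset_individuals(idx)


def inject_missing(G: GenotypeMatrix, rate, seed: int = 0) -> GenotypeMatrix:
    """Set genotypes to MISSING, each independently with the individual's rate
    (missing completely at random).

    ``rate`` is a scalar or per-individual vector in [0, 1).
    """
    rate = np.broadcast_to(np.asarray(rate, dtype=np.float64), (G.n_individuals,))
    if np.any((rate < 0) | (rate >= 1)):
        raise NeldError("missingness rate must be in [0, 1)")
    out = G.copy()
    if np.all(rate == 0):
        return out
    rng = rng_from(seed, "inject-missing")
    mask = rng.random(G.shape) < rate[:, None]
    out.dosages[mask] = MISSING
    realized = out.missing_mask().mean(axis=1)
    log.info(
        "injected MCAR missingness: target mean %.3f, realized mean %.3f",
        float(rate.mean()),
        float(realized.mean()),
    )
    return out


def inject_missing_genotype_dependent(
    G: GenotypeMatrix, rate, het_factor: float = 2.0, seed: int = 0
) -> GenotypeMatrix:
    """Missingness with heterozygote-inflated dropout probability.

    Probe for non-random missingness: heterozygous genotypes go missing with
    ``min(rate * het_factor, 0.999)`` while homozygotes use ``rate``.
    """
    rate = np.broadcast_to(np.asarray(rate, dtype=np.float64), (G.n_individuals,))
    if np.any((rate < 0) | (rate >= 1)):
        raise NeldError("missingness rate must be in [0, 1)")
    if het_factor < 1:
        raise NeldError("het_factor must be >= 1")
    out = G.copy()
    rng = rng_from(seed, "inject-missing-het")
    p = np.repeat(rate[:, None], G.n_loci, axis=1)
    p = np.where(G.dosages == 1, np.minimum(p * het_factor, 0.999), p)
    mask = rng.random(G.shape) < p
    out.dosages[mask] = MISSING
    return out


def downsample_loci(G: GenotypeMatrix, n: int, seed: int = 0) -> GenotypeMatrix:
    """``n`` distinct loci without replacement, original map order preserved."""
    if not 1 <= n <= G.n_loci:
        raise NeldError(f"cannot sample {n} loci from {G.n_loci} available")
    rng = rng_from(seed, "downsample-loci")
    idx = np.sort(rng.choice(G.n_loci, size=n, replace=False))
    return G.subset_loci(idx)


def fragment_map(locus_map: LocusMap, n_chrom_assumed: int, pseudo_length: float = 1.0) -> LocusMap:
    """Reassign loci to ``n_chrom_assumed`` pseudo-chromosomes.

    Each true chromosome's locus list is split into consecutive blocks of
    near-equal size (difference at most 1); pseudo-chromosomes are numbered
    1..n and each is rescaled to ``pseudo_length`` Morgans, mimicking the
    1-Morgan-per-chromosome convention assumed when real maps are absent.
    The chromosome's genetic interval is partitioned at midpoints between
    adjacent blocks, so a factor-1 split of a 1-Morgan map is a no-op.
    """
    n_true = locus_map.n_chromosomes
    if n_chrom_assumed < n_true or n_chrom_assumed % n_true != 0:
        raise NeldError(
            f"assumed chromosome count {n_chrom_assumed} must be a multiple of the "
            f"current count {n_true}"
        )
    factor = n_chrom_assumed // n_true
    new_chrom = np.empty(locus_map.n_loci, dtype=np.int64)
    new_gpos = np.empty(locus_map.n_loci, dtype=np.float64)
    next_id = 1
    for c in locus_map.chromosomes:
        idx = np.flatnonzero(locus_map.chrom_id == c)
        blocks = [b for b in np.array_split(idx, factor)]
        length = locus_map.chrom_length.get(int(c), 1.0)
        gp = locus_map.genetic_pos
        bounds = [0.0]
        for prev, nxt in zip(blocks[:-1], blocks[1:]):
            if prev.size and nxt.size:
                bounds.append(0.5 * (gp[prev[-1]] + gp[nxt[0]]))
            else:
                bounds.append(bounds[-1])
        bounds.append(length)
        for block, lo, hi in zip(blocks, bounds[:-1], bounds[1:]):
            new_chrom[block] = next_id
            next_id += 1
            if block.size == 0:
                continue
            span = hi - lo
            if span > 0:
                new_gpos[block] = (gp[block] - lo) / span * pseudo_length
            else:
                new_gpos[block] = 0.0
    return LocusMap(
        chrom_id=new_chrom,
        bp=locus_map.bp.copy(),
        genetic_pos=new_gpos,
        ref_allele=locus_map.ref_allele.copy(),
        alt_allele=locus_map.alt_allele.copy(),
        chrom_length={i: pseudo_length for i in range(1, n_chrom_assumed + 1)},
    )


def stratify_by_q(G: GenotypeMatrix, q_min: float, deme: str = "A") -> GenotypeMatrix:
    """Individuals whose pedigree ancestry to ``deme`` is at least ``q_min``."""
    if G.q_values is None:
        raise NeldError("genotype matrix carries no Q-values")
    if deme not in ("A", "B"):
        raise NeldError("deme must be 'A' or 'B'")
    q = G.q_values if deme == "A" else 1.0 - G.q_values
    idx = np.flatnonzero(q >= q_min)
    if idx.size == 0:
        raise EmptySelectionError(
            f"no individuals with ancestry to deme {deme} >= {q_min}"
        )
    return G.subset_individuals(idx)


def pool_demes(G: GenotypeMatrix) -> GenotypeMatrix:
    """All individuals regardless of deme (identity copy; explicit intent)."""
    return G.copy()
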