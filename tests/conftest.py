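import numpy as np
import pytest

from neld import GenotypeMatrix, LocusMap, MISSING, SimConfig, simulate_population


def make_map(chrom_ids, gpos=None, length=1.0):
    chrom_ids = np.asarray(chrom_ids, dtype=np.int64)
    n = chrom_ids.size
    if gpos is None:
        gpos = np.zeros(n)
        for c in np.unique(chrom_ids):
            sel = np.flatnonzero(chrom_ids == c)
            gpos[sel] = np.linspace(0.0, length, sel.size + 2)[1:-1]
    gpos = np.asarray(gpos, dtype=np.float64)
    bp = np.zeros(n, dtype=np.int64)
    for c in np.unique(chrom_ids):
        sel = np.flatnonzero(chrom_ids == c)
        bp[sel] = np.arange(1, sel.size + 1) * 1000
    return LocusMap(
        chrom_id=chrom_ids,
        bp=bp,
        genetic_pos=gpos,
        chrom_length={int(c): length for c in np.unique(chrom_ids)},
    )


def make_matrix(dosages, chrom_ids=None, gpos=None, q=None, demes=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    if chrom_ids is None:
        chrom_ids = np.ones(dosages.shape[1], dtype=np.int64)
    return GenotypeMatrix(
        dosages=dosages,
        map=make_map(chrom_ids, gpos),
        q_values=q,
        deme_labels=demes,
    )


def random_matrix(rng, n_ind=20, n_loci=40, n_chrom=4, missing_rate=0.0):
    """Random polymorphic-ish matrix with optional MCAR missingness."""
    freqs = rng.uniform(0.15, 0.85, n_loci)
    dos = (rng.random((n_ind, n_loci)) < freqs).astype(np.int8)
    dos += (rng.random((n_ind, n_loci)) < freqs).astype(np.int8)
    if missing_rate > 0:
        dos[rng.random((n_ind, n_loci)) < missing_rate] = MISSING
    chrom = np.repeat(np.arange(1, n_chrom + 1), n_loci // n_chrom)
    if chrom.size < n_loci:
        chrom = np.concatenate([chrom, np.full(n_loci - chrom.size, n_chrom)])
    return make_matrix(dos, chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_population():
    """One modest constant-N simulation shared by read-only tests."""
    cfg = SimConfig(
        ne_trajectory=[(0, 50)],
        n_chromosomes=2,
        loci_per_chromosome=120,
        burnin_generations=120,
        seed=77,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def two_deme_population():
    cfg = SimConfig(
        ne_trajectory=[(0, 40)],
        n_demes=2,
        migration_rate=0.0,
        divergence_burnin=80,
        n_chromosomes=2,
        loci_per_chromosome=100,
        burnin_generations=100,
        seed=1234,
    )
    return simulate_population(cfg)
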