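"""Pairwise composite r^2 and LD-based contemporary Ne estimation.

The r^2 statistic is the squared Pearson correlation of unphased dosage
vectors over pairwise-complete individuals (the composite, Burrows-type
surrogate appropriate for unphased diploid data under random mating).

Two estimators are provided:

* :func:`estimate_ne_unlinked` — contemporary Ne from between-chromosome
  (or all) pairs, with the random-mating sample-size bias correction and the
  quadratic inversion of the drift-LD expectation, plus delete-one-individual
  jackknife confidence intervals.
* :func:`estimate_ne_trajectory` — a step trajectory of Ne over past
  generations from within-chromosome pairs binned by recombination fraction,
  inverting ``E[r^2] = 1/(1 + 4Nc)`` per bin with time reference
  ``t = 1/(2c)`` generations ago.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from ._rng import rng_from
from .errors import NeldError, TooFewSnpPairsError
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

UNLINKED = "unlinked"
LINKED_BINNED = "linked_binned"
ALL = "all"

# largest pair set enumerated exhaustively before switching to seeded
# rejection sampling
_ENUM_LIMIT = 5_000_000
# per-pair chunk size for the gather kernel (bounds peak memory)
_CHUNK = 200_000


def haldane_c(d) -> float | np.ndarray:
    """Recombination fraction for a genetic distance ``d`` in Morgans.

    ``c = 0.5 * (1 - exp(-2 d))``; 0 at d=0, asymptote 0.5.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise NeldError("genetic distance must be non-negative")
    c = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(c) if c.ndim == 0 else c


def default_bin_edges(n_bins: int = 12, c_min: float = 0.001) -> np.ndarray:
    """Log-spaced recombination-fraction bin edges over [c_min, 0.5]."""
    return np.geomspace(c_min, 0.5, n_bins + 1)


@dataclass
class PairPolicy:
    """Which locus pairs enter the LD summary, and caps on their number."""

    mode: str = UNLINKED
    bin_edges: np.ndarray | None = None
    max_pairs_per_bin: int = 50_000
    min_pairs_per_bin: int = 100
    min_pair_s: int = 10
    max_locus_missing: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (UNLINKED, LINKED_BINNED, ALL):
            raise NeldError(f"unknown pair policy mode: {self.mode!r}")
        if self.bin_edges is None:
            self.bin_edges = default_bin_edges()
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.bin_edges.size < 2 or np.any(np.diff(self.bin_edges) <= 0):
            raise NeldError("bin edges must be strictly increasing")
        if not math.isclose(self.bin_edges[-1], 0.5):
            raise NeldError("last bin edge must be 0.5")
        if self.bin_edges[0] <= 0:
            raise NeldError("bin edges must lie in (0, 0.5]")


@dataclass
class PairClassStats:
    """Mean r^2 and bookkeeping for one pair class (or distance bin)."""

    label: str
    mean_r2: float
    s_harmonic: float
    n_pairs: int
    n_skipped: int
    c_mean: float | None = None


@dataclass
class LDSummary:
    classes: list[PairClassStats]
    n_loci_used: int
    n_loci_excluded: int

    def get(self, label: str) -> PairClassStats:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass
class NeEstimate:
    point: float
    ci_low: float
    ci_high: float
    method: str
    generations_ago: float
    n_pairs: int
    s_tilde: float
    r2_mean: float
    r2_prime: float
    flags: set[str] = field(default_factory=set)
    correction_divisor: float | None = None

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.point)


@dataclass
class TrajectoryPoint:
    t: float
    ne: float
    c_mean: float
    n_pairs: int
    r2_mean: float
    s_tilde: float


@dataclass
class NeTrajectory:
    points: list[TrajectoryPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# sampling-bias correction and inversions


def expected_sample_r2(s_tilde: float) -> float:
    """Expected r^2 from finite sampling alone (random-mating calibration).

    ``1/S + 3.19/S^2`` for harmonic sample size S >= 30, else
    ``0.0018 + 0.907/S + 4.44/S^2``.
    """
    s = float(s_tilde)
    if s < 2:
        raise NeldError("sample size must be >= 2")
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def invert_unlinked_r2(r2_prime: float, s_tilde: float) -> tuple[float, set[str]]:
    """Ne from drift r^2 (sampling component removed) among unlinked pairs.

    For S >= 30 solves ``r2' = 1/(3N) - 0.69/N^2``; for S < 30 solves
    ``r2' = 0.308/N - 0.52/N^2`` — the random-mating quadratics matching
    :func:`expected_sample_r2`.  Returns ``(+inf, flags)`` when ``r2' <= 0``
    (no drift signal above the sampling floor).  When ``r2'`` exceeds the
    quadratic's maximum (negative discriminant) the drift LD is stronger
    than any Ne the calibration can resolve; the vertex Ne (the smallest
    invertible value, ~4.1) is returned with a ``saturated_low`` flag so
    that extreme mixture/drift LD reads as a very small Ne, not as infinity.
    """
    flags: set[str] = set()
    if r2_prime <= 0:
        flags.update({"infinite", "negative_r2_prime"})
        return math.inf, flags
    if s_tilde >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2_prime
        if disc < 0:
            flags.add("saturated_low")
            return 2.0 * 0.69 * 3.0, flags
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_prime), flags
    disc = 0.308**2 - 2.08 * r2_prime
    if disc < 0:
        flags.add("saturated_low")
        return 2.0 * 0.52 / 0.308, flags
    return (0.308 + math.sqrt(disc)) / (2.0 * r2_prime), flags


def sved_ne(r2_prime: float, c: float) -> float:
    """Invert the Sved relation ``E[r^2] = 1/(1 + 4Nc)`` for Ne."""
    if not 0 < c <= 0.5:
        raise NeldError("recombination fraction must be in (0, 0.5]")
    if r2_prime <= 0:
        return math.inf
    return (1.0 / r2_prime - 1.0) / (4.0 * c)


# ---------------------------------------------------------------------------
# pair enumeration


def _eligible_loci(G: GenotypeMatrix, policy: PairPolicy) -> np.ndarray:
    miss_frac = G.missing_mask().mean(axis=0)
    ok = (~G.monomorphic_mask()) & (miss_frac <= policy.max_locus_missing)
    n_excl = int((~ok).sum())
    if n_excl:
        log.info("excluding %d monomorphic or missing-heavy loci before pairing", n_excl)
    return np.flatnonzero(ok)


def _enumerate_cross(chrom: np.ndarray, rng: np.random.Generator, cap: int):
    """Index pairs on different chromosomes, capped by seeded subsampling."""
    n = chrom.size
    total = n * (n - 1) // 2
    if total <= _ENUM_LIMIT:
        iu, ju = np.triu_indices(n, k=1)
        keep = chrom[iu] != chrom[ju]
        iu, ju = iu[keep], ju[keep]
        if iu.size > cap:
            sel = rng.choice(iu.size, size=cap, replace=False)
            sel.sort()
            iu, ju = iu[sel], ju[sel]
        return iu, ju
    # rejection sampling for very large panels
    want = cap
    seen: set[tuple[int, int]] = set()
    out_i, out_j = [], []
    attempts = 0
    while len(out_i) < want and attempts < 50:
        attempts += 1
        a = rng.integers(0, n, size=2 * want)
        b = rng.integers(0, n, size=2 * want)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keep = (lo != hi) & (chrom[lo] != chrom[hi])
        for i, j in zip(lo[keep], hi[keep]):
            key = (int(i), int(j))
            if key not in seen:
                seen.add(key)
                out_i.append(key[0])
                out_j.append(key[1])
                if len(out_i) >= want:
                    break
    return np.asarray(out_i, dtype=np.int64), np.asarray(out_j, dtype=np.int64)


def _enumerate_all(chrom: np.ndarray, rng: np.random.Generator, cap: int):
    n = chrom.size
    total = n * (n - 1) // 2
    if total <= _ENUM_LIMIT:
        iu, ju = np.triu_indices(n, k=1)
        if iu.size > cap:
            sel = rng.choice(iu.size, size=cap, replace=False)
            sel.sort()
            iu, ju = iu[sel], ju[sel]
        return iu, ju
    want = cap
    seen: set[tuple[int, int]] = set()
    out_i, out_j = [], []
    attempts = 0
    while len(out_i) < want and attempts < 50:
        attempts += 1
        a = rng.integers(0, n, size=2 * want)
        b = rng.integers(0, n, size=2 * want)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keep = lo != hi
        for i, j in zip(lo[keep], hi[keep]):
            key = (int(i), int(j))
            if key not in seen:
                seen.add(key)
                out_i.append(key[0])
                out_j.append(key[1])
                if len(out_i) >= want:
                    break
    return np.asarray(out_i, dtype=np.int64), np.asarray(out_j, dtype=np.int64)


def _enumerate_within(chrom: np.ndarray, gpos: np.ndarray):
    """All within-chromosome pairs with their recombination fractions."""
    iu_all, ju_all, c_all = [], [], []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        if idx.size * (idx.size - 1) // 2 > _ENUM_LIMIT:
            raise NeldError(
                f"chromosome {c}: too many within-chromosome pairs to enumerate; "
                "thin the panel first"
            )
        a, b = np.triu_indices(idx.size, k=1)
        iu, ju = idx[a], idx[b]
        d = np.abs(gpos[ju] - gpos[iu])
        iu_all.append(iu)
        ju_all.append(ju)
        c_all.append(haldane_c(d))
    if not iu_all:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    return np.concatenate(iu_all), np.concatenate(ju_all), np.concatenate(c_all)


# ---------------------------------------------------------------------------
# r^2 kernel


def _pair_r2(dosages: np.ndarray, iu: np.ndarray, ju: np.ndarray, min_pair_s: int):
    """Composite r^2 per pair over pairwise-complete individuals.

    Returns ``(r2, n_complete, valid)`` where ``valid`` marks pairs with at
    least ``min_pair_s`` complete individuals and non-zero variance at both
    loci.  Invalid pairs carry ``nan`` r^2.
    """
    P = iu.size
    r2 = np.full(P, np.nan)
    ncomp = np.zeros(P, dtype=np.int64)
    valid = np.zeros(P, dtype=bool)
    for start in range(0, P, _CHUNK):
        sl = slice(start, min(start + _CHUNK, P))
        a = dosages[:, iu[sl]]
        b = dosages[:, ju[sl]]
        v = (a != MISSING) & (b != MISSING)
        xa = np.where(v, a, 0).astype(np.float64)
        xb = np.where(v, b, 0).astype(np.float64)
        n = v.sum(axis=0).astype(np.float64)
        sx = xa.sum(axis=0)
        sy = xb.sum(axis=0)
        sxx = (xa * xa).sum(axis=0)
        syy = (xb * xb).sum(axis=0)
        sxy = (xa * xb).sum(axis=0)
        num = n * sxy - sx * sy
        denx = n * sxx - sx * sx
        deny = n * syy - sy * sy
        ok = (n >= min_pair_s) & (denx > 0) & (deny > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_chunk = np.where(ok, (num * num) / np.where(ok, denx * deny, 1.0), np.nan)
        r2[sl] = r2_chunk
        ncomp[sl] = n.astype(np.int64)
        valid[sl] = ok
    return r2, ncomp, valid


def _summarize(r2, ncomp, valid) -> tuple[float, float, int, int]:
    n_pairs = int(valid.sum())
    n_skipped = int(valid.size - n_pairs)
    if n_pairs == 0:
        return math.nan, math.nan, 0, n_skipped
    mean_r2 = float(r2[valid].mean())
    s_harm = float(n_pairs / (1.0 / ncomp[valid]).sum())
    return mean_r2, s_harm, n_pairs, n_skipped


def pairwise_r2(G: GenotypeMatrix, policy: PairPolicy | None = None) -> LDSummary:
    """Mean composite r^2 per pair class under ``policy``.

    Between-chromosome pairs are the ``unlinked`` class (c = 0.5); the
    ``linked_binned`` mode bins within-chromosome pairs by Haldane
    recombination fraction.  Pairs with fewer than ``min_pair_s``
    pairwise-complete individuals or zero dosage variance are skipped and
    counted.
    """
    policy = policy or PairPolicy()
    if G.n_individuals < 2:
        raise NeldError("need at least 2 individuals")
    elig = _eligible_loci(G, policy)
    n_excl = G.n_loci - elig.size
    if elig.size < 2:
        raise TooFewSnpPairsError(
            f"too few SNP pairs: only {elig.size} usable loci after filtering"
        )
    dos = G.dosages[:, elig]
    chrom = G.map.chrom_id[elig]
    gpos = G.map.genetic_pos[elig]
    rng = rng_from(policy.seed, "pair-subsample")

    classes: list[PairClassStats] = []
    if policy.mode in (UNLINKED, ALL):
        if policy.mode == UNLINKED:
            iu, ju = _enumerate_cross(chrom, rng, policy.max_pairs_per_bin)
            label = "unlinked"
        else:
            iu, ju = _enumerate_all(chrom, rng, policy.max_pairs_per_bin)
            label = "all"
        if iu.size == 0:
            raise TooFewSnpPairsError(f"too few SNP pairs in class '{label}'")
        r2, ncomp, valid = _pair_r2(dos, iu, ju, policy.min_pair_s)
        mean_r2, s_harm, n_pairs, n_skip = _summarize(r2, ncomp, valid)
        if n_pairs == 0:
            raise TooFewSnpPairsError(
                f"too few SNP pairs in class '{label}': all {n_skip} candidates skipped"
            )
        classes.append(PairClassStats(label, mean_r2, s_harm, n_pairs, n_skip, c_mean=0.5))
    else:  # LINKED_BINNED
        iu, ju, cvals = _enumerate_within(chrom, gpos)
        if iu.size == 0:
            raise TooFewSnpPairsError("too few SNP pairs: no within-chromosome pairs")
        edges = policy.bin_edges
        which = np.digitize(cvals, edges[1:-1], right=False)
        in_range = cvals >= edges[0]
        any_bin = False
        for b in range(edges.size - 1):
            sel = np.flatnonzero((which == b) & in_range)
            if sel.size > policy.max_pairs_per_bin:
                take = rng.choice(sel.size, size=policy.max_pairs_per_bin, replace=False)
                take.sort()
                sel = sel[take]
            label = f"c[{edges[b]:.4g},{edges[b + 1]:.4g})"
            if sel.size == 0:
                classes.append(PairClassStats(label, math.nan, math.nan, 0, 0, c_mean=None))
                continue
            r2, ncomp, valid = _pair_r2(dos, iu[sel], ju[sel], policy.min_pair_s)
            mean_r2, s_harm, n_pairs, n_skip = _summarize(r2, ncomp, valid)
            c_mean = float(cvals[sel][valid].mean()) if n_pairs else None
            classes.append(PairClassStats(label, mean_r2, s_harm, n_pairs, n_skip, c_mean))
            any_bin = any_bin or n_pairs > 0
        if not any_bin:
            raise TooFewSnpPairsError("too few SNP pairs: all recombination bins empty")
    return LDSummary(classes=classes, n_loci_used=int(elig.size), n_loci_excluded=n_excl)


# ---------------------------------------------------------------------------
# Ne estimation


def _z(conf: float) -> float:
    return float(_sps.norm.ppf(0.5 + conf / 2.0))


def estimate_ne_unlinked(
    G: GenotypeMatrix,
    policy: PairPolicy | None = None,
    compute_ci: bool = True,
    conf: float = 0.95,
) -> NeEstimate:
    """Contemporary Ne from unlinked (or all) locus pairs.

    Point estimate: ``r2' = mean r^2 - E_samp(S~)`` inverted through the
    random-mating quadratic (:func:`invert_unlinked_r2`).  Confidence
    interval: delete-one jackknife over individuals with a normal
    approximation on ``r2'``, endpoints transformed through the inversion;
    a non-invertible endpoint maps to +inf.
    """
    policy = policy or PairPolicy()
    if policy.mode == LINKED_BINNED:
        raise NeldError("estimate_ne_unlinked needs an UNLINKED or ALL pair policy")
    elig = _eligible_loci(G, policy)
    if elig.size < 2:
        raise TooFewSnpPairsError(
            f"too few SNP pairs: only {elig.size} usable loci after filtering"
        )
    dos = G.dosages[:, elig]
    chrom = G.map.chrom_id[elig]
    rng = rng_from(policy.seed, "pair-subsample")
    if policy.mode == UNLINKED:
        iu, ju = _enumerate_cross(chrom, rng, policy.max_pairs_per_bin)
        label = "unlinked"
    else:
        iu, ju = _enumerate_all(chrom, rng, policy.max_pairs_per_bin)
        label = "all"
    if iu.size == 0:
        raise TooFewSnpPairsError(f"too few SNP pairs in class '{label}'")

    S = G.n_individuals
    # per-individual contributions kept for the incremental jackknife
    a = dos[:, iu]
    b = dos[:, ju]
    v = (a != MISSING) & (b != MISSING)
    xa = np.where(v, a, 0).astype(np.float64)
    xb = np.where(v, b, 0).astype(np.float64)

    def stats_excluding(i: int | None):
        if i is None:
            n = v.sum(axis=0).astype(np.float64)
            sx, sy = xa.sum(axis=0), xb.sum(axis=0)
            sxx = (xa * xa).sum(axis=0)
            syy = (xb * xb).sum(axis=0)
            sxy = (xa * xb).sum(axis=0)
        else:
            n = (v.sum(axis=0) - v[i]).astype(np.float64)
            sx, sy = xa.sum(axis=0) - xa[i], xb.sum(axis=0) - xb[i]
            sxx = (xa * xa).sum(axis=0) - xa[i] * xa[i]
            syy = (xb * xb).sum(axis=0) - xb[i] * xb[i]
            sxy = (xa * xb).sum(axis=0) - xa[i] * xb[i]
        num = n * sxy - sx * sy
        denx = n * sxx - sx * sx
        deny = n * syy - sy * sy
        ok = (n >= policy.min_pair_s) & (denx > 0) & (deny > 0)
        if not ok.any():
            return math.nan, math.nan, 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (num[ok] ** 2) / (denx[ok] * deny[ok])
        mean_r2 = float(r2.mean())
        s_harm = float(ok.sum() / (1.0 / n[ok]).sum())
        return mean_r2, s_harm, int(ok.sum())

    mean_r2, s_tilde, n_pairs = stats_excluding(None)
    if n_pairs == 0:
        raise TooFewSnpPairsError(
            f"too few SNP pairs in class '{label}': all candidates skipped"
        )
    if s_tilde < 4:
        raise NeldError(f"harmonic mean sample size {s_tilde:.2f} < 4: too few samples")
    r2_prime = mean_r2 - expected_sample_r2(s_tilde)
    point, flags = invert_unlinked_r2(r2_prime, s_tilde)

    ci_low, ci_high = math.nan, math.nan
    if compute_ci:
        theta = []
        for i in range(S):
            m_i, s_i, np_i = stats_excluding(i)
            if np_i == 0 or s_i < 2:
                continue
            theta.append(m_i - expected_sample_r2(s_i))
        theta = np.asarray(theta)
        if theta.size >= 2:
            k = theta.size
            var_jk = (k - 1) / k * ((theta - theta.mean()) ** 2).sum()
            se = math.sqrt(var_jk)
            z = _z(conf)
            r2p_lo, r2p_hi = r2_prime - z * se, r2_prime + z * se
            # higher drift r^2 -> smaller Ne
            ci_low, _ = invert_unlinked_r2(r2p_hi, s_tilde)
            ci_high, _ = invert_unlinked_r2(r2p_lo, s_tilde)
            if ci_low > point:  # both endpoints non-invertible
                ci_low = point
        else:
            flags.add("jackknife_failed")
            ci_low, ci_high = math.nan, math.nan

    return NeEstimate(
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        method=f"ld-{label}",
        generations_ago=1.0,
        n_pairs=n_pairs,
        s_tilde=s_tilde,
        r2_mean=mean_r2,
        r2_prime=r2_prime,
        flags=flags,
    )


def estimate_ne_trajectory(G: GenotypeMatrix, policy: PairPolicy | None = None) -> NeTrajectory:
    """Recent-history Ne trajectory from distance-binned within-chromosome LD.

    Per retained bin ``b``: ``Ne_b = (1/r2'_b - 1) / (4 c_b)`` and
    ``t_b = 1/(2 c_b)`` generations ago; bins with fewer than
    ``min_pairs_per_bin`` pairs are dropped with a warning.
    """
    if policy is None:
        policy = PairPolicy(mode=LINKED_BINNED)
    if policy.mode != LINKED_BINNED:
        raise NeldError("estimate_ne_trajectory needs a LINKED_BINNED pair policy")
    summary = pairwise_r2(G, policy)
    points: list[TrajectoryPoint] = []
    for cls in summary.classes:
        if cls.n_pairs < policy.min_pairs_per_bin or cls.c_mean is None:
            if cls.n_pairs:
                log.warning(
                    "dropping bin %s with %d < %d pairs",
                    cls.label,
                    cls.n_pairs,
                    policy.min_pairs_per_bin,
                )
            continue
        r2_prime = cls.mean_r2 - expected_sample_r2(cls.s_harmonic)
        ne = sved_ne(r2_prime, cls.c_mean) if r2_prime > 0 else math.inf
        points.append(
            TrajectoryPoint(
                t=1.0 / (2.0 * cls.c_mean),
                ne=ne,
                c_mean=cls.c_mean,
                n_pairs=cls.n_pairs,
                r2_mean=cls.mean_r2,
                s_tilde=cls.s_harmonic,
            )
        )
    if not points:
        raise TooFewSnpPairsError("too few SNP pairs: no bin met the minimum pair count")
    points.sort(key=lambda p: p.t)
    return NeTrajectory(points=points)
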