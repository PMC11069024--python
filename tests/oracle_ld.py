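"""Independent brute-force oracle for the LD estimator chain.

Deliberately naive: explicit Python loops over locus pairs, r^2 via
scipy.stats.pearsonr on pairwise-complete lists, harmonic means via the
statistics module, and the quadratic drift-LD inversions solved numerically
with brentq instead of the closed form.  Written before the vectorized
implementation and kept independent of it.
"""

from __future__ import annotations

import math
import statistics

from scipy.optimize import brentq
from scipy.stats import pearsonr

MISSING = -1


def eligible_loci(dosages, max_locus_missing=0.5):
    n_ind = len(dosages)
    n_loci = len(dosages[0])
    keep = []
    for l in range(n_loci):
        col = [dosages[i][l] for i in range(n_ind)]
        called = [d for d in col if d != MISSING]
        if not called:
            continue
        if sum(1 for d in col if d == MISSING) / n_ind > max_locus_missing:
            continue
        alt = sum(called)
        copies = 2 * len(called)
        if alt == 0 or alt == copies:
            continue
        keep.append(l)
    return keep


def pair_r2(dosages, i_locus, j_locus, rows=None, min_pair_s=10):
    """r^2 over pairwise-complete individuals or None if the pair is skipped."""
    if rows is None:
        rows = range(len(dosages))
    xs, ys = [], []
    for i in rows:
        a, b = dosages[i][i_locus], dosages[i][j_locus]
        if a != MISSING and b != MISSING:
            xs.append(a)
            ys.append(b)
    n = len(xs)
    if n < min_pair_s:
        return None, n
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return None, n
    r, _ = pearsonr(xs, ys)
    return r * r, n


def unlinked_pairs(chrom):
    out = []
    for i in range(len(chrom)):
        for j in range(i + 1, len(chrom)):
            if chrom[i] != chrom[j]:
                out.append((i, j))
    return out


def all_pairs(chrom):
    return [(i, j) for i in range(len(chrom)) for j in range(i + 1, len(chrom))]


def mean_r2_and_harmonic_s(dosages, pairs, rows=None, min_pair_s=10):
    r2s, ns = [], []
    for i, j in pairs:
        r2, n = pair_r2(dosages, i, j, rows=rows, min_pair_s=min_pair_s)
        if r2 is not None:
            r2s.append(r2)
            ns.append(n)
    if not r2s:
        return None, None, 0
    return (
        sum(r2s) / len(r2s),
        statistics.harmonic_mean(ns),
        len(r2s),
    )


def expected_sample_r2(s):
    if s >= 30:
        return 1.0 / s + 3.19 / (s * s)
    return 0.0018 + 0.907 / s + 4.44 / (s * s)


def invert(r2_prime, s):
    """Numerical inversion of the drift-LD expectation (larger root)."""
    if r2_prime <= 0:
        return math.inf
    if s >= 30:
        f = lambda N: 1.0 / (3.0 * N) - 0.69 / N**2 - r2_prime
        n_peak = 2 * 0.69 * 3.0
    else:
        f = lambda N: 0.308 / N - 0.52 / N**2 - r2_prime
        n_peak = 2 * 0.52 / 0.308
    if f(n_peak) < 0:
        # drift LD beyond the calibration's range: smallest resolvable Ne
        return n_peak
    return brentq(f, n_peak, 1e15, xtol=1e-12, rtol=8.9e-16, maxiter=500)


def estimate_unlinked(dosages, chrom, mode="unlinked", min_pair_s=10,
                      max_locus_missing=0.5, conf=0.95):
    """Full chain: eligibility, pairing, r2', Ne, delete-one jackknife CI."""
    keep = eligible_loci(dosages, max_locus_missing)
    sub = [[row[l] for l in keep] for row in dosages]
    sub_chrom = [chrom[l] for l in keep]
    pairs = unlinked_pairs(sub_chrom) if mode == "unlinked" else all_pairs(sub_chrom)
    mean_r2, s_tilde, n_pairs = mean_r2_and_harmonic_s(sub, pairs, min_pair_s=min_pair_s)
    assert mean_r2 is not None, "oracle: no valid pairs"
    r2_prime = mean_r2 - expected_sample_r2(s_tilde)
    point = invert(r2_prime, s_tilde)

    n_ind = len(sub)
    thetas = []
    for drop in range(n_ind):
        rows = [i for i in range(n_ind) if i != drop]
        m, s, k = mean_r2_and_harmonic_s(sub, pairs, rows=rows, min_pair_s=min_pair_s)
        if m is None or s < 2:
            continue
        thetas.append(m - expected_sample_r2(s))
    k = len(thetas)
    mean_t = sum(thetas) / k
    var_jk = (k - 1) / k * sum((t - mean_t) ** 2 for t in thetas)
    se = math.sqrt(var_jk)
    z = statistics.NormalDist().inv_cdf(0.5 + conf / 2.0)
    ci_low = invert(r2_prime + z * se, s_tilde)
    ci_high = invert(r2_prime - z * se, s_tilde)
    if ci_low > point:
        ci_low = point
    return {
        "mean_r2": mean_r2,
        "s_tilde": s_tilde,
        "n_pairs": n_pairs,
        "r2_prime": r2_prime,
        "point": point,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "jackknife_se": se,
    }


def quantile_type7(values, q):
    """Sort-and-interpolate quantile (R type 7), written from the definition."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
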