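"""The five robustness experiment designs and replicate summarization.

Each design perturbs a base dataset (or a fresh simulation per replicate)
at an ordered ladder of factor levels, estimates Ne per replicate, and
summarizes each level with the geometric mean of the finite estimates and a
95% percentile interval across replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._rng import child_seed
from .errors import InvalidConfigError, NeldError
from .ldcore import (
    LINKED_BINNED,
    NeEstimate,
    PairPolicy,
    estimate_ne_trajectory,
    estimate_ne_unlinked,
)
from .filters import exclude_singletons
from .matrix import GenotypeMatrix
from .simdata import (
    SimConfig,
    SimulatedPopulation,
    downsample_loci,
    fragment_map,
    inject_missing,
    sample_individuals,
    simulate_population,
    stratify_by_q,
)

log = logging.getLogger(__name__)

MISSING_DATA = "MISSING_DATA"
SNP_TITRATION = "SNP_TITRATION"
SAMPLE_SIZE = "SAMPLE_SIZE"
ADMIXTURE_GRADIENT = "ADMIXTURE_GRADIENT"
FRAGMENTATION = "FRAGMENTATION"
POOLED = "POOLED"

_KINDS = (MISSING_DATA, SNP_TITRATION, SAMPLE_SIZE, ADMIXTURE_GRADIENT, FRAGMENTATION)


def geometric_mean_ci(values, conf: float = 0.95) -> tuple[float, float, float]:
    """``exp(mean(log x))`` with empirical percentile bounds.

    Infinite values are excluded (callers count them separately); quantiles
    use linear interpolation on the sorted finite values (type-7 rule).
    """
    vals = np.asarray(values, dtype=np.float64)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise NeldError("geometric mean undefined: no finite values")
    if np.any(finite <= 0):
        raise NeldError("geometric mean requires positive values")
    gmean = float(np.exp(np.mean(np.log(finite))))
    alpha = (1.0 - conf) / 2.0
    low = float(np.quantile(finite, alpha, method="linear"))
    high = float(np.quantile(finite, 1.0 - alpha, method="linear"))
    return gmean, low, high


@dataclass
class ExperimentDesign:
    kind: str
    levels: list
    base: GenotypeMatrix | SimulatedPopulation | SimConfig = None
    n_replicates: int = 50
    estimator: str = "unlinked"  # "unlinked" | "trajectory"
    policy: PairPolicy | None = None
    exclude_singleton_loci: bool = True
    compute_ci: bool = False
    deme: str = "A"
    standardized_sample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidConfigError(f"unknown experiment kind: {self.kind!r}")
        if len(self.levels) < 2:
            raise InvalidConfigError("an experiment needs at least 2 levels")
        if self.n_replicates < 2:
            raise InvalidConfigError("n_replicates must be >= 2")
        if self.estimator not in ("unlinked", "trajectory"):
            raise InvalidConfigError("estimator must be 'unlinked' or 'trajectory'")
        if self.base is None:
            raise InvalidConfigError("an experiment needs a base input")


@dataclass
class LevelSummary:
    level: Any
    gmean: float | None
    ci_low: float | None
    ci_high: float | None
    n_finite: int
    n_infinite: int
    failed: bool = False
    reason: str | None = None


@dataclass
class ExperimentResult:
    design_kind: str
    table: pd.DataFrame  # long format: level, replicate, estimate, ci, flags
    summaries: list[LevelSummary]
    truth: list[tuple[int, int]] | None = None

    def summary_for(self, level) -> LevelSummary:
        for s in self.summaries:
            if s.level == level:
                return s
        raise KeyError(level)


def _scalar_estimate(G: GenotypeMatrix, design: ExperimentDesign, seed: int) -> NeEstimate:
    policy = design.policy
    if design.estimator == "trajectory":
        policy = policy or PairPolicy(mode=LINKED_BINNED)
        traj = estimate_ne_trajectory(G, policy)
        # most recent point (largest c bin) as the per-replicate scalar
        pt = traj.points[0]
        return NeEstimate(
            point=pt.ne,
            ci_low=math.nan,
            ci_high=math.nan,
            method="ld-trajectory-recent",
            generations_ago=pt.t,
            n_pairs=pt.n_pairs,
            s_tilde=pt.s_tilde,
            r2_mean=pt.r2_mean,
            r2_prime=pt.r2_mean,
            flags=set() if math.isfinite(pt.ne) else {"infinite"},
        )
    if policy is None:
        policy = PairPolicy()
    # per-replicate pair subsampling stream
    policy = PairPolicy(
        mode=policy.mode,
        bin_edges=policy.bin_edges,
        max_pairs_per_bin=policy.max_pairs_per_bin,
        min_pairs_per_bin=policy.min_pairs_per_bin,
        min_pair_s=policy.min_pair_s,
        max_locus_missing=policy.max_locus_missing,
        seed=seed,
    )
    return estimate_ne_unlinked(G, policy, compute_ci=design.compute_ci)


def _base_matrix(design: ExperimentDesign, rep_seed: int) -> GenotypeMatrix:
    base = design.base
    if isinstance(base, SimConfig):
        cfg_seed = int(child_seed(design.seed, "sim", rep_seed).generate_state(1)[0])
        cfg = SimConfig(**{**base.__dict__, "seed": cfg_seed})
        return simulate_population(cfg).matrix
    if isinstance(base, SimulatedPopulation):
        return base.matrix
    return base


def _perturb(G: GenotypeMatrix, design: ExperimentDesign, level, seed: int) -> GenotypeMatrix:
    if design.kind == MISSING_DATA:
        return inject_missing(G, float(level), seed=seed)
    if design.kind == SNP_TITRATION:
        return downsample_loci(G, int(level), seed=seed)
    if design.kind == SAMPLE_SIZE:
        return sample_individuals(G, int(level), seed=seed)
    if design.kind == ADMIXTURE_GRADIENT:
        size = design.standardized_sample_size
        if size is None:
            raise NeldError("standardized sample size not resolved")
        sub = G if level == POOLED else stratify_by_q(G, float(level), design.deme)
        return sample_individuals(sub, size, seed=seed)
    if design.kind == FRAGMENTATION:
        out = G.copy()
        out.map = fragment_map(G.map, int(level))
        return out
    raise NeldError(design.kind)


def _resolve_standardized_size(design: ExperimentDesign, G: GenotypeMatrix) -> int:
    """Smallest Q-value subset size across the design's threshold levels."""
    if design.standardized_sample_size is not None:
        return design.standardized_sample_size
    sizes = []
    for level in design.levels:
        if level == POOLED:
            continue
        try:
            sizes.append(stratify_by_q(G, float(level), design.deme).n_individuals)
        except NeldError:
            sizes.append(0)
    size = min((s for s in sizes if s > 0), default=0)
    if size == 0:
        raise NeldError("every Q-value subset is empty")
    return size


def run_experiment(design: ExperimentDesign) -> ExperimentResult:
    """Run ``n_replicates`` perturbation+estimation rounds per level.

    Seeds are derived per (level, replicate) from the design seed, so a rerun
    of the same design is bit-identical and replicates are independent.
    Levels whose perturbation is infeasible are marked failed and the run
    continues.
    """
    rows = []
    summaries: list[LevelSummary] = []
    truth = None
    if isinstance(design.base, SimulatedPopulation):
        truth = design.base.true_ne_trajectory

    std_size_cache: dict[int, int] = {}
    sim_cache: dict[int, GenotypeMatrix] = {}
    for li, level in enumerate(design.levels):
        estimates: list[float] = []
        n_inf = 0
        fail_reason = None
        for rep in range(design.n_replicates):
            seed = int(child_seed(design.seed, "exp", li, rep).generate_state(1)[0])
            try:
                # one base population per replicate, shared across levels
                if rep not in sim_cache:
                    sim_cache[rep] = _base_matrix(design, rep)
                G = sim_cache[rep]
                if design.kind == ADMIXTURE_GRADIENT and design.standardized_sample_size is None:
                    if rep not in std_size_cache:
                        std_size_cache[rep] = _resolve_standardized_size(design, G)
                    design_level = std_size_cache[rep]
                    d = _with_size(design, design_level)
                else:
                    d = design
                Gp = _perturb(G, d, level, seed)
                if design.exclude_singleton_loci:
                    Gp = exclude_singletons(Gp)
                est = _scalar_estimate(Gp, design, seed)
            except NeldError as exc:
                fail_reason = str(exc)
                rows.append(
                    {
                        "kind": design.kind,
                        "level": level,
                        "replicate": rep,
                        "estimate": math.nan,
                        "ci_low": math.nan,
                        "ci_high": math.nan,
                        "flags": "failed",
                        "error": fail_reason,
                    }
                )
                continue
            if not est.is_finite:
                n_inf += 1
            estimates.append(est.point)
            rows.append(
                {
                    "kind": design.kind,
                    "level": level,
                    "replicate": rep,
                    "estimate": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "flags": ",".join(sorted(est.flags)),
                    "error": "",
                }
            )
        finite = [e for e in estimates if math.isfinite(e)]
        if finite:
            gmean, lo, hi = geometric_mean_ci(finite)
            summaries.append(LevelSummary(level, gmean, lo, hi, len(finite), n_inf))
        else:
            summaries.append(
                LevelSummary(
                    level,
                    None,
                    None,
                    None,
                    0,
                    n_inf,
                    failed=True,
                    reason=fail_reason or "no finite estimates",
                )
            )
            log.warning("level %r failed: %s", level, fail_reason)
    table = pd.DataFrame(rows)
    return ExperimentResult(
        design_kind=design.kind, table=table, summaries=summaries, truth=truth
    )


def _with_size(design: ExperimentDesign, size: int) -> ExperimentDesign:
    import dataclasses

    return dataclasses.replace(design, standardized_sample_size=size)
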