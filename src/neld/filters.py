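"""Locus filters, the physical-linkage bias correction, missingness
profiling, and a validator for the input limits of map-based LD estimators."""

from __future__ import annotations

import copy
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyPanelError, NeldError
from .ldcore import NeEstimate
from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

#: per-individual missingness beyond which estimates become unreliable
MISSINGNESS_GUIDELINE = 0.20

# validator limits of the map-based (GONE-style) estimator
MAX_CHROMOSOMES = 200
MAX_TOTAL_SNPS = 10_000_000
MAX_SNPS_PER_CHROMOSOME = 1_000_000
SNPS_PER_CHROMOSOME_USED = 50_000
#: default sparse-data warning threshold (avg SNPs per chromosome); the
#: empirical bracket is ~247 failing vs ~670 succeeding
SPARSE_SNPS_PER_CHROMOSOME = 300


def linkage_correction_divisor(chr_count: int) -> float:
    """``y = 0.098 + 0.219 * ln(Chr)`` for haploid chromosome number Chr."""
    if chr_count < 1:
        raise NeldError("chromosome count must be >= 1")
    return 0.098 + 0.219 * math.log(chr_count)


@dataclass
class CorrectionParams:
    chr_count: int
    y: float = field(init=False)

    def __post_init__(self) -> None:
        self.y = linkage_correction_divisor(self.chr_count)


def correct_physical_linkage(ne, chr_count: int):
    """Divide an Ne estimate by the physical-linkage correction divisor.

    Accepts a scalar or an :class:`~neld.ldcore.NeEstimate`; CI endpoints are
    divided too, infinities stay infinite.  Intended for estimates computed
    from ALL-pairs policies (which mix physically linked pairs); estimates
    from an UNLINKED policy already exclude within-chromosome pairs and a
    log note is emitted when they are corrected anyway.
    """
    y = linkage_correction_divisor(chr_count)

    def _div(x: float) -> float:
        if x is None or not math.isfinite(x):
            return x
        return x / y

    if isinstance(ne, NeEstimate):
        if ne.point <= 0 and math.isfinite(ne.point):
            raise NeldError("cannot correct a non-positive estimate")
        if ne.method == "ld-unlinked":
            log.info(
                "applying physical-linkage correction to an UNLINKED-policy "
                "estimate; such estimates already exclude within-chromosome pairs"
            )
        out = copy.copy(ne)
        out.point = _div(ne.point)
        out.ci_low = _div(ne.ci_low)
        out.ci_high = _div(ne.ci_high)
        out.flags = set(ne.flags)
        out.correction_divisor = y
        return out
    ne = float(ne)
    if math.isfinite(ne) and ne <= 0:
        raise NeldError("cannot correct a non-positive estimate")
    return _div(ne)


def display_round(x: float, ndigits: int = 1) -> float:
    """Report-display rounding: round-half-even at one decimal by default."""
    if not math.isfinite(x):
        return x
    return round(x, ndigits)


# ---------------------------------------------------------------------------
# locus filters


def exclude_singletons(G: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci whose minor allele is seen exactly once among non-missing
    gene copies (a heterozygote in a single individual counts as one copy);
    monomorphic loci are removed too."""
    called = G.dosages != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, G.dosages, 0).sum(axis=0)
    minor = np.minimum(alt, copies - alt)
    keep = minor >= 2
    n_singleton = int(((minor == 1)).sum())
    n_mono = int((minor == 0).sum())
    if not keep.any():
        raise EmptyPanelError("singleton/monomorphic filter removed every locus")
    if n_singleton or n_mono:
        log.info(
            "excluded %d singleton and %d monomorphic loci (of %d)",
            n_singleton,
            n_mono,
            G.n_loci,
        )
    return G.subset_loci(np.flatnonzero(keep))


def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Remove loci with minor-allele frequency below ``threshold``.

    MAF filtering upstream of a map-based trajectory estimator is not
    required and may cause a small upward bias; a warning says so whenever a
    positive threshold is used.
    """
    if not 0 <= threshold < 0.5:
        raise NeldError("MAF threshold must be in [0, 0.5)")
    if threshold > 0:
        warnings.warn(
            "MAF filtering is not required for map-based LD Ne estimation and "
            "might cause a small upward bias in the estimates",
            stacklevel=2,
        )
    freq = G.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= threshold if threshold > 0 else (maf > 0)
    keep &= ~np.isnan(maf)
    if not keep.any():
        raise EmptyPanelError(f"MAF filter at {threshold} removed every locus")
    return G.subset_loci(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# missingness profiling


@dataclass
class MissingnessProfile:
    per_individual: np.ndarray
    per_locus: np.ndarray
    mean: float
    median: float
    max: float
    individuals_over_guideline: list[str]

    @property
    def guideline_exceeded(self) -> bool:
        return bool(self.individuals_over_guideline)


def missingness_profile(G: GenotypeMatrix) -> MissingnessProfile:
    """Exact per-individual and per-locus missing fractions plus a check
    against the 20%-per-individual guideline."""
    miss = G.missing_mask()
    per_ind = miss.mean(axis=1)
    over = [G.individual_ids[i] for i in np.flatnonzero(per_ind > MISSINGNESS_GUIDELINE)]
    if over:
        log.warning(
            "%d individuals exceed the %.0f%% missing-data guideline",
            len(over),
            100 * MISSINGNESS_GUIDELINE,
        )
    return MissingnessProfile(
        per_individual=per_ind,
        per_locus=miss.mean(axis=0),
        mean=float(per_ind.mean()),
        median=float(np.median(per_ind)),
        max=float(per_ind.max()) if per_ind.size else 0.0,
        individuals_over_guideline=over,
    )


# ---------------------------------------------------------------------------
# input validation for map-based estimators


@dataclass
class ValidationRule:
    rule_id: str
    severity: str  # "error" | "warning" | "note"
    message: str
    observed: float
    limit: float

    def to_dict(self) -> dict:
        return {
            "rule": self.rule_id,
            "severity": self.severity,
            "message": self.message,
            "observed": self.observed,
            "limit": self.limit,
        }


@dataclass
class ValidationReport:
    rules: list[ValidationRule]

    @property
    def passed(self) -> bool:
        return not self.rules

    @property
    def errors(self) -> list[ValidationRule]:
        return [r for r in self.rules if r.severity == "error"]

    @property
    def warnings(self) -> list[ValidationRule]:
        return [r for r in self.rules if r.severity == "warning"]

    def to_json(self, **kw) -> str:
        return json.dumps([r.to_dict() for r in self.rules], **kw)


def validate_gone_input(
    G: GenotypeMatrix, sparse_threshold: float = SPARSE_SNPS_PER_CHROMOSOME
) -> ValidationReport:
    """Check a dataset against the input limits of a map-based LD estimator:
    at most 200 chromosomes, 10 M SNPs in total and 1 M SNPs per chromosome;
    warn on sparse chromosomes and note when only a 50 K subset per
    chromosome would be used."""
    rules: list[ValidationRule] = []
    per_chrom = G.map.loci_per_chromosome()
    n_chrom = len(per_chrom)
    n_snps = G.n_loci
    if n_chrom > MAX_CHROMOSOMES:
        rules.append(
            ValidationRule(
                "max-chromosomes",
                "error",
                f"{n_chrom} chromosomes exceed the maximum of {MAX_CHROMOSOMES}",
                n_chrom,
                MAX_CHROMOSOMES,
            )
        )
    if n_snps > MAX_TOTAL_SNPS:
        rules.append(
            ValidationRule(
                "max-total-snps",
                "error",
                f"{n_snps} SNPs exceed the maximum of {MAX_TOTAL_SNPS}",
                n_snps,
                MAX_TOTAL_SNPS,
            )
        )
    worst = max(per_chrom.values()) if per_chrom else 0
    if worst > MAX_SNPS_PER_CHROMOSOME:
        rules.append(
            ValidationRule(
                "max-snps-per-chromosome",
                "error",
                f"a chromosome carries {worst} SNPs, above the maximum of "
                f"{MAX_SNPS_PER_CHROMOSOME}",
                worst,
                MAX_SNPS_PER_CHROMOSOME,
            )
        )
    avg = n_snps / n_chrom if n_chrom else 0.0
    if avg < sparse_threshold:
        rules.append(
            ValidationRule(
                "sparse-snps-per-chromosome",
                "warning",
                f"average of {avg:.0f} SNPs per chromosome/scaffold is below "
                f"{sparse_threshold:.0f}; the estimator is likely to fail with "
                "'too few SNPs'",
                avg,
                sparse_threshold,
            )
        )
    if worst > SNPS_PER_CHROMOSOME_USED:
        rules.append(
            ValidationRule(
                "subset-per-chromosome",
                "note",
                f"a chromosome carries {worst} SNPs; only a random subset of "
                f"{SNPS_PER_CHROMOSOME_USED} per chromosome would be used",
                worst,
                SNPS_PER_CHROMOSOME_USED,
            )
        )
    return ValidationReport(rules=rules)
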