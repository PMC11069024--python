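"""Core containers: locus maps and unphased genotype dosage matrices.

Dosages are stored as ``int8`` counts of the alternate allele (0, 1, 2) with
:data:`MISSING` (``-1``) as the missing-genotype sentinel.  Dosage 0 is a valid
homozygote and is never used to encode missingness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NeldError

#: Sentinel for a missing genotype in a dosage matrix.  Never 0.
MISSING: int = -1


@dataclass
class LocusMap:
    """Per-locus chromosome id, physical position and genetic position.

    Parameters
    ----------
    chrom_id
        Integer chromosome (or scaffold) identifiers, ``>= 1``.
    bp
        1-based physical positions.
    genetic_pos
        Genetic position in Morgans from the chromosome start.
    ref_allele, alt_allele
        Allele labels used by the PED writer; default ``A``/``C``.
    chrom_length
        Genetic length (Morgans) of each chromosome.  Defaults to the
        conventional 1 Morgan per chromosome when not given.
    """

    chrom_id: np.ndarray
    bp: np.ndarray
    genetic_pos: np.ndarray
    ref_allele: np.ndarray | None = None
    alt_allele: np.ndarray | None = None
    chrom_length: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.chrom_id = np.asarray(self.chrom_id, dtype=np.int64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)
        n = self.chrom_id.size
        if not (self.bp.size == n and self.genetic_pos.size == n):
            raise NeldError("chrom_id, bp and genetic_pos must have equal length")
        if self.ref_allele is None:
            self.ref_allele = np.full(n, "A", dtype=object)
        else:
            self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        if self.alt_allele is None:
            self.alt_allele = np.full(n, "C", dtype=object)
        else:
            self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.chrom_length is None:
            self.chrom_length = {int(c): 1.0 for c in np.unique(self.chrom_id)}
        self._validate()

    def _validate(self) -> None:
        if self.n_loci == 0:
            return
        if np.any(self.chrom_id < 1):
            raise NeldError("chromosome ids must be >= 1")
        order = np.lexsort((self.bp, self.chrom_id))
        if not np.array_equal(order, np.arange(self.n_loci)):
            raise NeldError("loci must be sorted by (chrom_id, bp)")
        for c in self.chromosomes:
            sel = self.chrom_id == c
            g = self.genetic_pos[sel]
            if np.any(np.diff(g) < 0):
                raise NeldError(
                    f"genetic positions must be non-decreasing within chromosome {c}"
                )
            length = self.chrom_length.get(int(c), 1.0)
            if np.any(g < 0) or np.any(g > length + 1e-9):
                raise NeldError(
                    f"genetic positions on chromosome {c} outside [0, {length}]"
                )

    @property
    def n_loci(self) -> int:
        return int(self.chrom_id.size)

    def __len__(self) -> int:
        return self.n_loci

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome ids, ascending."""
        return np.unique(self.chrom_id)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosomes.size)

    def loci_per_chromosome(self) -> dict[int, int]:
        ids, counts = np.unique(self.chrom_id, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def subset(self, idx: np.ndarray) -> "LocusMap":
        """New map restricted to ``idx`` (kept in given order)."""
        idx = np.asarray(idx)
        return LocusMap(
            chrom_id=self.chrom_id[idx].copy(),
            bp=self.bp[idx].copy(),
            genetic_pos=self.genetic_pos[idx].copy(),
            ref_allele=self.ref_allele[idx].copy(),
            alt_allele=self.alt_allele[idx].copy(),
            chrom_length=dict(self.chrom_length),
        )

    def copy(self) -> "LocusMap":
        return self.subset(np.arange(self.n_loci))


@dataclass
class GenotypeMatrix:
    """Individuals x loci unphased dosage matrix bound to a :class:`LocusMap`.

    ``dosages[i, l]`` counts copies of the alternate allele carried by
    individual ``i`` at locus ``l`` (0, 1, 2) or :data:`MISSING`.
    """

    dosages: np.ndarray
    map: LocusMap
    individual_ids: Sequence[str] | None = None
    deme_labels: np.ndarray | None = None
    q_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise NeldError("dosages must be a 2-D (individuals x loci) array")
        s, l = self.dosages.shape
        if l != self.map.n_loci:
            raise NeldError(
                f"dosage columns ({l}) must equal locus map length ({self.map.n_loci})"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise NeldError("dosages must be in {0, 1, 2, MISSING}")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1}" for i in range(s)]
        else:
            self.individual_ids = list(self.individual_ids)
            if len(self.individual_ids) != s:
                raise NeldError("individual_ids length must equal row count")
        if self.deme_labels is not None:
            self.deme_labels = np.asarray(self.deme_labels, dtype=object)
            if self.deme_labels.size != s:
                raise NeldError("deme_labels length must equal row count")
        if self.q_values is not None:
            self.q_values = np.asarray(self.q_values, dtype=np.float64)
            if self.q_values.size != s:
                raise NeldError("q_values length must equal row count")
            if np.any((self.q_values < 0) | (self.q_values > 1)):
                raise NeldError("q_values must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.dosages.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing gene copies.

        Loci with no called genotypes get ``nan``.
        """
        called = self.dosages != MISSING
        n_copies = 2 * called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_copies > 0, alt / np.maximum(n_copies, 1), np.nan)

    def monomorphic_mask(self) -> np.ndarray:
        """Loci with no polymorphism among the non-missing genotypes.

        Such columns are flagged here and excluded by the LD machinery; they
        are never silently used in r^2 computations.
        """
        freq = self.allele_frequencies()
        return ~((freq > 0) & (freq < 1))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.copy(),
            map=self.map.copy(),
            individual_ids=list(self.individual_ids),
            deme_labels=None if self.deme_labels is None else self.deme_labels.copy(),
            q_values=None if self.q_values is None else self.q_values.copy(),
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx].copy(),
            map=self.map.copy(),
            individual_ids=[self.individual_ids[i] for i in idx],
            deme_labels=None if self.deme_labels is None else self.deme_labels[idx].copy(),
            q_values=None if self.q_values is None else self.q_values[idx].copy(),
        )

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            map=self.map.subset(idx),
            individual_ids=list(self.individual_ids),
            deme_labels=None if self.deme_labels is None else self.deme_labels.copy(),
            q_values=None if self.q_values is None else self.q_values.copy(),
        )

    def replace(self, **changes) -> "GenotypeMatrix":
        return dataclasses.replace(self, **changes)
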