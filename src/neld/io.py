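"""PED/MAP and minimal-VCF genotype I/O plus result serialization.

PED dialect: PLINK-style whitespace text with six leading columns
(family id, individual id, four neutral placeholders), one allele pair per
locus; the missing allele code is ``0`` on both alleles.  The MAP file
carries chromosome id, SNP id, genetic distance in centiMorgans and bp.
Within a locus, allele labels are ordered alphabetically when read back
(ref = first), which round-trips the writer's default ``A``/``C`` labels.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError
from .ldcore import NeEstimate, NeTrajectory
from .matrix import MISSING, GenotypeMatrix, LocusMap

log = logging.getLogger(__name__)

_PED_PLACEHOLDER = ["0", "0", "0", "-9"]
_ALLELE_ALPHABET = {"A", "C", "G", "T", "1", "2"}


def write_ped_map(G: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    m = G.map
    with open(map_path, "w") as fh:
        for l in range(m.n_loci):
            cm = m.genetic_pos[l] * 100.0
            fh.write(f"{m.chrom_id[l]}\tsnp{l + 1}\t{cm:.8g}\t{m.bp[l]}\n")
    ref, alt = m.ref_allele, m.alt_allele
    with open(ped_path, "w") as fh:
        for i in range(G.n_individuals):
            fields = ["FAM1", str(G.individual_ids[i])] + _PED_PLACEHOLDER
            row = G.dosages[i]
            for l in range(G.n_loci):
                d = row[l]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [str(ref[l])] * 2
                elif d == 1:
                    fields += [str(ref[l]), str(alt[l])]
                else:
                    fields += [str(alt[l])] * 2
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read ``<prefix>.ped``/``.map`` back into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    chroms, bps, cms = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                chroms.append(int(parts[0]))
                cms.append(float(parts[2]))
                bps.append(int(parts[3]))
            except ValueError as exc:
                raise ParseError(f"{map_path}:{lineno}: {exc}") from exc
    n_loci = len(chroms)
    if n_loci == 0:
        raise ParseError(f"{map_path}: empty map file")

    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                    f"(6 + 2 x {n_loci} loci), got {len(parts)}"
                )
            alleles = parts[6:]
            bad = set(alleles) - _ALLELE_ALPHABET - {"0"}
            if bad:
                raise ParseError(
                    f"{ped_path}:{lineno}: allele codes {sorted(bad)} outside the "
                    f"declared alphabet"
                )
            ids.append(parts[1])
            allele_rows.append(alleles)
    if not ids:
        raise ParseError(f"{ped_path}: empty ped file")

    arr = np.asarray(allele_rows, dtype=object).reshape(len(ids), n_loci, 2)
    ref = np.full(n_loci, "A", dtype=object)
    alt = np.full(n_loci, "C", dtype=object)
    dosages = np.zeros((len(ids), n_loci), dtype=np.int8)
    n_half_missing = 0
    for l in range(n_loci):
        col = arr[:, l, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise ParseError(f"{ped_path}: locus {l + 1} has >2 alleles: {observed}")
        if observed:
            ref[l] = observed[0]
            alt[l] = observed[1] if len(observed) == 2 else observed[0]
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        n_half_missing += int(((col[:, 0] == "0") ^ (col[:, 1] == "0")).sum())
        dos = (col[:, 0] == alt[l]).astype(np.int8) + (col[:, 1] == alt[l]).astype(np.int8)
        if len(observed) < 2:
            dos[:] = 0  # monomorphic: orientation unknowable, flagged downstream
        dos[miss] = MISSING
        dosages[:, l] = dos
    if n_half_missing:
        log.warning("%d half-missing genotypes recoded as fully missing", n_half_missing)

    order = np.lexsort((bps, chroms))
    chrom_arr = np.asarray(chroms, dtype=np.int64)[order]
    gpos = np.asarray(cms, dtype=np.float64)[order] / 100.0
    lengths = {}
    for c in np.unique(chrom_arr):
        gmax = gpos[chrom_arr == c].max()
        lengths[int(c)] = max(1.0, float(gmax))
    locus_map = LocusMap(
        chrom_id=chrom_arr,
        bp=np.asarray(bps, dtype=np.int64)[order],
        genetic_pos=gpos,
        ref_allele=ref[order],
        alt_allele=alt[order],
        chrom_length=lengths,
    )
    return GenotypeMatrix(dosages=dosages[:, order], map=locus_map, individual_ids=ids)


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read GT fields of a diploid, biallelic VCF into a dosage matrix.

    ``0/0 -> 0``, ``0/1``/``1/0`` (phased or not) ``-> 1``, ``1/1 -> 2``,
    ``./.`` (both alleles missing) ``-> MISSING``.  Multiallelic and
    non-diploid records are skipped and counted; contigs are mapped to
    integer chromosome ids in order of appearance (logged).  Genetic
    positions are synthesized at 1 cM per Mb.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: no samples in VCF")
    contig_map: dict[str, int] = {}
    chroms, bps, refs, alts, dosage_cols = [], [], [], [], []
    n_multi = n_nondiploid = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes
        col = np.empty(len(samples), dtype=np.int8)
        ok = True
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                ok = False
                break
            a, b = alleles
            if a < 0 or b < 0:
                col[i] = MISSING
            else:
                col[i] = int(a > 0) + int(b > 0)
        if not ok:
            n_nondiploid += 1
            continue
        if var.CHROM not in contig_map:
            contig_map[var.CHROM] = len(contig_map) + 1
        chroms.append(contig_map[var.CHROM])
        bps.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dosage_cols.append(col)
    if n_multi or n_nondiploid:
        log.info(
            "skipped %d multiallelic and %d non-diploid records", n_multi, n_nondiploid
        )
    if not dosage_cols:
        raise ParseError(f"{path}: no usable biallelic diploid records")
    log.info("contig mapping: %s", contig_map)

    chrom_arr = np.asarray(chroms, dtype=np.int64)
    bp_arr = np.asarray(bps, dtype=np.int64)
    order = np.lexsort((bp_arr, chrom_arr))
    gpos = np.empty(order.size)
    chrom_sorted = chrom_arr[order]
    bp_sorted = bp_arr[order]
    lengths = {}
    for c in np.unique(chrom_sorted):
        sel = chrom_sorted == c
        g = (bp_sorted[sel] - bp_sorted[sel].min()) / 1e8  # 1 cM per Mb
        gpos[sel] = g
        lengths[int(c)] = max(1.0, float(g.max()))
    locus_map = LocusMap(
        chrom_id=chrom_sorted,
        bp=bp_sorted,
        genetic_pos=gpos,
        ref_allele=np.asarray(refs, dtype=object)[order],
        alt_allele=np.asarray(alts, dtype=object)[order],
        chrom_length=lengths,
    )
    dosages = np.stack(dosage_cols, axis=1)[:, order]
    return GenotypeMatrix(dosages=dosages, map=locus_map, individual_ids=samples)


# ---------------------------------------------------------------------------
# result serialization


def _inf_str(x):
    if isinstance(x, float):
        if math.isinf(x):
            return "Inf"
        if math.isnan(x):
            return "NA"
    return x


def _estimate_record(est: NeEstimate) -> dict:
    return {
        "ne": _inf_str(est.point),
        "ci_low": _inf_str(est.ci_low),
        "ci_high": _inf_str(est.ci_high),
        "method": est.method,
        "generations_ago": est.generations_ago,
        "n_pairs": est.n_pairs,
        "s_tilde": est.s_tilde,
        "r2_mean": est.r2_mean,
        "r2_prime": est.r2_prime,
        "flags": sorted(est.flags),
        "correction_divisor": est.correction_divisor,
    }


def results_to_records(result) -> list[dict]:
    """Flatten an estimate/trajectory/experiment result to plain records."""
    if isinstance(result, NeEstimate):
        return [_estimate_record(result)]
    if isinstance(result, NeTrajectory):
        return [
            {
                "t_generations_ago": p.t,
                "ne": _inf_str(p.ne),
                "c_mean": p.c_mean,
                "n_pairs": p.n_pairs,
                "r2_mean": p.r2_mean,
                "s_tilde": p.s_tilde,
            }
            for p in result.points
        ]
    # ExperimentResult (duck-typed to avoid a circular import)
    if hasattr(result, "table"):
        records = result.table.to_dict(orient="records")
        for r in records:
            for k in ("estimate", "ci_low", "ci_high"):
                r[k] = _inf_str(r[k])
        return records
    if is_dataclass(result):
        return [asdict(result)]
    raise TypeError(f"cannot serialize {type(result).__name__}")


def write_results(result, path: str | Path, fmt: str = "tsv") -> Path:
    """Serialize a result to TSV or JSON; +inf becomes the string ``Inf``."""
    path = Path(path)
    records = results_to_records(result)
    if fmt == "json":
        payload = records[0] if isinstance(result, NeEstimate) else records
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    elif fmt == "tsv":
        if not records:
            path.write_text("")
            return path
        cols = list(records[0].keys())
        lines = ["\t".join(cols)]
        for r in records:
            lines.append("\t".join(_fmt_cell(r.get(c)) for c in cols))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _fmt_cell(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isinf(v):
            return "Inf"
        if math.isnan(v):
            return "NA"
        return f"{v:.10g}"
    if isinstance(v, (list, set, tuple)):
        return ",".join(map(str, v))
    return str(v)


def read_results_tsv(path: str | Path) -> list[dict]:
    """Round-trip reader for :func:`write_results` TSV output."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    cols = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = line.split("\t")
        rec = {}
        for c, v in zip(cols, vals):
            if v == "Inf":
                rec[c] = math.inf
            elif v == "NA":
                rec[c] = None
            else:
                try:
                    rec[c] = float(v) if ("." in v or "e" in v or v.isdigit() or v.lstrip("-").isdigit()) else v
                except ValueError:
                    rec[c] = v
            if isinstance(rec[c], float) and rec[c].is_integer() and c in ("n_pairs", "replicate"):
                rec[c] = int(rec[c])
        out.append(rec)
    return out


def write_truth_table(trajectory: list[tuple[int, int]], path: str | Path) -> Path:
    """True (generation, N) table as TSV."""
    path = Path(path)
    lines = ["generation\ttrue_N"] + [f"{g}\t{n}" for g, n in trajectory]
    path.write_text("\n".join(lines) + "\n")
    return path
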