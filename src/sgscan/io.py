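"""Genotype, candidate and variant-table I/O.

The heterozygosity scan only needs, for every individual at every variant,
whether the genotype is heterozygous, homozygous, or missing.  Diploid calls
are therefore collapsed at load time to three codes: ``HOM`` (two identical
alleles), ``HET`` (two distinct alleles, regardless of which alternate
alleles they are), ``MISSING`` (any uncalled allele).  Phasing is ignored
("0|1" is "0/1" for our purposes).

Coordinates are 1-based base pairs throughout, following VCF; BED output is
converted to 0-based half-open on write.

Two input formats are supported:

* VCF 4.x, plain or gzipped, read with :mod:`cyvcf2`.  Minor allele
  frequencies are computed from the called alleles of the loaded sample.
* A plain TSV genotype dialect for desk-scale fixtures: header row
  ``chrom  pos  id  <sample1> <sample2> ...``; one row per variant with the
  codes 0=HOM, 1=HET, 9=MISSING.  Because the dialect stores het/hom status
  only, MAF is estimated as h/(2(g+h)), i.e. assuming no minor-allele
  homozygotes — adequate for the rare variants the method targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype codes used throughout the package.
HOM: int = 0
HET: int = 1
MISSING: int = 9

_VALID_CODES = (HOM, HET, MISSING)


class DataError(ValueError):
    """Malformed or internally inconsistent input data."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Ordered table of variant sites.

    Variants are stored grouped by chromosome (in order of first appearance)
    with strictly increasing positions within each chromosome and no
    duplicate (chrom, pos) pairs.  ``maf`` is the minor allele frequency in
    the loaded sample, a fraction in [0, 0.5].
    """

    chrom: np.ndarray
    pos: np.ndarray
    vid: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.vid = np.asarray(self.vid, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.vid) == len(self.maf) == n):
            raise ValueError("VariantTable fields have unequal lengths")
        if n and (np.nanmin(self.maf) < 0 or np.nanmax(self.maf) > 0.5):
            raise ValueError("maf outside [0, 0.5]")
        # chromosome blocks: contiguous, positions strictly increasing within
        self._blocks: dict[str, slice] = {}
        if n:
            change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
            bounds = np.concatenate(([0], change, [n]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                c = self.chrom[a]
                if c in self._blocks:
                    raise ValueError(f"chromosome {c!r} occurs in non-contiguous blocks")
                p = self.pos[a:b]
                if np.any(np.diff(p) <= 0):
                    raise ValueError(f"positions not strictly increasing on {c!r}")
                self._blocks[c] = slice(int(a), int(b))

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in table order."""
        return list(self._blocks)

    def block(self, chrom: str) -> slice:
        """Index slice of the variants on ``chrom``."""
        return self._blocks[chrom]

    def subset(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        return VariantTable(self.chrom[idx], self.pos[idx], self.vid[idx], self.maf[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "id": self.vid, "maf": self.maf}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VariantTable":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["pos"].to_numpy(dtype=np.int64),
            df["id"].to_numpy(dtype=object),
            df["maf"].to_numpy(dtype=float),
        )


@dataclass
class GenotypeMatrix:
    """Coded diploid genotypes, individuals x variants."""

    variants: VariantTable
    individuals: list[str]
    codes: np.ndarray  # int8, shape (n_individuals, n_variants)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.individuals = list(self.individuals)
        if self.codes.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.individuals)} individuals, {len(self.variants)} variants)"
            )
        if self.codes.size and not np.isin(self.codes, _VALID_CODES).all():
            raise ValueError("genotype codes must be HOM=0, HET=1 or MISSING=9")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def individual_index(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(self.variants.subset(idx), self.individuals, self.codes[:, idx])


@dataclass
class CandidateSet:
    """Per-individual candidate disease-variant positions (H_max peaks).

    ``positions`` is a list of (chrom, pos) pairs sorted by (chrom, pos);
    ``peak_h`` optionally carries the H_max value of each peak, kept in the
    same order.  ``k`` is the number of candidate positions.
    """

    individual: str
    positions: list[tuple[str, int]]
    peak_h: list[float] | None = None

    def __post_init__(self) -> None:
        pos = [(str(c), int(p)) for c, p in self.positions]
        if self.peak_h is not None:
            if len(self.peak_h) != len(pos):
                raise ValueError("peak_h length != positions length")
            order = sorted(range(len(pos)), key=lambda i: pos[i])
            self.positions = [pos[i] for i in order]
            self.peak_h = [float(self.peak_h[i]) for i in order]
        else:
            self.positions = sorted(pos)

    @property
    def k(self) -> int:
        return len(self.positions)

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted position arrays keyed by chromosome."""
        out: dict[str, list[int]] = {}
        for c, p in self.positions:
            out.setdefault(c, []).append(p)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class FilterReport:
    """Variant counts removed at each filtering step, for logging."""

    n_input: int
    n_monomorphic_removed: int
    n_common_removed: int
    n_retained: int


@dataclass
class CandidateSummary:
    n_individuals: int
    total_k: int
    mean_k: float
    min_k: int
    max_k: int


# ---------------------------------------------------------------------------
# Genotype reading
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF (plain or gzipped) or the TSV dialect.

    ``format`` is ``"vcf"`` or ``"tsv"``; if None it is inferred from the
    file extension.  Unsorted positions are sorted with a warning; duplicate
    (chrom, pos) records keep the first occurrence with a warning; any
    non-diploid genotype raises :class:`DataError` naming the record.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
            format = "vcf"
        elif name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")):
            format = "tsv"
        else:
            raise DataError(f"cannot infer genotype format from file name {path.name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise DataError(f"VCF {path} contains no samples")
    chroms: list[str] = []
    poss: list[int] = []
    vids: list[str] = []
    mafs: list[float] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        gts = var.genotypes
        row = np.empty(len(samples), dtype=np.int8)
        allele_counts: dict[int, int] = {}
        for j, gt in enumerate(gts):
            if len(gt) != 3:  # [a1, a2, phased] for diploid calls
                raise DataError(
                    f"non-diploid genotype in record {var.CHROM}:{var.POS} "
                    f"(sample {samples[j]})"
                )
            a1, a2 = int(gt[0]), int(gt[1])
            if a1 < 0 or a2 < 0:
                row[j] = MISSING
            else:
                row[j] = HOM if a1 == a2 else HET
                allele_counts[a1] = allele_counts.get(a1, 0) + 1
                allele_counts[a2] = allele_counts.get(a2, 0) + 1
        chroms.append(var.CHROM)
        poss.append(int(var.POS))
        vids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        mafs.append(_maf_from_allele_counts(allele_counts))
        rows.append(row)
    vcf.close()
    codes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return _assemble_matrix(
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.asarray(vids, dtype=object),
        np.asarray(mafs, dtype=float),
        samples,
        codes,
    )


def _maf_from_allele_counts(counts: dict[int, int]) -> float:
    total = sum(counts.values())
    if total == 0 or len(counts) <= 1:
        return 0.0
    # minor allele frequency folded to [0, 0.5]; for multi-allelic sites the
    # complement of the modal allele may exceed 0.5, so clip
    return min(1.0 - max(counts.values()) / total, 0.5)


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    except Exception as exc:
        raise DataError(f"cannot parse TSV genotype file {path}: {exc}") from exc
    required = ["chrom", "pos", "id"]
    if list(df.columns[:3]) != required:
        raise DataError(
            f"TSV genotype dialect requires leading columns {required}, "
            f"found {list(df.columns[:3])}"
        )
    samples = [str(c) for c in df.columns[3:]]
    if not samples:
        raise DataError(f"TSV genotype file {path} contains no sample columns")
    codes = df[df.columns[3:]].to_numpy()
    try:
        codes = codes.astype(np.int8)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-integer genotype code in {path}: {exc}") from exc
    if codes.size and not np.isin(codes, _VALID_CODES).all():
        bad = sorted(set(codes.ravel()) - set(_VALID_CODES))
        raise DataError(f"invalid genotype codes {bad} in {path} (expect 0/1/9)")
    h = (codes == HET).sum(axis=1)
    g = (codes == HOM).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(g + h > 0, h / (2.0 * np.maximum(g + h, 1)), 0.0)
    return _assemble_matrix(
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
        df["id"].to_numpy(dtype=object),
        maf,
        samples,
        codes,
    )


def _assemble_matrix(chrom, pos, vid, maf, samples, codes_by_variant) -> GenotypeMatrix:
    """Order variants per chromosome, drop duplicate positions, build matrix.

    ``codes_by_variant`` has shape (n_variants, n_individuals)... transposed
    relative to GenotypeMatrix; chromosomes keep file order of first
    appearance.
    """
    n = len(pos)
    keep_order: list[int] = []
    seen: dict[str, None] = {}
    for c in chrom:
        if c not in seen:
            seen[c] = None
    for c in seen:
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            warnings.warn(f"positions unsorted on chromosome {c}; sorting")
            idx = idx[np.argsort(p, kind="stable")]
            p = pos[idx]
        if np.any(np.diff(p) == 0):
            # stable sort preserved file order within ties -> keep first record
            dup = np.concatenate(([False], np.diff(p) == 0))
            warnings.warn(
                f"{int(dup.sum())} duplicate position(s) on chromosome {c}; "
                "keeping first record"
            )
            idx = idx[~dup]
        keep_order.extend(idx.tolist())
    order = np.asarray(keep_order, dtype=np.int64)
    if n and len(order) == 0:
        raise DataError("no variants left after ordering")
    variants = VariantTable(chrom[order], pos[order], vid[order], maf[order])
    codes = codes_by_variant[order].T if n else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(variants, samples, codes)


# ---------------------------------------------------------------------------
# Genotype writing
# ---------------------------------------------------------------------------


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect (round-trips through ``read_genotypes``)."""
    df = pd.DataFrame(
        {
            "chrom": gm.variants.chrom,
            "pos": gm.variants.pos,
            "id": gm.variants.vid,
        }
    )
    for j, s in enumerate(gm.individuals):
        df[s] = gm.codes[j]
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF rendering of the coded genotypes.

    Because only het/hom status is stored, HOM is rendered as 0/0, HET as
    0/1 and MISSING as ./. against placeholder REF=A, ALT=C alleles.  This
    is a synthetic rendering sufficient for the scan, which never looks at
    alleles, and it round-trips the code matrix through the VCF reader.
    """
    _GT = {HOM: "0/0", HET: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sgscan\n")
        for c in gm.variants.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for i in range(gm.n_variants):
            gts = "\t".join(_GT[int(code)] for code in gm.codes[:, i])
            fh.write(
                f"{gm.variants.chrom[i]}\t{gm.variants.pos[i]}\t{gm.variants.vid[i]}"
                f"\tA\tC\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------


def filter_variants(
    gm: GenotypeMatrix, maf_max: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop monomorphic variants, then common variants with MAF > ``maf_max``.

    The removal is strict (> maf_max); a variant with MAF exactly equal to
    the threshold is retained.  Returns the filtered matrix and a
    :class:`FilterReport` with the counts removed at each step.
    """
    if not 0 < maf_max <= 0.5:
        raise ValueError(f"maf_max must be in (0, 0.5], got {maf_max}")
    maf = gm.variants.maf
    polymorphic = maf > 0
    keep = polymorphic & (maf <= maf_max)
    report = FilterReport(
        n_input=len(maf),
        n_monomorphic_removed=int((~polymorphic).sum()),
        n_common_removed=int((polymorphic & (maf > maf_max)).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise DataError(
            "all variants removed by filtering; review the maf_max threshold "
            f"(maf_max={maf_max}, {report.n_input} input variants)"
        )
    logger.info(
        "variant filter: %d loaded, %d monomorphic removed, %d common (maf > %g) "
        "removed, %d retained",
        report.n_input,
        report.n_monomorphic_removed,
        report.n_common_removed,
        maf_max,
        report.n_retained,
    )
    return gm.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Candidate and variant-table TSV round trips
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = ["individual", "chrom", "pos", "peak_H"]


def write_candidates(candidates: Sequence[CandidateSet], path) -> None:
    """Write candidate positions as TSV (individual, chrom, pos, peak_H)."""
    rows = []
    for cs in candidates:
        hs = cs.peak_h if cs.peak_h is not None else [np.nan] * cs.k
        for (c, p), h in zip(cs.positions, hs):
            rows.append((cs.individual, c, p, h))
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[CandidateSet]:
    """Read candidate sets written by :func:`write_candidates`.

    Individuals appear in order of first appearance; malformed rows raise
    :class:`DataError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CANDIDATE_COLUMNS:
            raise DataError(
                f"{path}: expected header {_CANDIDATE_COLUMNS}, got {header}"
            )
        per_ind: dict[str, tuple[list, list]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            ind, chrom, pos_s, h_s = parts
            try:
                pos = int(pos_s)
                h = float(h_s) if h_s not in ("", "nan") else float("nan")
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            entry = per_ind.setdefault(ind, ([], []))
            entry[0].append((chrom, pos))
            entry[1].append(h)
    return [
        CandidateSet(ind, positions, peak_h)
        for ind, (positions, peak_h) in per_ind.items()
    ]


def candidate_summary(candidates: Sequence[CandidateSet]) -> CandidateSummary:
    """Per-cohort accounting of candidate counts (k per individual)."""
    ks = [cs.k for cs in candidates]
    if not ks:
        return CandidateSummary(0, 0, float("nan"), 0, 0)
    return CandidateSummary(
        n_individuals=len(ks),
        total_k=int(sum(ks)),
        mean_k=float(sum(ks)) / len(ks),
        min_k=int(min(ks)),
        max_k=int(max(ks)),
    )


def write_variants(vt: VariantTable, path) -> None:
    """Write a variant table as TSV (chrom, pos, id, maf)."""
    vt.to_dataframe().to_csv(path, sep="\t", index=False)


def read_variants(path) -> VariantTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    except Exception as exc:
        raise DataError(f"cannot parse variant table {path}: {exc}") from exc
    missing = {"chrom", "pos", "id", "maf"} - set(df.columns)
    if missing:
        raise DataError(f"variant table {path} lacks columns {sorted(missing)}")
    return VariantTable.from_dataframe(df)
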