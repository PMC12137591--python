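"""Genotype, phenotype and relationship-matrix containers plus file I/O.

The central container is :class:`PhasedGenotypes`: a panel of individuals
typed at biallelic autosomal SNPs, with phase-resolved allele calls when the
source provides them (phased VCF) and reference-allele dosages otherwise
(PLINK bed).  Relationship matrices travel in the GCTA binary GRM dialect
(``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``).

Allele orientation: internally a haplotype call of 0 means the VCF REF
(PLINK A2) allele and 1 the ALT (A1) allele.  ``dosages`` counts copies of
the *reference* allele, so a 1/1 genotype has dosage 0.  GRM construction is
invariant to swapping this orientation, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhasedGenotypes",
    "PhenotypeTable",
    "RelationshipMatrix",
    "GenotypeFormatError",
    "PhaseError",
    "MissingDataError",
    "PhaseUnavailableError",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_plink_bed",
    "read_phenotypes",
    "write_grm",
    "read_grm",
]


class GenotypeFormatError(ValueError):
    """Malformed or internally inconsistent genotype input."""


class PhaseError(GenotypeFormatError):
    """A retained site carries an unphased genotype separator."""


class MissingDataError(GenotypeFormatError):
    """A retained site carries a missing call; hard calls are required."""


class PhaseUnavailableError(RuntimeError):
    """An operation requiring phase was asked of phase-free data."""


@dataclass
class PhasedGenotypes:
    """Individuals x SNPs panel with optional phase resolution.

    ``haplotype_calls`` is an ``(n_individuals, n_snps, 2)`` array of 0/1
    alternate-allele indicators, or ``None`` when the source (PLINK bed)
    carries no phase; then ``_dosages`` holds reference-allele counts.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    individual_ids: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    haplotype_calls: np.ndarray | None = None
    _dosages: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype=object)
        self.alt_alleles = np.asarray(self.alt_alleles, dtype=object)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise GenotypeFormatError("duplicate individual ids in panel")
        if self.haplotype_calls is None and self._dosages is None:
            raise GenotypeFormatError("need haplotype calls or dosages")
        if self.haplotype_calls is not None:
            self.haplotype_calls = np.asarray(self.haplotype_calls, dtype=np.int8)
            if self.haplotype_calls.shape != (self.n_individuals, self.n_snps, 2):
                raise GenotypeFormatError(
                    "haplotype_calls shape inconsistent with ids/sites"
                )
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions_bp[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeFormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.positions_bp)

    @property
    def phase_available(self) -> bool:
        return self.haplotype_calls is not None

    @property
    def dosages(self) -> np.ndarray:
        """Reference-allele counts, ``(n_individuals, n_snps)`` in {0,1,2}."""
        if self.haplotype_calls is not None:
            return (2 - self.haplotype_calls.sum(axis=2)).astype(np.int8)
        return self._dosages

    def ref_allele_frequencies(self, snp_indices: Sequence[int] | None = None) -> np.ndarray:
        d = self.dosages if snp_indices is None else self.dosages[:, snp_indices]
        return d.mean(axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.ref_allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, snp_indices: Sequence[int]) -> "PhasedGenotypes":
        idx = np.asarray(snp_indices, dtype=np.intp)
        return PhasedGenotypes(
            individual_ids=self.individual_ids,
            chromosomes=self.chromosomes[idx],
            positions_bp=self.positions_bp[idx],
            ref_alleles=self.ref_alleles[idx],
            alt_alleles=self.alt_alleles[idx],
            haplotype_calls=None if self.haplotype_calls is None
            else self.haplotype_calls[:, idx, :],
            _dosages=None if self._dosages is None else self._dosages[:, idx],
        )

    def subset_individuals(self, ids: Sequence) -> "PhasedGenotypes":
        order = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([order[i] for i in ids], dtype=np.intp)
        return PhasedGenotypes(
            individual_ids=self.individual_ids[idx],
            chromosomes=self.chromosomes,
            positions_bp=self.positions_bp,
            ref_alleles=self.ref_alleles,
            alt_alleles=self.alt_alleles,
            haplotype_calls=None if self.haplotype_calls is None
            else self.haplotype_calls[idx],
            _dosages=None if self._dosages is None else self._dosages[idx],
        )


@dataclass
class PhenotypeTable:
    """Trait records with fixed-effect covariates and random-effect labels.

    ``records`` has one row per measurement; ``repeated`` flags designs with
    multiple records per individual (which add a permanent-environment
    effect in the mixed model).
    """

    records: pd.DataFrame
    trait_name: str
    id_column: str = "id"
    repeated: bool = False

    def __post_init__(self) -> None:
        if self.trait_name not in self.records.columns:
            raise ValueError(f"trait column {self.trait_name!r} absent")
        if self.id_column not in self.records.columns:
            raise ValueError(f"id column {self.id_column!r} absent")
        if not self.repeated and self.records[self.id_column].duplicated().any():
            raise ValueError("duplicate individual ids in non-repeated table")

    @property
    def individual_ids(self) -> np.ndarray:
        return self.records[self.id_column].to_numpy()

    def restrict_to(self, panel_ids: Iterable) -> tuple["PhenotypeTable", int]:
        """Drop records whose individual is absent from the genotype panel."""
        keep = self.records[self.id_column].isin(set(panel_ids))
        dropped = int((~keep).sum())
        return (
            PhenotypeTable(
                self.records.loc[keep].reset_index(drop=True),
                self.trait_name,
                self.id_column,
                self.repeated,
            ),
            dropped,
        )


VALID_GRM_KINDS = {"snp_regional", "hap_regional", "loco", "whole_genome"}


@dataclass
class RelationshipMatrix:
    """Symmetric individual x individual genomic relationship matrix.

    ``loadings`` optionally stores an ``n x r`` factor with
    ``values == loadings @ loadings.T``; low-rank regional GRMs carry it so
    the REML fitter can use Woodbury identities.
    """

    individual_ids: np.ndarray
    values: np.ndarray
    kind: str
    n_markers: int
    source_block: str | None = None
    excluded_chromosome: str | None = None
    loadings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match individual ids")
        if self.kind not in VALID_GRM_KINDS:
            raise ValueError(f"unknown GRM kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix not symmetric")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


# ---------------------------------------------------------------------------
# VCF

def read_phased_vcf(
    path: str | Path,
    region_filter: set[str] | None = None,
    skip_multiallelic: bool = True,
) -> PhasedGenotypes:
    """Read phased, biallelic, hard-called genotypes from a VCF.

    Raises :class:`PhaseError` on an unphased genotype and
    :class:`MissingDataError` on a missing call at any retained site.
    Multiallelic sites are skipped when ``skip_multiallelic`` (the count is
    recorded on the returned object as ``n_skipped_sites``), otherwise they
    raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeFormatError("duplicate sample id in VCF header")

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    calls: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if region_filter is not None and var.CHROM not in region_filter:
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if skip_multiallelic:
                n_skipped += 1
                continue
            raise GenotypeFormatError(
                f"non-biallelic-SNP site at {var.CHROM}:{var.POS}"
            )
        gts = np.array(var.genotypes)  # (n, 3): allele0, allele1, phased flag
        if np.any(gts[:, :2] < 0):
            raise MissingDataError(
                f"missing call at {var.CHROM}:{var.POS}; hard calls required"
            )
        if not np.all(gts[:, 2] == 1):
            raise PhaseError(f"unphased genotype at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        calls.append(gts[:, :2].astype(np.int8))
    vcf.close()

    hap = (
        np.stack(calls, axis=1)
        if calls
        else np.zeros((len(samples), 0, 2), dtype=np.int8)
    )
    geno = PhasedGenotypes(
        individual_ids=np.array(samples, dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        positions_bp=np.array(positions, dtype=np.int64),
        ref_alleles=np.array(refs, dtype=object),
        alt_alleles=np.array(alts, dtype=object),
        haplotype_calls=hap,
    )
    geno.n_skipped_sites = n_skipped  # type: ignore[attr-defined]
    return geno


def write_phased_vcf(genotypes: PhasedGenotypes, path: str | Path) -> None:
    """Write a minimal phased VCF (pipe-separated GT only)."""
    if not genotypes.phase_available:
        raise PhaseUnavailableError("cannot write phased VCF without phase")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(genotypes.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.individual_ids))
            + "\n"
        )
        hap = genotypes.haplotype_calls
        for k in range(genotypes.n_snps):
            gts = "\t".join(f"{hap[i, k, 0]}|{hap[i, k, 1]}" for i in range(genotypes.n_individuals))
            fh.write(
                f"{genotypes.chromosomes[k]}\t{genotypes.positions_bp[k]}\t"
                f"snp{k}\t{genotypes.ref_alleles[k]}\t{genotypes.alt_alleles[k]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major

# 2-bit PLINK codes -> reference(A2)-allele count; 1 = missing
_BED_CODE_TO_REF = {0: 0, 2: 1, 3: 2}


def read_plink_bed(prefix: str | Path) -> PhasedGenotypes:
    """Read a PLINK .bed/.bim/.fam triple as a phase-free panel.

    The returned object has ``phase_available == False``: it supports SNP
    GRMs and block finding but not haplotype enumeration.  A2 is treated as
    the reference allele, matching the VCF REF convention.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(".bed magic bytes wrong or not SNP-major")
    bytes_per_snp = (n + 3) // 4
    if len(raw) - 3 != bytes_per_snp * m:
        raise GenotypeFormatError(
            f".bed payload size {len(raw) - 3} inconsistent with "
            f"{n} samples x {m} variants from .fam/.bim"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    if np.any(codes == 1):
        raise MissingDataError("missing genotype in .bed; hard calls required")
    lut = np.zeros(4, dtype=np.int8)
    for c, v in _BED_CODE_TO_REF.items():
        lut[c] = v
    dosages = lut[codes].T  # (n, m) reference-allele counts

    return PhasedGenotypes(
        individual_ids=fam["iid"].to_numpy(dtype=object),
        chromosomes=bim["chrom"].to_numpy(dtype=object),
        positions_bp=bim["pos"].to_numpy(dtype=np.int64),
        ref_alleles=bim["a2"].to_numpy(dtype=object),
        alt_alleles=bim["a1"].to_numpy(dtype=object),
        haplotype_calls=None,
        _dosages=dosages,
    )


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(
    path: str | Path,
    trait_name: str,
    id_column: str = "id",
    repeated: bool = False,
    sep: str = "\t",
) -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep)
    return PhenotypeTable(df, trait_name, id_column=id_column, repeated=repeated)


# ---------------------------------------------------------------------------
# GCTA binary GRM dialect

def write_grm(matrix: RelationshipMatrix, prefix: str | Path) -> None:
    """Write GCTA ``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id`` files.

    Lower-triangle (row-major, diagonal included) single-precision values;
    per-pair marker counts; two-column id list.
    """
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite GRM values")
    prefix = Path(prefix)
    n = matrix.n_individuals
    tri = matrix.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix.with_suffix(".grm.bin"))
    np.full(tri.shape, matrix.n_markers, dtype="<f4").tofile(
        prefix.with_suffix(".grm.N.bin")
    )
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for iid in matrix.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str | Path, kind: str = "whole_genome") -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = [
        line.split()[1]
        for line in Path(prefix.with_suffix(".grm.id")).read_text().splitlines()
        if line.strip()
    ]
    n = len(ids)
    tri = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise GenotypeFormatError(
            f".grm.bin holds {tri.size} values, expected {n * (n + 1) // 2} "
            f"for {n} ids"
        )
    counts = np.fromfile(prefix.with_suffix(".grm.N.bin"), dtype="<f4")
    values = np.zeros((n, n))
    il = np.tril_indices(n)
    values[il] = tri
    values = values + values.T - np.diag(np.diag(values))
    return RelationshipMatrix(
        individual_ids=np.array(ids, dtype=object),
        values=values,
        kind=kind,
        n_markers=int(round(float(counts[0]))) if counts.size else 0,
    )
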