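"""Genomic relationship matrices from SNP dosages and haplotype alleles.

SNP-based matrices use the VanRaden scaling applied marker-by-marker:

    A_ij = (1/N) sum_k (s_ik - 2 p_k)(s_jk - 2 p_k) / (2 p_k (1 - p_k))

with s_ik the reference-allele count of individual i at SNP k and p_k the
reference-allele frequency in the analyzed sample.  Haplotype-based
matrices apply the same scaling to diplotype codes d_ik (copies carried of
haplotype allele k within a block), averaging over the h distinct observed
alleles.  Both are returned with a low-rank factorisation attached, which
the REML fitter exploits for regional models.

All accumulation is double precision; single precision appears only at the
GCTA file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geno_io import PhasedGenotypes, PhaseUnavailableError, RelationshipMatrix
from .hapblocks import HaplotypeBlock

__all__ = [
    "HaplotypeAlleleTable",
    "DegenerateMarkerError",
    "DegenerateBlockError",
    "snp_grm",
    "enumerate_haplotypes",
    "hap_grm",
    "loco_grm",
    "whole_genome_grm",
]

log = logging.getLogger(__name__)


class DegenerateMarkerError(ValueError):
    """A SNP in the requested subset is monomorphic in the analyzed sample."""


class DegenerateBlockError(ValueError):
    """A block carries a single haplotype allele; its GRM is undefined."""


@dataclass
class HaplotypeAlleleTable:
    """Distinct phased allele strings of one block with diplotype codes.

    ``allele_strings[k]`` is the concatenated 0/1 alternate-allele string of
    haplotype allele k; ``diplotype_codes[i, k]`` counts copies (0/1/2) that
    individual i carries, so each row sums to 2, and ``frequencies`` are
    sample haplotype frequencies summing to 1.
    """

    block_id: str
    allele_strings: list[str]
    frequencies: np.ndarray
    diplotype_codes: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.diplotype_codes = np.asarray(self.diplotype_codes, dtype=np.int8)
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("haplotype frequencies must sum to 1")
        if not np.all(self.diplotype_codes.sum(axis=1) == 2):
            raise ValueError("each individual must carry exactly 2 haplotypes")

    @property
    def h(self) -> int:
        """Number of distinct haplotype alleles observed in the block."""
        return len(self.allele_strings)


def _vanraden(
    counts: np.ndarray, freqs: np.ndarray, names: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (matrix, loadings) for the per-marker standardized cross-product."""
    bad = (freqs <= 0.0) | (freqs >= 1.0)
    if np.any(bad):
        which = np.flatnonzero(bad)
        label = names[which[0]] if names is not None else f"index {which[0]}"
        raise DegenerateMarkerError(
            f"marker {label} is monomorphic in the analyzed sample (p={freqs[which[0]]})"
        )
    z = (counts - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    loadings = z / np.sqrt(z.shape[1])
    return loadings @ loadings.T, loadings


def snp_grm(
    genotypes: PhasedGenotypes, snp_subset: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden SNP GRM over ``snp_subset`` (all SNPs when ``None``).

    Every subset SNP must be polymorphic in the sample.  The result is
    invariant under swapping reference and alternate allele labels at any
    SNP.
    """
    idx = (
        np.arange(genotypes.n_snps)
        if snp_subset is None
        else np.asarray(snp_subset, dtype=np.intp)
    )
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    s = genotypes.dosages[:, idx].astype(np.float64)
    p = s.mean(axis=0) / 2.0
    names = np.array(
        [f"{genotypes.chromosomes[k]}:{genotypes.positions_bp[k]}" for k in idx],
        dtype=object,
    )
    values, loadings = _vanraden(s, p, names)
    return RelationshipMatrix(
        individual_ids=genotypes.individual_ids,
        values=values,
        kind="snp_regional" if snp_subset is not None else "whole_genome",
        n_markers=int(idx.size),
        loadings=loadings,
    )


def enumerate_haplotypes(
    genotypes: PhasedGenotypes, block: HaplotypeBlock | np.ndarray
) -> HaplotypeAlleleTable:
    """Enumerate the distinct phased allele strings of one block.

    Only observed alleles are enumerated, so every frequency is positive
    and ``h`` counts observed alleles.  No frequency floor is applied: rare
    haplotype alleles are the point of the haplotype-based model.
    """
    if not genotypes.phase_available:
        raise PhaseUnavailableError("haplotype enumeration requires phased data")
    if isinstance(block, HaplotypeBlock):
        idx = np.asarray(block.snp_indices, dtype=np.intp)
        block_id = block.block_id
    else:
        idx = np.asarray(block, dtype=np.intp)
        block_id = "adhoc"
    if idx.size == 0:
        raise ValueError("block has no SNPs")
    hap = genotypes.haplotype_calls[:, idx, :]  # (n, m, 2)
    n = genotypes.n_individuals
    # string per (individual, chromosome copy)
    strings = hap.transpose(0, 2, 1).reshape(2 * n, idx.size)
    uniq, inverse = np.unique(strings, axis=0, return_inverse=True)
    h = uniq.shape[0]
    codes = np.zeros((n, h), dtype=np.int64)
    np.add.at(codes, (np.repeat(np.arange(n), 2), inverse), 1)
    freqs = np.bincount(inverse, minlength=h) / (2.0 * n)
    return HaplotypeAlleleTable(
        block_id=block_id,
        allele_strings=["".join(map(str, row)) for row in uniq],
        frequencies=freqs,
        diplotype_codes=codes,
    )


def hap_grm(
    table: HaplotypeAlleleTable,
    individual_ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Haplotype-allele GRM H from a block's diplotype codes.

    H_ij = (1/h) sum_k (d_ik - 2 p_k)(d_jk - 2 p_k) / (2 p_k (1 - p_k)).
    A block with a single observed allele (h = 1, p = 1) is degenerate.
    """
    if table.h < 2:
        raise DegenerateBlockError(
            f"block {table.block_id}: single haplotype allele; GRM undefined"
        )
    d = table.diplotype_codes.astype(np.float64)
    values, loadings = _vanraden(d, table.frequencies)
    n = d.shape[0]
    ids = (
        individual_ids
        if individual_ids is not None
        else np.array([str(i) for i in range(n)], dtype=object)
    )
    return RelationshipMatrix(
        individual_ids=np.asarray(ids, dtype=object),
        values=values,
        kind="hap_regional",
        n_markers=table.h,
        source_block=table.block_id,
        loadings=loadings,
    )


def loco_grm(genotypes: PhasedGenotypes, excluded_chromosome: str) -> RelationshipMatrix:
    """Leave-one-chromosome-out GRM: all polymorphic SNPs off one chromosome."""
    chroms = set(map(str, dict.fromkeys(genotypes.chromosomes)))
    if str(excluded_chromosome) not in chroms:
        raise ValueError(f"chromosome {excluded_chromosome!r} not in panel")
    keep = np.flatnonzero(
        np.array([str(c) != str(excluded_chromosome) for c in genotypes.chromosomes])
    )
    keep = _polymorphic(genotypes, keep)
    if keep.size == 0:
        raise ValueError(
            f"no polymorphic SNP outside chromosome {excluded_chromosome!r}"
        )
    base = snp_grm(genotypes, keep)
    return RelationshipMatrix(
        individual_ids=base.individual_ids,
        values=base.values,
        kind="loco",
        n_markers=base.n_markers,
        excluded_chromosome=str(excluded_chromosome),
        loadings=base.loadings,
    )


def whole_genome_grm(genotypes: PhasedGenotypes) -> RelationshipMatrix:
    """GRM over every SNP polymorphic in the analyzed sample."""
    keep = _polymorphic(genotypes, np.arange(genotypes.n_snps))
    if keep.size == 0:
        raise ValueError("no polymorphic SNPs in panel")
    return snp_grm(genotypes, None) if keep.size == genotypes.n_snps else _as_wg(
        snp_grm(genotypes, keep)
    )


def _as_wg(m: RelationshipMatrix) -> RelationshipMatrix:
    return RelationshipMatrix(
        individual_ids=m.individual_ids,
        values=m.values,
        kind="whole_genome",
        n_markers=m.n_markers,
        loadings=m.loadings,
    )


def _polymorphic(genotypes: PhasedGenotypes, idx: np.ndarray) -> np.ndarray:
    p = genotypes.dosages[:, idx].mean(axis=0) / 2.0
    keep = idx[(p > 0.0) & (p < 1.0)]
    if keep.size < idx.size:
        log.warning("dropped %d monomorphic SNP(s)", idx.size - keep.size)
    return keep
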