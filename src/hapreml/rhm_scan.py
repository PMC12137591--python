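"""End-to-end regional heritability scan.

Pipeline: (1) pre-correct each trait with a leave-one-chromosome-out (LOCO)
mixed model so genome-wide polygenic signal, fixed effects and non-genetic
random effects are removed; (2) for every haplotype block, fit four models
to the pre-corrected phenotype that excluded the block's chromosome —

    null:   y_pre = e
    SNP:    y_pre = g_snp + e       g_snp ~ MVN(0, A_block s2_rSNP)
    Hap:    y_pre = g_hap + e       g_hap ~ MVN(0, H_block s2_rHap)
    SNHap:  y_pre = g_snp + g_hap + e

(an intercept is always included); (3) compare them with five
likelihood-ratio tests whose null distributions are boundary mixtures of
chi-squared distributions: 0.5*chi2(1) for the four 1-df comparisons and
0.25*chi2(2) + 0.5*chi2(1) for SNHap vs null; (4) Bonferroni-correct over
the number of blocks scanned; (5) report the genetic variance explained by
significant regions, merging nearby blocks into loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .geno_io import PhenotypeTable, RelationshipMatrix
from .grm import (
    DegenerateBlockError,
    DegenerateMarkerError,
    enumerate_haplotypes,
    hap_grm,
    snp_grm,
)
from .hapblocks import HaplotypeBlock
from .varcomp import ModelSpec, VarianceModelFit, reml_fit

__all__ = [
    "PrecorrectedPhenotype",
    "RegionalScanResult",
    "precorrect",
    "fit_block",
    "scan",
    "lrt_pvalue",
    "significance_threshold",
    "summarize_variance",
    "COMPARISONS",
]

log = logging.getLogger(__name__)

LRT_CLAMP_TOL = 1e-4

# comparison name -> (alternative model, nested model, degrees of freedom)
COMPARISONS = {
    "snp_vs_null": ("snp", "null", 1),
    "hap_vs_null": ("hap", "null", 1),
    "snhap_vs_null": ("snhap", "null", 2),
    "snhap_vs_hap": ("snhap", "hap", 1),
    "snhap_vs_snp": ("snhap", "snp", 1),
}


@dataclass
class PrecorrectedPhenotype:
    """One pre-corrected value per individual, per excluded chromosome."""

    individual_ids: np.ndarray
    values: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def for_chromosome(self, chrom: str) -> np.ndarray:
        if str(chrom) not in self.values:
            raise KeyError(
                f"no pre-corrected phenotype excluding chromosome {chrom!r}"
            )
        return self.values[str(chrom)]

    def merge(self, other: "PrecorrectedPhenotype") -> "PrecorrectedPhenotype":
        if not np.array_equal(self.individual_ids, other.individual_ids):
            raise ValueError("individual sets differ between LOCO variants")
        return PrecorrectedPhenotype(
            self.individual_ids,
            {**self.values, **other.values},
            {**self.provenance, **other.provenance},
        )


def precorrect(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    loco: RelationshipMatrix,
) -> PrecorrectedPhenotype:
    """Pre-correct a trait with one LOCO mixed model.

    Non-repeated traits: the pre-corrected value is the residual of the
    LOCO model.  Repeated traits: the permanent-environment BLUP plus the
    mean of the individual's record residuals.  Individuals without a
    genotype are excluded (count logged).
    """
    if len(spec.genetic_components) != 1:
        raise ValueError("pre-correction spec must have exactly one genetic component")
    if loco.kind != "loco" or loco.excluded_chromosome is None:
        raise ValueError("pre-correction requires a LOCO relationship matrix")
    phen, n_dropped = phenotypes.restrict_to(loco.individual_ids)
    if n_dropped:
        log.info("excluded %d record(s) with phenotype but no genotype", n_dropped)
    label = spec.genetic_components[0][1]
    use_spec = ModelSpec(
        response=spec.response,
        fixed_effects=spec.fixed_effects,
        iid_random_effects=spec.iid_random_effects,
        genetic_components=[(loco, label)],
        repeated=spec.repeated or phen.repeated,
    )
    fit = reml_fit(use_spec, phen)
    ids = phen.individual_ids
    if use_spec.repeated:
        pe_levels = pd.unique(ids)
        pe = dict(zip(pe_levels, fit.blups["pe"]))
        resid = pd.Series(fit.residuals).groupby(pd.Series(ids)).mean()
        out_ids = np.array(pe_levels, dtype=object)
        vals = np.array([pe[i] + resid[i] for i in out_ids])
    else:
        out_ids = np.asarray(ids, dtype=object)
        vals = np.asarray(fit.residuals, dtype=float)
    return PrecorrectedPhenotype(
        individual_ids=out_ids,
        values={str(loco.excluded_chromosome): vals},
        provenance={
            str(loco.excluded_chromosome): {
                "spec": use_spec,
                "loco_n_markers": loco.n_markers,
                "variances": fit.variance_estimates,
                "converged": fit.converged,
            }
        },
    )


# ---------------------------------------------------------------------------
# mixture chi-squared machinery

def lrt_pvalue(lrt: float, comparison: str) -> float:
    """Mixture chi-squared p-value for one of the five comparisons.

    A single variance tested on its boundary gives 0.5*chi2(1); two give
    0.25*chi2(2) + 0.5*chi2(1) (the remaining mass sits at zero).  Negative
    statistics within optimizer tolerance are clamped to 0; larger
    violations indicate a convergence failure of the larger model.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if lrt < -LRT_CLAMP_TOL:
        raise ValueError(
            f"negative LRT {lrt:.3g}: larger model fit worse than nested model"
        )
    lrt = max(lrt, 0.0)
    if COMPARISONS[comparison][2] == 2:
        return float(0.25 * chi2.sf(lrt, 2) + 0.5 * chi2.sf(lrt, 1))
    return float(0.5 * chi2.sf(lrt, 1))


def significance_threshold(n_blocks: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold over all blocks scanned for one trait."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    return alpha / n_blocks


# ---------------------------------------------------------------------------
# per-block fitting

@dataclass
class RegionalScanResult:
    """Tabular scan output; one row per block with fits, LRTs and p-values."""

    table: pd.DataFrame
    n_blocks: int
    threshold: float

    def significant(self, comparison: str) -> pd.DataFrame:
        return self.table[self.table[f"sig_{comparison}"]]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pheno_from_values(ids: np.ndarray, values: np.ndarray) -> PhenotypeTable:
    return PhenotypeTable(
        pd.DataFrame({"id": ids, "y_pre": values}), "y_pre"
    )


def fit_block(
    y_pre: PrecorrectedPhenotype,
    block: HaplotypeBlock,
    snp_matrix: RelationshipMatrix,
    hap_matrix: RelationshipMatrix,
) -> dict:
    """Fit null/SNP/Hap/SNHap models for one block and compute the five LRTs.

    The pre-corrected phenotype variant excluding the block's chromosome is
    used, so the block's SNPs are never modelled twice.
    """
    vals = y_pre.for_chromosome(block.chromosome)
    phen = _pheno_from_values(y_pre.individual_ids, vals)

    null_fit = reml_fit(ModelSpec("y_pre"), phen, compute_blups=False)
    fits: dict[str, VarianceModelFit] = {"null": null_fit}
    fits["snp"] = reml_fit(
        ModelSpec("y_pre", genetic_components=[(snp_matrix, "r_snp")]),
        phen, compute_blups=False,
    )
    fits["hap"] = reml_fit(
        ModelSpec("y_pre", genetic_components=[(hap_matrix, "r_hap")]),
        phen, compute_blups=False,
    )
    fits["snhap"] = reml_fit(
        ModelSpec(
            "y_pre",
            genetic_components=[(snp_matrix, "r_snp"), (hap_matrix, "r_hap")],
        ),
        phen, compute_blups=False,
    )

    row: dict = {
        "block_id": block.block_id,
        "chrom": block.chromosome,
        "start_bp": block.start_bp,
        "end_bp": block.end_bp,
        "n_snps": block.n_snps,
        "n_hap_alleles": hap_matrix.n_markers,
        "skipped": False,
    }
    for name, fit in fits.items():
        row[f"loglik_{name}"] = fit.restricted_loglik
        row[f"converged_{name}"] = fit.converged
    row["var_rsnp_snp"] = fits["snp"].variance_estimates.get("r_snp", np.nan)
    row["var_e_snp"] = fits["snp"].variance_estimates["residual"]
    row["var_rhap_hap"] = fits["hap"].variance_estimates.get("r_hap", np.nan)
    row["var_e_hap"] = fits["hap"].variance_estimates["residual"]
    row["var_rsnp_snhap"] = fits["snhap"].variance_estimates.get("r_snp", np.nan)
    row["var_rhap_snhap"] = fits["snhap"].variance_estimates.get("r_hap", np.nan)
    row["var_e_snhap"] = fits["snhap"].variance_estimates["residual"]
    row["var_e_null"] = fits["null"].variance_estimates["residual"]

    for comp, (alt, nested, _) in COMPARISONS.items():
        lrt = 2.0 * (fits[alt].restricted_loglik - fits[nested].restricted_loglik)
        if lrt < -LRT_CLAMP_TOL:
            log.warning(
                "block %s comparison %s: negative LRT %.4g; refitting with "
                "general path", block.block_id, comp, lrt,
            )
            refit = reml_fit(
                ModelSpec(
                    "y_pre",
                    genetic_components=[(snp_matrix, "r_snp"), (hap_matrix, "r_hap")]
                    if alt == "snhap"
                    else [(snp_matrix, "r_snp")] if alt == "snp"
                    else [(hap_matrix, "r_hap")],
                ),
                phen, compute_blups=False, force_general=True,
            )
            if refit.restricted_loglik > fits[alt].restricted_loglik:
                fits[alt] = refit
                row[f"loglik_{alt}"] = refit.restricted_loglik
                lrt = 2.0 * (refit.restricted_loglik - fits[nested].restricted_loglik)
        lrt = max(lrt, 0.0) if lrt >= -LRT_CLAMP_TOL else lrt
        row[f"lrt_{comp}"] = lrt
        row[f"p_{comp}"] = lrt_pvalue(lrt, comp) if lrt >= 0 else np.nan
    return row


def scan(
    genotypes,
    blocks: list[HaplotypeBlock],
    y_pre: PrecorrectedPhenotype,
    alpha: float = 0.05,
) -> RegionalScanResult:
    """Run the four-model comparison over every block.

    Blocks with degenerate regional matrices (single haplotype allele, or
    fewer than two polymorphic SNPs in the phenotyped subsample) are flagged
    skipped; the scan continues.
    """
    sub = genotypes.subset_individuals(y_pre.individual_ids)
    rows = []
    for block in blocks:
        try:
            idx = np.asarray(block.snp_indices, dtype=np.intp)
            p = sub.dosages[:, idx].mean(axis=0) / 2.0
            poly = idx[(p > 0) & (p < 1)]
            if poly.size < idx.size:
                log.warning(
                    "block %s: dropped %d SNP(s) monomorphic in subsample",
                    block.block_id, idx.size - poly.size,
                )
            if poly.size < 2:
                raise DegenerateBlockError(
                    f"block {block.block_id}: <2 polymorphic SNPs in subsample"
                )
            a = snp_grm(sub, poly)
            table = enumerate_haplotypes(sub, block)
            h = hap_grm(table, individual_ids=sub.individual_ids)
            rows.append(fit_block(y_pre, block, a, h))
        except (DegenerateBlockError, DegenerateMarkerError) as exc:
            log.warning("block %s skipped: %s", block.block_id, exc)
            rows.append(
                {
                    "block_id": block.block_id,
                    "chrom": block.chromosome,
                    "start_bp": block.start_bp,
                    "end_bp": block.end_bp,
                    "n_snps": block.n_snps,
                    "skipped": True,
                }
            )
    df = pd.DataFrame(rows)
    threshold = significance_threshold(len(blocks), alpha)
    for comp in COMPARISONS:
        col = f"p_{comp}"
        if col in df.columns:
            df[f"sig_{comp}"] = df[col] < threshold
        else:
            df[f"sig_{comp}"] = False
    return RegionalScanResult(table=df, n_blocks=len(blocks), threshold=threshold)


# ---------------------------------------------------------------------------
# variance-explained accounting

_METHOD_SHARE = {
    "snp": lambda r: r.get("var_rsnp_snp", np.nan),
    "hap": lambda r: r.get("var_rhap_hap", np.nan),
    "snhap": lambda r: (
        r.get("var_rsnp_snhap", np.nan) + r.get("var_rhap_snhap", np.nan)
    ),
}
_METHOD_COMPARISON = {
    "snp": "snp_vs_null",
    "hap": "hap_vs_null",
    "snhap": "snhap_vs_null",
}


def summarize_variance(
    results: RegionalScanResult,
    total_genetic_variance: float,
    locus_merge_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Percent of total genetic variance explained by significant regions.

    Significant blocks on the same chromosome closer than ``locus_merge_bp``
    are merged into one locus, and only the block with the highest regional
    variance in each locus contributes.  For the joint model the regional
    variance is the SNP plus haplotype component.  Returns one row per
    method with locus counts and the percentage explained; zero rows of
    significance give 0%.
    """
    if total_genetic_variance <= 0:
        raise ValueError("total genetic variance must be positive")
    out = []
    for method, share_of in _METHOD_SHARE.items():
        comp = _METHOD_COMPARISON[method]
        sig = results.table[
            results.table.get(f"sig_{comp}", False) & ~results.table["skipped"]
        ]
        total = 0.0
        n_loci = 0
        for chrom, grp in sig.groupby("chrom"):
            grp = grp.sort_values("start_bp")
            locus_best = None
            prev_end = None
            for _, r in grp.iterrows():
                v = float(share_of(r))
                if prev_end is not None and r["start_bp"] - prev_end < locus_merge_bp:
                    locus_best = max(locus_best, v)
                else:
                    if locus_best is not None:
                        total += locus_best
                        n_loci += 1
                    locus_best = v
                prev_end = r["end_bp"]
            if locus_best is not None:
                total += locus_best
                n_loci += 1
        out.append(
            {
                "method": method,
                "n_significant_blocks": int(len(sig)),
                "n_loci": n_loci,
                "percent_genetic_variance": 100.0 * total / total_genetic_variance,
            }
        )
    return pd.DataFrame(out)
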