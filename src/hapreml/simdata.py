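"""Synthetic phased genotypes and phenotypes with known truth.

The generator emulates the statistical structure the regional-mapping
pipeline assumes: block-structured LD (each block's haplotypes drawn from a
small founder pool, independent across blocks), a polygenic background
drawn with covariance proportional to the genome-wide relationship matrix,
and a regional QTL that is either

* ``snp_additive`` (scenario A): several small additive effects on typed
  SNPs inside one block — the architecture the SNP-based regional model
  targets; or
* ``hap_allele`` (scenario B): one effect attached to a single founder
  haplotype identity, deliberately not tagged by any private SNP allele —
  the architecture the haplotype-based model targets.

Fixed effects (sex), iid non-genetic random effects (year, mother) and a
repeated-measures design with a permanent-environment effect mirror the
effect structure of wild-population morphometric traits.  Components are
rescaled to their realized sample variance, so the generated variance
shares hit the scenario targets exactly and truth is returned alongside
the phenotypes.  Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geno_io import PhasedGenotypes, PhenotypeTable
from .grm import enumerate_haplotypes, snp_grm
from .hapblocks import HaplotypeBlock

__all__ = [
    "SimScenario",
    "SimTruth",
    "ScenarioError",
    "load_scenario",
    "simulate_genotypes",
    "simulate_phenotypes",
    "true_blocks",
]

ARCHITECTURES = ("none", "snp_additive", "hap_allele")


class ScenarioError(ValueError):
    pass


@dataclass
class SimScenario:
    """A fully stated simulation world; the seed is mandatory.

    Variance shares are fractions of the total phenotypic variance (fixed
    at 1): ``polygenic_h2`` + ``regional_share`` + ``year_share`` +
    ``mother_share`` + ``pe_share`` must sum below 1; the remainder is the
    residual.
    """

    seed: int
    n_individuals: int = 1000
    n_chromosomes: int = 2
    blocks_per_chromosome: int = 10
    snps_per_block: int = 8
    n_founders: int = 6
    maf_min: float = 0.05
    maf_max: float = 0.5
    qtl_architecture: str = "none"
    causal_block_index: int = 0
    n_causal_snps: int = 4
    causal_allele_freq_target: float = 0.15
    regional_share: float = 0.0
    polygenic_h2: float = 0.0
    sex_effect: float = 0.0
    year_levels: int = 0
    year_share: float = 0.0
    mother_group_size: int = 0
    mother_share: float = 0.0
    records_per_individual: int = 1
    pe_share: float = 0.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ScenarioError("seed is mandatory")
        if self.qtl_architecture not in ARCHITECTURES:
            raise ScenarioError(f"unknown architecture {self.qtl_architecture!r}")
        if not (0.0 < self.maf_min < self.maf_max <= 0.5):
            raise ScenarioError("need 0 < maf_min < maf_max <= 0.5")
        shares = [
            self.regional_share, self.polygenic_h2, self.year_share,
            self.mother_share, self.pe_share,
        ]
        if any(s < 0 or s >= 1 for s in shares) or sum(shares) >= 1:
            raise ScenarioError("variance shares must lie in [0,1) and sum below 1")
        if self.records_per_individual < 1:
            raise ScenarioError("records_per_individual must be >= 1")
        if self.pe_share > 0 and self.records_per_individual < 2:
            raise ScenarioError("permanent-environment share needs repeated records")

    @property
    def n_blocks(self) -> int:
        return self.n_chromosomes * self.blocks_per_chromosome

    @property
    def residual_share(self) -> float:
        return 1.0 - (
            self.regional_share + self.polygenic_h2 + self.year_share
            + self.mother_share + self.pe_share
        )


@dataclass
class SimTruth:
    """Ground truth of one phenotype draw, reproducible from the seed."""

    causal_block_id: str | None
    causal_snp_indices: list[int] | None
    causal_snp_effects: list[float] | None
    causal_allele_string: str | None
    regional_values: np.ndarray | None
    polygenic_values: np.ndarray | None
    realized_components: dict[str, float] = field(default_factory=dict)


def load_scenario(name_or_path: str, **overrides) -> SimScenario:
    """Load a shipped scenario config (``null``, ``scenario_a``,
    ``scenario_b``) or a YAML file path; keyword overrides win."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        cfg = yaml.safe_load(p.read_text())
    else:
        ref = resources.files("hapreml") / "scenarios" / f"{name_or_path}.yaml"
        cfg = yaml.safe_load(ref.read_text())
    cfg.update(overrides)
    return SimScenario(**cfg)


# ---------------------------------------------------------------------------
# genome layout

_BLOCK_SPACING_BP = 700_000     # > the 500 kb gap rule: blocks are LD-isolated
_SNP_SPACING_BP = 2_000
_CHROM_OFFSET_BP = 1_000_000


def _layout(scenario: SimScenario) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP chromosome labels and positions for the scenario's genome."""
    chroms, pos = [], []
    for c in range(scenario.n_chromosomes):
        for b in range(scenario.blocks_per_chromosome):
            start = _CHROM_OFFSET_BP + b * _BLOCK_SPACING_BP
            for s in range(scenario.snps_per_block):
                chroms.append(f"chr{c + 1}")
                pos.append(start + s * _SNP_SPACING_BP)
    return np.array(chroms, dtype=object), np.array(pos, dtype=np.int64)


def _block_slices(scenario: SimScenario) -> list[slice]:
    m = scenario.snps_per_block
    return [slice(b * m, (b + 1) * m) for b in range(scenario.n_blocks)]


def true_blocks(scenario: SimScenario) -> list[HaplotypeBlock]:
    """The generating block partition, as scan-ready block objects."""
    chroms, pos = _layout(scenario)
    out = []
    for i, sl in enumerate(_block_slices(scenario)):
        idx = tuple(range(sl.start, sl.stop))
        out.append(
            HaplotypeBlock(
                chromosome=str(chroms[sl.start]),
                start_bp=int(pos[sl.start]),
                end_bp=int(pos[sl.stop - 1]),
                snp_indices=idx,
                block_id=f"simblock{i}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotypes

def _founder_pool(
    rng: np.random.Generator, scenario: SimScenario, shared_alleles: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotype strings (F x m) and frequencies for one block.

    Every SNP's expected alternate-allele frequency under the founder
    frequencies lies within the scenario MAF bounds.  With
    ``shared_alleles`` every allele at every SNP is carried by at least two
    founders, so no founder is tagged by a private SNP allele.
    """
    F, m = scenario.n_founders, scenario.snps_per_block
    for _ in range(2000):
        freqs = rng.dirichlet(np.ones(F) * 2.0)
        founders = np.zeros((F, m), dtype=np.int8)
        ok = True
        for j in range(m):
            for _ in range(500):
                col = rng.integers(0, 2, size=F).astype(np.int8)
                n1 = int(col.sum())
                if shared_alleles and (n1 < 2 or n1 > F - 2):
                    continue
                p_alt = float(freqs @ col)
                if scenario.maf_min <= min(p_alt, 1 - p_alt) <= scenario.maf_max:
                    founders[:, j] = col
                    break
            else:
                ok = False
                break
        if ok and len({tuple(r) for r in founders}) == F and freqs.min() > 0.01:
            return founders, freqs
    raise ScenarioError(
        "could not satisfy MAF bounds with this founder configuration; "
        "widen the bounds or change n_founders"
    )


def simulate_genotypes(scenario: SimScenario) -> PhasedGenotypes:
    """Draw a phased panel: per block, two founder haplotypes per individual."""
    rng = np.random.default_rng([int(scenario.seed), 11])
    chroms, pos = _layout(scenario)
    n, m_total = scenario.n_individuals, len(pos)
    hap = np.zeros((n, m_total, 2), dtype=np.int8)
    founder_info: list[dict] = []
    for bi, sl in enumerate(_block_slices(scenario)):
        shared = (
            scenario.qtl_architecture == "hap_allele"
            and bi == scenario.causal_block_index
        )
        founders, freqs = _founder_pool(rng, scenario, shared)
        draws = rng.choice(scenario.n_founders, size=(n, 2), p=freqs)
        hap[:, sl, 0] = founders[draws[:, 0]]
        hap[:, sl, 1] = founders[draws[:, 1]]
        founder_info.append({"haplotypes": founders, "frequencies": freqs})
    geno = PhasedGenotypes(
        individual_ids=np.array([f"ind{i}" for i in range(n)], dtype=object),
        chromosomes=chroms,
        positions_bp=pos,
        ref_alleles=np.array(["A"] * m_total, dtype=object),
        alt_alleles=np.array(["G"] * m_total, dtype=object),
        haplotype_calls=hap,
    )
    geno.founder_info = founder_info  # type: ignore[attr-defined]
    return geno


# ---------------------------------------------------------------------------
# phenotypes

def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ScenarioError("degenerate component with zero variance")
    return (x - x.mean()) / sd * np.sqrt(target_var)


def _regional_value(
    rng: np.random.Generator,
    genotypes: PhasedGenotypes,
    scenario: SimScenario,
    block: HaplotypeBlock,
    truth: SimTruth,
) -> np.ndarray:
    idx = np.asarray(block.snp_indices)
    if scenario.qtl_architecture == "snp_additive":
        k = min(scenario.n_causal_snps, idx.size)
        causal = np.sort(rng.choice(idx, size=k, replace=False))
        effects = rng.normal(size=k)
        # effects act on standardized dosages: the iid-standardized-effect
        # architecture under which the SNP-based regional model is exact
        s = genotypes.dosages[:, causal].astype(float)
        p = s.mean(axis=0) / 2.0
        z = (s - 2 * p) / np.sqrt(2 * p * (1 - p))
        raw = z @ effects
        truth.causal_snp_indices = [int(i) for i in causal]
        truth.causal_snp_effects = [float(e) for e in effects]
        return raw
    # hap_allele: effect on the founder haplotype whose frequency is closest
    # to the target; carried copies act additively
    table = enumerate_haplotypes(genotypes, block)
    k = int(np.argmin(np.abs(table.frequencies - scenario.causal_allele_freq_target)))
    if table.frequencies[k] < 2.0 / (2 * genotypes.n_individuals):
        raise ScenarioError(
            "causal haplotype allele essentially absent; reseed or increase n"
        )
    truth.causal_allele_string = table.allele_strings[k]
    return table.diplotype_codes[:, k].astype(float)


def simulate_phenotypes(
    genotypes: PhasedGenotypes,
    scenario: SimScenario,
    cache: dict | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw phenotypes on a simulated panel; returns the table and truth.

    Realized variance shares are exact by construction: each component is
    rescaled to its target share of a unit total phenotypic variance.
    Pass the same ``cache`` dict across replicate calls on one panel to
    reuse the polygenic GRM square root (an O(n^3) eigendecomposition).
    """
    rng = np.random.default_rng([int(scenario.seed), 23])
    n = genotypes.n_individuals
    R = scenario.records_per_individual
    truth = SimTruth(None, None, None, None, None, None)
    base = np.zeros(n)

    if scenario.qtl_architecture != "none" and scenario.regional_share > 0:
        blocks = true_blocks(scenario)
        block = blocks[scenario.causal_block_index]
        truth.causal_block_id = block.block_id
        raw = _regional_value(rng, genotypes, scenario, block, truth)
        z = _standardize(raw, scenario.regional_share)
        truth.regional_values = z
        base = base + z

    if scenario.polygenic_h2 > 0:
        causal_chrom = (
            true_blocks(scenario)[scenario.causal_block_index].chromosome
            if scenario.qtl_architecture != "none"
            else None
        )
        if causal_chrom is not None and scenario.n_chromosomes > 1:
            keep = np.flatnonzero(genotypes.chromosomes != causal_chrom)
        elif causal_chrom is not None:
            causal_idx = set(
                true_blocks(scenario)[scenario.causal_block_index].snp_indices
            )
            keep = np.array(
                [i for i in range(genotypes.n_snps) if i not in causal_idx]
            )
        else:
            keep = np.arange(genotypes.n_snps)
        p = genotypes.dosages[:, keep].mean(axis=0) / 2.0
        keep = keep[(p > 0) & (p < 1)]
        key = ("polygenic_sqrt", keep.tobytes())
        if cache is not None and key in cache:
            B = cache[key]
        else:
            A = snp_grm(genotypes, keep)
            lam, Q = np.linalg.eigh(A.values)
            B = Q * np.sqrt(np.clip(lam, 0, None))
            if cache is not None:
                cache[key] = B
        g = B @ rng.normal(size=n)
        g = _standardize(g, scenario.polygenic_h2)
        truth.polygenic_values = g
        base = base + g

    df = pd.DataFrame(
        {"id": np.repeat(genotypes.individual_ids, R)}
    )
    y = scenario.intercept + np.repeat(base, R)

    sex = rng.integers(0, 2, size=n)
    df["sex"] = np.repeat(sex, R)
    y = y + scenario.sex_effect * df["sex"].to_numpy()

    if scenario.year_levels > 0 and scenario.year_share > 0:
        year = rng.integers(0, scenario.year_levels, size=n * R)
        df["year"] = np.array([f"y{v}" for v in year], dtype=object)
        eff = rng.normal(size=scenario.year_levels)
        y = y + _standardize(eff[year], scenario.year_share)

    if scenario.mother_group_size > 1 and scenario.mother_share > 0:
        mother = np.arange(n) // scenario.mother_group_size
        df["mother"] = np.repeat(
            np.array([f"m{v}" for v in mother], dtype=object), R
        )
        eff = rng.normal(size=mother.max() + 1)
        y = y + _standardize(np.repeat(eff[mother], R), scenario.mother_share)

    if R > 1 and scenario.pe_share > 0:
        pe = rng.normal(size=n)
        y = y + _standardize(np.repeat(pe, R), scenario.pe_share)

    e = rng.normal(size=n * R)
    y = y + _standardize(e, scenario.residual_share)
    df["trait"] = y

    realized = {
        "regional": scenario.regional_share if truth.regional_values is not None else 0.0,
        "polygenic": scenario.polygenic_h2 if truth.polygenic_values is not None else 0.0,
        "year": scenario.year_share if "year" in df.columns else 0.0,
        "mother": scenario.mother_share if "mother" in df.columns else 0.0,
        "pe": scenario.pe_share if (R > 1 and scenario.pe_share > 0) else 0.0,
        "residual": scenario.residual_share,
    }
    truth.realized_components = realized

    return (
        PhenotypeTable(df, "trait", repeated=R > 1),
        truth,
    )


def scenario_to_yaml(scenario: SimScenario, path: str) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(scenario), sort_keys=False))
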