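"""Synthetic clone-family populations with known variance architecture.

The generator emulates the nested design of a clonal natural population:
a small number of nearly-isogenic families, each containing several
accessions grown in biological replicates.  Genotypes are homozygous
biallelic SNPs assigned at the family level; methylomes are CG-window
methylation levels built on the logit scale from family, accession and
replicate (plant) layers with binomial read sampling at low coverage; traits
are drawn from the mixed model the analysis fits, with the methylation
random effect drawn against the similarity matrix actually computed from the
simulated methylomes — so genetic/methylation confounding arises naturally,
as it does in a real clonal population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import sample_mvn
from .io_formats import CytosineCallSet, PhenotypeTable
from .methylation_similarity import (
    SimilarityStructure,
    WindowMethylationMatrix,
    filter_windows,
    pool_replicates,
    similarity_matrix,
    window_proportions,
)
from .relatedness import CovarianceStructure, SnpMatrix, grm_from_snps

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "CloneHierarchy",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_methylomes",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Study-design and variance-architecture knobs for the generator.

    Defaults mirror the clonal-population design the pipeline targets:
    7 families x 12 accessions x 3 replicates, low (~3x) per-site coverage,
    and methylation variation dominated by the family layer, with smaller
    accession and replicate layers (logit-scale standard deviations).
    """

    n_families: int = 7
    accessions_per_family: int = 12
    replicates: int = 3
    n_snps: int = 300
    n_windows: int = 120
    window_size: int = 200
    cg_per_window: int = 5
    coverage_mean: float = 3.0
    family_meth_sd: float = 1.2
    accession_meth_sd: float = 0.4
    replicate_meth_sd: float = 0.2
    baseline_meth_sd: float = 1.0
    h2_g: float = 0.5
    h2_m: float = 0.2
    sigma2_total: float = 1.0
    trait_mean: float = 10.0
    trait_name: str = "trait"
    environment: str = "spring"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_families", "accessions_per_family", "replicates",
            "n_snps", "n_windows", "window_size", "cg_per_window",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cg_per_window > self.window_size:
            raise ValueError("cg_per_window cannot exceed window_size")
        if not (0.0 <= self.h2_g <= 1.0 and 0.0 <= self.h2_m <= 1.0):
            raise ValueError("variance fractions must lie in [0, 1]")
        if self.h2_g + self.h2_m > 1.0:
            raise ValueError("h2_g + h2_m must not exceed 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")


@dataclass
class CloneHierarchy:
    """family -> accession -> replicate plant structure of the population."""

    plants: pd.DataFrame  # columns: plant_id, accession_id, clone_group

    @property
    def families(self) -> list[str]:
        return sorted(self.plants["clone_group"].unique())

    @property
    def accessions(self) -> list[str]:
        return sorted(self.plants["accession_id"].unique())

    @property
    def accession_map(self) -> dict[str, str]:
        return dict(zip(self.plants["plant_id"], self.plants["accession_id"]))

    @property
    def family_map(self) -> dict[str, str]:
        return dict(zip(self.plants["accession_id"], self.plants["clone_group"]))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _build_hierarchy(cfg: SimConfig) -> CloneHierarchy:
    rows = []
    for f in range(1, cfg.n_families + 1):
        fam = f"F{f}"
        for a in range(1, cfg.accessions_per_family + 1):
            acc = f"{fam}A{a:02d}"
            for r in range(1, cfg.replicates + 1):
                rows.append((f"{acc}R{r}", acc, fam))
    return CloneHierarchy(pd.DataFrame(rows, columns=["plant_id", "accession_id", "clone_group"]))


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SnpMatrix, CloneHierarchy]:
    """Family-level homozygous genotypes and the plant hierarchy.

    All accessions of a family share the family genotype, so the SNP matrix
    has one representative row per family.  Per-SNP alternate-allele
    frequencies are drawn from Uniform(0.1, 0.9).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    p = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    geno = (rng.random((cfg.n_families, cfg.n_snps)) < p[None, :]).astype(float)
    hierarchy = _build_hierarchy(cfg)
    snps = SnpMatrix(
        pd.DataFrame(
            geno,
            index=hierarchy.families,
            columns=[f"snp{j + 1}" for j in range(cfg.n_snps)],
        )
    )
    return snps, hierarchy


def simulate_methylomes(
    cfg: SimConfig,
    hierarchy: CloneHierarchy,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CytosineCallSet], pd.DataFrame]:
    """Per-plant CG call sets with layered window-level methylation.

    Window logit level = baseline + family effect + accession effect (+ a
    plant-level replicate effect); every CG site of a window shares the
    window's level.  Site coverage is Poisson(coverage_mean) and methylated
    counts binomial; zero-coverage sites are absent from the call set, as in
    a real low-coverage experiment.  Also returns the accession-level true
    window proportions (without replicate noise).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    plants = hierarchy.plants
    families = hierarchy.families
    accessions = hierarchy.accessions
    fam_idx = {f: i for i, f in enumerate(families)}
    acc_idx = {a: i for i, a in enumerate(accessions)}

    nw = cfg.n_windows
    baseline = rng.normal(0.0, cfg.baseline_meth_sd, size=nw)
    fam_eff = rng.normal(0.0, cfg.family_meth_sd, size=(len(families), nw))
    acc_eff = rng.normal(0.0, cfg.accession_meth_sd, size=(len(accessions), nw))

    # CG positions: same "genome" for every plant, uniform within windows
    offsets = np.sort(
        np.stack([rng.choice(cfg.window_size, size=cfg.cg_per_window, replace=False) for _ in range(nw)])
    )
    pos = (np.arange(nw)[:, None] * cfg.window_size + offsets + 1).ravel()  # 1-based
    site_window = np.repeat(np.arange(nw), cfg.cg_per_window)
    n_sites = pos.size

    true_logit = np.zeros((len(accessions), nw))
    for a, i in acc_idx.items():
        fam = hierarchy.family_map[a]
        true_logit[i] = baseline + fam_eff[fam_idx[fam]] + acc_eff[i]
    true_levels = pd.DataFrame(_sigmoid(true_logit), index=accessions, columns=[f"w{j}" for j in range(nw)])

    calls: dict[str, CytosineCallSet] = {}
    for row in plants.itertuples(index=False):
        rep_eff = rng.normal(0.0, cfg.replicate_meth_sd, size=nw)
        level = _sigmoid(true_logit[acc_idx[row.accession_id]] + rep_eff)
        site_level = level[site_window]
        coverage = rng.poisson(cfg.coverage_mean, size=n_sites)
        meth = rng.binomial(coverage, site_level)
        keep = coverage > 0
        data = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos[keep],
                "strand": "+",
                "meth": meth[keep],
                "total": coverage[keep],
                "context": "CG",
            }
        )
        calls[row.plant_id] = CytosineCallSet(sample_id=row.plant_id, data=data)
    return calls, true_levels


def simulate_phenotypes(
    cfg: SimConfig,
    grm: CovarianceStructure,
    methmat: CovarianceStructure,
    hierarchy: CloneHierarchy,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Trait values from the mixed model with target variance fractions.

    y = mean + Z_g v + Z_m r + e with v ~ N(0, s2_g G) over families and
    r ~ N(0, s2_m M) over accessions.  Component variances are scaled by the
    mean diagonal of the induced per-plant covariance so the *population*
    variance fractions equal (h2_g, h2_m); structures are PSD-bent before
    sampling.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    plants = hierarchy.plants
    g_bent = grm.bend()
    m_bent = methmat.bend()
    gi = {lab: i for i, lab in enumerate(g_bent.labels)}
    mi = {lab: i for i, lab in enumerate(m_bent.labels)}
    fam_of_plant = [gi[f] for f in plants["clone_group"]]
    acc_of_plant = [mi[a] for a in plants["accession_id"]]

    c_g = float(np.mean(np.diag(g_bent.values)[fam_of_plant]))
    c_m = float(np.mean(np.diag(m_bent.values)[acc_of_plant]))
    sigma2_g = cfg.h2_g * cfg.sigma2_total / c_g if cfg.h2_g > 0 else 0.0
    sigma2_m = cfg.h2_m * cfg.sigma2_total / c_m if cfg.h2_m > 0 else 0.0
    sigma2_e = (1.0 - cfg.h2_g - cfg.h2_m) * cfg.sigma2_total

    v = sample_mvn(rng, sigma2_g * g_bent.values) if sigma2_g > 0 else np.zeros(g_bent.n)
    r = sample_mvn(rng, sigma2_m * m_bent.values) if sigma2_m > 0 else np.zeros(m_bent.n)
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=len(plants)) if sigma2_e > 0 else np.zeros(len(plants))
    y = cfg.trait_mean + v[fam_of_plant] + r[acc_of_plant] + e

    data = plants.copy()
    data["environment"] = cfg.environment
    data[cfg.trait_name] = y
    truth = {
        "sigma2_g": sigma2_g,
        "sigma2_m": sigma2_m,
        "sigma2_e": sigma2_e,
        "h2_g": cfg.h2_g,
        "h2_m": cfg.h2_m,
        "cov_scale": {"genetic": c_g, "methylation": c_m},
        "family_effects": dict(zip(g_bent.labels, v.tolist())),
        "accession_effects": dict(zip(m_bent.labels, r.tolist())),
    }
    return PhenotypeTable(data), truth


@dataclass
class SimulatedDataset:
    """Everything one end-to-end run of the generator produced."""

    config: SimConfig
    snps: SnpMatrix
    hierarchy: CloneHierarchy
    grm: CovarianceStructure
    calls: dict[str, CytosineCallSet]
    true_window_levels: pd.DataFrame
    windows: WindowMethylationMatrix
    similarity: SimilarityStructure
    methmat: CovarianceStructure
    phenotypes: PhenotypeTable
    truth: dict = field(default_factory=dict)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generator: genotypes -> G, methylomes -> M, phenotypes.

    The methylation similarity used to draw the trait is the one computed
    from the sampled methylomes through the standard window pipeline, not an
    idealized matrix, so its correlation with the family structure carries
    through to the trait exactly as in a real clonal design.
    """
    rng = np.random.default_rng(cfg.seed)
    snps, hierarchy = simulate_genotypes(cfg, rng)
    grm = grm_from_snps(snps)
    calls, true_levels = simulate_methylomes(cfg, hierarchy, rng)
    pooled = pool_replicates(list(calls.values()), hierarchy.accession_map)
    q = window_proportions(pooled, window_size=cfg.window_size, min_reads=10)
    q = filter_windows(q, max_missing_frac=0.5)
    sim = similarity_matrix(q)
    methmat = sim.to_covariance(bend=True)
    pheno, truth = simulate_phenotypes(cfg, grm, methmat, hierarchy, rng)
    return SimulatedDataset(
        config=cfg,
        snps=snps,
        hierarchy=hierarchy,
        grm=grm,
        calls=calls,
        true_window_levels=true_levels,
        windows=q,
        similarity=sim,
        methmat=methmat,
        phenotypes=pheno,
        truth=truth,
    )
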