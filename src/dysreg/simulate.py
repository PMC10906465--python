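"""Synthetic count experiments with known ground truth.

Emulates a two-genotype (WT vs HET), two-treatment (vehicle vs drug) bulk
RNA-seq design with 6 biological replicates per cell: negative-binomial
counts with planted per-gene log2 fold-changes, a planted "dysregulated"
gene set whose members are more likely to be differentially expressed, a
latent binary batch covariate, library-size heterogeneity, and a
per-sample mineralization phenotype driven by an osteogenic gene program.

The generative model for gene g in sample s is

    counts[g, s] ~ NB(mean = mu_g * 2**(x_s * beta_g + d_s * delta_g
                                        + b_s * gamma_g) * L_s,
                      var = mu + alpha(mu_g) * mu**2)

with genotype indicator x_s, drug-within-HET indicator d_s, batch loading
b_s in {0, 1}, library-size factor L_s ~ U(0.7, 1.3), and dispersion trend
alpha(mu) = a0 + a1/mu.  All outputs are pure functions of the parameters
including the seed; each component (counts, phenotype, annotation) draws
from its own child stream so it can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import compute_log_cpm
from .io import CountMatrix, DataError, GeneSet, GenomicInterval, SampleTable

DEFAULT_GROUPS = (("WT", "VEHICLE"), ("HET", "VEHICLE"))
DRUG_GROUPS = (
    ("WT", "VEHICLE"),
    ("HET", "VEHICLE"),
    ("HET", "DRUG"),
)

_STREAM = {"counts": 1, "phenotype": 2, "annotation": 3}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[component]])


@dataclass
class SimParams:
    """Parameters of the synthetic experiment.

    Defaults reflect a 6-vs-6 bulk design with moderate effect sizes:
    10% of genes differentially expressed at |log2fc| = 1, a 179-member
    planted set enriched 5-fold for DE, lognormal baseline means centered
    at 100, and a bulk-like dispersion trend alpha(mu) = 0.01 + 2/mu.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    groups: tuple = DEFAULT_GROUPS
    frac_de: float = 0.1
    lfc_mean: float = 1.0
    lfc_sd: float = 0.0  # 0 -> fixed |log2fc| = lfc_mean with random sign
    set_size: int = 179
    set_de_enrichment: float = 5.0
    reversal_fraction: float = 0.0
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    n_batches: int = 1
    batch_sd: float = 0.0
    program_size: int = 50
    program_activity_sd: float = 0.0  # log2-scale sd of a shared latent
    # per-sample "differentiation activity" loading on program genes
    program_coherent: bool = False  # DE program genes all upregulated in HET,
    # giving the program a common direction along the genotype axis
    phenotype_intercept: float = 1.0
    phenotype_slope: float = 1.0
    phenotype_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.set_size > self.n_genes:
            raise ValueError("set_size cannot exceed n_genes")
        if self.set_de_enrichment < 1.0:
            raise ValueError("set_de_enrichment must be >= 1")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 <= 0:
            raise ValueError("dispersion parameters must be positive")
        # expected in-set DE count is enrichment * frac_de * set_size; it
        # cannot exceed the set itself
        if self.set_de_enrichment * self.frac_de > 1.0:
            raise ValueError(
                "infeasible enrichment: set_de_enrichment * frac_de exceeds 1"
            )
        if self.n_batches not in (1, 2):
            raise ValueError("n_batches must be 1 (no batch) or 2 (binary batch)")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    gene_ids: list[str]
    true_lfc: dict[str, np.ndarray]  # contrast -> per-gene log2fc
    de_genes: dict[str, list[str]]  # contrast -> DE gene ids
    planted_set: GeneSet
    program_genes: list[str]
    batch: np.ndarray  # per-sample batch label (0/1)
    phenotype_coefficients: tuple[float, float] | None
    seed: int
    baseline_mean: np.ndarray | None = None  # per-gene mu_g
    library_factors: np.ndarray | None = None  # per-sample L_s
    dispersion: np.ndarray | None = None  # per-gene alpha(mu_g)

    def de_mask(self, contrast: str) -> np.ndarray:
        ids = set(self.de_genes[contrast])
        return np.array([g in ids for g in self.gene_ids])


def simulate_experiment(params: SimParams) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Generate counts, sample metadata and ground truth."""
    rng = _rng(params.seed, "counts")
    G = params.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]

    # design layout
    rows = []
    for geno, treat in params.groups:
        for r in range(params.n_per_group):
            rows.append(
                {
                    "sample_id": f"{geno}_{treat}_{r + 1}",
                    "genotype": geno,
                    "treatment": treat,
                }
            )
    meta = pd.DataFrame(rows)
    n = len(meta)
    x_geno = (meta["genotype"] == "HET").to_numpy(dtype=float)
    x_drug = (
        (meta["genotype"] == "HET") & (meta["treatment"] == "DRUG")
    ).to_numpy(dtype=float)

    # batch assignment: alternate within each design cell (orthogonal to design)
    batch = np.zeros(n, dtype=int)
    if params.n_batches == 2:
        for _, grp in meta.groupby(["genotype", "treatment"], sort=False):
            idx = grp.index.to_numpy()
            batch[idx[1::2]] = 1

    # baseline means and dispersions
    mu = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=G))
    alpha = params.dispersion_a0 + params.dispersion_a1 / mu

    # planted set and DE assignment
    set_idx = rng.choice(G, size=params.set_size, replace=False)
    program_idx = np.array(sorted(set_idx[: params.program_size]), dtype=int)
    in_set = np.zeros(G, dtype=bool)
    in_set[set_idx] = True
    p_de = np.where(
        in_set,
        min(params.set_de_enrichment * params.frac_de, 1.0),
        params.frac_de,
    )
    is_de = rng.random(G) < p_de

    if params.lfc_sd > 0:
        magnitude = rng.normal(params.lfc_mean, params.lfc_sd, size=G)
    else:
        magnitude = np.full(G, params.lfc_mean)
    sign = rng.choice([-1.0, 1.0], size=G)
    if params.program_coherent:
        sign[program_idx] = 1.0
    beta = np.where(is_de, sign * magnitude, 0.0)  # genotype-contrast log2fc

    # drug-contrast effect: sign-opposed for reversal_fraction of DE genes,
    # concordant for the rest, zero for non-DE genes
    delta = np.zeros(G)
    if params.reversal_fraction > 0 or any(t == "DRUG" for _g, t in params.groups):
        reverse = rng.random(G) < params.reversal_fraction
        delta = np.where(is_de, np.where(reverse, -beta, beta), 0.0)

    gamma = (
        rng.normal(0.0, params.batch_sd, size=G)
        if params.batch_sd > 0 and params.n_batches == 2
        else np.zeros(G)
    )

    libsize = rng.uniform(0.7, 1.3, size=n)

    log2_mean = (
        np.log2(mu)[:, None]
        + beta[:, None] * x_geno[None, :]
        + delta[:, None] * x_drug[None, :]
        + gamma[:, None] * batch[None, :]
    )
    # optional shared latent axis over the osteogenic program: per-sample
    # differentiation activity loading equally on all program genes
    if params.program_activity_sd > 0:
        activity = rng.normal(0.0, params.program_activity_sd, size=n)
        log2_mean[program_idx] += activity[None, :]
    mean = (2.0**log2_mean) * libsize[None, :]

    # gamma-Poisson mixture: NB with var = mu + alpha mu^2
    shape = 1.0 / alpha[:, None]
    lam = rng.gamma(shape, mean * alpha[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    meta["replicate_group"] = meta["sample_id"]
    samples = SampleTable(meta)
    counts_matrix = CountMatrix(gene_ids, list(meta["sample_id"]), counts)

    program = [gene_ids[i] for i in program_idx]
    true_lfc = {"genotype": beta.copy(), "treatment": delta.copy()}
    de_genes = {
        "genotype": [g for g, d in zip(gene_ids, beta != 0) if d],
        "treatment": [g for g, d in zip(gene_ids, delta != 0) if d],
    }
    truth = SimTruth(
        gene_ids=gene_ids,
        true_lfc=true_lfc,
        de_genes=de_genes,
        planted_set=GeneSet("planted", frozenset(gene_ids[i] for i in set_idx)),
        program_genes=program,
        batch=batch,
        phenotype_coefficients=None,
        seed=params.seed,
        baseline_mean=mu,
        library_factors=libsize,
        dispersion=alpha,
    )
    return counts_matrix, samples, truth


def simulate_phenotype(
    counts: CountMatrix, truth: SimTruth, params: SimParams
) -> SampleTable:
    """Attach a mineralization phenotype linear in the osteogenic program.

    phenotype_s = c0 + c1 * mean over program genes of log2-CPM_s + noise.
    """
    program = [g for g in truth.program_genes if g in set(counts.gene_ids)]
    if not program:
        raise DataError("no osteogenic-program gene present in the count matrix")
    rng = _rng(params.seed, "phenotype")
    expr = compute_log_cpm(counts)
    idx = [counts.gene_ids.index(g) for g in program]
    program_mean = expr.values[idx].mean(axis=0)
    noise = (
        rng.normal(0.0, params.phenotype_noise_sd, size=counts.n_samples)
        if params.phenotype_noise_sd > 0
        else np.zeros(counts.n_samples)
    )
    pheno = (
        params.phenotype_intercept + params.phenotype_slope * program_mean + noise
    )
    truth.phenotype_coefficients = (
        params.phenotype_intercept,
        params.phenotype_slope,
    )
    df = pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "phenotype": pheno,
        }
    )
    return df


def attach_phenotype(samples: SampleTable, phenotype: pd.DataFrame) -> SampleTable:
    merged = samples.frame.drop(columns=["phenotype"], errors="ignore").merge(
        phenotype, on="sample_id", how="left"
    )
    return SampleTable(merged)


def program_axis(counts: CountMatrix, truth: SimTruth) -> np.ndarray:
    """Per-sample mean log2-CPM over the osteogenic program genes."""
    expr = compute_log_cpm(counts)
    idx = [counts.gene_ids.index(g) for g in truth.program_genes]
    return expr.values[idx].mean(axis=0)


def simulate_annotation(
    n_genes: int,
    n_clusters: int,
    planted_target_fraction: float,
    genome_span: int = 50_000_000,
    seed: int = 0,
    flank: int = 2000,
) -> tuple[list[GenomicInterval], list[GenomicInterval], set[str]]:
    """Place TSS records and TFBS clusters with a known target set.

    Exactly ceil(planted_target_fraction * n_genes) genes receive a cluster
    overlapping their +/- flank promoter window; all remaining clusters are
    placed in inter-promoter gaps, clear of every promoter window.
    """
    if not 0.0 <= planted_target_fraction <= 1.0:
        raise ValueError("planted_target_fraction must lie in [0, 1]")
    rng = _rng(seed, "annotation")
    n_targets = math.ceil(planted_target_fraction * n_genes)
    if n_clusters < n_targets:
        raise DataError(
            f"need at least {n_targets} clusters to cover {n_targets} targets"
        )
    cluster_len = 300
    # each gene occupies a slot wide enough that promoters and decoy clusters
    # never collide across genes
    slot = 4 * flank + 4 * cluster_len
    if (n_genes + 1) * slot > genome_span:
        raise DataError("genome_span too small to place all features without overlap")

    tss_list: list[GenomicInterval] = []
    promoters: list[tuple[int, int]] = []
    for i in range(n_genes):
        pos = (i + 1) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        tss_list.append(GenomicInterval("chr1", pos, pos + 1, strand, f"g{i:05d}"))
        promoters.append((max(pos - flank, 0), pos + flank))

    target_idx = rng.choice(n_genes, size=n_targets, replace=False) if n_targets else np.array([], dtype=int)
    targets = {f"g{int(i):05d}" for i in target_idx}

    clusters: list[GenomicInterval] = []
    for i in target_idx:
        p0, p1 = promoters[int(i)]
        start = int(rng.integers(p0, p1 - 1))  # guarantees >= 1 base overlap
        clusters.append(
            GenomicInterval("chr1", start, start + cluster_len, ".", f"tfbs_hit_{i}")
        )
    # decoys live in the dead zone at the end of each slot, > flank away from
    # both neighbouring promoter windows
    n_decoys = n_clusters - n_targets
    for j in range(n_decoys):
        i = int(rng.integers(0, n_genes))
        pos = (i + 1) * slot + flank + cluster_len + 10
        clusters.append(
            GenomicInterval("chr1", pos, pos + cluster_len, ".", f"tfbs_decoy_{j}")
        )
    return tss_list, clusters, targets
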