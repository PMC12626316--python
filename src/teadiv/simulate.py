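"""Synthetic genotype + phenotype datasets with known truth.

Allele frequencies follow the Balding-Nichols construction: subpopulation
frequencies are Dirichlet draws around ancestral frequencies with
concentration (1 - F)/F, so the divergence parameter F is exactly the
expected Fst — which makes quantitative parameter-recovery tests possible.
A second, within-cluster Balding-Nichols level lets populations that share
an ancestral cluster differ mildly from one another, emulating a survey of
several related local populations plus one divergent outlier population.

SSR mutation is not modelled: allele labels are arbitrary fragment sizes and
distances between alleles are identity/non-identity, consistent with the
mismatch-distance AMOVA used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Locus, PhenotypeTable, PopulationMap

__all__ = [
    "SimulationConfig",
    "SimulatedFrequencies",
    "SimulatedBundle",
    "simulate_allele_freqs",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_study_like_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generator.

    ``fst_target`` is the Balding-Nichols divergence of the ancestral
    clusters; ``within_cluster_fst`` (optional) adds a second draw giving each
    population its own frequencies around its cluster's. ``admixture`` maps a
    population to a q vector over clusters for admixed sampling (only in the
    single-level model). Phenotype effect sizes are in within-cluster SD
    units; zero effects decouple phenotype from genotype.
    """

    pop_sizes: tuple[int, ...] = (5, 5, 10, 5, 5, 5, 5)
    pop_names: tuple[str, ...] | None = None
    n_clusters: int = 2
    pop_clusters: tuple[int, ...] | None = None  # cluster index per population
    n_loci: int = 14
    allele_range: tuple[int, int] = (4, 15)
    fst_target: float = 0.20
    within_cluster_fst: float = 0.0
    admixture: dict[str, tuple[float, ...]] | None = None
    missing_rate: float = 0.0
    n_descriptive: int = 18
    quantitative_effect: float = 2.0  # cluster offset on log leaf size, SD units
    descriptive_effect: float = 0.8  # cluster offset on the latent ordinal scale, SD units
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must be in (0, 1)")
        if any(s <= 0 for s in self.pop_sizes):
            raise ValueError("population sizes must be positive")
        if self.allele_range[0] < 2:
            raise ValueError("loci need at least 2 alleles")

    @property
    def populations(self) -> tuple[str, ...]:
        if self.pop_names is not None:
            return self.pop_names
        return tuple(f"P{i+1}" for i in range(len(self.pop_sizes)))

    @property
    def clusters_of_pops(self) -> tuple[int, ...]:
        if self.pop_clusters is not None:
            return self.pop_clusters
        # default: spread populations over clusters round-robin
        return tuple(i % self.n_clusters for i in range(len(self.pop_sizes)))


@dataclass
class SimulatedFrequencies:
    """Per-locus allele labels, ancestral frequencies and per-cluster frequencies."""

    allele_labels: list[np.ndarray]  # per locus, integer fragment sizes
    ancestral: list[np.ndarray]
    clusters: list[np.ndarray]  # per locus, (n_clusters, n_alleles)


@dataclass
class SimulatedBundle:
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    phenotypes: PhenotypeTable
    true_q: pd.DataFrame
    freqs: SimulatedFrequencies
    config: SimulationConfig


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float, n: int) -> np.ndarray:
    """n Dirichlet draws around p with concentration p * (1 - f) / f."""
    conc = np.maximum(p, 1e-12) * (1.0 - f) / f
    return rng.dirichlet(conc, size=n)


def simulate_allele_freqs(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedFrequencies:
    """Ancestral frequencies from a flat Dirichlet per locus; cluster
    frequencies from Dirichlet(ancestral * (1 - F)/F) with F = fst_target."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels, anc, clus = [], [], []
    lo, hi = cfg.allele_range
    for _ in range(cfg.n_loci):
        n_all = int(rng.integers(lo, hi + 1))
        base = int(rng.integers(90, 300))
        labels.append(base + 2 * np.arange(n_all))
        p = rng.dirichlet(np.ones(n_all))
        anc.append(p)
        clus.append(_balding_nichols(rng, p, cfg.fst_target, cfg.n_clusters))
    return SimulatedFrequencies(labels, anc, clus)


def simulate_genotypes(
    freqs: SimulatedFrequencies,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Draw diploid genotypes; each allele copy picks a cluster of origin from
    the individual's true q, then an allele from that cluster's frequencies.

    With ``within_cluster_fst`` > 0 each population first receives its own
    frequencies around its cluster's (pure ancestry only in that mode).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pops = cfg.populations
    pop_cluster = cfg.clusters_of_pops
    n = sum(cfg.pop_sizes)
    individuals = [f"S{i+1}" for i in range(n)]
    assignment = {}
    pop_of = []
    c = 0
    for pop, size in zip(pops, cfg.pop_sizes):
        for _ in range(size):
            assignment[individuals[c]] = pop
            pop_of.append(pop)
            c += 1

    # per-population sampling frequencies
    if cfg.within_cluster_fst > 0:
        if cfg.admixture:
            raise ValueError("admixture not supported with a within-cluster level")
        samp = [
            _stack([_balding_nichols(rng, freqs.clusters[j][pop_cluster[pi]],
                                     cfg.within_cluster_fst, 1)[0]
                    for pi in range(len(pops))])
            for j in range(cfg.n_loci)
        ]
    else:
        samp = None

    # true ancestry
    q_rows = []
    for pop in pop_of:
        if cfg.admixture and pop in cfg.admixture:
            q_rows.append(np.asarray(cfg.admixture[pop], dtype=float))
        else:
            q = np.zeros(cfg.n_clusters)
            q[pop_cluster[pops.index(pop)]] = 1.0
            q_rows.append(q)
    true_q = np.vstack(q_rows)

    calls = np.empty((n, cfg.n_loci, 2), dtype=np.int64)
    for j in range(cfg.n_loci):
        labels = freqs.allele_labels[j]
        for i in range(n):
            pi = pops.index(pop_of[i])
            for copy in range(2):
                if samp is not None:
                    p = samp[j][pi]
                else:
                    z = rng.choice(cfg.n_clusters, p=true_q[i])
                    p = freqs.clusters[j][z]
                calls[i, j, copy] = labels[rng.choice(labels.size, p=p / p.sum())]
    if cfg.missing_rate > 0:
        drop = rng.random((n, cfg.n_loci)) < cfg.missing_rate
        calls[drop] = MISSING

    loci = [Locus(f"L{j+1:02d}") for j in range(cfg.n_loci)]
    g = GenotypeMatrix(individuals, loci, calls)
    m = PopulationMap(assignment, list(pops))
    qdf = pd.DataFrame(true_q, index=individuals,
                       columns=[f"Q{c+1}" for c in range(cfg.n_clusters)])
    return g, m, qdf


def _stack(rows: list[np.ndarray]) -> np.ndarray:
    return np.vstack(rows)


# quantitative leaf traits: (median, log-scale SD) for the two directly
# simulated measurements. Dimensions are lognormal (multiplicative noise),
# the usual morphometric model; it keeps values positive and the derived
# length/width ratio well-behaved. Ratio and area follow the
# descriptor-standard derivations.
_LEAF_LENGTH = (9.5, 0.22)  # cm, log-SD
_LEAF_WIDTH = (3.2, 0.20)  # cm, log-SD


def simulate_phenotypes(
    m: PopulationMap,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Population-correlated phenotypes: quantitative leaf measurements with a
    cluster offset (in SD units) plus Gaussian noise, and coded descriptive
    traits from cluster-specific categorical distributions.

    Leaf area is leaf length x leaf width x 0.7 and the length-width ratio is
    length/width, matching the descriptor-standard derivations.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pops = cfg.populations
    pop_cluster = dict(zip(pops, cfg.clusters_of_pops))
    accessions = list(m.assignment)  # input order preserved
    cluster = np.array([pop_cluster[m.assignment[a]] for a in accessions])

    # cluster offsets alternate in sign so clusters separate symmetrically
    dirs = np.where(np.arange(cfg.n_clusters) % 2 == 0, -0.5, 0.5)
    quant = {}
    for name, (med, log_sd) in (("leaf_length", _LEAF_LENGTH), ("leaf_width", _LEAF_WIDTH)):
        log_vals = (
            np.log(med)
            + cfg.quantitative_effect * dirs[cluster] * log_sd
            + rng.normal(0, log_sd, cluster.size)
        )
        quant[name] = np.exp(log_vals)
    quant["length_width_ratio"] = quant["leaf_length"] / quant["leaf_width"]
    quant["leaf_area"] = quant["leaf_length"] * quant["leaf_width"] * 0.7
    quantitative = pd.DataFrame(quant, index=accessions)

    # descriptive traits: ordinal codes from a discretized latent Gaussian
    # whose mean is offset by cluster (descriptor codes are ordinal scores,
    # and divergent populations shift systematically along them)
    desc = {}
    code_sets = {}
    for t in range(cfg.n_descriptive):
        n_codes = int(rng.integers(2, 6))
        latent = cfg.descriptive_effect * dirs[cluster] + rng.normal(0, 1, cluster.size)
        edges = np.linspace(-1.2, 1.2, n_codes - 1)
        name = f"trait_{t+1:02d}"
        desc[name] = np.searchsorted(edges, latent) + 1
        code_sets[name] = tuple(range(1, n_codes + 1))
    descriptive = pd.DataFrame(desc, index=accessions)
    return PhenotypeTable(descriptive, quantitative, code_sets)


def make_study_like_dataset(seed: int | None = None) -> SimulatedBundle:
    """A full synthetic survey with the structure of the Chongzuo wild-tea
    sampling design: 40 accessions in 7 populations of sizes (5,5,10,5,5,5,5),
    14 multi-allelic SSR loci (4-15 alleles), two ancestral clusters with the
    first population drawn from the minor cluster (the divergent-outlier
    pattern), and population-correlated phenotypes.

    The two Balding-Nichols levels (cluster divergence 0.35, within-cluster
    0.08) are calibrated so the AMOVA among-population share of variance is
    about 20%.
    """
    cfg = SimulationConfig(
        pop_sizes=(5, 5, 10, 5, 5, 5, 5),
        pop_names=("P1", "P2", "P3", "P4", "P5", "P6", "P7"),
        n_clusters=2,
        pop_clusters=(1, 0, 0, 0, 0, 0, 0),  # first population is the outlier
        n_loci=14,
        allele_range=(4, 15),
        fst_target=0.35,
        within_cluster_fst=0.08,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    freqs = simulate_allele_freqs(cfg, rng)
    g, m, true_q = simulate_genotypes(freqs, cfg, rng)
    phen = simulate_phenotypes(m, cfg, rng)
    return SimulatedBundle(g, m, phen, true_q, freqs, cfg)
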