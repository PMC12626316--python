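"""Population differentiation: codominant AMOVA, pairwise Fst, island-model
gene flow, Nei (1972) standard genetic distance and the Mantel test.

AMOVA partitions allele-copy variance into three strata (among populations,
among individuals within populations, within individuals) using the 0/1
allele-mismatch distance summed over loci — the standard choice for
codominant SSR data when a stepwise mutation model is not assumed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, DistanceMatrix, GenotypeMatrix, PopulationMap
from .markers import AlleleFreqTable, allele_frequencies

__all__ = [
    "AmovaTable",
    "DifferentiationMatrix",
    "amova",
    "pairwise_fst",
    "gene_flow",
    "nei_distance",
    "allele_sharing_distance",
    "mantel_test",
]

_STRATA = [
    "Among populations",
    "Among individuals within populations",
    "Within individuals",
]


@dataclass
class AmovaTable:
    """df/SS/MS/variance-component/percent rows for the three strata plus
    derived F-statistics. ``components_raw`` keeps untruncated sigma^2."""

    table: pd.DataFrame  # index: strata + Total; columns df, SS, MS, sigma2, percent
    fst: float
    fis: float | None
    fit: float | None
    components_raw: tuple[float, float, float]
    truncated: bool = False


def _pair_mismatch(counts: np.ndarray) -> float:
    """Number of mismatching pairs among allele copies with these type counts."""
    n = counts.sum()
    return n * (n - 1) / 2.0 - float((counts * (counts - 1) / 2.0).sum())


def _amova_ss(g: GenotypeMatrix, m: PopulationMap) -> tuple[float, float, float]:
    """Sums of squares (among pops, among individuals within pops, within
    individuals) from per-locus allele-mismatch distances."""
    ss_ap = ss_ai = ss_wi = 0.0
    pop_rows = {p: [g.individuals.index(i) for i in m.individuals_in(p)] for p in m.populations}
    for j in range(g.n_loci):
        calls = g.calls[:, j, :]
        ok = calls[:, 0] != MISSING
        if not ok.any():
            continue
        # within individuals: each heterozygote contributes d(c1,c2)/2 = 1/2
        wi = 0.5 * float(np.sum(ok & (calls[:, 0] != calls[:, 1])))
        # within populations
        wp = 0.0
        for p, rows in pop_rows.items():
            rows_ok = [r for r in rows if ok[r]]
            if not rows_ok:
                continue
            copies = calls[rows_ok].ravel()
            _, counts = np.unique(copies, return_counts=True)
            wp += _pair_mismatch(counts) / copies.size
        copies_all = calls[ok].ravel()
        _, counts_all = np.unique(copies_all, return_counts=True)
        tot = _pair_mismatch(counts_all) / copies_all.size
        ss_wi += wi
        ss_ai += wp - wi
        ss_ap += tot - wp
    return ss_ap, ss_ai, ss_wi


def amova(g: GenotypeMatrix, m: PopulationMap) -> AmovaTable:
    """Three-level AMOVA for diploid codominant genotypes.

    Degrees of freedom are k-1 / N-k / N for N individuals in k populations;
    variance components follow the standard moment equations with
    n0 = (N - sum(n_i^2)/N)/(k-1). Negative components are truncated to zero
    for percentages and F-statistics (raw values retained).
    """
    sizes = m.sizes()
    k = len(m.populations)
    n_tot = g.n_individuals
    if k < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    for p, n in sizes.items():
        if n < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")

    ss_ap, ss_ai, ss_wi = _amova_ss(g, m)
    df = np.array([k - 1, n_tot - k, n_tot], dtype=float)
    ss = np.array([ss_ap, ss_ai, ss_wi])
    ms = ss / df
    n0 = (n_tot - sum(n * n for n in sizes.values()) / n_tot) / (k - 1)
    sigma_a = (ms[0] - ms[1]) / (2.0 * n0)
    sigma_b = (ms[1] - ms[2]) / 2.0
    sigma_c = ms[2]
    raw = (float(sigma_a), float(sigma_b), float(sigma_c))

    comp = np.array(raw)
    truncated = bool(np.any(comp < 0))
    if truncated:
        warnings.warn("negative variance component truncated to 0 for percentages")
        comp = np.clip(comp, 0.0, None)
    total = comp.sum()
    pct = 100.0 * comp / total if total > 0 else np.full(3, np.nan)

    table = pd.DataFrame(
        {"df": df.astype(int), "SS": ss, "MS": ms, "sigma2": raw, "percent": pct},
        index=_STRATA,
    )
    table.loc["Total"] = [int(df.sum()), ss.sum(), np.nan, total, pct.sum()]
    fst = float(comp[0] / total) if total > 0 else 0.0
    fis = float(comp[1] / (comp[1] + comp[2])) if (comp[1] + comp[2]) > 0 else None
    fit = float((comp[0] + comp[1]) / total) if total > 0 else None
    return AmovaTable(table, fst, fis, fit, raw, truncated)


@dataclass
class DifferentiationMatrix:
    """Pairwise Fst (symmetric, zero diagonal) and island-model Nm."""

    fst: DistanceMatrix
    nm: pd.DataFrame  # symmetric, NaN diagonal; inf where Fst truncated to 0

    def combined(self) -> pd.DataFrame:
        """Fst below the diagonal, Nm above it (reporting layout)."""
        labels = self.fst.labels
        out = pd.DataFrame("", index=labels, columns=labels, dtype=object)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i > j:
                    out.iloc[i, j] = f"{self.fst.values[i, j]:.2f}"
                elif i < j:
                    out.iloc[i, j] = f"{self.nm.iloc[i, j]:.2f}"
        return out


def pairwise_fst(g: GenotypeMatrix, m: PopulationMap) -> DifferentiationMatrix:
    """Fst for every population pair via the 2-population AMOVA, with
    Nm = (1-Fst)/(4 Fst); negative Fst estimates truncated to 0."""
    labels = list(m.populations)
    n = len(labels)
    fst = np.zeros((n, n))
    nm = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = labels[i], labels[j]
        inds = m.individuals_in(pa) + m.individuals_in(pb)
        sub_m = PopulationMap({x: m.assignment[x] for x in inds}, [pa, pb])
        res = amova(g.subset(inds), sub_m)
        f = max(res.fst, 0.0)
        fst[i, j] = fst[j, i] = f
        nm[i, j] = nm[j, i] = gene_flow(f) if f > 0 else math.inf
    return DifferentiationMatrix(DistanceMatrix(labels, fst), pd.DataFrame(nm, index=labels, columns=labels))


def gene_flow(fst: float) -> float:
    """Island-model migrants per generation, Nm = (1 - Fst) / (4 Fst)."""
    if fst <= 0:
        warnings.warn("Fst <= 0: gene flow unbounded, returning inf")
        return math.inf
    if fst >= 1:
        return 0.0
    return (1.0 - fst) / (4.0 * fst)


def nei_distance(freqs_by_pop: dict[str, AlleleFreqTable]) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between all population pairs.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with Jxy the mean over loci of the
    cross-population identity sum(x_a * y_a); loci with no data in either
    population are excluded pairwise.
    """
    pops = list(freqs_by_pop)
    n = len(pops)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        fa, fb = freqs_by_pop[pops[i]], freqs_by_pop[pops[j]]
        loci = [
            l for l in fa.freqs
            if l in fb.freqs and l not in fa.all_missing and l not in fb.all_missing
        ]
        if not loci:
            raise ValueError(f"no shared loci between {pops[i]!r} and {pops[j]!r}")
        jxy = jx = jy = 0.0
        for l in loci:
            x, y = fa.freqs[l], fb.freqs[l]
            jxy += sum(x[a] * y.get(a, 0.0) for a in x)
            jx += sum(v * v for v in x.values())
            jy += sum(v * v for v in y.values())
        jxy, jx, jy = jxy / len(loci), jx / len(loci), jy / len(loci)
        if jxy == 0:
            warnings.warn(f"no shared alleles between {pops[i]!r} and {pops[j]!r}: D = inf")
            d = math.inf
        else:
            d = max(-math.log(jxy / math.sqrt(jx * jy)), 0.0)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(pops, vals)


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Individual-level genetic distance 1 - (shared alleles)/(2 * loci),
    counting shared alleles with multiplicity over pairwise non-missing loci.

    This is the default metric for individual dendrograms and phenotype
    concordance tests; other choices are possible and population-level
    analyses do not depend on it.
    """
    n = g.n_individuals
    vals = np.zeros((n, n))
    calls = g.calls
    for i in range(n):
        for j in range(i + 1, n):
            shared = compared = 0
            for l in range(g.n_loci):
                a, b = calls[i, l], calls[j, l]
                if a[0] == MISSING or b[0] == MISSING:
                    continue
                compared += 1
                remaining = list(b)
                for x in a:
                    if x in remaining:
                        remaining.remove(x)
                        shared += 1
            d = 1.0 - shared / (2.0 * compared) if compared else 1.0
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(g.individuals, vals)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel matrix correlation with a one-tailed permutation p-value.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1) under simultaneous row/column
    permutation of ``d2``.
    """
    if sorted(d1.labels) != sorted(d2.labels):
        raise ValueError("distance matrices must share the same labels")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    order = [d2.labels.index(l) for l in d1.labels]
    a = d1.values
    b = d2.values[np.ix_(order, order)]
    n = len(d1.labels)
    il = np.tril_indices(n, k=-1)
    x = a[il]
    if x.std() == 0 or b[il].std() == 0:
        raise ValueError("zero variance in a distance triangle")
    xc = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = mat[il]
        return float(np.mean(xc * (y - y.mean()) / y.std()))

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
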