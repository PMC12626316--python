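"""Per-locus and per-population SSR diversity statistics.

Estimators follow the conventions of standard codominant-marker software:
expected heterozygosity is the biased 1 - sum(p^2) form by default (an
unbiased 2n/(2n-1) correction is available), Shannon's information index
uses natural logs, and missing data is handled by per-locus deletion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "AlleleFreqTable",
    "LocusSummary",
    "PopulationSummary",
    "allele_frequencies",
    "effective_alleles",
    "shannon_information",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fixation_index",
    "pic",
    "summarize_loci",
    "summarize_populations",
]


@dataclass
class AlleleFreqTable:
    """Allele frequencies per locus for one (sub)sample of individuals.

    ``freqs[locus]`` maps allele label -> frequency; ``copies[locus]`` is the
    number of allele copies counted (2 per non-missing call). Loci where every
    call in the subset is missing appear in ``all_missing``.
    """

    freqs: dict[str, dict[int, float]]
    copies: dict[str, int]
    all_missing: list[str] = field(default_factory=list)

    def vector(self, locus: str) -> np.ndarray:
        return np.array(sorted(self.freqs[locus].values(), reverse=True))


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    na: int
    ne: float
    i: float
    ho: float
    he: float
    f: float | None
    pic: float


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    mean_na: float
    mean_ne: float
    pct_effective: float  # 100 * mean Ne / mean Na
    mean_i: float
    mean_ho: float
    mean_he: float


def allele_frequencies(
    g: GenotypeMatrix, subset=None
) -> AlleleFreqTable:
    """Tally allele copies (2 per non-missing call) and normalize per locus."""
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty subset")
        g = g.subset(subset)
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    all_missing: list[str] = []
    for j, name in enumerate(g.locus_names):
        col = g.calls[:, j, :].ravel()
        col = col[col != MISSING]
        copies[name] = int(col.size)
        if col.size == 0:
            all_missing.append(name)
            freqs[name] = {}
            continue
        labels, counts = np.unique(col, return_counts=True)
        freqs[name] = {int(a): float(c) / col.size for a, c in zip(labels, counts)}
    return AlleleFreqTable(freqs, copies, all_missing)


def _check_p(p) -> np.ndarray:
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0 or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be positive and sum to 1")
    return p


def effective_alleles(p) -> float:
    """Effective allele count Ne = 1 / sum(p^2)."""
    p = _check_p(p)
    return float(1.0 / np.sum(p**2))


def shannon_information(p) -> float:
    """Shannon's information index I = -sum(p ln p) over allele frequencies."""
    p = _check_p(p)
    return float(-(p * np.log(p)).sum())


def observed_heterozygosity(g: GenotypeMatrix, locus: str, subset=None) -> float:
    """Fraction of non-missing calls whose two allele labels differ."""
    if subset is not None:
        g = g.subset(list(subset))
    j = g.locus_names.index(locus)
    calls = g.calls[:, j, :]
    ok = calls[:, 0] != MISSING
    if not ok.any():
        raise ValueError(f"locus {locus!r}: all calls missing in subset")
    return float(np.mean(calls[ok, 0] != calls[ok, 1]))


def expected_heterozygosity(p, unbiased: bool = False, n_copies: int | None = None) -> float:
    """He = 1 - sum(p^2); optionally the unbiased (2n/(2n-1)) small-sample form."""
    p = _check_p(p)
    he = 1.0 - float(np.sum(p**2))
    if unbiased:
        if n_copies is None or n_copies < 2:
            raise ValueError("unbiased He needs the allele-copy count (2n >= 2)")
        he *= n_copies / (n_copies - 1)
    return he


def fixation_index(ho: float, he: float) -> float | None:
    """F = 1 - Ho/He; None (undefined) when He = 0."""
    if he == 0:
        return None
    return 1.0 - ho / he


def pic(p) -> float:
    """Polymorphism information content (Botstein form):
    1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _check_p(p)
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - 2.0 * cross)


def _locus_stats(g: GenotypeMatrix, table: AlleleFreqTable, locus: str) -> LocusSummary:
    p = np.array(list(table.freqs[locus].values()))
    ho = observed_heterozygosity(g, locus)
    he = expected_heterozygosity(p)
    return LocusSummary(
        locus=locus,
        na=int(p.size),
        ne=effective_alleles(p),
        i=shannon_information(p),
        ho=ho,
        he=he,
        f=fixation_index(ho, he),
        pic=pic(p),
    )


def summarize_loci(
    g: GenotypeMatrix, m: PopulationMap | None = None
) -> pd.DataFrame:
    """Per-locus Na/Ne/I/Ho/He/F/PIC over all individuals, plus Total and Mean rows."""
    table = allele_frequencies(g)
    rows = []
    for locus in g.locus_names:
        if locus in table.all_missing:
            warnings.warn(f"locus {locus!r} skipped: no non-missing calls")
            continue
        s = _locus_stats(g, table, locus)
        rows.append(
            {"locus": s.locus, "Na": s.na, "Ne": s.ne, "I": s.i, "Ho": s.ho,
             "He": s.he, "F": s.f, "PIC": s.pic}
        )
    df = pd.DataFrame(rows).set_index("locus")
    df.loc["Total"] = df.sum(numeric_only=True)
    df.loc["Mean"] = df.drop(index="Total").mean(numeric_only=True)
    return df


def summarize_populations(g: GenotypeMatrix, m: PopulationMap) -> pd.DataFrame:
    """Per-population means across loci of Na, Ne, I, Ho, He, with the percent
    of effective alleles 100 * mean(Ne)/mean(Na)."""
    rows = []
    for pop in m.populations:
        inds = m.individuals_in(pop)
        sub = g.subset(inds)
        table = allele_frequencies(sub)
        na, ne, ii, ho, he = [], [], [], [], []
        for locus in sub.locus_names:
            if locus in table.all_missing:
                warnings.warn(f"population {pop!r}: locus {locus!r} all-missing, skipped")
                continue
            p = np.array(list(table.freqs[locus].values()))
            na.append(p.size)
            ne.append(effective_alleles(p))
            ii.append(shannon_information(p))
            ho.append(observed_heterozygosity(sub, locus))
            he.append(expected_heterozygosity(p))
        mean_na, mean_ne = float(np.mean(na)), float(np.mean(ne))
        rows.append(
            {
                "population": pop,
                "Na": mean_na,
                "Ne": mean_ne,
                "pct_effective": 100.0 * mean_ne / mean_na,
                "I": float(np.mean(ii)),
                "Ho": float(np.mean(ho)),
                "He": float(np.mean(he)),
            }
        )
    return pd.DataFrame(rows).set_index("population")
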