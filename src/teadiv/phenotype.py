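"""Phenotypic trait diversity: frequencies, Shannon-Weaver H', CV, grading,
standardization and Euclidean clustering of accessions.

Descriptive traits are ordinal integer codes from the germplasm descriptor
standard; the coefficient of variation is computed on those codes directly
(sample SD, n-1 denominator). Quantitative traits enter diversity analysis
after grading into classes of width 0.5*SD around the mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Dendrogram, DistanceMatrix, PhenotypeTable
from . import trees

__all__ = [
    "FrequencyVector",
    "TraitSummary",
    "category_frequencies",
    "shannon_index",
    "coefficient_of_variation",
    "grade_quantitative",
    "standardize",
    "euclidean_matrix",
    "hierarchical_cluster",
    "cut_tree",
    "summarize_descriptive",
]


@dataclass(frozen=True)
class FrequencyVector:
    """Category codes with their observed proportions (sum to 1)."""

    codes: tuple[int, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    frequencies: FrequencyVector
    cv: float  # percent
    shannon: float  # nats


def category_frequencies(codes) -> FrequencyVector:
    """Observed proportion of each category code, ordered by ascending code."""
    codes = np.asarray(list(codes), dtype=int)
    if codes.size == 0:
        raise ValueError("empty code list")
    uniq, counts = np.unique(codes, return_counts=True)
    props = counts / counts.sum()
    return FrequencyVector(tuple(int(c) for c in uniq), tuple(float(p) for p in props))


def shannon_index(f: FrequencyVector | np.ndarray | list) -> float:
    """Shannon-Weaver diversity H' = -sum(Pi ln Pi) in nats, with 0 ln 0 := 0."""
    p = np.asarray(f.proportions if isinstance(f, FrequencyVector) else f, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def coefficient_of_variation(values) -> float:
    """CV as a percent: 100 * sample SD (n-1) / mean."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def grade_quantitative(values, n_classes: int = 10) -> np.ndarray:
    """Grade continuous measurements into ordinal classes for diversity analysis.

    Class 1 collects x < mean - 2*SD and class ``n_classes`` collects
    x >= mean + 2*SD; the interior classes are each 0.5*SD wide. With the
    default 10 classes the grid spans mean +/- 2 SD. Returns one integer class
    (1-based) per value.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("grading requires at least 2 values")
    m, s = x.mean(), x.std(ddof=1)
    if s == 0:
        warnings.warn("zero SD: all observations fall in the central class")
        return np.full(x.shape, (n_classes + 1) // 2, dtype=int)
    # interior boundaries at m-2s, m-1.5s, ..., m+2s (n_classes-1 of them)
    offsets = -2.0 + 0.5 * np.arange(n_classes - 1)
    bounds = m + offsets * s
    return (np.searchsorted(bounds, x, side="right") + 1).astype(int)


def standardize(table: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
    """Per-trait z-scores (mean 0, sample SD 1); descriptive traits enter via
    their integer codes. Traits with zero SD are dropped with a warning."""
    if isinstance(table, PhenotypeTable):
        parts = [df for df in (table.descriptive, table.quantitative) if not df.empty]
        data = pd.concat(parts, axis=1).astype(float)
    else:
        data = table.astype(float)
    sd = data.std(ddof=1)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"traits with zero SD excluded: {list(dead)}")
        data = data.drop(columns=dead)
        sd = sd.drop(dead)
    return (data - data.mean()) / sd


def euclidean_matrix(z: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between accessions over all traits."""
    if z.isna().any().any():
        raise ValueError(
            "missing entries in standardized matrix; impute or drop before clustering"
        )
    from scipy.spatial.distance import pdist, squareform

    vals = squareform(pdist(z.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(z.index), vals)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of accessions; see :mod:`teadiv.trees`."""
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    return trees.upgma(d)


# tree cutting is shared with the marker-side dendrograms
cut_tree = trees.cut_tree


def summarize_descriptive(descriptive: pd.DataFrame) -> list[TraitSummary]:
    """Frequency distribution, CV (on codes) and Shannon H' for each coded trait."""
    out = []
    for trait in descriptive.columns:
        codes = descriptive[trait].dropna().astype(int)
        f = category_frequencies(codes)
        out.append(
            TraitSummary(
                trait=trait,
                frequencies=f,
                cv=coefficient_of_variation(codes),
                shannon=shannon_index(f),
            )
        )
    return out
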