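"""Core data model for codominant SSR genotypes, phenotypes, distances and trees.

The containers here are deliberately small and validated on construction:
every downstream statistic (diversity indices, AMOVA, UPGMA, admixture)
assumes the invariants enforced in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call. A call is either a pair of positive
#: integer allele labels (fragment sizes) or both copies MISSING.
MISSING: int = -1


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus / primer pair.

    Only ``name`` is required; motif, expected fragment size and annealing
    temperature are descriptive metadata carried through from panel design.
    """

    name: str
    repeat_motif: str = ""
    expected_size: int | None = None
    anneal_temp: float | None = None


class GenotypeMatrix:
    """Diploid codominant genotypes: individuals x loci, two allele labels per call.

    Allele labels are positive integers (fragment sizes in bp); genotypes are
    unordered, so calls are stored with the smaller label first. A missing
    call has both entries equal to :data:`MISSING`.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[Locus | str],
        calls: np.ndarray,
    ) -> None:
        self.individuals = list(individuals)
        self.loci = [l if isinstance(l, Locus) else Locus(str(l)) for l in loci]
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique within a panel")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual identifiers must be unique")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        # normalize: unordered genotypes stored sorted; missing is (-1, -1)
        calls = np.sort(calls, axis=2)
        half_missing = (calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("a call must have two allele labels or be fully missing")
        bad = (calls != MISSING) & (calls <= 0)
        if bad.any():
            raise ValueError("allele labels must be positive integers")
        self.calls = calls

    # -- shape ---------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x loci) array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    # -- access --------------------------------------------------------------
    def call(self, individual: str, locus: str) -> tuple[int, int] | None:
        i = self.individuals.index(individual)
        j = self.locus_names.index(locus)
        a, b = self.calls[i, j]
        return None if a == MISSING else (int(a), int(b))

    def subset(self, individuals: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], self.loci, self.calls[idx]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_loci} loci)"


class PopulationMap:
    """Assignment of every individual to exactly one non-empty population."""

    def __init__(
        self,
        assignment: Mapping[str, str],
        populations: Sequence[str] | None = None,
        display_names: Mapping[str, str] | None = None,
    ) -> None:
        self.assignment = dict(assignment)
        seen: list[str] = []
        for pop in self.assignment.values():
            if pop not in seen:
                seen.append(pop)
        self.populations = list(populations) if populations is not None else seen
        self.display_names = dict(display_names or {})
        for pop in self.populations:
            if not any(p == pop for p in self.assignment.values()):
                raise ValueError(f"population {pop!r} has no individuals")
        missing = set(self.assignment.values()) - set(self.populations)
        if missing:
            raise ValueError(f"populations {sorted(missing)} not declared")

    def individuals_in(self, population: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == population]

    def sizes(self) -> dict[str, int]:
        return {p: len(self.individuals_in(p)) for p in self.populations}

    def __len__(self) -> int:
        return len(self.populations)


@dataclass
class PhenotypeTable:
    """Coded descriptive traits plus quantitative traits per accession.

    ``descriptive`` holds integer category codes (ordinal scores from the
    germplasm descriptor standard), ``quantitative`` real-valued measurements
    (cm, cm^2, dimensionless ratios). ``code_sets`` declares the admissible
    code set per descriptive trait.
    """

    descriptive: pd.DataFrame
    quantitative: pd.DataFrame
    code_sets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.descriptive.empty and not self.quantitative.empty:
            if not self.descriptive.index.equals(self.quantitative.index):
                raise ValueError("descriptive and quantitative accession sets differ")
        for trait, codes in self.code_sets.items():
            if trait not in self.descriptive.columns:
                continue
            col = self.descriptive[trait].dropna()
            if not col.isin(codes).all():
                bad = sorted(set(col) - set(codes))
                raise ValueError(f"trait {trait!r} has codes outside its code set: {bad}")
        quant = self.quantitative.to_numpy(dtype=float) if not self.quantitative.empty else np.empty((0, 0))
        present = ~np.isnan(quant)
        if present.any() and not np.all(np.isfinite(quant[present]) & (quant[present] > 0)):
            raise ValueError("quantitative values must be finite and positive where present")

    @property
    def accessions(self) -> list[str]:
        base = self.descriptive if not self.descriptive.empty else self.quantitative
        return list(base.index)


class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix with zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        self.labels = list(labels)
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix must be symmetric (tol 1e-12)")
        if np.any(np.diag(values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(values < 0):
            raise ValueError("distances must be nonnegative")
        # enforce exact symmetry so downstream triangle extraction is stable
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @classmethod
    def from_lower_triangle(
        cls, labels: Sequence[str], entries: Mapping[tuple[str, str], float]
    ) -> "DistanceMatrix":
        """Build from a dict of unordered label pairs (e.g. a printed lower triangle)."""
        n = len(labels)
        vals = np.zeros((n, n))
        index = {l: i for i, l in enumerate(labels)}
        for (a, b), v in entries.items():
            i, j = index[a], index[b]
            vals[i, j] = vals[j, i] = v
        return cls(labels, vals)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in scipy condensed (row-major upper) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration step: the two clusters joined and the merge height.

    Heights are on the tree scale (half the inter-cluster distance under the
    UPGMA convention used throughout this package).
    """

    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float


class Dendrogram:
    """Ultrametric merge tree: n-1 merges with non-decreasing heights."""

    def __init__(self, leaves: Sequence[str], merges: Sequence[MergeStep]) -> None:
        self.leaves = list(leaves)
        self.merges = list(merges)
        n = len(self.leaves)
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def root_height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dendrogram({len(self.leaves)} leaves, root height {self.root_height:.4g})"
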