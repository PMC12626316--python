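"""Readers and writers: delimited codominant genotype tables, STRUCTURE
export, Newick trees and labelled distance matrices.

The genotype layout follows the GenAlEx codominant convention: a header row
declaring each locus name over two allele columns, then one row per
individual (identifier, population, two allele labels per locus). Allele
label 0 or a blank cell means a missing call.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import MISSING, Dendrogram, DistanceMatrix, GenotypeMatrix, Locus, MergeStep, PopulationMap

__all__ = [
    "GenotypeDialect",
    "read_genotypes",
    "write_genotypes",
    "write_structure",
    "write_newick",
    "read_newick",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class GenotypeDialect:
    delimiter: str = ","
    missing: str = "0"


class GenotypeParseError(ValueError):
    pass


def read_genotypes(
    path: str | Path, dialect: GenotypeDialect = GenotypeDialect()
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Parse a codominant genotype table; returns the matrix and population map."""
    lines = Path(path).read_text().splitlines()
    rows = [ln.split(dialect.delimiter) for ln in lines if ln.strip()]
    if not rows:
        raise GenotypeParseError("empty file")
    header = [c.strip() for c in rows[0]]
    allele_cols = header[2:]
    if len(allele_cols) % 2 != 0:
        raise GenotypeParseError(
            f"odd number of allele columns ({len(allele_cols)}): "
            "each locus needs two columns"
        )
    loci = []
    for j in range(0, len(allele_cols), 2):
        name = allele_cols[j]
        if allele_cols[j + 1] not in (name, ""):
            raise GenotypeParseError(
                f"locus columns {j} and {j+1} disagree: {allele_cols[j]!r} vs {allele_cols[j+1]!r}"
            )
        loci.append(Locus(name))

    individuals, assignment = [], {}
    calls = np.empty((len(rows) - 1, len(loci), 2), dtype=np.int64)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise GenotypeParseError(
                f"row {r}: expected {len(header)} fields, got {len(row)}"
            )
        ind, pop = row[0].strip(), row[1].strip()
        individuals.append(ind)
        assignment[ind] = pop
        for j in range(len(loci)):
            a, b = row[2 + 2 * j].strip(), row[3 + 2 * j].strip()
            pair = []
            for cell in (a, b):
                if cell in ("", dialect.missing):
                    pair.append(MISSING)
                else:
                    try:
                        pair.append(int(cell))
                    except ValueError:
                        raise GenotypeParseError(
                            f"row {r}: allele label {cell!r} is not an integer"
                        ) from None
            if (pair[0] == MISSING) != (pair[1] == MISSING):
                raise GenotypeParseError(
                    f"row {r}, locus {loci[j].name!r}: half-missing call"
                )
            calls[r - 2, j] = pair
    g = GenotypeMatrix(individuals, loci, calls)
    return g, PopulationMap(assignment)


def write_genotypes(
    g: GenotypeMatrix,
    m: PopulationMap,
    path: str | Path,
    dialect: GenotypeDialect = GenotypeDialect(),
) -> None:
    """Write the matrix back in the same delimited codominant layout."""
    sep = dialect.delimiter
    out = _io.StringIO()
    cols = ["Individual", "Population"]
    for name in g.locus_names:
        cols += [name, name]
    out.write(sep.join(cols) + "\n")
    for i, ind in enumerate(g.individuals):
        cells = [ind, m.assignment[ind]]
        for j in range(g.n_loci):
            a, b = g.calls[i, j]
            cells += [dialect.missing if a == MISSING else str(a),
                      dialect.missing if b == MISSING else str(b)]
        out.write(sep.join(cells) + "\n")
    Path(path).write_text(out.getvalue())


def write_structure(g: GenotypeMatrix, m: PopulationMap, path: str | Path) -> None:
    """Two-row-per-individual integer export (missing encoded -9), with a
    numeric population column, for cross-checks with external software."""
    pop_code = {p: i + 1 for i, p in enumerate(m.populations)}
    lines = []
    for i, ind in enumerate(g.individuals):
        for copy in range(2):
            cells = [ind, str(pop_code[m.assignment[ind]])]
            for j in range(g.n_loci):
                a = g.calls[i, j, copy]
                cells.append("-9" if a == MISSING else str(int(a)))
            lines.append(" ".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# -- Newick -------------------------------------------------------------------

def _newick_string(d: Dendrogram) -> str:
    if len(d.leaves) == 1:
        return f"{d.leaves[0]};"
    node_of: dict[tuple[str, ...], tuple[str, float]] = {
        (leaf,): (leaf, 0.0) for leaf in d.leaves
    }
    for step in d.merges:
        ls, lh = node_of.pop(step.left)
        rs, rh = node_of.pop(step.right)
        text = f"({ls}:{step.height - lh:.10g},{rs}:{step.height - rh:.10g})"
        node_of[tuple(sorted(step.left + step.right))] = (text, step.height)
    (text, _), = node_of.values()
    return text + ";"


def write_newick(d: Dendrogram, path: str | Path) -> None:
    """Serialize with branch lengths such that every leaf's root-to-tip
    distance equals the final merge height (ultrametric)."""
    Path(path).write_text(_newick_string(d) + "\n")


def read_newick(path: str | Path) -> Dendrogram:
    """Parse an ultrametric Newick tree back into a merge list."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.calc_node_root_distances()
    root_height = max(
        leaf.root_distance for leaf in tree.leaf_node_iter()
    ) if tree.leaf_node_iter() else 0.0
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if len(leaves) == 1:
        return Dendrogram(leaves, [])
    internal = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        height = root_height - (node.root_distance or 0.0)
        children = [
            tuple(sorted(l.taxon.label for l in ch.leaf_iter()))
            for ch in node.child_nodes()
        ]
        if len(children) != 2:
            raise ValueError("only binary ultrametric trees are supported")
        internal.append(MergeStep(children[0], children[1], height))
    internal.sort(key=lambda s: s.height)
    return Dendrogram(leaves, internal)


# -- distance matrices --------------------------------------------------------

def write_distance_matrix(d: DistanceMatrix, path: str | Path, sep: str = "\t") -> None:
    d.to_dataframe().to_csv(path, sep=sep)


def read_distance_matrix(path: str | Path, sep: str = "\t") -> DistanceMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))
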