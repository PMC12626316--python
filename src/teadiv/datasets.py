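"""Bundled reference tables from the published Chongzuo wild-tea germplasm
survey (40 accessions, 7 populations, 14 SSR loci).

These are verbatim transcriptions of the survey's printed summary tables,
shipped so the analysis formulas can be exercised and checked against the
published numbers without the raw genotype files. Known typographical
defects in the source are repaired once, here, and flagged:

* quantitative trait table: S17 leaf area printed ``25..70`` -> 25.70; S31
  leaf width printed ``2.890.96±`` -> 2.89; S34 leaf width 0.94 is retained
  as printed but flagged suspect (`SUSPECT_LEAF_WIDTH`), and the whole leaf
  width column is inconsistent with its printed mean (3.51 recomputed vs
  3.61 printed).
* the population roster lists overlapping accession ranges for two
  populations; S35 is assigned to NN and S36-S40 to JB, keeping both
  population sizes at 5.
* several descriptive-trait rows print a CV or H' that cannot be reproduced
  from their own printed frequency distribution; per-row consistency flags
  (`cv_consistent`, `h_consistent`) mark which printed values the formulas
  reproduce to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DistanceMatrix

__all__ = [
    "POPULATIONS",
    "TRAIT_CODE_SETS",
    "SUSPECT_LEAF_WIDTH",
    "load_trait_summary",
    "load_quantitative_traits",
    "load_locus_summary",
    "load_population_distances",
    "load_fst_nm",
    "load_amova",
    "load_paper_fixtures",
]

#: population code -> accession identifiers (roster overlap repaired)
POPULATIONS: dict[str, list[str]] = {
    "QS": [f"S{i}" for i in range(1, 6)],
    "RX": [f"S{i}" for i in range(6, 11)],
    "CQ": [f"S{i}" for i in range(11, 21)],
    "XL": [f"S{i}" for i in range(21, 26)],
    "LT": [f"S{i}" for i in range(26, 31)],
    "NN": [f"S{i}" for i in range(31, 36)],
    "JB": [f"S{i}" for i in range(36, 41)],
}

#: descriptive trait -> admissible ordinal codes (descriptor standard)
TRAIT_CODE_SETS: dict[str, tuple[int, ...]] = {
    "Tree type": (1, 2, 3),
    "Tree posture": (1, 2, 3),
    "Branch density": (1, 2, 3),
    "Bud and leaf color": (1, 2, 3, 4, 5),
    "Bud and leaf pubescence": (1, 2, 3, 4, 5),
    "Leaf blade shape": (1, 2, 3, 4, 5),
    "Leaf blade color": (1, 2, 3, 4),
    "Leaf surface relief": (1, 2, 3),
    "Leaf blade curvature": (1, 2, 3),
    "Leaf blade texture": (1, 2, 3),
    "Serration sharpness": (1, 2, 3),
    "Serration density": (1, 2, 3),
    "Serration depth": (1, 2, 3),
    "Leaf base shape": (1, 2),
    "Leaf apex shape": (1, 2, 3, 4),
    "Leaf margin undulation": (1, 2, 3),
    "Leaf attitude": (1, 2, 3, 4),
    "Leaf size": (1, 2, 3, 4),
}

# trait: (percent per code 1..5 or None, printed CV, printed H',
#         cv_consistent, h_consistent)
_TRAIT_ROWS = [
    ("Tree type", (0.0, 87.5, 12.5, None, None), 15.76, 0.38, True, True),
    ("Tree posture", (50.0, 40.0, 10.0, None, None), 41.99, 0.71, True, False),
    ("Branch density", (62.5, 25.0, 12.5, None, None), 47.74, 0.90, True, True),
    ("Bud and leaf color", (0.0, 37.5, 50.0, 12.5, 0.0), 24.36, 0.97, True, True),
    ("Bud and leaf pubescence", (12.5, 50.0, 27.5, 10.0, 0.0), 35.47, 0.70, True, False),
    ("Leaf blade shape", (0.0, 5.0, 7.5, 62.5, 25.0), 17.91, 0.83, True, False),
    ("Leaf blade color", (37.5, 37.5, 12.5, 12.5, None), 50.64, 1.00, True, False),
    ("Leaf surface relief", (25.0, 60.0, 15.0, None, None), 32.38, 0.94, False, True),
    ("Leaf blade curvature", (12.5, 42.5, 45.0, None, None), 29.68, 0.98, False, True),
    ("Leaf blade texture", (12.2, 62.5, 25.0, None, None), 28.57, 0.90, False, True),
    ("Serration sharpness", (25.0, 50.0, 25.0, None, None), 35.81, 1.04, True, True),
    ("Serration density", (15.0, 47.5, 37.5, None, None), 29.77, 1.01, False, True),
    ("Serration depth", (40.0, 47.5, 12.5, None, None), 39.36, 0.72, True, False),
    ("Leaf base shape", (87.5, 12.5, None, None, None), 29.77, 0.38, True, True),
    ("Leaf apex shape", (10.0, 40.0, 35.0, 15.0, None), 34.34, 1.02, True, False),
    ("Leaf margin undulation", (40.0, 47.5, 12.5, None, None), 38.28, 0.98, False, True),
    ("Leaf attitude", (12.5, 75.0, 12.5, 0.0, None), 25.32, 0.74, True, True),
    ("Leaf size", (25.0, 62.5, 12.5, 0.0, None), 32.38, 1.00, True, False),
]


def load_trait_summary() -> pd.DataFrame:
    """Printed descriptive-trait distributions (percent per code), CV and H',
    with per-row flags marking which printed statistics are internally
    consistent with the printed frequencies."""
    rows = []
    for name, pct, cv, h, okc, okh in _TRAIT_ROWS:
        row = {"trait": name, "cv": cv, "shannon": h,
               "cv_consistent": okc, "h_consistent": okh}
        for c, v in enumerate(pct, start=1):
            row[f"pct_{c}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


# per-accession quantitative traits (mean of 3 measurements); typo repairs
# applied: S17 leaf area 25.70, S31 leaf width 2.89
_QUANT = {
    # acc: (leaf_length, leaf_width, length_width_ratio, leaf_area)
    "S1": (15.81, 5.49, 2.91, 60.74), "S2": (16.99, 5.31, 3.23, 63.00),
    "S3": (16.16, 5.56, 2.93, 62.79), "S4": (16.82, 5.25, 3.29, 61.46),
    "S5": (16.72, 5.49, 3.14, 63.49), "S6": (7.87, 3.82, 2.13, 21.29),
    "S7": (7.67, 3.86, 2.08, 20.63), "S8": (7.68, 2.26, 1.84, 22.71),
    "S9": (7.47, 4.25, 1.89, 21.86), "S10": (7.89, 4.07, 1.99, 22.62),
    "S11": (12.57, 2.82, 5.00, 24.26), "S12": (13.13, 2.51, 5.53, 22.97),
    "S13": (13.20, 3.03, 4.57, 27.68), "S14": (12.06, 3.04, 4.26, 25.47),
    "S15": (12.35, 3.26, 3.87, 28.30), "S16": (12.64, 3.05, 4.29, 27.27),
    "S17": (12.38, 3.00, 4.44, 25.70), "S18": (12.88, 3.62, 3.59, 32.94),
    "S19": (11.41, 3.83, 3.13, 30.77), "S20": (14.28, 3.07, 4.90, 30.59),
    "S21": (6.60, 2.77, 2.57, 12.75), "S22": (6.96, 3.34, 2.11, 16.30),
    "S23": (7.59, 2.91, 2.95, 15.14), "S24": (6.94, 2.80, 2.82, 13.22),
    "S25": (7.64, 2.77, 2.90, 15.02), "S26": (12.38, 3.15, 4.16, 27.35),
    "S27": (11.89, 3.40, 3.78, 27.96), "S28": (12.58, 3.39, 3.78, 29.93),
    "S29": (11.88, 3.09, 4.02, 25.60), "S30": (13.35, 2.69, 5.11, 24.97),
    "S31": (5.97, 2.89, 2.16, 12.39), "S32": (6.47, 2.65, 2.53, 12.08),
    "S33": (5.65, 2.75, 2.10, 11.06), "S34": (5.96, 0.94, 2.32, 12.08),
    "S35": (6.84, 2.61, 2.82, 12.20), "S36": (7.91, 4.50, 1.87, 24.42),
    "S37": (7.61, 4.38, 1.77, 23.15), "S38": (8.09, 4.52, 1.89, 25.13),
    "S39": (8.36, 4.43, 2.00, 25.70), "S40": (8.20, 3.75, 2.26, 21.19),
}

#: accessions whose printed leaf width is suspect (excluded from any
#: computation that relies on the leaf-width column)
SUSPECT_LEAF_WIDTH: tuple[str, ...] = ("S34",)

#: printed summary row of the quantitative table (mean over the 40 accessions)
QUANT_PRINTED_MEANS = {
    "leaf_length": 10.42,
    "leaf_width": 3.61,  # NOT reproducible from the printed per-accession values
    "length_width_ratio": 3.12,
    "leaf_area": 27.10,
}
QUANT_PRINTED_SHANNON = {
    "leaf_length": 1.91,
    "leaf_width": 1.90,
    "length_width_ratio": 1.93,
    "leaf_area": 1.70,
}


def load_quantitative_traits() -> pd.DataFrame:
    """The 40 printed per-accession quantitative leaf traits (repairs applied)."""
    return pd.DataFrame.from_dict(
        _QUANT, orient="index",
        columns=["leaf_length", "leaf_width", "length_width_ratio", "leaf_area"],
    )


# printed per-locus polymorphism statistics
_LOCUS_ROWS = [
    # locus, Na, Ne, I, Ho, He, F, PIC
    ("234", 8, 3.76, 1.58, 0.70, 0.73, 0.05, 0.69),
    ("478", 5, 3.75, 1.39, 0.40, 0.73, 0.46, 0.69),
    ("A5", 4, 1.58, 0.72, 0.44, 0.37, -0.20, 0.34),
    ("CsFM1051", 9, 5.45, 1.89, 0.76, 0.82, 0.07, 0.79),
    ("CsFM1058", 8, 4.74, 1.71, 0.69, 0.79, 0.12, 0.76),
    ("CsFM1068", 14, 8.41, 2.31, 0.74, 0.88, 0.16, 0.87),
    ("CsFM1158", 6, 3.19, 1.32, 0.45, 0.69, 0.35, 0.64),
    ("CsFM1599", 5, 3.78, 1.42, 0.64, 0.74, 0.13, 0.69),
    ("CsFM1696", 10, 4.34, 1.83, 0.65, 0.77, 0.16, 0.75),
    ("CsFM1715", 15, 8.28, 2.36, 0.88, 0.88, 0.01, 0.87),
    ("CsFM1828", 13, 5.00, 2.05, 0.74, 0.80, 0.07, 0.79),
    ("CSK014", 9, 2.62, 1.33, 0.44, 0.62, 0.30, 0.58),
    ("CSK065", 4, 1.36, 0.54, 0.08, 0.26, 0.69, 0.25),
    ("SSR1", 7, 2.61, 1.36, 0.44, 0.62, 0.29, 0.59),
]


def load_locus_summary() -> pd.DataFrame:
    """Printed per-locus Na/Ne/I/Ho/He/F/PIC for the 14-primer panel."""
    return pd.DataFrame(
        _LOCUS_ROWS, columns=["locus", "Na", "Ne", "I", "Ho", "He", "F", "PIC"]
    ).set_index("locus")


_DIST_LABELS = ["CQ", "LT", "JB", "NN", "RX", "QS", "XL"]
_DIST_LOWER = {
    ("LT", "CQ"): 0.32,
    ("JB", "CQ"): 0.25, ("JB", "LT"): 0.25,
    ("NN", "CQ"): 0.35, ("NN", "LT"): 0.41, ("NN", "JB"): 0.34,
    ("RX", "CQ"): 0.30, ("RX", "LT"): 0.33, ("RX", "JB"): 0.24, ("RX", "NN"): 0.45,
    ("QS", "CQ"): 0.68, ("QS", "LT"): 0.74, ("QS", "JB"): 0.70,
    ("QS", "NN"): 0.69, ("QS", "RX"): 0.65,
    ("XL", "CQ"): 0.30, ("XL", "LT"): 0.41, ("XL", "JB"): 0.34,
    ("XL", "NN"): 0.30, ("XL", "RX"): 0.45, ("XL", "QS"): 0.66,
}


def load_population_distances() -> DistanceMatrix:
    """Printed Nei genetic distances among the 7 populations (symmetrized
    from the printed lower triangle)."""
    return DistanceMatrix.from_lower_triangle(_DIST_LABELS, _DIST_LOWER)


_FST_LOWER = {
    ("LT", "CQ"): 0.11,
    ("JB", "CQ"): 0.06, ("JB", "LT"): 0.10,
    ("NN", "CQ"): 0.13, ("NN", "LT"): 0.23, ("NN", "JB"): 0.16,
    ("RX", "CQ"): 0.09, ("RX", "LT"): 0.16, ("RX", "JB"): 0.09, ("RX", "NN"): 0.19,
    ("QS", "CQ"): 0.26, ("QS", "LT"): 0.37, ("QS", "JB"): 0.31,
    ("QS", "NN"): 0.38, ("QS", "RX"): 0.27,
    ("XL", "CQ"): 0.09, ("XL", "LT"): 0.18, ("XL", "JB"): 0.12,
    ("XL", "NN"): 0.15, ("XL", "RX"): 0.18, ("XL", "QS"): 0.32,
}
_NM_UPPER = {
    ("CQ", "LT"): 1.98, ("CQ", "JB"): 4.06, ("CQ", "NN"): 1.69,
    ("CQ", "RX"): 2.69, ("CQ", "QS"): 0.71, ("CQ", "XL"): 2.53,
    ("LT", "JB"): 2.30, ("LT", "NN"): 0.86, ("LT", "RX"): 1.34,
    ("LT", "QS"): 0.42, ("LT", "XL"): 1.17,
    ("JB", "NN"): 1.35, ("JB", "RX"): 2.69, ("JB", "QS"): 0.57, ("JB", "XL"): 1.83,
    ("NN", "RX"): 1.09, ("NN", "QS"): 0.41, ("NN", "XL"): 1.41,
    ("RX", "QS"): 0.68, ("RX", "XL"): 1.18,
    ("QS", "XL"): 0.52,
}
_FSTNM_LABELS = ["CQ", "LT", "JB", "NN", "RX", "QS", "XL"]


def load_fst_nm() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Printed pairwise Fst and island-model gene flow Nm (both symmetrized)."""
    n = len(_FSTNM_LABELS)
    fst = pd.DataFrame(np.zeros((n, n)), index=_FSTNM_LABELS, columns=_FSTNM_LABELS)
    nm = pd.DataFrame(np.full((n, n), np.nan), index=_FSTNM_LABELS, columns=_FSTNM_LABELS)
    for (a, b), v in _FST_LOWER.items():
        fst.loc[a, b] = fst.loc[b, a] = v
    for (a, b), v in _NM_UPPER.items():
        nm.loc[a, b] = nm.loc[b, a] = v
    return fst, nm


def load_amova() -> pd.DataFrame:
    """Printed AMOVA rows (df, SS, MS, variance component, percent).

    The printed third stratum is labelled "Among individuals" but its degrees
    of freedom (40, with 6/33/40 summing to 79 = 2N-1) identify it as the
    within-individual stratum of a standard codominant AMOVA; it is stored
    under that name.
    """
    rows = [
        ("Among populations", 6, 99.29, 16.55, 1.08, 20.46),
        ("Among individuals within populations", 33, 147.15, 4.46, 0.28, 5.32),
        ("Within individuals", 40, 156.00, 3.90, 3.90, 74.22),
        ("Total", 79, 402.44, np.nan, 5.26, 100.0),
    ]
    return pd.DataFrame(
        rows, columns=["stratum", "df", "SS", "MS", "sigma2", "percent"]
    ).set_index("stratum")


@dataclass
class FixtureBundle:
    trait_summary: pd.DataFrame
    quantitative: pd.DataFrame
    locus_summary: pd.DataFrame
    population_distances: DistanceMatrix
    fst: pd.DataFrame
    nm: pd.DataFrame
    amova: pd.DataFrame
    populations: dict[str, list[str]]
    trait_code_sets: dict[str, tuple[int, ...]]


def load_paper_fixtures() -> FixtureBundle:
    """Everything at once: all bundled printed tables of the survey."""
    fst, nm = load_fst_nm()
    return FixtureBundle(
        trait_summary=load_trait_summary(),
        quantitative=load_quantitative_traits(),
        locus_summary=load_locus_summary(),
        population_distances=load_population_distances(),
        fst=fst,
        nm=nm,
        amova=load_amova(),
        populations={k: list(v) for k, v in POPULATIONS.items()},
        trait_code_sets=dict(TRAIT_CODE_SETS),
    )
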