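"""One-command orchestration: run the full dual phenotype + SSR analysis and
write the report tables.

Artifacts (delimited text, 2-decimal rendering with full-precision sidecars
where relevant) mirror the standard layout of such surveys: descriptive-trait
summary, quantitative summary, phenotype dendrogram + groups, per-locus and
per-population marker summaries, Delta-K table + Q matrix, population
distance matrix + Newick tree, combined Fst/Nm matrix, AMOVA table and the
Mantel result, plus a manifest recording config and seeds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix, PhenotypeTable, PopulationMap
from . import admixture as adm
from . import differentiation as diff
from . import io as tio
from . import markers, phenotype, trees

log = logging.getLogger("teadiv.pipeline")

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Run configuration; all randomness flows from ``seed``."""

    output_dir: str | Path = "teadiv_out"
    genotype_path: str | Path | None = None  # else pass objects to run_full_analysis
    phenotype_quant_path: str | Path | None = None
    linkage: str = "average"
    nei_variant: str = "nei1972"
    grading_classes: int = 10
    mantel_permutations: int = 9999
    kmax: int = 5
    reps: int = 10
    sweeps: int = 20_000
    burnin: int = 5_000
    membership_threshold: float = 0.6
    seed: int = 0


def _fmt(df: pd.DataFrame, path: Path, decimals: int = 2) -> None:
    df.round(decimals).to_csv(path, sep="\t")
    df.to_csv(path.with_suffix(".full.tsv"), sep="\t")


def run_full_analysis(
    cfg: AnalysisConfig,
    genotypes: GenotypeMatrix | None = None,
    popmap: PopulationMap | None = None,
    phenotypes: PhenotypeTable | None = None,
) -> Path:
    """Run every stage in order and return the report directory.

    Inputs come either from the config paths or as in-memory objects. A stage
    failure aborts with the stage name; artifacts already written remain.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": {k: str(v) for k, v in asdict(cfg).items()},
                      "stages": [], "warnings": []}

    if genotypes is None:
        if cfg.genotype_path is None:
            raise ValueError("no genotype input given")
        genotypes, popmap = tio.read_genotypes(cfg.genotype_path)
    assert popmap is not None

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            if phenotypes is not None:
                stage("trait_summary")
                summaries = phenotype.summarize_descriptive(phenotypes.descriptive)
                rows = []
                for s in summaries:
                    row = {"trait": s.trait, "cv": s.cv, "shannon": s.shannon}
                    for c, p in zip(s.frequencies.codes, s.frequencies.proportions):
                        row[f"pct_{c}"] = 100.0 * p
                    rows.append(row)
                _fmt(pd.DataFrame(rows).set_index("trait"), out / "trait_summary.tsv")

                stage("quantitative_summary")
                q = phenotypes.quantitative
                summ = pd.DataFrame({
                    "min": q.min(), "max": q.max(), "mean": q.mean(),
                    "sd": q.std(ddof=1),
                    "cv_pct": 100.0 * q.std(ddof=1) / q.mean(),
                    "shannon_graded": [
                        phenotype.shannon_index(
                            phenotype.category_frequencies(
                                phenotype.grade_quantitative(q[c], cfg.grading_classes)))
                        for c in q.columns],
                })
                _fmt(summ, out / "quantitative_summary.tsv")

                stage("phenotype_clustering")
                z = phenotype.standardize(phenotypes)
                pheno_d = phenotype.euclidean_matrix(z)
                pheno_tree = phenotype.hierarchical_cluster(pheno_d, cfg.linkage)
                tio.write_newick(pheno_tree, out / "phenotype_dendrogram.nwk")
                groups = trees.cut_tree(pheno_tree, k=3)
                pd.Series(groups, name="group").to_csv(out / "phenotype_groups.tsv", sep="\t")
            else:
                pheno_d = None

            stage("locus_summary")
            _fmt(markers.summarize_loci(genotypes, popmap), out / "locus_summary.tsv")

            stage("population_summary")
            _fmt(markers.summarize_populations(genotypes, popmap), out / "population_summary.tsv")

            stage("admixture_scan")
            scan = adm.replicate_scan(
                genotypes, kmax=cfg.kmax, reps=cfg.reps,
                sweeps=cfg.sweeps, burnin=cfg.burnin, seed=cfg.seed)
            scan.to_csv(out / "lnpd_table.tsv", sep="\t")
            evanno, best_k = adm.evanno_delta_k(scan)
            _fmt(evanno, out / "evanno.tsv", decimals=3)
            manifest["optimal_K"] = best_k
            run = adm.gibbs_admixture(
                genotypes, best_k, sweeps=cfg.sweeps, burnin=cfg.burnin, seed=cfg.seed)
            run.q.round(4).to_csv(out / "q_matrix.tsv", sep="\t")
            adm.classify_membership(run.q, cfg.membership_threshold).to_csv(
                out / "membership.tsv", sep="\t")

            stage("population_distances")
            freqs_by_pop = {
                p: markers.allele_frequencies(genotypes, popmap.individuals_in(p))
                for p in popmap.populations}
            nei = diff.nei_distance(freqs_by_pop)
            tio.write_distance_matrix(nei, out / "population_distances.tsv")
            pop_tree = trees.upgma(nei)
            tio.write_newick(pop_tree, out / "population_dendrogram.nwk")

            stage("fst_nm")
            dm = diff.pairwise_fst(genotypes, popmap)
            dm.combined().to_csv(out / "fst_nm.tsv", sep="\t")

            stage("amova")
            res = diff.amova(genotypes, popmap)
            _fmt(res.table, out / "amova.tsv")
            manifest["fst_overall"] = res.fst

            stage("mantel")
            if pheno_d is not None:
                ind_d = diff.allele_sharing_distance(genotypes)
                r, p = diff.mantel_test(
                    ind_d, pheno_d, n_perm=cfg.mantel_permutations, seed=cfg.seed)
                (out / "mantel.tsv").write_text(f"r\tp\tn_perm\n{r:.4f}\t{p:.4g}\t{cfg.mantel_permutations}\n")
                manifest["mantel"] = {"r": r, "p": p}

            manifest["warnings"] = [str(w.message) for w in caught]
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        failed = manifest["stages"][-1] if manifest["stages"] else "input"
        raise RuntimeError(f"stage {failed!r} failed: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
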