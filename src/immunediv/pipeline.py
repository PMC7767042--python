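"""End-to-end orchestration: simulate/load -> filter -> statistics -> tests.

Stage order: load or generate genotypes; potentially-functional filter;
per-locus population statistics and taxon association; pairwise set F_ST
per contrast; LD summaries; gene-set resampling tests; inversion-overlap
permutation; hierarchical-island outlier scan.  Each stage writes a TSV
and logs its counts; a summary JSON aggregates the headline numbers.

All randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawning, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core_io, functional, ld, outliers, popstats, resampling, simulate

logger = logging.getLogger("immunediv")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``synthetic`` (the default study-mimic generator) or the four
    input paths must be provided.  ``contrasts`` defaults to all taxon
    pairs.  ``m`` is the Bonferroni denominator (defaults to the number of
    SNPs tested).
    """

    synthetic: simulate.StudyMimicConfig | None = field(
        default_factory=simulate.StudyMimicConfig
    )
    vcf: str | None = None
    taxon_table: str | None = None
    genes_bed: str | None = None
    inversions_bed: str | None = None
    immune_list: str | None = None
    codon_usage: str | None = None
    exclusion_bed: str | None = None
    contrasts: tuple[tuple[str, str], ...] | None = None
    B: int = 1000
    alpha: float = 0.05
    m: int | None = None
    near_distance: int = 1_000_000
    ld_thresholds: tuple[float, ...] = (0.5, 0.8, 0.95)
    ld_max_between_pairs: int = 500
    outlier: outliers.HierIslandConfig | None = None
    run_outlier_scan: bool = True
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "inversions" in syn:
                syn["inversions"] = tuple(
                    core_io.InversionRegion(**iv) for iv in syn["inversions"]
                )
            raw["synthetic"] = simulate.StudyMimicConfig(**syn)
        elif raw.get("vcf"):
            raw["synthetic"] = None
        if raw.get("outlier"):
            cfg = dict(raw["outlier"])
            if "sampled_demes" in cfg:
                cfg["sampled_demes"] = tuple(tuple(x) for x in cfg["sampled_demes"])
            raw["outlier"] = outliers.HierIslandConfig(**cfg)
        if raw.get("contrasts"):
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(**raw)


def _load(config: RunConfig, seed: int):
    if config.vcf is not None:
        matrix = core_io.read_vcf(config.vcf, config.taxon_table)
        genes, inversions = core_io.read_annotations(
            config.genes_bed, config.inversions_bed, config.immune_list
        )
        immune_ids = [g.gene_id for g in genes if g.immune]
        matrix.loci = core_io.assign_snps_to_genes(matrix.loci, genes)
        return matrix, genes, inversions, immune_ids
    syn = config.synthetic or simulate.StudyMimicConfig()
    bundle = simulate.gen_study_mimic(syn, seed=seed)
    return bundle.matrix, bundle.genes, bundle.inversions, bundle.immune_gene_ids


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the summary dictionary.

    When ``config.out_dir`` is set, per-stage TSVs and ``summary.json``
    are written there.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % 2**31
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed}

    # ---- stage 1: load / generate -------------------------------------
    matrix, genes, inversions, immune_ids = _load(config, int(seeds[0]))
    taxa = matrix.taxa
    logger.info(
        "loaded %d individuals x %d SNPs, %d genes (%d immune), %d inversions",
        matrix.n_individuals, matrix.n_loci, len(genes), len(immune_ids), len(inversions),
    )
    summary["n_individuals"] = matrix.n_individuals
    summary["n_snps_total"] = matrix.n_loci

    exclusions: list[core_io.GeneAnnotation] = []
    if config.exclusion_bed:
        raw = core_io._read_bed(config.exclusion_bed)
        exclusions = [
            core_io.GeneAnnotation(gene_id=n, chromosome=c, start=s, end=e)
            for c, s, e, n in raw
        ]

    # ---- stage 2: potentially-functional filter -----------------------
    usage = (
        functional.CodonUsageTable.from_tsv(config.codon_usage)
        if config.codon_usage
        else None
    )
    mask = functional.potentially_functional_mask(matrix.loci, usage)
    kept = np.flatnonzero(mask)
    if kept.size < matrix.n_loci:
        matrix = matrix.subset_loci(kept)
    logger.info("functional filter kept %d / %d SNPs", kept.size, mask.size)
    summary["n_snps_functional"] = int(kept.size)

    # ---- stage 3: per-locus statistics + association ------------------
    assoc = [popstats.genotype_association(matrix, i, taxa) for i in range(matrix.n_loci)]
    pvals = np.array([a.p_value for a in assoc])
    m = config.m if config.m is not None else matrix.n_loci
    flags, threshold = popstats.bonferroni_adjust(pvals, m=m, alpha=config.alpha)
    het = {t: popstats.observed_heterozygosity(matrix, t) for t in taxa}
    rows = []
    for i, snp in enumerate(matrix.loci):
        row = {
            "locus": snp.label,
            "chrom": snp.chromosome,
            "pos": snp.position,
            "gene": ";".join(snp.gene_ids) or None,
        }
        for t in taxa:
            row[f"freq_{t}"] = popstats.allele_frequency(matrix, t, i)[0]
            row[f"hobs_{t}"] = het[t].per_locus[i]
        row.update(
            chi2=assoc[i].chi2, df=assoc[i].df, p=assoc[i].p_value,
            bonferroni=bool(flags[i]),
        )
        rows.append(row)
    tables["per_locus_stats"] = pd.DataFrame(rows)
    sig_genes = {
        g for i, snp in enumerate(matrix.loci) if flags[i] for g in snp.gene_ids
    }
    summary["n_significant_snps"] = int(flags.sum())
    summary["n_diverged_genes"] = len(sig_genes)
    summary["bonferroni_threshold"] = threshold
    summary["mean_heterozygosity"] = {t: het[t].mean for t in taxa}
    logger.info("association: %d SNPs significant at p < %.3g", flags.sum(), threshold)

    # ---- stage 4: pairwise F_ST per contrast --------------------------
    contrasts = config.contrasts or tuple(itertools.combinations(taxa, 2))
    fst_rows = []
    gene_map = core_io.gene_locus_map(matrix.loci)
    immune_loci = sorted({i for g in immune_ids for i in gene_map.get(g, [])})
    summary["set_fst"] = {}
    for ta, tb in contrasts:
        res_all = popstats.wc_fst_set(matrix, [ta, tb])
        res_imm = (
            popstats.wc_fst_set(matrix, [ta, tb], immune_loci) if immune_loci else None
        )
        fst_rows.append(
            {
                "taxon_a": ta,
                "taxon_b": tb,
                "fst_all": res_all.theta,
                "fst_immune": res_imm.theta if res_imm else np.nan,
                "n_loci_used": res_all.n_loci_used,
                "n_monomorphic": res_all.n_excluded,
            }
        )
        summary["set_fst"][f"{ta}_vs_{tb}"] = res_imm.theta if res_imm else res_all.theta
    tables["set_fst"] = pd.DataFrame(fst_rows)

    # ---- stage 5: LD summaries ----------------------------------------
    ld_frames = []
    for t in taxa:
        ld_frames.append(
            ld.ld_summary(
                matrix,
                t,
                thresholds=config.ld_thresholds,
                max_between_pairs=config.ld_max_between_pairs,
                seed=int(seeds[1]),
            )
        )
    tables["ld_summary"] = pd.concat(ld_frames, ignore_index=True)
    high_ld = tables["ld_summary"].query("threshold == 0.8")["proportion"]
    summary["ld_prop_r2_gt_0.8"] = float(np.nanmean(high_ld)) if len(high_ld) else None

    # ---- stage 6: gene-set resampling tests ---------------------------
    summary["geneset_fst_p"] = {}
    gs_rows = []
    for ci, (ta, tb) in enumerate(contrasts):
        res = resampling.geneset_fst_test(
            matrix, (ta, tb), genes, immune_ids,
            B=config.B, seed=int(seeds[2]) + ci,
            exclusion_regions=exclusions,
        )
        gs_rows.append(
            {
                "test": "geneset_fst", "contrast": f"{ta}_vs_{tb}",
                "observed": res.observed, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "null_sem": res.null_sem,
                "p": res.p_value, "B": res.B, "seed": res.seed,
            }
        )
        summary["geneset_fst_p"][f"{ta}_vs_{tb}"] = res.p_value
    snp_res = resampling.geneset_snpcount_test(
        matrix, genes, immune_ids, B=config.B, seed=int(seeds[3]),
        exclusion_regions=exclusions,
    )
    gs_rows.append(
        {
            "test": "geneset_snpcount", "contrast": "all",
            "observed": snp_res.observed, "null_mean": snp_res.null_mean,
            "null_sd": snp_res.null_sd, "null_sem": snp_res.null_sem,
            "p": snp_res.p_value, "B": snp_res.B, "seed": snp_res.seed,
        }
    )
    summary["geneset_snpcount_p"] = snp_res.p_value

    # ---- stage 7: inversion-overlap permutation -----------------------
    if inversions:
        inv_res = resampling.inversion_overlap_test(
            genes, immune_ids, inversions,
            near_distance=config.near_distance, B=config.B, seed=int(seeds[4]),
        )
        gs_rows.append(
            {
                "test": "inversion_overlap", "contrast": "all",
                "observed": inv_res.observed, "null_mean": inv_res.null_mean,
                "null_sd": inv_res.null_sd, "null_sem": inv_res.null_sem,
                "p": inv_res.p_value, "B": inv_res.B, "seed": inv_res.seed,
            }
        )
        summary["inversion_overlap_p"] = inv_res.p_value
    tables["resampling_tests"] = pd.DataFrame(gs_rows)

    # ---- stage 8: outlier scan ----------------------------------------
    if config.run_outlier_scan:
        ocfg = config.outlier or outliers.HierIslandConfig(
            diploids_per_deme=max(2, round(np.mean([
                len(matrix.taxon_rows(t)) for t in taxa
            ]))),
            seed=int(seeds[5]),
        )
        null = outliers.simulate_hier_island_null(ocfg)
        obs_het, obs_theta = outliers.locus_scan_stats(matrix, taxa)
        scan = outliers.outlier_pvalues(obs_het, obs_theta, null)
        flagged = outliers.flag_outliers(scan, alpha=config.alpha, m=m)
        flag_set = {r.locus for r in flagged}
        tables["outlier_scan"] = pd.DataFrame(
            {
                "locus": [s.label for s in matrix.loci],
                "theta": [r.theta for r in scan],
                "het": [r.heterozygosity for r in scan],
                "het_bin": [r.het_bin for r in scan],
                "p": [r.p_value for r in scan],
                "flagged": [r.locus in flag_set for r in scan],
            }
        )
        summary["n_outlier_flagged"] = len(flagged)
        logger.info("outlier scan flagged %d / %d loci", len(flagged), matrix.n_loci)

    # ---- outputs -------------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        core_io.write_results(tables, out)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    summary["_tables"] = tables
    return summary
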