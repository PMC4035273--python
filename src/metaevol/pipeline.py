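"""End-to-end pipeline: simulate or load data, QC, classify, summarize.

Stages run in the analysis order: filter -> outlier removal -> normalize ->
postmortem exclusion -> permutation ANOVA -> lineage classification ->
clustering -> enrichment -> expression agreement -> functional units ->
divergence regression.  A single global seed is expanded into per-stage
seeds (seed * 1000 + stage counter) so any stage can be reproduced in
isolation; the final report is plain JSON.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, divergence, enrichment, expression, funcunits, io, peakproc
from .constants import LINEAGES, TISSUE_CATEGORIES
from .phylo import Phylogeny, make_phylogeny
from .synthio import SimConfig, apply_annotation_mz, simulate_annotation, \
    simulate_expression, simulate_metabolome

log = logging.getLogger("metaevol")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    phylogeny: Phylogeny = field(default_factory=Phylogeny)
    n_perm: int = 200
    p_cutoff: float = 0.01
    fdr: float = 0.05
    anova_fdr: float = 0.05
    seed: int = 0
    n_metabolites: int = 300
    n_pathways: int = 40
    outdir: Path | None = None
    run_clustering: bool = True
    run_expression: bool = True

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        sim = SimConfig(**obj.get("sim", {}))
        phylo = make_phylogeny(**obj.get("phylogeny", {}))
        kwargs = {k: v for k, v in obj.items() if k not in ("sim", "phylogeny")}
        if "outdir" in kwargs and kwargs["outdir"] is not None:
            kwargs["outdir"] = Path(kwargs["outdir"])
        return cls(sim=sim, phylogeny=phylo, **kwargs)


def _stage_seed(config: PipelineConfig, counter: int) -> int:
    return (config.seed * 1000 + counter) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis on synthetic data; returns the JSON report."""
    t0 = time.time()
    report: dict = {"stages": {}}

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        return report["stages"].setdefault(name, {})

    sim = config.sim
    sim.seed = _stage_seed(config, 1)
    table, meta, truth = simulate_metabolome(sim, config.phylogeny)
    mass_db, annotation, pdb = simulate_annotation(
        n_peaks=sim.n_peaks, n_metabolites=config.n_metabolites,
        n_pathways=config.n_pathways, seed=_stage_seed(config, 2),
        peak_ids=list(table.peak_ids),
    )
    annotation = apply_annotation_mz(table, annotation, mass_db,
                                     seed=_stage_seed(config, 3))
    stage("simulate").update(n_peaks=table.n_peaks, n_samples=len(meta),
                             n_planted=len(truth.planted_peak_effects))

    # --- filtering per dataset
    filtered_parts = []
    s = stage("filter")
    for ds in ("posLC", "negLC", "GC"):
        ids = table.peak_ids[table.peak_meta["dataset"] == ds]
        if len(ids) == 0:
            continue
        part = table.subset_peaks(ids)
        if ds == "GC":
            filt, rep = peakproc.filter_gcms_peaks(part, meta, internal_standards=[])
        else:
            filt, rep = peakproc.filter_lcms_peaks(part, meta)
        s[ds] = {"input": rep.input_count, "retained": rep.retained_count,
                 "removals": rep.removals}
        filtered_parts.append(filt)
    intens = pd.concat([p.intensities for p in filtered_parts])
    pmeta = pd.concat([p.peak_meta for p in filtered_parts])
    from .containers import PeakTable
    table = PeakTable(intens.loc[sorted(intens.index)], pmeta.loc[sorted(intens.index)])

    # outlier samples are judged against their own (species, tissue) cell:
    # on a whole-dataset PCA the leading components separate tissues and
    # then species — genuine biology — and entire clusters would be flagged
    outliers: set = set()
    pooled_mask = meta["is_pooled"].astype(bool)
    cells = list(meta[~pooled_mask].groupby(["species", "tissue"],
                                            observed=True)) \
        + list(meta[pooled_mask].groupby("tissue", observed=True))
    for _, grp in cells:
        ids = [s for s in grp.index if s in table.sample_ids]
        if len(ids) >= 4:
            outliers |= peakproc.detect_outlier_samples(table.subset_samples(ids))
    table = table.subset_samples([c for c in table.sample_ids if c not in outliers])
    stage("outliers").update(removed=sorted(outliers))

    norm = peakproc.normalize(table, meta)
    pm_flags = peakproc.flag_postmortem_peaks(norm, meta)
    stage("postmortem").update(
        flagged_per_tissue={t: len(v) for t, v in pm_flags.items()})

    # --- permutation ANOVA, two modes
    s = stage("anova")
    gates = {}
    for mode, primates_only in (("all", False), ("primate", True)):
        sig = set()
        for i, factor in enumerate(("species", "species:tissue")):
            res = divergence.permutation_fdr(
                norm, meta, factor=factor, cutoff=config.p_cutoff,
                n_perm=config.n_perm, seed=_stage_seed(config, 10 + i),
                primates_only=primates_only)
            sig |= set(res.significant(config.anova_fdr))
            s[f"{mode}_{factor}"] = {
                "n_significant": res.n_discoveries, "fdr": res.fdr_at_cutoff}
        gates[mode] = sig
        s[f"{mode}_gate"] = len(sig)

    assign = divergence.classify_species_specific(
        norm, meta, gate_primate=gates["primate"], gate_all=gates["all"],
        p_cutoff=config.p_cutoff, fdr=config.fdr, n_perm=config.n_perm,
        seed=_stage_seed(config, 20), excluded_per_tissue=pm_flags)
    unique_assign = divergence.exclude_multitissue(assign)
    stage("classify").update(
        n_calls=len(assign.assignments),
        n_unique_calls=len(unique_assign.assignments),
        calls_per_lineage={
            lin: int((assign.assignments["lineage"] == lin).sum())
            for lin in LINEAGES},
    )

    summary = divergence.divergence_regression(assign, config.phylogeny)
    stage("regression").update(
        slope=summary.slope, intercept=summary.intercept,
        r_squared=summary.r_squared,
        fold_excess={t: float(summary.per_tissue.loc[t, "fold_excess_vs_chimp"])
                     for t in TISSUE_CATEGORIES},
    )

    if config.run_clustering:
        tissue_res = divergence.permutation_fdr(
            norm, meta, factor="tissue", cutoff=config.p_cutoff,
            n_perm=config.n_perm, seed=_stage_seed(config, 30))
        tissue_sig = list(tissue_res.significant(config.anova_fdr))
        if len(tissue_sig) >= 10:
            dist = clustering.profile_distance(norm.subset_peaks(tissue_sig), meta)
            cres = clustering.cluster_peaks(dist, range(2, min(21, len(tissue_sig) - 1)))
            cres = clustering.drop_small_clusters(cres)
            labels = clustering.assign_tissue_specificity(cres, norm, meta)
            stage("clustering").update(
                n_clustered=len(tissue_sig), chosen_k=cres.chosen_k,
                tissue_labels={str(k): list(v) for k, v in labels.items()})

    # --- enrichment of species-specific metabolite groups
    s = stage("enrichment")
    background = enrichment.peaks_to_metabolites(norm.peak_ids, annotation)
    enriched_by_group: dict = {}
    a = assign.assignments
    for (lineage, cat), grp in a.groupby(["lineage", "tissue"], observed=True):
        mets = enrichment.peaks_to_metabolites(grp["peak_id"], annotation)
        mets &= background
        if not mets:
            continue
        res = enrichment.enrich(mets, background, pdb, n_perm=config.n_perm,
                                seed=_stage_seed(config, 40))
        hits = res[(res["hyper_p"] < 0.05) & (res["perm_p"] < 0.05)]
        if len(hits):
            enriched_by_group[(lineage, cat)] = list(hits.index)
    s["n_groups_enriched"] = len(enriched_by_group)
    s["n_pathway_hits"] = int(sum(len(v) for v in enriched_by_group.values()))

    if config.run_expression:
        expr, expr_meta, gene_meta = simulate_expression(
            pdb, truth, annotation, seed=_stage_seed(config, 50))
        kept = expression.expression_floor(expr, expr_meta)
        spec = expression.classify_specific_genes(expr.loc[kept], expr_meta)
        agree = expression.agreement_pathway_test(
            enriched_by_group, spec, pdb, measured_genes=kept,
            n_perm=config.n_perm, seed=_stage_seed(config, 51))
        stage("expression").update(
            n_genes=len(expr), n_above_floor=len(kept),
            n_specific_labels=len(spec),
            n_agreement_pathways=int((agree["perm_p"] < 0.05).sum())
            if len(agree) else 0)

        units_per_group = {}
        for (lineage, cat), pathways in enriched_by_group.items():
            mets_sets = {}
            grp = a[(a["lineage"] == lineage) & (a["tissue"] == cat)]
            group_mets = enrichment.peaks_to_metabolites(grp["peak_id"], annotation)
            for m in group_mets:
                ps = {pid for pid in pathways if m in pdb.metabolites[pid]}
                if ps:
                    mets_sets[m] = ps
            units = funcunits.group_functional_units(
                mets_sets, tissue=cat, lineage=lineage)
            units_per_group[f"{lineage}|{cat}"] = len(units)
        stage("funcunits").update(units_per_group=units_per_group)

    report["elapsed_s"] = round(time.time() - t0, 2)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_peak_table(norm, outdir / "normalized")
        io.write_sample_metadata(meta, outdir / "samples.tsv")
        assign.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        summary.proportions.to_csv(outdir / "lineage_proportions.tsv", sep="\t")
        io.write_json(truth.to_json(), outdir / "truth.json")
        io.write_json(report, outdir / "report.json")
    return report
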