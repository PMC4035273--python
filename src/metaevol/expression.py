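"""Enzyme gene-expression quantification, specificity classification, and
metabolite-enzyme agreement tests.

Expression is quantified as reads per 100 bp of mappable exon,
N*100/(L-99) for N aligned reads and exon length L (the denominator counts
valid 100-bp read start positions).  Genes pass a global expression floor,
are classified tissue-/species-specific by quantile rules on pairwise mean
differences, and the concordance between species-specific metabolites and
the expression of their linked enzymes is tested by metabolite resampling.

Note on terminology: the thresholds are tail *quantiles* (5% / 10%) of the
difference distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import LINEAGE_SPECIES, PRIMATES, SPECIES
from .containers import PathwayDB


def quantify_expression(n_reads, exon_length):
    """Reads per 100 bp of exon: N*100/(L-99).

    ``exon_length`` must be >= 100 (the formula counts read start positions
    for 100-bp reads and is undefined below that).
    """
    n_reads = np.asarray(n_reads, dtype=float)
    exon_length = np.asarray(exon_length, dtype=float)
    if np.any(exon_length <= 99):
        raise ValueError("exon length must be >= 100")
    if np.any(n_reads < 0):
        raise ValueError("read counts must be >= 0")
    out = n_reads * 100.0 / (exon_length - 99.0)
    return out if out.ndim else float(out)


def expression_floor(expr: pd.DataFrame, meta: pd.DataFrame, q: float = 0.05) -> pd.Index:
    """Genes expressed above the global floor in at least one cell.

    The floor is the ``q`` quantile of all nonzero expression values across
    the table; a gene is retained if its mean expression in at least one
    (species, tissue) cell exceeds the floor.
    """
    vals = expr.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero expression table")
    cutoff = float(np.quantile(nonzero, q))
    keep = np.zeros(expr.shape[0], dtype=bool)
    sub = meta.loc[expr.columns]
    for (_, _), grp in sub.groupby(["species", "tissue"], observed=True):
        cell = expr[list(grp.index)].to_numpy().mean(axis=1)
        keep |= cell > cutoff
    return expr.index[keep]


def _cell_means(expr: pd.DataFrame, meta: pd.DataFrame, by: list[str]) -> dict:
    sub = meta.loc[expr.columns]
    out = {}
    for key, grp in sub.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = expr[list(grp.index)].to_numpy(dtype=float).mean(axis=1)
    return out


def classify_specific_genes(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    tissue_q: float = 0.10,
    species_q: float = 0.05,
    per_gene_standardize: bool = False,
) -> pd.DataFrame:
    """Quantile-based tissue- and species-specificity labels per gene.

    For every tissue pair, the per-gene difference of mean expression forms
    a distribution across genes; a gene is tissue-specific when its
    difference versus *all* other tissues falls in the same upper or lower
    ``tissue_q`` tail of the corresponding pair distribution.  Species
    specificity works the same way within each tissue with the ``species_q``
    tail, comparing each primate against the other primates and mouse
    against all primates.

    Returns a frame with columns (gene, scope, label, tissue, direction);
    ``tissue`` is empty for tissue-scope rows.  With
    ``per_gene_standardize`` the mean differences are divided by each
    gene's expression SD before the tail thresholds are applied, so highly
    expressed genes do not dominate the pooled difference distributions.
    """
    sub = meta.loc[expr.columns]
    if per_gene_standardize:
        sd = expr.to_numpy(dtype=float).std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        expr = expr.div(sd, axis=0)
    tissues = sorted(sub["tissue"].unique())
    genes = expr.index.to_numpy()
    rows = []

    tissue_means = _cell_means(expr, meta, ["tissue"])
    for t in tissues:
        up = np.ones(len(genes), dtype=bool)
        down = np.ones(len(genes), dtype=bool)
        for t2 in tissues:
            if t2 == t:
                continue
            diff = tissue_means[(t,)] - tissue_means[(t2,)]
            lo, hi = np.quantile(diff, [tissue_q, 1.0 - tissue_q])
            up &= diff >= hi
            down &= diff <= lo
        for g in genes[up]:
            rows.append((g, "tissue", t, "", "up"))
        for g in genes[down]:
            rows.append((g, "tissue", t, "", "down"))

    cell_means = _cell_means(expr, meta, ["species", "tissue"])
    present_species = sorted(sub["species"].unique())
    for t in tissues:
        for sp in present_species:
            if sp == "mouse":
                others = [s for s in PRIMATES if (s, t) in cell_means]
            else:
                others = [s for s in PRIMATES if s != sp and (s, t) in cell_means]
            if not others or (sp, t) not in cell_means:
                continue
            up = np.ones(len(genes), dtype=bool)
            down = np.ones(len(genes), dtype=bool)
            for sp2 in others:
                diff = cell_means[(sp, t)] - cell_means[(sp2, t)]
                lo, hi = np.quantile(diff, [species_q, 1.0 - species_q])
                up &= diff >= hi
                down &= diff <= lo
            for g in genes[up]:
                rows.append((g, "species", sp, t, "up"))
            for g in genes[down]:
                rows.append((g, "species", sp, t, "down"))
    return pd.DataFrame(rows, columns=["gene", "scope", "label", "tissue", "direction"])


def matching_genes(spec: pd.DataFrame, species: str, tissue: str,
                   direction: str | None = None) -> set[str]:
    """Genes labeled species-specific for (species, tissue)."""
    hit = spec[(spec["scope"] == "species") & (spec["label"] == species)
               & (spec["tissue"] == tissue)]
    if direction is not None:
        hit = hit[hit["direction"] == direction]
    return set(hit["gene"])


def agreement_pathway_test(
    enriched_pathways: dict,
    spec: pd.DataFrame,
    db: PathwayDB,
    measured_genes,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Overrepresentation of matching-profile enzymes in enriched pathways.

    ``enriched_pathways`` maps (lineage, tissue) -> iterable of pathway ids.
    For each enriched pathway, counts the pathway enzymes (restricted to
    measured genes) whose species-specific expression label matches the
    metabolite group's lineage and tissue, and compares the count with
    size-matched random enzyme draws from the measured-gene universe.
    Pathways without measured enzymes are skipped.
    """
    rng = np.random.default_rng(seed)
    measured = sorted(set(measured_genes))
    rows = []
    for (lineage, tissue), pathways in sorted(enriched_pathways.items()):
        species = LINEAGE_SPECIES[lineage]
        match_set = matching_genes(spec, species, tissue)
        match_arr = np.array([g in match_set for g in measured])
        for pid in sorted(set(pathways)):
            enzymes = sorted(db.enzymes.get(pid, set()) & set(measured))
            if not enzymes:
                continue
            obs = sum(1 for e in enzymes if e in match_set)
            linked_obs = sum(
                1 for e in enzymes
                if e in match_set and db.linked_metabolites(e) & db.metabolites[pid]
            )
            ge = 0
            for _ in range(n_perm):
                samp = rng.choice(len(measured), size=len(enzymes), replace=False)
                if int(match_arr[samp].sum()) >= obs:
                    ge += 1
            p = (1.0 + ge) / (n_perm + 1.0)
            rows.append(dict(lineage=lineage, tissue=tissue, pathway=pid,
                             n_enzymes=len(enzymes), matching=obs,
                             linked_matching=linked_obs, perm_p=p))
    return pd.DataFrame(rows, columns=["lineage", "tissue", "pathway", "n_enzymes",
                                       "matching", "linked_matching", "perm_p"])


def agreement_link_test(
    metab_group,
    lineage: str,
    tissue: str,
    spec: pd.DataFrame,
    db: PathwayDB,
    measured_genes,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Proportion of matching-profile enzymes among enzymes directly linked
    to a species-specific metabolite group, with a metabolite-resampling p.

    The null samples metabolite sets of the group's size from the
    metabolites linked to any measured enzyme and recomputes the proportion;
    p = (1 + #{null proportion >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    measured = set(measured_genes)
    species = LINEAGE_SPECIES[lineage]
    match_set = matching_genes(spec, species, tissue)

    met_links = {}
    for e, m in db.links:
        if e in measured:
            met_links.setdefault(m, set()).add(e)
    background = sorted(met_links)

    def proportion(mets) -> float | None:
        linked = set()
        for m in mets:
            linked |= met_links.get(m, set())
        if not linked:
            return None
        return sum(1 for e in linked if e in match_set) / len(linked)

    group = sorted(set(metab_group))
    obs = proportion(group)
    if obs is None:
        raise ValueError("metabolite group has no linked measured enzymes")
    if len(background) < len(group):
        raise ValueError("background smaller than the metabolite group")
    ge = 0
    for _ in range(n_perm):
        samp = rng.choice(background, size=len(group), replace=False)
        prop = proportion(samp)
        if prop is not None and prop >= obs:
            ge += 1
    p = (1.0 + ge) / (n_perm + 1.0)
    return float(obs), float(p)
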