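"""Synthetic multi-species multi-tissue metabolome data with planted truth.

The generator emulates the study design the pipeline targets: four species
(human, chimpanzee, macaque, mouse), five tissues (three brain regions,
kidney, skeletal muscle), ~14 individuals per species, plus the special
macaque groups (postmortem-delayed, environment condition 1/2) and pooled
quality-control samples for the LC datasets.

The statistical model is multiplicative (log2-additive):

    log2 x[p, s] = base[p] + tissue_off[p, t(s)] + lineage/condition shifts
                   + N(0, sigma)

Lineage-specific shifts of +/- delta log2 units are planted per
(lineage, tissue) with probability ``min(1, rate_per_my * branch_length *
acceleration)``, so the expected fraction of shifted peaks scales with the
length of each evolutionary lineage — the structure that the divergence
regression downstream is designed to recover.  Intensities below the
detection limit are recorded as 0 ("not detected").

Every planted effect is recorded in a :class:`SyntheticTruth` ledger so
recovery and calibration tests can score pipeline output against the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import COMPOSITE_TISSUES, LINEAGES, LINEAGE_SPECIES, SPECIES, TISSUES
from .containers import PathwayDB, PeakTable, check_sample_metadata
from .phylo import Phylogeny


# ---------------------------------------------------------------------------
# configuration and truth ledger


@dataclass
class SimConfig:
    """Parameters of the synthetic metabolome.

    Units: baseline/effect/noise parameters are log2 arbitrary units (AU);
    ``detection_limit`` is linear AU; ``rate_per_my`` is the fraction of
    peaks shifted per million years of branch length.
    """

    n_individuals: int = 14
    tissues: tuple[str, ...] = TISSUES
    n_peaks: int = 2000
    baseline_mean: float = 15.0
    baseline_sd: float = 2.0
    tissue_sd: float = 1.0
    rate_per_my: float = 0.002
    human_accel: dict = field(default_factory=dict)   # tissue -> multiplier
    accel: dict = field(default_factory=dict)         # (lineage, tissue) -> multiplier
    delta: float = 1.0
    sigma: float = 0.5
    detection_limit: float = 0.0
    dataset_fractions: tuple[float, float, float] = (0.45, 0.28, 0.27)  # posLC, negLC, GC
    n_pooled_per_tissue: int = 4
    pooled_sd: float = 0.1
    n_pm_individuals: int = 2
    pm_delay_hours: float = 5.0
    pm_fraction: float = 0.05
    pm_size: float = 1.0
    n_condition: int = 6
    condition_fractions: dict = field(
        default_factory=lambda: {"condition1": 0.005, "condition2": 0.01}
    )
    condition_sizes: dict = field(
        default_factory=lambda: {"condition1": 1.0, "condition2": 1.0}
    )
    condition_human_concordance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("n_individuals must be >= 3")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        fracs = [self.pm_fraction, self.condition_human_concordance,
                 *self.condition_fractions.values(), *self.dataset_fractions]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.rate_per_my < 0:
            raise ValueError("rate_per_my must be >= 0")

    def acceleration(self, lineage: str, tissue: str) -> float:
        """Effect-frequency multiplier for a (lineage, tissue) pair."""
        if (lineage, tissue) in self.accel:
            return float(self.accel[(lineage, tissue)])
        if lineage == "human" and tissue in self.human_accel:
            return float(self.human_accel[tissue])
        return 1.0


@dataclass
class SyntheticTruth:
    """Ledger of every planted effect, for recovery/calibration scoring."""

    planted_peak_effects: list[tuple] = field(default_factory=list)
    # entries: (peak_id, tissue, lineage, direction "up"/"down", delta)
    planted_pm_peaks: set = field(default_factory=set)
    planted_condition_peaks: dict = field(default_factory=dict)  # condition -> {peak: dir}
    planted_enriched_pathways: dict = field(default_factory=dict)
    planted_specific_genes: dict = field(default_factory=dict)   # (lineage, tissue) -> set

    def effect_index(self) -> dict:
        """(peak_id, tissue, lineage) -> direction."""
        return {(p, t, lin): d for p, t, lin, d, _ in self.planted_peak_effects}

    def is_true_call(self, peak_id: str, tissue: str, lineage: str,
                     direction: str | None = None) -> bool:
        """Whether a (peak, tissue-category, lineage) call matches a planted effect.

        Composite tissue categories (cortex, brain) count as true when any
        constituent tissue carries a matching planted effect.
        """
        tissues = COMPOSITE_TISSUES.get(tissue, (tissue,))
        idx = self.effect_index()
        for t in tissues:
            d = idx.get((peak_id, t, lineage))
            if d is not None and (direction is None or d == direction):
                return True
        return False

    def to_json(self) -> dict:
        return {
            "planted_peak_effects": [list(e) for e in self.planted_peak_effects],
            "planted_pm_peaks": sorted(self.planted_pm_peaks),
            "planted_condition_peaks": {
                c: dict(sorted(d.items())) for c, d in self.planted_condition_peaks.items()
            },
            "planted_enriched_pathways": {
                f"{lin}|{t}": sorted(v)
                for (lin, t), v in self.planted_enriched_pathways.items()
            },
            "planted_specific_genes": {
                f"{lin}|{t}": sorted(v)
                for (lin, t), v in self.planted_specific_genes.items()
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SyntheticTruth":
        return cls(
            planted_peak_effects=[tuple(e) for e in obj["planted_peak_effects"]],
            planted_pm_peaks=set(obj["planted_pm_peaks"]),
            planted_condition_peaks={
                c: dict(d) for c, d in obj["planted_condition_peaks"].items()
            },
            planted_enriched_pathways={
                tuple(k.split("|")): set(v)
                for k, v in obj["planted_enriched_pathways"].items()
            },
            planted_specific_genes={
                tuple(k.split("|")): set(v)
                for k, v in obj["planted_specific_genes"].items()
            },
        )


# ---------------------------------------------------------------------------
# metabolome simulation


def _sample_grid(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the sample-metadata frame for the full study design."""
    rows = []

    def add_individuals(species, prefix, n, condition="standard", pm_delay=0.25):
        for i in range(n):
            ind = f"{prefix}{i + 1:02d}"
            sex = "F" if rng.random() < 0.5 else "M"
            age = float(np.round(rng.uniform(2, 60) if species != "mouse"
                                 else rng.uniform(0.2, 2.0), 1))
            for t in config.tissues:
                rows.append(dict(
                    sample_id=f"{ind}_{t}",
                    species=species, tissue=t, individual_id=ind, sex=sex,
                    age=age, rin=float(np.round(rng.normal(8.0, 1.0), 2)),
                    condition=condition, postmortem_delay=pm_delay,
                    is_pooled=False,
                ))

    for sp in SPECIES:
        add_individuals(sp, f"{sp[:2]}", config.n_individuals)
    # special macaque groups
    add_individuals("macaque", "mapm", config.n_pm_individuals,
                    pm_delay=config.pm_delay_hours)
    add_individuals("macaque", "mac1_", config.n_condition, condition="condition1")
    add_individuals("macaque", "mac2_", config.n_condition, condition="condition2")

    # pooled QC samples (LC datasets only), one series per tissue
    order = 0
    for t in config.tissues:
        for k in range(config.n_pooled_per_tissue):
            rows.append(dict(
                sample_id=f"pooled_{t}_{k + 1:02d}",
                species=np.nan, tissue=t, individual_id=np.nan, sex=np.nan,
                age=np.nan, rin=np.nan, condition="standard",
                postmortem_delay=0.0, is_pooled=True,
            ))
    meta = pd.DataFrame(rows).set_index("sample_id")
    # injection sequence: pooled samples interleaved early (rank k), then
    # individual samples; used by the pooled-consistency filter criterion
    meta["acquisition_order"] = 0
    pooled = meta["is_pooled"].astype(bool)
    pooled_ids = meta.index[pooled]
    ranks = {sid: int(sid.rsplit("_", 1)[-1]) for sid in pooled_ids}
    meta.loc[pooled_ids, "acquisition_order"] = [
        ranks[s] * 1000 + i for i, s in enumerate(pooled_ids)
    ]
    meta.loc[~pooled, "acquisition_order"] = 10_000_000 + np.arange((~pooled).sum())
    return meta


def _peak_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_peaks
    ids = [f"peak{i + 1:05d}" for i in range(n)]
    f_pos, f_neg, _ = config.dataset_fractions
    u = rng.random(n)
    dataset = np.where(u < f_pos, "posLC", np.where(u < f_pos + f_neg, "negLC", "GC"))
    mz = np.where(dataset != "GC", rng.uniform(85.0, 900.0, n), np.nan)
    mass = np.where(dataset == "GC", rng.integers(70, 600, n).astype(float), np.nan)
    rt = np.where(dataset == "GC", rng.uniform(2.0, 20.0, n), rng.uniform(0.7, 12.0, n))
    return pd.DataFrame(
        {"mz": mz, "mass": mass, "rt": np.round(rt, 3), "dataset": dataset},
        index=pd.Index(ids, name="peak_id"),
    )


def simulate_metabolome(
    config: SimConfig, phylogeny: Phylogeny | None = None
) -> tuple[PeakTable, pd.DataFrame, SyntheticTruth]:
    """Generate a peak table, sample metadata and the planted-effect ledger.

    Identical configs (including seed) give bit-identical output.
    """
    phylogeny = phylogeny or Phylogeny()
    rng = np.random.default_rng(config.seed)
    peak_meta = _peak_metadata(config, rng)
    meta = _sample_grid(config, rng)
    truth = SyntheticTruth()

    individual = ~meta["is_pooled"].astype(bool)
    ind_meta = meta[individual]
    n_peaks, n_ind = config.n_peaks, len(ind_meta)
    tissues = list(config.tissues)

    base = rng.normal(config.baseline_mean, config.baseline_sd, n_peaks)
    tissue_off = rng.normal(0.0, config.tissue_sd, (n_peaks, len(tissues)))

    t_idx = np.array([tissues.index(t) for t in ind_meta["tissue"]])
    log2 = base[:, None] + tissue_off[:, t_idx]

    # lineage-specific shifts, frequency ~ branch length x acceleration
    species_arr = ind_meta["species"].to_numpy()
    for lineage in LINEAGES:
        target_sp = LINEAGE_SPECIES[lineage]
        for ti, tissue in enumerate(tissues):
            frac = config.rate_per_my * phylogeny[lineage] * config.acceleration(lineage, tissue)
            if frac > 1.0:
                warnings.warn(
                    f"planted fraction {frac:.2f} for ({lineage}, {tissue}) clipped to 1",
                    stacklevel=2,
                )
                frac = 1.0
            if config.delta == 0.0 or frac == 0.0:
                continue
            hit = rng.random(n_peaks) < frac
            signs = np.where(rng.random(n_peaks) < 0.5, 1.0, -1.0)
            cols = (species_arr == target_sp) & (t_idx == ti)
            shift = np.where(hit, signs * config.delta, 0.0)
            log2[:, cols] += shift[:, None]
            for p in np.nonzero(hit)[0]:
                truth.planted_peak_effects.append((
                    peak_meta.index[p], tissue, lineage,
                    "up" if signs[p] > 0 else "down", config.delta,
                ))

    # postmortem-delay effects (delayed macaque samples, all tissues)
    pm_hit = rng.random(n_peaks) < config.pm_fraction
    pm_signs = np.where(rng.random(n_peaks) < 0.5, 1.0, -1.0)
    delayed = (ind_meta["postmortem_delay"].to_numpy() >= 4.0)
    if config.pm_size != 0.0 and delayed.any():
        log2[:, delayed] += np.where(pm_hit, pm_signs * config.pm_size, 0.0)[:, None]
        truth.planted_pm_peaks = set(peak_meta.index[pm_hit])

    # environment-condition effects; a configurable fraction is concordantly
    # shifted in humans as well (mimicking lifestyle-related overlap)
    cond_arr = ind_meta["condition"].to_numpy()
    human_cols = species_arr == "human"
    planted_idx = {(p, t, lin) for p, t, lin, _, _ in truth.planted_peak_effects}
    for cond, frac in config.condition_fractions.items():
        size = config.condition_sizes.get(cond, 1.0)
        hit = rng.random(n_peaks) < frac
        signs = np.where(rng.random(n_peaks) < 0.5, 1.0, -1.0)
        concord = rng.random(n_peaks) < config.condition_human_concordance
        if size != 0.0 and hit.any():
            cols = cond_arr == cond
            shift = np.where(hit, signs * size, 0.0)
            log2[:, cols] += shift[:, None]
            log2[:, human_cols] += np.where(hit & concord, signs * size, 0.0)[:, None]
            # the human-concordant shift is a genuine human-specific change
            # (applied in every tissue) and belongs in the truth ledger
            for p in np.nonzero(hit & concord)[0]:
                pid = peak_meta.index[p]
                d = "up" if signs[p] > 0 else "down"
                for tissue in tissues:
                    if (pid, tissue, "human") not in planted_idx:
                        truth.planted_peak_effects.append(
                            (pid, tissue, "human", d, size))
                        planted_idx.add((pid, tissue, "human"))
        truth.planted_condition_peaks[cond] = {
            peak_meta.index[p]: "up" if signs[p] > 0 else "down"
            for p in np.nonzero(hit)[0]
        }

    log2 += rng.normal(0.0, config.sigma, log2.shape)
    linear = np.power(2.0, log2)

    # pooled QC samples: per-tissue mean of individual samples (LC peaks only)
    pooled_meta = meta[~individual]
    pooled_vals = np.zeros((n_peaks, len(pooled_meta)))
    is_lc = (peak_meta["dataset"] != "GC").to_numpy()
    for j, (sid, row) in enumerate(pooled_meta.iterrows()):
        cols = t_idx == tissues.index(row["tissue"])
        mean_lin = linear[:, cols].mean(axis=1)
        noise = np.power(2.0, rng.normal(0.0, config.pooled_sd, n_peaks))
        pooled_vals[:, j] = np.where(is_lc, mean_lin * noise, 0.0)

    all_vals = np.concatenate([linear, pooled_vals], axis=1)
    all_ids = list(ind_meta.index) + list(pooled_meta.index)
    if config.detection_limit > 0:
        all_vals = np.where(all_vals < config.detection_limit, 0.0, all_vals)

    intens = pd.DataFrame(all_vals, index=peak_meta.index, columns=all_ids)
    intens = intens[meta.index]  # metadata order
    table = PeakTable(intens, peak_meta)
    check_sample_metadata(meta)
    return table, meta, truth


# ---------------------------------------------------------------------------
# annotation / pathway / expression simulation


def simulate_annotation(
    n_peaks: int,
    n_metabolites: int,
    n_pathways: int,
    pathway_size_range: tuple[int, int] = (3, 25),
    seed: int = 0,
    annotated_fraction: float = 1535 / 10615,
    peak_ids: list[str] | None = None,
    n_enzymes: int | None = None,
    enzyme_size_range: tuple[int, int] = (3, 25),
    link_fraction: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, PathwayDB]:
    """Generate a metabolite mass table, peak annotation and pathway database.

    Returns ``(mass_db, annotation, pathway_db)`` where ``mass_db`` maps
    metabolite ids to monoisotopic neutral masses (Da), and ``annotation``
    maps a configurable fraction of peaks to metabolites.
    """
    if n_metabolites > n_peaks:
        raise ValueError("n_metabolites must be <= n_peaks")
    if pathway_size_range[0] < 2:
        raise ValueError("pathway sizes must be >= 2")
    rng = np.random.default_rng(seed)
    if peak_ids is None:
        peak_ids = [f"peak{i + 1:05d}" for i in range(n_peaks)]
    met_ids = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    masses = np.sort(rng.uniform(80.0, 800.0, n_metabolites))
    mass_db = pd.DataFrame(
        {
            "mass": masses,
            "external_id": [f"HMDB{i + 1:07d}" for i in range(n_metabolites)],
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )

    n_annot = int(round(annotated_fraction * len(peak_ids)))
    chosen = rng.choice(len(peak_ids), size=n_annot, replace=False)
    assigned = rng.integers(0, n_metabolites, size=n_annot) if n_metabolites else []
    annotation = pd.DataFrame(
        {
            "peak_id": [peak_ids[i] for i in sorted(chosen)],
            "metabolite_id": [met_ids[assigned[k]] for k in np.argsort(chosen)],
        }
    )

    n_enzymes = n_enzymes if n_enzymes is not None else n_metabolites
    enz_ids = [f"E{i + 1:04d}" for i in range(n_enzymes)]
    mets_sets, enz_sets, names = {}, {}, {}
    links: set[tuple[str, str]] = set()
    for p in range(n_pathways):
        pid = f"P{p + 1:03d}"
        m_size = int(rng.integers(pathway_size_range[0], pathway_size_range[1] + 1))
        e_size = int(rng.integers(enzyme_size_range[0], enzyme_size_range[1] + 1))
        mets = set(rng.choice(met_ids, size=min(m_size, n_metabolites), replace=False))
        enzs = set(rng.choice(enz_ids, size=min(e_size, n_enzymes), replace=False))
        mets_sets[pid] = mets
        enz_sets[pid] = enzs
        names[pid] = f"synthetic pathway {p + 1}"
        for e in sorted(enzs):
            for m in sorted(mets):
                if rng.random() < link_fraction:
                    links.add((e, m))
    db = PathwayDB(metabolites=mets_sets, enzymes=enz_sets, links=links, names=names)
    return mass_db, annotation, db


def apply_annotation_mz(
    table: PeakTable,
    annotation: pd.DataFrame,
    mass_db: pd.DataFrame,
    seed: int = 0,
    max_jitter_ppm: float = 3.0,
) -> pd.DataFrame:
    """Make annotated LC peaks' m/z consistent with their metabolite masses.

    Each annotated LC peak is assigned a mode-appropriate adduct and its m/z
    set to the adduct mass with at most ``max_jitter_ppm`` of random mass
    error, so that accurate-mass annotation can recover the planted mapping.
    Returns the annotation frame with an ``adduct`` column added.
    """
    from .constants import ADDUCTS

    rng = np.random.default_rng(seed)
    ann = annotation.copy()
    ann["adduct"] = ""
    for i, row in ann.iterrows():
        pid = row["peak_id"]
        dataset = table.peak_meta.loc[pid, "dataset"]
        if dataset == "GC":
            continue
        mode = "positive" if dataset == "posLC" else "negative"
        adduct = rng.choice(sorted(ADDUCTS[mode]))
        mass = mass_db.loc[row["metabolite_id"], "mass"]
        theo = mass + ADDUCTS[mode][adduct]
        jitter = rng.uniform(-max_jitter_ppm, max_jitter_ppm) * 1e-6 * theo
        table.peak_meta.loc[pid, "mz"] = theo + jitter
        ann.loc[i, "adduct"] = adduct
    return ann


def simulate_expression(
    pathway_db: PathwayDB,
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    concordance: float = 0.8,
    seed: int = 0,
    n_per_cell: int = 6,
    tissues: tuple[str, ...] = TISSUES,
    baseline_mean: float = 6.0,
    baseline_sd: float = 2.0,
    expr_delta: float = 2.0,
    background_fraction: float = 0.01,
    sigma: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a gene x sample expression table concordant with the truth.

    Enzymes directly linked to a planted species-specific metabolite receive
    a matching species-specific expression shift with probability
    ``concordance``; an independent ``background_fraction`` of genes receive
    random species-specific shifts.  Planted specific genes are recorded in
    ``truth.planted_specific_genes``.

    Returns ``(expression, expr_meta, gene_meta)`` with linear expression
    values in reads per 100 bp of exon.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(pathway_db.enzyme_universe())
    rows = []
    for sp in SPECIES:
        for t in tissues:
            for i in range(n_per_cell):
                rows.append(dict(sample_id=f"expr_{sp}_{t}_{i + 1:02d}",
                                 species=sp, tissue=t))
    expr_meta = pd.DataFrame(rows).set_index("sample_id")

    n_g, n_s = len(genes), len(expr_meta)
    base = rng.normal(baseline_mean, baseline_sd, n_g)
    t_list = list(tissues)
    t_idx = np.array([t_list.index(t) for t in expr_meta["tissue"]])
    tissue_off = rng.normal(0.0, 1.0, (n_g, len(t_list)))
    log2 = base[:, None] + tissue_off[:, t_idx]

    peak_to_met = dict(zip(annotation["peak_id"], annotation["metabolite_id"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    species_arr = expr_meta["species"].to_numpy()
    planted: dict[tuple[str, str, str], str] = {}  # (gene, tissue, lineage) -> dir

    decided: set[tuple[str, str, str]] = set()
    for peak_id, tissue, lineage, direction, _ in truth.planted_peak_effects:
        met = peak_to_met.get(peak_id)
        if met is None or tissue not in t_list:
            continue
        for enz in sorted(pathway_db.linked_enzymes(met)):
            key = (enz, tissue, lineage)
            if key in decided or enz not in gene_pos:
                continue
            decided.add(key)  # one concordance draw per enzyme target
            if rng.random() < concordance:
                planted[key] = direction

    # independent background species-specific genes
    for g in genes:
        if rng.random() < background_fraction:
            lineage = LINEAGES[rng.integers(len(LINEAGES))]
            tissue = t_list[rng.integers(len(t_list))]
            key = (g, tissue, lineage)
            if key not in planted:
                planted[key] = "up" if rng.random() < 0.5 else "down"

    for (g, tissue, lineage), direction in planted.items():
        cols = (species_arr == LINEAGE_SPECIES[lineage]) & (t_idx == t_list.index(tissue))
        sign = 1.0 if direction == "up" else -1.0
        log2[gene_pos[g], cols] += sign * expr_delta
        truth.planted_specific_genes.setdefault((lineage, tissue), set()).add(g)

    log2 += rng.normal(0.0, sigma, log2.shape)
    expr = pd.DataFrame(np.power(2.0, log2), index=pd.Index(genes, name="gene_id"),
                        columns=expr_meta.index)
    gene_meta = pd.DataFrame(
        {"exon_length": rng.integers(400, 5000, n_g)},
        index=pd.Index(genes, name="gene_id"),
    )
    return expr, expr_meta, gene_meta
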