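"""Calibration and recovery experiments on synthetic data.

These functions define the standard study-condition experiments used by the
test suite and by ``scripts/acceptance.py``: a global-null calibration of
the permutation ANOVA, the realized false-discovery proportion of the
lineage classification with planted effects, the calibration of the dual
enrichment rule under random test sets, and the recovery of planted human
acceleration ratios by the full classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import divergence as dv
from . import enrichment, peakproc
from .constants import COMPOSITE_TISSUES, LINEAGES
from .phylo import Phylogeny
from .synthio import SimConfig, SyntheticTruth, simulate_annotation, simulate_metabolome

#: expected planted effects per peak per MY summed over lineages and tissues
_TOTAL_MY_TISSUE = (6.5 + 6.5 + 23.0 + 101.0) * 5


def _anova_gates(norm, meta, cutoff, n_perm, seed, anova_fdr=0.05):
    gates = {}
    for mode, primates_only in (("all", False), ("primate", True)):
        sig: set = set()
        for i, factor in enumerate(("species", "species:tissue")):
            res = dv.permutation_fdr(norm, meta, factor=factor, cutoff=cutoff,
                                     n_perm=n_perm, seed=seed + i,
                                     primates_only=primates_only)
            sig |= set(res.significant(anova_fdr))
        gates[mode] = sig
    return gates


def null_anova_calibration(
    n_peaks: int = 2000,
    n_perm: int = 200,
    seed: int = 0,
    cutoff: float = 0.01,
) -> float:
    """Fraction of peaks with permutation ANOVA species p < cutoff under a
    global-null simulation (no species effects of any kind)."""
    cfg = SimConfig(n_peaks=n_peaks, seed=seed, rate_per_my=0.0,
                    pm_fraction=0.0, condition_fractions={},
                    detection_limit=1000.0)
    table, meta, truth = simulate_metabolome(cfg)
    assert not truth.planted_peak_effects
    norm = peakproc.normalize(table, meta)
    res = dv.permutation_fdr(norm, meta, factor="species", cutoff=cutoff,
                             n_perm=n_perm, seed=seed + 1)
    return float((res.perm_p < cutoff).mean())


def _is_planted_at(truth: SyntheticTruth, peak_id: str, tissue: str,
                   lineage: str | None = None) -> bool:
    idx = truth.effect_index()
    for t in COMPOSITE_TISSUES.get(tissue, (tissue,)):
        if lineage is not None:
            if (peak_id, t, lineage) in idx:
                return True
        else:
            if any((peak_id, t, lin) in idx for lin in LINEAGES):
                return True
    return False


@dataclass
class ClassificationRun:
    """One end-to-end classification on synthetic data, scored vs truth."""

    n_calls: int
    fdp_peak_tissue: float     # calls without any planted effect at (peak, tissue)
    fdp_lineage: float         # calls without the matching planted lineage+direction
    assign: "dv.LineageAssignment"
    truth: SyntheticTruth


def run_classification(
    config: SimConfig,
    phylogeny: Phylogeny | None = None,
    n_perm: int = 200,
    cutoff: float = 0.01,
    fdr: float = 0.05,
    seed: int = 0,
) -> ClassificationRun:
    """Simulate, normalize, gate by permutation ANOVA, classify, and score."""
    table, meta, truth = simulate_metabolome(config, phylogeny)
    norm = peakproc.normalize(table, meta)
    gates = _anova_gates(norm, meta, cutoff, n_perm, seed=seed + 100)
    assign = dv.classify_species_specific(
        norm, meta, gate_primate=gates["primate"], gate_all=gates["all"],
        p_cutoff=cutoff, fdr=fdr, n_perm=n_perm, seed=seed + 200)
    a = assign.assignments
    if len(a) == 0:
        return ClassificationRun(0, 0.0, 0.0, assign, truth)
    pt_true = sum(_is_planted_at(truth, r.peak_id, r.tissue) for r in a.itertuples())
    lin_true = sum(truth.is_true_call(r.peak_id, r.tissue, r.lineage, r.direction)
                   for r in a.itertuples())
    return ClassificationRun(
        n_calls=len(a),
        fdp_peak_tissue=1.0 - pt_true / len(a),
        fdp_lineage=1.0 - lin_true / len(a),
        assign=assign,
        truth=truth,
    )


def classification_fdp(
    n_peaks: int = 5000,
    planted_fraction: float = 0.10,
    delta: float = 1.0,
    n_perm: int = 200,
    seeds=range(10),
) -> dict:
    """Realized false-discovery proportion of the classification, averaged
    over seeds, with ``planted_fraction`` of peaks given a +/-delta shift.

    The planted effects follow the generator's branch-length-proportional
    model; the rate is set so the expected number of planted
    (peak, tissue, lineage) effects equals ``planted_fraction * n_peaks``.
    """
    rate = planted_fraction / _TOTAL_MY_TISSUE
    fdp_pt, fdp_lin, n_calls = [], [], []
    for s in seeds:
        cfg = SimConfig(n_peaks=n_peaks, seed=int(s), rate_per_my=rate,
                        delta=delta, detection_limit=1000.0)
        run = run_classification(cfg, n_perm=n_perm, seed=int(s))
        fdp_pt.append(run.fdp_peak_tissue)
        fdp_lin.append(run.fdp_lineage)
        n_calls.append(run.n_calls)
    return {
        "fdp_peak_tissue": float(np.mean(fdp_pt)),
        "fdp_lineage": float(np.mean(fdp_lin)),
        "mean_calls": float(np.mean(n_calls)),
        "per_seed_fdp": [float(v) for v in fdp_pt],
    }


def enrichment_calibration(
    n_pathways: int = 60,
    n_metabolites: int = 500,
    n_sets: int = 200,
    set_size: int = 30,
    n_perm: int = 200,
    seed: int = 0,
    hyper_alpha: float = 0.05,
    perm_alpha: float = 0.05,
) -> float:
    """Fraction of pathway calls passing both enrichment thresholds when
    test sets are drawn uniformly at random from the background."""
    _, _, db = simulate_annotation(
        n_peaks=n_metabolites, n_metabolites=n_metabolites,
        n_pathways=n_pathways, seed=seed)
    background = sorted(db.metabolite_universe())
    rng = np.random.default_rng(seed + 1)
    n_pass = 0
    n_total = 0
    for i in range(n_sets):
        test = set(rng.choice(background, size=set_size, replace=False))
        res = enrichment.enrich(test, background, db, n_perm=n_perm,
                                seed=seed + 2 + i)
        n_pass += int(((res["hyper_p"] < hyper_alpha)
                       & (res["perm_p"] < perm_alpha)).sum())
        n_total += len(res)
    return n_pass / n_total


def acceleration_recovery(
    seeds=range(10),
    n_peaks: int = 5000,
    rate_per_my: float = 0.001,
    accel: dict | None = None,
    n_perm: int = 200,
) -> dict:
    """Recovery of planted human acceleration ratios by the full pipeline.

    Plants human accelerations (default 8x muscle, 4x PFC), classifies, and
    compares the estimated human:chimp fold excess per tissue with the
    planted (realized) count ratio, averaged over seeds.  Condition and
    postmortem effects are disabled so the planted ratio reflects the
    acceleration alone.
    """
    accel = accel if accel is not None else {"muscle": 8.0, "PFC": 4.0}
    est: dict[str, list[float]] = {t: [] for t in accel}
    planted: dict[str, list[float]] = {t: [] for t in accel}
    for s in seeds:
        cfg = SimConfig(n_peaks=n_peaks, seed=int(s), rate_per_my=rate_per_my,
                        human_accel=dict(accel), pm_fraction=0.0,
                        condition_fractions={}, detection_limit=1000.0)
        run = run_classification(cfg, n_perm=n_perm, seed=int(s) + 1)
        from collections import Counter
        cnt = Counter((e[1], e[2]) for e in run.truth.planted_peak_effects)
        for t in accel:
            h, c = run.assign.count(t, "human"), run.assign.count(t, "chimp")
            if c > 0:
                est[t].append(h / c)
            ph, pc = cnt[(t, "human")], cnt[(t, "chimp")]
            if pc > 0:
                planted[t].append(ph / pc)
    return {
        t: {
            "estimated_fold": float(np.mean(est[t])) if est[t] else float("nan"),
            "planted_fold": float(np.mean(planted[t])) if planted[t] else float("nan"),
        }
        for t in accel
    }
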