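"""Pathway enrichment with hypergeometric + resampling p values, and
environment-effect detection with its overlap test.

Enrichment of a metabolite set against a background follows the dual rule:
an upper-tail hypergeometric p and a permutation p from size-matched random
metabolite sets, both thresholded.  Two background conventions are used
downstream: the full set of measured metabolites (species-specific groups)
and, for tissue-cluster analyses, the metabolites of clusters specific to
*other* tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PathwayDB, PeakTable


def peaks_to_metabolites(peaks, annotation: pd.DataFrame) -> set[str]:
    """Collapse a peak set to the metabolites any of its peaks annotate to."""
    peaks = set(peaks)
    hit = annotation[annotation["peak_id"].isin(peaks)]
    return set(hit["metabolite_id"])


def cluster_background(labels, tissue_labels: dict, tested_cluster,
                       annotation: pd.DataFrame) -> set[str]:
    """Background for tissue-cluster enrichment: metabolites of peaks in
    clusters whose concentration profiles are specific to tissues other
    than the tested cluster's tissue.

    ``labels`` is the peak -> cluster mapping (dropped peaks excluded),
    ``tissue_labels`` maps cluster -> (tissue, direction).
    """
    tested_tissue = tissue_labels[tested_cluster][0]
    peaks = [p for p, c in labels.items()
             if c != "dropped" and c != tested_cluster
             and tissue_labels.get(c, ("",))[0] != tested_tissue]
    return peaks_to_metabolites(peaks, annotation)


def hypergeom_enrichment(
    test_set, background, db: PathwayDB
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per pathway.

    For each pathway: N = |background|, K = |pathway ∩ background|,
    n = |test_set|, k = |pathway ∩ test_set|; p = P(X >= k).
    """
    test_set = set(test_set)
    background = set(background)
    if not test_set:
        raise ValueError("empty test set")
    if not test_set <= background:
        raise ValueError("test_set must be a subset of background")
    N, n = len(background), len(test_set)
    rows = []
    for pid in db.pathway_ids:
        members = db.metabolites[pid] & background
        K = len(members)
        k = len(members & test_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(dict(pathway=pid, k=k, K=K, n=n, N=N, hyper_p=p))
    return pd.DataFrame(rows).set_index("pathway")


def permutation_enrichment(
    test_set, background, db: PathwayDB, n_perm: int = 1000, seed: int = 0
) -> pd.Series:
    """Permutation p per pathway from size-matched random metabolite sets.

    p = (1 + #{sampled overlap >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    test_set = set(test_set)
    background = sorted(set(background))
    if len(background) < len(test_set):
        raise ValueError("background smaller than test set")
    rng = np.random.default_rng(seed)
    pathways = db.pathway_ids
    bg_index = {m: i for i, m in enumerate(background)}
    member = np.zeros((len(pathways), len(background)), dtype=np.float64)
    for r, pid in enumerate(pathways):
        for m in db.metabolites[pid]:
            if m in bg_index:
                member[r, bg_index[m]] = 1.0
    test_idx = np.array([bg_index[m] for m in test_set])
    obs = member[:, test_idx].sum(axis=1)
    count = np.zeros(len(pathways))
    for _ in range(n_perm):
        samp = rng.choice(len(background), size=len(test_set), replace=False)
        count += member[:, samp].sum(axis=1) >= obs
    p = (1.0 + count) / (n_perm + 1.0)
    return pd.Series(p, index=pd.Index(pathways, name="pathway"), name="perm_p")


def enrich(
    test_set, background, db: PathwayDB, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Hypergeometric and permutation enrichment in one frame."""
    out = hypergeom_enrichment(test_set, background, db)
    out["perm_p"] = permutation_enrichment(test_set, background, db, n_perm, seed)
    return out


def environment_effect_peaks(
    table: PeakTable,
    meta: pd.DataFrame,
    condition: str,
    p_cutoff: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Peaks altered by an environment condition, per tissue.

    Per tissue, condition-group macaques are compared with all
    standard-condition control macaques by a Welch t-test with a
    label-permutation p; peaks passing both (p < cutoff, permutation
    p < cutoff) are kept only if human samples shift in the same direction
    relative to the control macaques.
    """
    if condition not in ("condition1", "condition2"):
        raise ValueError(f"unknown condition {condition!r}")
    if not table.log_scale:
        raise ValueError("expects a normalized table")
    rng = np.random.default_rng(seed)
    sub = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    sub = sub[~sub["is_pooled"].astype(bool)]
    out: dict[str, set[str]] = {}
    for tissue, grp in sub.groupby("tissue", observed=True):
        mac = grp[grp["species"] == "macaque"]
        cond_ids = mac.index[mac["condition"] == condition]
        ctrl_ids = mac.index[(mac["condition"] == "standard")
                             & (mac["postmortem_delay"] < 4.0)]
        human_ids = grp.index[grp["species"] == "human"]
        if len(cond_ids) == 0:
            raise ValueError(f"no {condition} samples in tissue {tissue}")
        if len(ctrl_ids) < 2 or len(human_ids) == 0:
            continue
        C = table.intensities[list(cond_ids)].to_numpy()
        K = table.intensities[list(ctrl_ids)].to_numpy()
        H = table.intensities[list(human_ids)].to_numpy()
        t_obs, p_obs = stats.ttest_ind(C, K, axis=1, equal_var=False,
                                       nan_policy="omit")
        t_obs = np.asarray(t_obs, dtype=float)
        p_obs = np.asarray(p_obs, dtype=float)

        pool = np.concatenate([C, K], axis=1)
        n_c = C.shape[1]
        count = np.zeros(table.n_peaks)
        abs_t = np.abs(np.nan_to_num(t_obs))
        for _ in range(n_perm):
            order = rng.permutation(pool.shape[1])
            tb, _ = stats.ttest_ind(pool[:, order[:n_c]], pool[:, order[n_c:]],
                                    axis=1, equal_var=False, nan_policy="omit")
            count += np.abs(np.nan_to_num(np.asarray(tb, dtype=float))) >= abs_t
        perm_p = (1.0 + count) / (n_perm + 1.0)

        cond_dir = np.sign(np.nanmean(C, axis=1) - np.nanmean(K, axis=1))
        human_dir = np.sign(np.nanmean(H, axis=1) - np.nanmean(K, axis=1))
        keep = ((np.nan_to_num(p_obs, nan=1.0) < p_cutoff)
                & (perm_p < p_cutoff)
                & (cond_dir == human_dir) & (cond_dir != 0))
        out[tissue] = set(table.peak_ids[keep])
    return out


def overlap_significance(
    env_pathways,
    human_assign,
    annotation: pd.DataFrame,
    db: PathwayDB,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Count human-specific peaks annotated to the environment-enriched
    pathways and test the count against equally many random pathways.

    ``human_assign`` is an iterable of human-specific peak ids.  The null
    draws |env_pathways| pathways uniformly from the pathway universe and
    recomputes the count; p is the add-one permutation estimator.
    """
    env_pathways = sorted(set(env_pathways))
    if not env_pathways:
        raise ValueError("empty enriched pathway set")
    universe = db.pathway_ids
    if not universe:
        raise ValueError("empty pathway universe")
    rng = np.random.default_rng(seed)
    human_peaks = set(human_assign)
    peak_met = annotation[annotation["peak_id"].isin(human_peaks)]

    def count_for(pathways) -> int:
        mets = set()
        for pid in pathways:
            mets |= db.metabolites[pid]
        return int(peak_met["metabolite_id"].isin(mets).sum())

    obs = count_for(env_pathways)
    ge = 0
    for _ in range(n_perm):
        samp = rng.choice(universe, size=len(env_pathways), replace=False)
        if count_for(samp) >= obs:
            ge += 1
    p = (1.0 + ge) / (n_perm + 1.0)
    return obs, float(p)
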