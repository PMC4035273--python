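"""Cross-tissue concentration-profile clustering of metabolite peaks.

Each peak is summarized by its mean normalized concentration in every
(species, tissue) cell (up to 20 values for 4 species x 5 tissues); peaks
are clustered by complete-linkage hierarchical clustering on correlation
distance (1 - Pearson r between profiles).  The cluster count is chosen by
mean silhouette over a search range, small clusters are dropped up to a
cumulative mass bound, and each retained cluster is labeled with the tissue
its mean profile deviates in most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .constants import SPECIES
from .containers import PeakTable


def profile_matrix(table: PeakTable, meta: pd.DataFrame,
                   tissues=None, species=SPECIES) -> pd.DataFrame:
    """Per-peak mean normalized value in each (species, tissue) cell."""
    sub = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    sub = sub[~sub["is_pooled"].astype(bool) & (sub["condition"] == "standard")]
    tissues = tissues or sorted(sub["tissue"].unique())
    cols = {}
    for sp in species:
        for t in tissues:
            ids = sub.index[(sub["species"] == sp) & (sub["tissue"] == t)]
            if len(ids) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cols[f"{sp}|{t}"] = np.nanmean(
                    table.intensities[list(ids)].to_numpy(), axis=1)
    return pd.DataFrame(cols, index=table.peak_ids)


def profile_distance(table: PeakTable, meta: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between per-peak (species, tissue) profiles.

    Zero-variance profiles get maximal distance (2.0) to every other peak.
    """
    if table.n_peaks < 2:
        raise ValueError("need >= 2 peaks")
    profiles = profile_matrix(table, meta).to_numpy()
    centered = profiles - np.nanmean(profiles, axis=1, keepdims=True)
    centered = np.nan_to_num(centered)
    norms = np.sqrt((centered**2).sum(axis=1))
    degenerate = norms <= 1e-12
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance profiles set to "
                      "maximal distance", stacklevel=2)
    return pd.DataFrame(dist, index=table.peak_ids, columns=table.peak_ids)


@dataclass
class ClusterResult:
    labels: pd.Series                 # peak_id -> cluster id (int) or "dropped"
    silhouette_by_k: dict[int, float]
    chosen_k: int
    tissue_labels: dict = field(default_factory=dict)  # cluster -> (tissue, direction)

    def sizes(self) -> pd.Series:
        kept = self.labels[self.labels != "dropped"]
        return kept.value_counts().sort_index()


def cluster_peaks(dist: pd.DataFrame, k_range=range(2, 31)) -> ClusterResult:
    """Complete-linkage clustering; k chosen by maximal mean silhouette
    (smallest k on ties)."""
    n = dist.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range out of bounds for this peak count")
    D = dist.to_numpy()
    offdiag = D[np.triu_indices(n, 1)]
    if np.allclose(offdiag, offdiag[0]):
        raise ValueError("all pairwise distances equal: degenerate geometry")
    Z = linkage(squareform(D, checks=False), method="complete")
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        labelings[k] = labels
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
            continue
        sil[k] = float(silhouette_score(D, labels, metric="precomputed"))
    best = max(sil, key=lambda k: (sil[k], -k))
    return ClusterResult(
        labels=pd.Series(labelings[best], index=dist.index, dtype=object),
        silhouette_by_k=sil,
        chosen_k=int(best),
    )


def drop_small_clusters(result: ClusterResult, threshold: float = 0.10) -> ClusterResult:
    """Iteratively drop the smallest clusters while the cumulative dropped
    fraction of all peaks stays below ``threshold``."""
    labels = result.labels.copy()
    total = len(labels)
    sizes = labels[labels != "dropped"].value_counts().sort_values()
    dropped_mass = int((labels == "dropped").sum())
    for cid, size in sizes.items():
        if (dropped_mass + size) / total < threshold:
            labels[labels == cid] = "dropped"
            dropped_mass += int(size)
        else:
            break
    return ClusterResult(labels=labels, silhouette_by_k=result.silhouette_by_k,
                         chosen_k=result.chosen_k, tissue_labels=dict(result.tissue_labels))


def assign_tissue_specificity(result: ClusterResult, table: PeakTable,
                              meta: pd.DataFrame) -> dict:
    """Label each retained cluster with the tissue whose cluster-mean profile
    deviates most (in absolute value) from the cross-tissue mean.

    Returns cluster id -> (tissue, direction) with direction "up"/"down";
    exact ties across tissues give ("ambiguous", "").
    """
    profiles = profile_matrix(table, meta)
    tissues = sorted({c.split("|")[1] for c in profiles.columns})
    out = {}
    for cid in sorted(set(result.labels) - {"dropped"}):
        members = result.labels.index[result.labels == cid]
        mean_profile = profiles.loc[members].mean(axis=0)
        per_tissue = {
            t: mean_profile[[c for c in profiles.columns if c.endswith(f"|{t}")]].mean()
            for t in tissues
        }
        grand = float(np.mean(list(per_tissue.values())))
        dev = {t: v - grand for t, v in per_tissue.items()}
        mags = sorted(((abs(v), t) for t, v in dev.items()), reverse=True)
        if len(mags) > 1 and np.isclose(mags[0][0], mags[1][0]):
            out[cid] = ("ambiguous", "")
            continue
        best_t = mags[0][1]
        out[cid] = (best_t, "up" if dev[best_t] > 0 else "down")
    result.tissue_labels = out
    return out
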