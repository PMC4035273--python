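"""Peak-table quality control: multistep filtering, outlier samples,
within-tissue quantile normalization, postmortem-affected-peak exclusion,
and accurate-mass adduct annotation.

Filtering follows ordered criterion lists (one list for the LC-MS datasets,
one for the GC dataset); the report attributes each removed peak to the
first criterion it fails, so per-criterion counts sum to the number of
removed peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ADDUCTS
from .containers import PeakTable


@dataclass
class FilterReport:
    input_count: int
    retained_count: int
    removals: dict[str, int] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.retained_count + sum(self.removals.values()) != self.input_count:
            raise AssertionError("filter report does not account for all peaks")


@dataclass
class LcFilterThresholds:
    """Thresholds of the four LC-MS filter criteria (AU = arbitrary units)."""

    min_rt: float = 0.6                 # criterion 1: minutes
    pooled_presence_frac: float = 0.8   # criterion 2
    pooled_min_intensity: float = 1000  # criterion 2: AU
    pooled_ratio_log2: float = 1.0      # criterion 3: |log2 ratio| bound
    group_min_intensity: float = 10000  # criterion 4: AU
    group_presence_frac: float = 0.5    # criterion 4


@dataclass
class GcFilterThresholds:
    rt_window: float = 2.0              # criterion 2: minutes around median RT
    is_rt_window: float = 0.75          # criterion 3: minutes
    is_same_mass_window: float = 1.5    # criterion 3: minutes, same-mass case
    group_min_intensity: float = 3000   # criterion 4: AU
    group_presence_frac: float = 0.5    # criterion 4
    overlap_rt: float = 0.5             # criterion 5: minutes


def _group_presence(intens: np.ndarray, meta: pd.DataFrame, sample_ids,
                    min_intensity: float, frac: float) -> np.ndarray:
    """Peaks present at >= min_intensity in >= frac of samples of any
    (species, tissue) group of individual (non-pooled) samples."""
    sub = meta.loc[sample_ids]
    individual = ~sub["is_pooled"].astype(bool)
    ok = np.zeros(intens.shape[0], dtype=bool)
    for (_, _), grp in sub[individual].groupby(["species", "tissue"], observed=True):
        cols = [sample_ids.get_loc(s) for s in grp.index]
        if not cols:
            continue
        present = (intens[:, cols] >= min_intensity).mean(axis=1)
        ok |= present >= frac
    return ok


def filter_lcms_peaks(
    raw: PeakTable,
    meta: pd.DataFrame,
    thresholds: LcFilterThresholds | None = None,
) -> tuple[PeakTable, FilterReport]:
    """Apply the four LC-MS filter criteria.

    1. retention time >= 0.6 min;
    2. present at >= 1,000 AU in >= 80% of pooled samples;
    3. consistent level in the first two pooled injections
       (|log2 ratio| <= 1, configurable);
    4. >= 10,000 AU in >= 50% of samples of some (species, tissue) group.

    Outlier samples are expected to be removed before criterion 4 (see
    :func:`detect_outlier_samples`).
    """
    th = thresholds or LcFilterThresholds()
    datasets = set(raw.peak_meta["dataset"].unique())
    if not datasets <= {"posLC", "negLC"}:
        raise ValueError(f"filter_lcms_peaks expects LC peaks, got datasets {datasets}")
    sub = meta.loc[raw.sample_ids]
    pooled_ids = sub.index[sub["is_pooled"].astype(bool)]
    if len(pooled_ids) == 0:
        raise ValueError("criterion 2 requires pooled samples, none present")

    intens = raw.intensities.to_numpy()
    sample_ids = raw.sample_ids

    c1 = raw.peak_meta["rt"].to_numpy() >= th.min_rt

    pooled_cols = [sample_ids.get_loc(s) for s in pooled_ids]
    present = (intens[:, pooled_cols] >= th.pooled_min_intensity).mean(axis=1)
    c2 = present >= th.pooled_presence_frac

    if "acquisition_order" in sub.columns:
        first_two = sub.loc[pooled_ids, "acquisition_order"].nsmallest(2).index
    else:
        first_two = pooled_ids[:2]
    if len(first_two) < 2:
        raise ValueError("criterion 3 requires at least two pooled samples")
    a = intens[:, sample_ids.get_loc(first_two[0])]
    b = intens[:, sample_ids.get_loc(first_two[1])]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(np.log2(a) - np.log2(b))
    c3 = (a > 0) & (b > 0) & (ratio <= th.pooled_ratio_log2)

    c4 = _group_presence(intens, meta, sample_ids,
                         th.group_min_intensity, th.group_presence_frac)

    return _apply_criteria(raw, [("criterion_1_rt", c1),
                                 ("criterion_2_pooled_presence", c2),
                                 ("criterion_3_pooled_consistency", c3),
                                 ("criterion_4_group_level", c4)])


def filter_gcms_peaks(
    raw: PeakTable,
    meta: pd.DataFrame,
    internal_standards: list[tuple[float, float]],
    thresholds: GcFilterThresholds | None = None,
) -> tuple[PeakTable, FilterReport]:
    """Apply the five GC filter criteria.

    1. distinct from background — an upstream peak-shape property, accepted
       as a boolean ``distinct_from_background`` column in peak_meta
       (absent = pass);
    2. per-sample RTs within +/- 2 min of the peak's median RT — accepted as
       ``rt_min``/``rt_max`` columns in peak_meta when available;
    3. RT at least 0.75 min away from every internal standard (1.5 min if
       the peak shares the standard's mass);
    4. >= 3,000 AU in >= 50% of samples of some (species, tissue) group;
    5. peaks with the same mass and RTs differing by <= 0.5 min are
       overlapping: all members of such a group are removed.
    """
    if internal_standards is None:
        raise ValueError("internal_standards list is required for GC filtering")
    th = thresholds or GcFilterThresholds()
    if set(raw.peak_meta["dataset"].unique()) != {"GC"}:
        raise ValueError("filter_gcms_peaks expects GC peaks only")

    pm = raw.peak_meta
    n = raw.n_peaks
    rt = pm["rt"].to_numpy(dtype=float)
    mass = pm["mass"].to_numpy(dtype=float)

    if "distinct_from_background" in pm.columns:
        c1 = pm["distinct_from_background"].astype(bool).to_numpy()
    else:
        c1 = np.ones(n, dtype=bool)

    if {"rt_min", "rt_max"} <= set(pm.columns):
        c2 = ((pm["rt_min"].to_numpy() >= rt - th.rt_window)
              & (pm["rt_max"].to_numpy() <= rt + th.rt_window))
    else:
        c2 = np.ones(n, dtype=bool)

    c3 = np.ones(n, dtype=bool)
    for is_mass, is_rt in internal_standards:
        drt = np.abs(rt - is_rt)
        same_mass = np.abs(mass - is_mass) < 0.5
        window = np.where(same_mass, th.is_same_mass_window, th.is_rt_window)
        c3 &= drt >= window

    c4 = _group_presence(raw.intensities.to_numpy(), meta, raw.sample_ids,
                         th.group_min_intensity, th.group_presence_frac)

    # criterion 5: chain peaks of identical mass whose successive RTs differ
    # by <= overlap_rt; any group of size >= 2 is removed entirely
    c5 = np.ones(n, dtype=bool)
    order = np.lexsort((rt, mass))
    for i in range(1, n):
        a, b = order[i - 1], order[i]
        if mass[a] == mass[b] and (rt[b] - rt[a]) <= th.overlap_rt:
            c5[a] = c5[b] = False

    return _apply_criteria(raw, [("criterion_1_background", c1),
                                 ("criterion_2_rt_spread", c2),
                                 ("criterion_3_internal_standards", c3),
                                 ("criterion_4_group_level", c4),
                                 ("criterion_5_overlap", c5)])


def _apply_criteria(raw: PeakTable, criteria) -> tuple[PeakTable, FilterReport]:
    keep = np.ones(raw.n_peaks, dtype=bool)
    attributed = np.zeros(raw.n_peaks, dtype=bool)
    removals = {}
    for name, ok in criteria:
        fails_here = ~ok & ~attributed
        removals[name] = int(fails_here.sum())
        attributed |= fails_here
        keep &= ok
    filtered = raw.subset_peaks(raw.peak_ids[keep])
    report = FilterReport(
        input_count=raw.n_peaks,
        retained_count=int(keep.sum()),
        removals=removals,
    )
    report.check()
    return filtered, report


def drop_zero_containing_peaks(table: PeakTable) -> PeakTable:
    """Sensitivity mode: restrict to peaks detected in every sample.

    Rules out detection-limit censoring as a driver of downstream results
    by keeping only peaks with no zero (missing) values anywhere.
    """
    vals = table.intensities.to_numpy()
    if table.log_scale:
        keep = ~np.isnan(vals).any(axis=1)
    else:
        keep = (vals > 0).all(axis=1)
    return table.subset_peaks(table.peak_ids[keep])


def detect_outlier_samples(table: PeakTable, k: float = 5.0) -> set[str]:
    """Flag samples extreme on either of the first two principal components.

    The PCA is run on the log2 intensity matrix (samples as observations);
    a sample is an outlier if its score on PC1 or PC2 is more than ``k``
    robust standard deviations (1.4826 x MAD) from the median score.
    """
    from sklearn.decomposition import PCA

    if table.intensities.shape[1] < 4:
        raise ValueError("outlier detection requires >= 4 samples")
    if table.log_scale:
        X = np.nan_to_num(table.intensities.to_numpy().T)
    else:
        X = np.log2(table.intensities.to_numpy().T + 1.0)
    scores = PCA(n_components=2).fit_transform(X - X.mean(axis=0))
    out = np.zeros(X.shape[0], dtype=bool)
    for pc in range(2):
        s = scores[:, pc]
        med = np.median(s)
        scale = 1.4826 * np.median(np.abs(s - med))
        if scale == 0:
            scale = np.std(s) or 1.0
        out |= np.abs(s - med) > k * scale
    return set(table.sample_ids[out])


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of X in place of NaN-aware rank mapping.

    Zeros must already be encoded as NaN.  Each column's empirical quantile
    function is interpolated onto a common grid; the reference distribution
    is the grid-wise mean, and each value is replaced by the reference value
    at its (average-rank) quantile.  For complete, tie-free columns this is
    exactly the classical sort/average/reorder algorithm.
    """
    n_rows, n_cols = X.shape
    counts = (~np.isnan(X)).sum(axis=0)
    M = int(counts.max())
    grid = (np.arange(M) + 0.5) / M
    ref = np.zeros(M)
    for j in range(n_cols):
        v = np.sort(X[~np.isnan(X[:, j]), j])
        if v.size == 0:
            continue
        q = (np.arange(v.size) + 0.5) / v.size
        ref += np.interp(grid, q, v)
    ref /= n_cols
    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(X[:, j])
        m = int(mask.sum())
        if m == 0:
            continue
        ranks = stats.rankdata(X[mask, j], method="average")
        out[mask, j] = np.interp((ranks - 0.5) / m, grid, ref)
    return out


def normalize(table: PeakTable, meta: pd.DataFrame) -> PeakTable:
    """Log2 transform and quantile-normalize within each tissue's samples.

    Zeros (not detected) propagate as NaN and are excluded from the
    reference distribution.  A tissue group with a single sample is only
    log-transformed (with a warning).
    """
    if table.log_scale:
        raise ValueError("table is already on the log scale")
    vals = table.intensities.to_numpy(dtype=float).copy()
    vals[vals == 0.0] = np.nan
    logv = np.log2(vals)
    out = np.full_like(logv, np.nan)
    sub = meta.loc[table.sample_ids]
    for tissue, grp in sub.groupby("tissue", observed=True):
        cols = [table.sample_ids.get_loc(s) for s in grp.index]
        if len(cols) == 1:
            warnings.warn(f"tissue {tissue!r} has a single sample; log transform only",
                          stacklevel=2)
            out[:, cols[0]] = logv[:, cols[0]]
            continue
        out[:, cols] = _quantile_normalize(logv[:, cols])
    norm = pd.DataFrame(out, index=table.peak_ids, columns=table.sample_ids)
    return PeakTable(norm, table.peak_meta, log_scale=True)


def flag_postmortem_peaks(
    table: PeakTable,
    meta: pd.DataFrame,
    q: float = 0.05,
    delay_hours: float = 4.0,
    mode: str = "quantile",
) -> dict[str, set[str]]:
    """Flag peaks affected by postmortem delay, per tissue.

    ``mode='quantile'`` (default): per tissue, compute per-peak
    mean(delayed) - mean(control) on normalized values over macaque samples
    and flag peaks in the top or bottom ``q`` tail of that difference
    distribution.  ``mode='qvalue'``: per-tissue Welch t-test of delayed vs
    control with Benjamini-Hochberg adjustment; flag q < 0.01.
    """
    if not table.log_scale:
        raise ValueError("flag_postmortem_peaks expects a normalized table")
    if mode not in ("quantile", "qvalue"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = meta.loc[table.sample_ids]
    mac = (sub["species"] == "macaque") & ~sub["is_pooled"].astype(bool) \
        & (sub["condition"] == "standard")
    delayed_ids = sub.index[mac & (sub["postmortem_delay"] >= delay_hours)]
    control_ids = sub.index[mac & (sub["postmortem_delay"] < delay_hours)]
    if len(delayed_ids) == 0:
        warnings.warn("no postmortem-delayed samples; nothing flagged", stacklevel=2)
        return {}
    flagged: dict[str, set[str]] = {}
    for tissue, grp in sub.groupby("tissue", observed=True):
        d_cols = [s for s in delayed_ids if s in grp.index]
        c_cols = [s for s in control_ids if s in grp.index]
        if not d_cols or not c_cols:
            continue
        D = table.intensities[d_cols].to_numpy()
        C = table.intensities[c_cols].to_numpy()
        if mode == "quantile":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                diff = np.nanmean(D, axis=1) - np.nanmean(C, axis=1)
            lo = np.nanquantile(diff, q)
            hi = np.nanquantile(diff, 1.0 - q)
            mask = (diff <= lo) | (diff >= hi)
        else:
            t, p = stats.ttest_ind(D, C, axis=1, equal_var=False, nan_policy="omit")
            p = np.asarray(p, dtype=float)
            qvals = _bh_adjust(p)
            mask = qvals < 0.01
        flagged[tissue] = set(table.peak_ids[np.nan_to_num(mask, nan=False).astype(bool)])
    return flagged


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    q[mask] = adj
    return q


def annotate_peaks(
    table: PeakTable,
    mass_db: pd.DataFrame,
    mode: str,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Accurate-mass annotation of LC peaks against a metabolite mass table.

    For each peak, each candidate metabolite and each mode-appropriate
    adduct, a match is reported when the relative mass error
    |mz - adduct_mz| / adduct_mz x 1e6 is at most ``tol_ppm``.

    Positive mode searches [M+H]+, [M+NH4]+ and [M+Na]+; negative mode
    [M-H]- and [M+FA-H]- (formate).  Returns a frame with columns
    (peak_id, metabolite_id, adduct, ppm_error).
    """
    if mode not in ADDUCTS:
        raise ValueError(f"unknown ionization mode {mode!r}")
    adducts = ADDUCTS[mode]
    masses = mass_db["mass"].to_numpy(dtype=float)
    met_ids = mass_db.index.to_numpy()
    has_mz = table.peak_meta["mz"].notna()
    rows = []
    for pid, mz in table.peak_meta.loc[has_mz, "mz"].items():
        for adduct, offset in adducts.items():
            theo = masses + offset
            ppm = (mz - theo) / theo * 1e6
            hits = np.nonzero(np.abs(ppm) <= tol_ppm)[0]
            for h in hits:
                rows.append((pid, met_ids[h], adduct, float(ppm[h])))
    return pd.DataFrame(rows, columns=["peak_id", "metabolite_id", "adduct", "ppm_error"])
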