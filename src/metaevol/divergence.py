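"""Species/tissue variance decomposition and lineage-specific classification.

The pipeline identifies metabolite peaks whose concentrations differ among
tissues or species (permutation ANOVA), then, within each tissue category
(five sampled tissues plus the composite cortex = PFC+V1 and
brain = PFC+V1+CBC), assigns significant peaks to the evolutionary lineage
on which the concentration change occurred:

* a primate species is compared against the other two primates
  (human-specific, chimpanzee-specific, or macaque-lineage change);
* mouse is compared against all primates (mouse-lineage change).

Acceptance of a (peak, tissue, lineage) call requires a t-test p below the
nominal cutoff at a significance level whose permutation-estimated FDR is
below the stated bound; the FDR is estimated by recomputing discoveries
after permuting species labels within the tissue.

Per-lineage proportions of significant peaks are finally regressed on
phylogenetic branch lengths; the human excess over the nonhuman fit is
quantified per tissue as observed/predicted and as the human:chimpanzee
fold difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (COMPOSITE_TISSUES, LINEAGE_SPECIES, LINEAGES,
                        PRIMATES, SPECIES, TISSUE_CATEGORIES)
from .containers import PeakTable
from .phylo import Phylogeny

MULTITISSUE_GROUPS = (("PFC", "V1"), ("cortex", "CBC"), ("brain", "kidney", "muscle"))


def analysis_samples(meta: pd.DataFrame, delay_hours: float = 4.0) -> pd.Index:
    """Sample ids entering the comparative analysis: individual samples under
    standard conditions without postmortem delay."""
    keep = (~meta["is_pooled"].astype(bool)
            & (meta["condition"] == "standard")
            & (meta["postmortem_delay"] < delay_hours))
    return meta.index[keep]


def build_composite_tissues(meta: pd.DataFrame) -> dict[str, pd.Index]:
    """Sample groups for the 7 tissue categories (5 sampled + cortex, brain)."""
    groups: dict[str, pd.Index] = {}
    for cat in TISSUE_CATEGORIES:
        tissues = COMPOSITE_TISSUES.get(cat, (cat,))
        groups[cat] = meta.index[meta["tissue"].isin(tissues)]
    return groups


# ---------------------------------------------------------------------------
# fast linear-model machinery


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank dummy coding (drop first level, sorted order)."""
    levels = sorted(set(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares per column of Y after projecting out X
    (X includes the intercept).  Returns (rss vector, model rank)."""
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R[0, 0]))))
    QtY = Q.T @ Y
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)
    return np.maximum(rss, 0.0), rank


def _impute_tissue_means(Y: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Replace NaN by the tissue mean of observed values (per peak); tissues
    with no data fall back to the peak mean.  Imputing within the
    permutation stratum (tissue) keeps the label-permutation null valid:
    the fill values carry no species information."""
    if not np.isnan(Y).any():
        return Y
    import warnings as _warnings

    Y = Y.copy()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nan_to_num(np.nanmean(Y, axis=0))
    for c in np.unique(cells):
        rows = cells == c
        block = Y[rows]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            cm = np.nanmean(block, axis=0)
        cm = np.where(np.isnan(cm), overall, cm)
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(cm, block.shape)[nan_mask]
        Y[rows] = block
    return Y


@dataclass
class AnovaResult:
    """Per-peak sequential (Type I) F statistics and parametric p values."""

    frame: pd.DataFrame          # columns F_<factor>, p_<factor>
    mode: str                    # "all" or "primate"
    factors: tuple[str, ...]


def anova_decompose(
    table: PeakTable,
    meta: pd.DataFrame,
    factors: tuple[str, ...] = ("tissue", "species", "species:tissue",
                                "sex", "age", "rin"),
    primates_only: bool = False,
) -> AnovaResult:
    """Sequential linear-model decomposition of each peak's variation.

    Factors are added in the given order; each term's F uses the full-model
    residual mean square.  Categorical factors are dummy-coded; ``age`` and
    ``rin`` enter as numeric covariates.  Missing values (censored zeros)
    are imputed by within-tissue means.  Constant peaks get NaN p.
    """
    ids = analysis_samples(meta)
    ids = [s for s in ids if s in table.sample_ids]
    sub = meta.loc[ids]
    if primates_only:
        sub = sub[sub["species"].isin(PRIMATES)]
    Y = table.intensities[list(sub.index)].to_numpy(dtype=float).T  # samples x peaks
    Y = _impute_tissue_means(Y, sub["tissue"].astype(str).to_numpy())
    n = Y.shape[0]
    cells = (sub["species"].astype(str) + "|" + sub["tissue"].astype(str)).to_numpy()

    def factor_columns(name: str) -> np.ndarray:
        if name == "species:tissue":
            return _dummies(cells)  # over-complete vs additive; rank handled by QR
        if name in ("age", "rin"):
            v = sub[name].to_numpy(dtype=float)
            return (v - v.mean())[:, None]
        return _dummies(sub[name].astype(str).to_numpy())

    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss(X, Y)
    seq: list[tuple[str, np.ndarray, int]] = []
    for name in factors:
        cols = factor_columns(name)
        X = np.column_stack([X, cols])
        rss_k, rank_k = _rss(X, Y)
        seq.append((name, rss_prev - rss_k, rank_k - rank_prev))
        rss_prev, rank_prev = rss_k, rank_k

    df_resid = n - rank_prev
    mse = rss_prev / max(df_resid, 1)
    out = {}
    total_var = Y.var(axis=0)
    constant = total_var <= 1e-12
    for name, ss, df in seq:
        if df <= 0:
            out[f"F_{name}"] = np.full(Y.shape[1], np.nan)
            out[f"p_{name}"] = np.full(Y.shape[1], np.nan)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df) / mse
        p = stats.f.sf(F, df, df_resid)
        F[constant] = np.nan
        p[constant] = np.nan
        out[f"F_{name}"] = F
        out[f"p_{name}"] = p
    frame = pd.DataFrame(out, index=table.peak_ids)
    return AnovaResult(frame=frame, mode="primate" if primates_only else "all",
                       factors=tuple(factors))


# ---------------------------------------------------------------------------
# permutation test and permutation FDR


@dataclass
class PermutationResult:
    """Permutation test of one ANOVA factor."""

    factor: str
    perm_p: pd.Series            # add-one permutation p per peak
    f_obs: pd.Series
    fdr_at_cutoff: float
    cutoff: float
    n_perm: int
    zero_discoveries: bool = False
    n_discoveries: int = 0
    p_param: pd.Series | None = None          # parametric p of observed F
    perm_param_p: np.ndarray | None = None    # flattened permuted parametric p

    def significant(self, fdr_bound: float = 0.05) -> pd.Index:
        """Peaks significant at the largest level <= cutoff whose estimated
        FDR is within the bound (empty if no such level exists)."""
        if self.p_param is None or self.perm_param_p is None:
            if self.zero_discoveries or self.fdr_at_cutoff > fdr_bound:
                return self.perm_p.index[:0]
            return self.perm_p.index[self.perm_p < self.cutoff]
        thr, _ = _adaptive_threshold(self.p_param.to_numpy(), self.perm_param_p,
                                     self.cutoff, fdr_bound, self.n_perm)
        if thr is None:
            return self.perm_p.index[:0]
        return self.p_param.index[self.p_param <= thr]


def _conditional_f(Y, X0, X1) -> np.ndarray:
    rss0, r0 = _rss(X0, Y)
    rss1, r1 = _rss(X1, Y)
    df1 = r1 - r0
    df2 = Y.shape[0] - r1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return np.nan_to_num(F, nan=0.0)


def permutation_fdr(
    table: PeakTable,
    meta: pd.DataFrame,
    factor: str = "species",
    cutoff: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    primates_only: bool = False,
) -> PermutationResult:
    """Permutation p values and FDR estimate for one ANOVA factor.

    The permutation scheme respects the design: species labels are permuted
    within tissue for the species (and interaction) term; tissue labels are
    permuted within species for the tissue term.  The permutation p is the
    add-one estimator (1 + #{F_perm >= F_obs}) / (n_perm + 1); the FDR at
    the cutoff is the mean permuted discovery count divided by the observed
    discovery count (clipped to [0, 1]).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if factor not in ("species", "tissue", "species:tissue"):
        raise ValueError(f"unsupported factor {factor!r}")
    rng = np.random.default_rng(seed)
    ids = [s for s in analysis_samples(meta) if s in table.sample_ids]
    sub = meta.loc[ids]
    if primates_only:
        sub = sub[sub["species"].isin(PRIMATES)]
    Y = table.intensities[list(sub.index)].to_numpy(dtype=float).T
    Y = _impute_tissue_means(Y, sub["tissue"].astype(str).to_numpy())
    n = Y.shape[0]
    species = sub["species"].astype(str).to_numpy()
    tissue = sub["tissue"].astype(str).to_numpy()

    if factor == "tissue":
        base_labels, strata, permuted = tissue, species, "tissue"
    else:
        base_labels, strata, permuted = species, tissue, "species"

    def designs(perm_labels):
        intercept = np.ones((n, 1))
        if factor == "tissue":
            X0 = np.column_stack([intercept, _dummies(species)])
            X1 = np.column_stack([X0, _dummies(perm_labels)])
        elif factor == "species":
            X0 = np.column_stack([intercept, _dummies(tissue)])
            X1 = np.column_stack([X0, _dummies(perm_labels)])
        else:  # species:tissue interaction given both main effects
            X0 = np.column_stack([intercept, _dummies(tissue), _dummies(perm_labels)])
            inter = np.char.add(np.char.add(perm_labels.astype(str), "|"), tissue)
            X1 = np.column_stack([X0, _dummies(inter)])
        return X0, X1

    f_obs = _conditional_f(Y, *designs(base_labels))
    df1, df2 = _df_of(designs(base_labels), n)
    p_param = stats.f.sf(f_obs, df1, df2)

    strata_index = {s: np.nonzero(strata == s)[0] for s in np.unique(strata)}
    count_ge = np.zeros(Y.shape[1])
    obs_disc = int((f_obs >= _f_threshold(df1, df2, cutoff)).sum())
    perm_disc = np.zeros(n_perm)
    perm_param = np.empty((n_perm, Y.shape[1]))
    for b in range(n_perm):
        labels = base_labels.copy()
        for rows in strata_index.values():
            labels[rows] = labels[rng.permutation(rows)]
        F_b = _conditional_f(Y, *designs(labels))
        # tolerance so exact ties (e.g. label assignments equivalent to the
        # observed one) are counted despite floating-point jitter
        count_ge += F_b >= f_obs - 1e-9 * (1.0 + np.abs(f_obs))
        d1, d2 = _df_of(designs(labels), n)
        perm_disc[b] = (F_b >= _f_threshold(d1, d2, cutoff)).sum()
        perm_param[b] = stats.f.sf(F_b, d1, d2)

    perm_p = (1.0 + count_ge) / (n_perm + 1.0)
    zero = obs_disc == 0
    fdr = 0.0 if zero else float(np.clip(perm_disc.mean() / obs_disc, 0.0, 1.0))
    return PermutationResult(
        factor=factor,
        perm_p=pd.Series(perm_p, index=table.peak_ids),
        f_obs=pd.Series(f_obs, index=table.peak_ids),
        fdr_at_cutoff=fdr,
        cutoff=cutoff,
        n_perm=n_perm,
        zero_discoveries=zero,
        n_discoveries=obs_disc,
        p_param=pd.Series(p_param, index=table.peak_ids),
        perm_param_p=np.sort(perm_param.ravel()),
    )


def _df_of(designs, n):
    X0, X1 = designs
    r0 = np.linalg.matrix_rank(X0)
    r1 = np.linalg.matrix_rank(X1)
    return r1 - r0, n - r1


def _f_threshold(df1: int, df2: int, cutoff: float) -> float:
    return float(stats.f.isf(cutoff, df1, df2))


# ---------------------------------------------------------------------------
# species-specific classification


@dataclass
class LineageAssignment:
    """Per (peak, tissue category) lineage calls with p and estimated q."""

    assignments: pd.DataFrame    # columns: peak_id, tissue, lineage, direction, p, q
    tested: dict = field(default_factory=dict)  # (tissue, lineage) -> n tested peaks

    def count(self, tissue: str, lineage: str) -> int:
        a = self.assignments
        return int(((a["tissue"] == tissue) & (a["lineage"] == lineage)).sum())


def _welch_from_moments(s1, ss1, n1, s2, ss2, n2, equal_var: bool = False):
    """Two-sample t and p from group sums, sums of squares and counts.

    Welch by default; ``equal_var=True`` gives the pooled-variance test."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        v1 = (ss1 - n1 * m1**2) / (n1 - 1)
        v2 = (ss2 - n2 * m2**2) / (n2 - 1)
        v1 = np.maximum(v1, 0.0)
        v2 = np.maximum(v2, 0.0)
        if equal_var:
            vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = vp * (1.0 / n1 + 1.0 / n2)
            t = (m1 - m2) / np.sqrt(se2)
            df = n1 + n2 - 2
        else:
            se2 = v1 / n1 + v2 / n2
            t = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
    return t, p, m1 - m2


def _group_moments(Y, mask_rows):
    """Row-subset sums/sumsq/counts of Y (samples x peaks), NaN-aware."""
    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y)
    sel = mask_rows.astype(float)
    s = sel @ Y0
    ss = sel @ (Y0**2)
    n = sel @ M
    return s, ss, n


def _adaptive_threshold(p_obs: np.ndarray, p_perm: np.ndarray, p_cutoff: float,
                        fdr: float, n_perm: int):
    """Largest p threshold <= p_cutoff whose permutation-estimated FDR is
    within ``fdr``.  Returns (threshold or None, q-value per observed peak).

    FDR(c) = (mean permuted discoveries at c) / (observed discoveries at c).
    q values are the monotonized FDR at each observed p.
    """
    finite = np.isfinite(p_obs)
    cand = np.sort(p_obs[finite & (p_obs <= p_cutoff)])
    qvals = np.full(p_obs.shape, np.nan)
    if cand.size == 0:
        return None, qvals
    perm_sorted = np.sort(p_perm[np.isfinite(p_perm)])
    perm_counts = np.searchsorted(perm_sorted, cand, side="right") / n_perm
    obs_counts = np.arange(1, cand.size + 1)
    fdr_at = np.clip(perm_counts / obs_counts, 0.0, None)
    # monotonize from the largest candidate down (q-value style)
    q_at = np.minimum.accumulate(fdr_at[::-1])[::-1]
    ok = np.nonzero(q_at <= fdr)[0]
    thr = float(cand[ok.max()]) if ok.size else None
    pos = np.searchsorted(cand, p_obs[finite & (p_obs <= p_cutoff)], side="left")
    qvals[finite & (p_obs <= p_cutoff)] = q_at[np.minimum(pos, cand.size - 1)]
    return thr, qvals


def classify_species_specific(
    table: PeakTable,
    meta: pd.DataFrame,
    gate_primate,
    gate_all,
    p_cutoff: float = 0.01,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tissue_categories: tuple[str, ...] = TISSUE_CATEGORIES,
    exclusion_p: float | None = None,
    excluded_per_tissue: dict | None = None,
    equal_var: bool = False,
) -> LineageAssignment:
    """Assign ANOVA-significant peaks to evolutionary lineages per tissue.

    ``gate_primate`` / ``gate_all`` are the peak sets significant in the
    primate-only and all-species ANOVA; primate-lineage tests are restricted
    to the former, the mouse test to the latter.  Within each tissue
    category, the focal species is compared with the remaining species by a
    two-sided Welch t-test; calls are accepted at the largest significance
    level <= ``p_cutoff`` whose within-tissue label-permutation FDR estimate
    is <= ``fdr``.

    A change is attributed to the focal lineage only if the comparison
    species agree with each other: peaks for which any pair of comparison
    species differs at ``exclusion_p`` (default: the nominal cutoff) are not
    assignable to the focal lineage.  Without this outgroup-homogeneity
    condition, a strong shift on one lineage leaks into the other species'
    one-vs-rest tests through the contaminated comparison group.

    ``excluded_per_tissue`` maps tissue -> peak ids excluded in that tissue
    (e.g. postmortem-affected peaks); a composite category excludes peaks
    flagged in any constituent tissue.
    """
    if exclusion_p is None:
        exclusion_p = p_cutoff
    excluded_per_tissue = excluded_per_tissue or {}
    rng = np.random.default_rng(seed)
    ids = [s for s in analysis_samples(meta) if s in table.sample_ids]
    sub = meta.loc[ids]
    groups = build_composite_tissues(sub)
    gate_primate = pd.Index(sorted(gate_primate))
    gate_all = pd.Index(sorted(gate_all))

    rows = []
    tested: dict = {}
    for cat in tissue_categories:
        cat_ids = groups[cat]
        cat_meta = sub.loc[cat_ids]
        cat_excluded: set = set()
        for t in COMPOSITE_TISSUES.get(cat, (cat,)):
            cat_excluded |= set(excluded_per_tissue.get(t, ()))
        for lineage in LINEAGES:
            focal_sp = LINEAGE_SPECIES[lineage]
            if focal_sp == "mouse":
                comparison = list(PRIMATES)
                gate = gate_all
            else:
                comparison = [s for s in PRIMATES if s != focal_sp]
                gate = gate_primate
            gate_cat = gate[~gate.isin(cat_excluded)] if cat_excluded else gate
            tested[(cat, lineage)] = len(gate_cat)
            if len(gate_cat) == 0:
                continue
            involved = cat_meta[cat_meta["species"].isin([focal_sp] + comparison)]
            focal_mask = (involved["species"] == focal_sp).to_numpy()
            if focal_mask.sum() < 2 or (~focal_mask).sum() < 2:
                continue
            gate_in_table = gate_cat[gate_cat.isin(table.peak_ids)]
            Y = table.intensities.loc[gate_in_table, list(involved.index)] \
                .to_numpy(dtype=float).T
            s1, ss1, n1 = _group_moments(Y, focal_mask)
            s2, ss2, n2 = _group_moments(Y, ~focal_mask)
            t_obs, p_obs, diff = _welch_from_moments(s1, ss1, n1, s2, ss2, n2,
                                                     equal_var)

            # outgroup homogeneity: the comparison species must not differ
            # from each other, else the change is not attributable to the
            # focal lineage
            species_arr = involved["species"].to_numpy()
            eligible = np.ones(Y.shape[1], dtype=bool)
            for ai in range(len(comparison)):
                for bi in range(ai + 1, len(comparison)):
                    ma = species_arr == comparison[ai]
                    mb = species_arr == comparison[bi]
                    b1, bb1, bn1 = _group_moments(Y, ma)
                    b2, bb2, bn2 = _group_moments(Y, mb)
                    _, p_pair, _ = _welch_from_moments(b1, bb1, bn1,
                                                       b2, bb2, bn2, equal_var)
                    eligible &= np.nan_to_num(p_pair, nan=1.0) > exclusion_p
            p_obs = np.where(eligible, p_obs, np.nan)

            # label permutations within the tissue category
            n_samp = Y.shape[0]
            perm_ps = np.empty((n_perm, Y.shape[1]))
            for b in range(n_perm):
                pm = np.zeros(n_samp, dtype=bool)
                pm[rng.choice(n_samp, size=int(focal_mask.sum()), replace=False)] = True
                a1, aa1, an1 = _group_moments(Y, pm)
                a2, aa2, an2 = _group_moments(Y, ~pm)
                _, perm_ps[b], _ = _welch_from_moments(a1, aa1, an1,
                                                       a2, aa2, an2, equal_var)

            thr, qvals = _adaptive_threshold(p_obs, perm_ps.ravel(), p_cutoff,
                                             fdr, n_perm)
            if thr is None:
                continue
            accepted = np.nonzero(np.nan_to_num(p_obs, nan=1.0) <= thr)[0]
            for j in accepted:
                rows.append(dict(
                    peak_id=gate_in_table[j], tissue=cat, lineage=lineage,
                    direction="up" if diff[j] > 0 else "down",
                    p=float(p_obs[j]), q=float(qvals[j]),
                ))
    frame = pd.DataFrame(rows, columns=["peak_id", "tissue", "lineage",
                                        "direction", "p", "q"])
    return LineageAssignment(assignments=frame, tested=tested)


def exclude_multitissue(assign: LineageAssignment) -> LineageAssignment:
    """Remove same-lineage same-direction calls repeated across tissues of a
    redundancy group: (i) PFC+V1, (ii) cortex+CBC, (iii) brain+kidney+muscle.

    Composite-tissue calls (cortex, brain) are never removed themselves but
    do count as counterparts for the individual tissues grouped with them.
    """
    a = assign.assignments
    if a.empty:
        return LineageAssignment(a.copy(), dict(assign.tested))
    drop = np.zeros(len(a), dtype=bool)
    key = list(zip(a["peak_id"], a["lineage"], a["direction"], a["tissue"]))
    present = set(key)
    composite = set(COMPOSITE_TISSUES)
    for i, (pid, lin, d, t) in enumerate(key):
        if t in composite:
            continue
        for grp in MULTITISSUE_GROUPS:
            if t in grp:
                for other in grp:
                    if other != t and (pid, lin, d, other) in present:
                        drop[i] = True
    return LineageAssignment(a[~drop].reset_index(drop=True), dict(assign.tested))


# ---------------------------------------------------------------------------
# divergence vs phylogenetic distance


@dataclass
class DivergenceSummary:
    proportions: pd.DataFrame      # tissue categories x lineages
    slope: float
    intercept: float
    r_squared: float
    per_tissue: pd.DataFrame       # predicted human prop, excess, fold excess, p
    n_points: int


def divergence_regression(
    assign: LineageAssignment,
    phylogeny: Phylogeny | None = None,
    tissue_categories: tuple[str, ...] = TISSUE_CATEGORIES,
) -> DivergenceSummary:
    """Regress per-lineage significant-peak proportions on branch lengths.

    The fit uses the 3 nonhuman lineages x all tissue categories; the human
    points are then compared with the regression prediction at the human
    branch length.  The human-excess p is a one-sided test on the
    studentized prediction residual of the human point.
    """
    phylogeny = phylogeny or Phylogeny()
    prop = pd.DataFrame(index=list(tissue_categories), columns=list(LINEAGES),
                        dtype=float)
    for cat in tissue_categories:
        for lineage in LINEAGES:
            n_tested = assign.tested.get((cat, lineage), 0)
            prop.loc[cat, lineage] = (
                assign.count(cat, lineage) / n_tested if n_tested else np.nan
            )

    xs, ys = [], []
    for cat in tissue_categories:
        for lineage in ("chimp", "macaque_anc", "mouse_anc"):
            y = prop.loc[cat, lineage]
            if np.isfinite(y):
                xs.append(phylogeny[lineage])
                ys.append(float(y))
    x = np.asarray(xs)
    y = np.asarray(ys)
    n = x.size
    if n < 3:
        raise ValueError("too few (lineage, tissue) points for regression")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    r2 = res.rvalue**2
    resid = y - (intercept + slope * x)
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())

    x_h = phylogeny["human"]
    pred = intercept + slope * x_h
    se_pred = np.sqrt(s2 * (1.0 + 1.0 / n + (x_h - x.mean()) ** 2 / sxx))
    rows = []
    for cat in tissue_categories:
        obs = prop.loc[cat, "human"]
        chimp = prop.loc[cat, "chimp"]
        excess = obs / pred if pred > 0 else np.nan
        if chimp == 0:
            fold = np.inf
        else:
            fold = obs / chimp
        t_stat = (obs - pred) / se_pred
        p_excess = float(stats.t.sf(t_stat, n - 2))
        rows.append(dict(tissue=cat, human_proportion=obs, predicted=pred,
                         excess=excess, fold_excess_vs_chimp=fold,
                         p_excess=p_excess,
                         infinite_fold=bool(np.isinf(fold))))
    per_tissue = pd.DataFrame(rows).set_index("tissue")
    return DivergenceSummary(
        proportions=prop, slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), per_tissue=per_tissue, n_points=n,
    )


def relative_concentration_matrix(
    table: PeakTable,
    meta: pd.DataFrame,
    log_input: bool | None = None,
) -> pd.DataFrame:
    """Per-peak log2 ratio of each primate sample to the mean of the other
    primate species' samples within the same tissue.

    With log-scale (normalized) input the entry is ``value - mean(others)``;
    with linear input it is ``log2(value) - log2(mean(others))``.
    """
    if log_input is None:
        log_input = table.log_scale
    ids = [s for s in analysis_samples(meta) if s in table.sample_ids]
    sub = meta.loc[ids]
    sub = sub[sub["species"].isin(PRIMATES)]
    vals = table.intensities[list(sub.index)].to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    species = sub["species"].to_numpy()
    tissue = sub["tissue"].to_numpy()
    for j, sid in enumerate(sub.index):
        others = (tissue == tissue[j]) & (species != species[j])
        if not others.any():
            raise ValueError(f"no other-primate samples for {sid}")
        if log_input:
            out[:, j] = vals[:, j] - np.nanmean(vals[:, others], axis=1)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, j] = np.log2(vals[:, j]) - np.log2(
                    np.nanmean(vals[:, others], axis=1))
    return pd.DataFrame(out, index=table.peak_ids, columns=sub.index)
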