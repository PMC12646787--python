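"""Identity signal in egg phenotypes.

For egg appearance to betray a parasitic egg, a female's eggs must resemble
each other more than they resemble other females' eggs.  This module
quantifies that premise three ways:

* within- versus between-clutch variance metrics with a one-sample t-test,
* Beecher's information statistic Hs (bits of individual identity carried by
  the decorrelated phenotype), with a label-shuffled control,
* laying-order deviation profiles (first- and last-laid eggs of many species
  deviate from their clutchmates, which confounds outlier-based detection).

All functions expect the nine traits z-scored over the full egg set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TRAIT_COLUMNS

F_CAP = 1e6  # keeps Hs finite when within-group variance degenerates to 0


@dataclass
class IdentityStats:
    """Within/between clutch variance metrics and the identity statistic."""

    within_per_clutch: np.ndarray
    within_mean: float
    within_sd: float
    between: float
    t_stat: float
    df: int
    p: float
    hs: float = float("nan")
    hs_control: float = float("nan")
    n_significant_vars: int = 0
    clutch_ids: list = field(default_factory=list)


def clutch_variance_stats(
    traits: pd.DataFrame, clutch_col: str = "clutch_id"
) -> IdentityStats:
    """Within- and between-clutch variance metrics with a one-sample t-test.

    Within metric (one per female): s.d. of each trait over the clutch's
    eggs, averaged over the nine traits.  Between metric: build each
    clutch's "average egg" (trait means), take the s.d. of each trait across
    clutches, average over traits.  The t-test compares the within metrics
    against the between value.  Sample s.d. (ddof=1) throughout.
    """
    X = traits[TRAIT_COLUMNS].to_numpy(dtype=float)
    ids = np.asarray(traits[clutch_col])
    uniq = pd.unique(ids)
    within = []
    kept_ids = []
    means = []
    for cid in uniq:
        sub = X[ids == cid]
        if len(sub) < 2:
            warnings.warn(f"clutch {cid} has a single egg; excluded")
            continue
        within.append(float(sub.std(axis=0, ddof=1).mean()))
        kept_ids.append(cid)
        means.append(sub.mean(axis=0))
    if len(within) < 2:
        raise ValueError("need at least 2 clutches with >= 2 eggs")
    within = np.asarray(within)
    means = np.asarray(means)
    between = float(means.std(axis=0, ddof=1).mean())
    t_res = stats.ttest_1samp(within, popmean=between)
    return IdentityStats(
        within_per_clutch=within,
        within_mean=float(within.mean()),
        within_sd=float(within.std(ddof=1)),
        between=between,
        t_stat=float(t_res.statistic),
        df=len(within) - 1,
        p=float(t_res.pvalue),
        clutch_ids=kept_ids,
    )


def _hs_from_matrix(X: np.ndarray, ids: np.ndarray) -> tuple[float, int]:
    """Hs on one matrix: PCA-decorrelate, sum 0.5*log2(F) over significant PCs."""
    n, p = X.shape
    n_comp = min(n - 1, p)
    if n_comp < p:
        warnings.warn("fewer eggs than variables; components truncated")
    Xc = X - X.mean(axis=0)
    # full PCA via SVD; scores are the decorrelated variables
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ Vt.T
    scores = scores[:, :n_comp]
    hs = 0.0
    n_sig = 0
    for j in range(scores.shape[1]):
        groups = [scores[ids == g, j] for g in pd.unique(ids)]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        if all(np.ptp(g) < 1e-12 for g in groups):
            F, pval = F_CAP, 0.0
            warnings.warn("zero within-group variance; F capped")
        else:
            F, pval = stats.f_oneway(*groups)
            if not np.isfinite(F) or F > F_CAP:
                warnings.warn("degenerate F capped at 1e6")
                F = F_CAP
        if pval < 0.05 and F > 1.0:
            hs += 0.5 * np.log2(F)
            n_sig += 1
    return hs, n_sig


def beecher_hs(
    traits: pd.DataFrame, clutch_col: str = "clutch_id", seed: int = 0
) -> tuple[float, float, int]:
    """Beecher's information statistic with a label-shuffled control.

    Traits are decorrelated by a full PCA; each component is tested for a
    female effect by one-way ANOVA, and components significant at p < 0.05
    contribute 0.5*log2(F) bits.  The control repeats the computation with
    clutch labels shuffled (seeded), estimating the statistic's noise floor.

    Returns ``(hs, hs_control, n_significant_vars)``.
    """
    ids = np.asarray(traits[clutch_col])
    uniq, counts = np.unique(ids, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 clutches with >= 2 eggs")
    X = traits[TRAIT_COLUMNS].to_numpy(dtype=float)
    hs, n_sig = _hs_from_matrix(X, ids)
    rng = np.random.default_rng(seed)
    ids_shuf = rng.permutation(ids)
    hs_control, _ = _hs_from_matrix(X, ids_shuf)
    return float(hs), float(hs_control), int(n_sig)


def laying_order_deviation(
    traits: pd.DataFrame,
    clutch_col: str = "clutch_id",
    order_col: str = "laying_order",
) -> pd.DataFrame:
    """Mean within-clutch distance of each egg, summarised by laying position.

    For every egg the mean Euclidean distance (scaled traits) to its
    clutchmates is computed; clutches with incomplete laying order are
    skipped.  Returns a table indexed by laying position with columns
    ``mean_deviation`` and ``n_eggs``.
    """
    rows = []
    for cid, sub in traits.groupby(clutch_col, sort=False):
        orders = sub[order_col]
        if orders.isna().any() or len(sub) < 2:
            warnings.warn(f"clutch {cid}: missing laying order; skipped")
            continue
        X = sub[TRAIT_COLUMNS].to_numpy(dtype=float)
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        mean_d = D.sum(axis=1) / (len(X) - 1)
        for pos, d in zip(orders.astype(int), mean_d):
            rows.append({"position": int(pos), "deviation": float(d)})
    if not rows:
        raise ValueError("no clutch with complete laying order")
    df = pd.DataFrame(rows)
    out = df.groupby("position")["deviation"].agg(["mean", "count"])
    out.columns = ["mean_deviation", "n_eggs"]
    return out
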