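"""Construction, ranking and weighting of the nine egg phenotypic traits.

Raw egg measurements are reduced to nine principal-component traits via five
separate PCAs, one per feature group:

===========  ==========================================================  =====
group        input columns                                               kept
===========  ==========================================================  =====
colour       10 spot/background channel means                            3
luminance    10 luminance-histogram bins                                 1
pattern      granularity energies + skewnesses (scales x regions)        2
pattern2     spot size, coverage, dispersion mean/s.d./CV                2
shape        length, width, volume, surface, ellipse dev, aspect ratio   1
===========  ==========================================================  =====

A random forest classifying female identity from the nine traits then ranks
them by permutation importance (mean decrease in accuracy), and the
importances serve as multiplicative weights for the Euclidean-distance
methods downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .imaging import (
    N_SCALES_DEFAULT,
    REGION_NAMES,
    colour_columns,
    shape_columns,
    spot_columns,
)

#: Fixed trait order used everywhere downstream.
TRAIT_COLUMNS = [
    "colour_pc1",
    "colour_pc2",
    "colour_pc3",
    "luminance_pc1",
    "pattern_pc1",
    "pattern_pc2",
    "pattern2_pc1",
    "pattern2_pc2",
    "shape_pc1",
]

#: Components retained per group.
GROUP_COMPONENTS = {
    "colour": 3,
    "luminance": 1,
    "pattern": 2,
    "pattern2": 2,
    "shape": 1,
}

#: Reference trait weights (mean decrease in accuracy, percentage scale) from
#: the published random-forest ranking on the original 270-egg dataset, in
#: TRAIT_COLUMNS order.
REFERENCE_WEIGHTS = np.array(
    [21.30, 22.48, 32.06, 19.73, 20.44, 28.44, 17.95, 18.61, 37.13]
)


def feature_groups(
    n_scales: int = N_SCALES_DEFAULT, pattern_whole_only: bool = False
) -> dict[str, list[str]]:
    """Column layout of the five PCA groups.

    ``pattern_whole_only`` restricts the pattern PCA to whole-egg energies
    and skewnesses (12 + 12 columns) instead of all scale-by-region values.
    """
    regions = ("whole",) if pattern_whole_only else REGION_NAMES
    pattern = [f"energy_s{i:02d}_{r}" for i in range(n_scales) for r in regions]
    pattern += [f"skew_s{i:02d}_{r}" for i in range(n_scales) for r in regions]
    return {
        "colour": colour_columns(),
        "luminance": [f"lum_bin_{i + 1:02d}" for i in range(10)],
        "pattern": pattern,
        "pattern2": spot_columns(),
        "shape": shape_columns(),
    }


@dataclass
class TraitModel:
    """Standardisation parameters and PCA loadings for the five groups."""

    groups: dict[str, list[str]]  # group -> columns actually used
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]  # group -> (n_components, n_cols)
    explained: dict[str, np.ndarray]  # variance fractions per component
    n_components: dict[str, int] = field(
        default_factory=lambda: dict(GROUP_COMPONENTS)
    )

    def __post_init__(self) -> None:
        for g, load in self.loadings.items():
            if load.shape[0] != self.n_components[g]:
                raise ValueError(f"group {g}: wrong component count")
            gram = load @ load.T
            if not np.allclose(gram, np.eye(load.shape[0]), atol=1e-8):
                raise ValueError(f"group {g}: loadings not orthonormal")


def fit_trait_model(
    features: pd.DataFrame,
    n_components: dict[str, int] | None = None,
    n_scales: int = N_SCALES_DEFAULT,
    pattern_whole_only: bool = False,
) -> TraitModel:
    """Fit the five per-group PCAs on z-scored feature columns.

    Constant columns are dropped with a warning before standardisation.
    The sign of each component is fixed so its largest-|loading| variable
    loads positively, making scores reproducible across fits.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 eggs to fit the trait model")
    if features[_all_feature_cols(n_scales, pattern_whole_only)].isna().any().any():
        raise ValueError("missing values in feature table")
    groups_all = feature_groups(n_scales, pattern_whole_only)
    n_comp = dict(n_components or GROUP_COMPONENTS)
    groups: dict[str, list[str]] = {}
    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    loadings: dict[str, np.ndarray] = {}
    explained: dict[str, np.ndarray] = {}
    for g, cols in groups_all.items():
        X = features[cols].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 1e-12
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"group {g}: dropping constant columns {dropped}")
        cols_kept = [c for c, k in zip(cols, keep) if k]
        if len(cols_kept) < n_comp[g]:
            raise ValueError(f"group {g}: too few varying columns")
        Xk = X[:, keep]
        mu = Xk.mean(axis=0)
        sdk = sd[keep]
        Z = (Xk - mu) / sdk
        pca = PCA(n_components=n_comp[g], svd_solver="full").fit(Z)
        load = pca.components_.copy()
        for ci in range(load.shape[0]):  # fix signs
            jmax = int(np.argmax(np.abs(load[ci])))
            if load[ci, jmax] < 0:
                load[ci] *= -1.0
        groups[g] = cols_kept
        means[g] = mu
        sds[g] = sdk
        loadings[g] = load
        explained[g] = pca.explained_variance_ratio_.copy()
    return TraitModel(
        groups=groups,
        means=means,
        sds=sds,
        loadings=loadings,
        explained=explained,
        n_components=n_comp,
    )


def _all_feature_cols(n_scales: int, pattern_whole_only: bool) -> list[str]:
    out: list[str] = []
    for cols in feature_groups(n_scales, pattern_whole_only).values():
        out.extend(cols)
    return out


def project_traits(model: TraitModel, features: pd.DataFrame) -> pd.DataFrame:
    """Project a feature table onto the nine traits.

    Returns a DataFrame with ``egg_id``/``clutch_id`` (and ``laying_order``
    if present) carried over and one column per trait in TRAIT_COLUMNS order.
    """
    scores: dict[str, np.ndarray] = {}
    for g, cols in model.groups.items():
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        X = features[cols].to_numpy(dtype=float)
        Z = (X - model.means[g]) / model.sds[g]
        S = Z @ model.loadings[g].T
        for ci in range(S.shape[1]):
            name = f"{g}_pc{ci + 1}"
            scores[name] = S[:, ci]
    out = pd.DataFrame(scores, index=features.index)[TRAIT_COLUMNS]
    for meta in ("egg_id", "clutch_id", "laying_order"):
        if meta in features.columns:
            out.insert(0, meta, features[meta].to_numpy())
    return out


def scale_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Z-score the nine trait columns over the full egg set (ddof=1)."""
    out = traits.copy()
    for c in TRAIT_COLUMNS:
        v = out[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        out[c] = (v - v.mean()) / (sd if sd > 1e-12 else 1.0)
    return out


@dataclass
class ImportanceWeights:
    """Per-trait multiplicative weights (mean decrease in accuracy)."""

    w: np.ndarray  # 9 nonnegative reals, TRAIT_COLUMNS order
    provenance: str  # "fitted" | "reference"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (9,):
            raise ValueError("expected 9 weights")
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")


def reference_weights() -> ImportanceWeights:
    """The published percentage-scale weights (Table ranking of the study)."""
    return ImportanceWeights(w=REFERENCE_WEIGHTS.copy(), provenance="reference")


def rank_traits(
    traits: pd.DataFrame,
    female_ids: np.ndarray | pd.Series | None = None,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceWeights:
    """Rank the nine traits by out-of-bag permutation importance.

    A random forest classifies female identity from the traits.  For each
    tree, accuracy on its out-of-bag eggs is compared with accuracy after
    permuting one trait's values among those eggs; the importance of the
    trait is the decrease averaged over trees (mean decrease in accuracy).
    Using out-of-bag rather than training rows keeps the importances of
    pure-noise traits centred on zero.  Negative importances are clamped to
    zero with a warning, since the weights multiply trait values downstream.
    """
    if female_ids is None:
        female_ids = traits["clutch_id"]
    y = np.asarray(female_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 females")
    X = traits[TRAIT_COLUMNS].to_numpy(dtype=float)
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, bootstrap=True
    ).fit(X, y)
    rng = np.random.default_rng(seed)
    n = len(X)
    drops = np.zeros((len(rf.estimators_), 9))
    for t, (tree, sampled) in enumerate(zip(rf.estimators_, rf.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        yo_enc = np.searchsorted(rf.classes_, yo)
        base = np.mean(tree.predict(Xo) == yo_enc)
        for j in range(9):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[t, j] = base - np.mean(tree.predict(Xp) == yo_enc)
    w = drops.mean(axis=0)
    if (w < 0).any():
        warnings.warn("negative permutation importances clamped to 0")
        w = np.maximum(w, 0.0)
    return ImportanceWeights(w=w, provenance="fitted")


def weight_traits(traits: pd.DataFrame, weights: ImportanceWeights) -> pd.DataFrame:
    """Multiply each trait column by its importance weight."""
    if not np.all(np.isfinite(weights.w)):
        raise ValueError("weights must be finite")
    out = traits.copy()
    for c, wi in zip(TRAIT_COLUMNS, weights.w):
        out[c] = out[c].to_numpy(dtype=float) * wi
    out.attrs["weighted"] = True
    out.attrs["weight_provenance"] = weights.provenance
    return out
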