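"""Detection of parasitized clutches and parasitic eggs.

Three detectors, in increasing order of supervision:

* **MED** — the maximum Euclidean distance statistic: within a clutch, each
  egg's mean pairwise distance to its clutchmates (weighted traits); the
  clutch-level maximum flags parasitized clutches against a threshold.
* **Unsupervised identification** — in a known-parasitized clutch, the egg
  with the largest mean weighted distance is called parasitic (game 1: all
  six eggs; game 2: the two candidates compared against the four known host
  eggs).
* **Supervised same/different voting** — a random forest trained on
  balanced pairs of eggs (features: absolute per-trait differences, label:
  same female or different females) classifies the within-clutch pairs; each
  "different" verdict credits both members of the pair, once per direction,
  and the egg with the most votes over repeated resampled trainings is
  called parasitic.  Exact vote ties are reported as ambiguous, never
  broken.  Validation is leave-one-clutch-out (the tested female's eggs are
  excluded from training) or, for game 2, leave-one-egg-out (the four
  regular-sequence host eggs join the training pool as known "same" pairs).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier

from .simulate import ParasitizedClutch
from .traits import TRAIT_COLUMNS

MED_THRESHOLD_DEFAULT = 350.0  # meaningful under reference (percentage-scale) weights


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MEDResult:
    clutch_id: str
    per_egg_mean_distance: dict[str, float]
    med: float
    classified_parasitized: bool
    threshold: float


@dataclass
class PairSample:
    """One training pair: absolute per-trait differences + same/different label."""

    features: np.ndarray
    label: str  # "same" | "different"
    egg_a: str
    egg_b: str


@dataclass
class VoteTally:
    """Per-egg counts of 'different' verdicts accumulated over repeats."""

    per_egg_votes: dict[str, int]
    n_repeats: int
    called_egg: str | None
    ambiguous: bool

    def __post_init__(self) -> None:
        if self.per_egg_votes:
            top = max(self.per_egg_votes.values())
            n_top = sum(1 for v in self.per_egg_votes.values() if v == top)
            if self.ambiguous != (n_top >= 2):
                raise ValueError("ambiguous flag inconsistent with votes")
            if (self.called_egg is not None) == self.ambiguous:
                raise ValueError("called_egg must be set iff not ambiguous")


@dataclass
class AccuracySummary:
    n_total: int
    n_ambiguous: int
    n_correct: int
    accuracy_pct: float


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _trait_matrix(traits: pd.DataFrame, egg_ids: list[str]) -> np.ndarray:
    sub = traits.set_index("egg_id").loc[egg_ids, TRAIT_COLUMNS]
    return sub.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# MED statistic
# ---------------------------------------------------------------------------


def med_statistic(
    clutch_traits: pd.DataFrame,
    threshold: float = MED_THRESHOLD_DEFAULT,
    weight_provenance: str | None = None,
) -> MEDResult:
    """Maximum Euclidean distance of a clutch (weighted traits expected).

    All pairwise distances within the clutch are computed; each egg's mean
    over its n-1 pairs is taken, and the maximum over eggs is the MED.  The
    default decision threshold (350) was calibrated on percentage-scale
    reference weights — a warning is issued when the provenance differs.
    """
    egg_ids = [str(e) for e in clutch_traits["egg_id"]]
    if len(egg_ids) < 3:
        raise ValueError("MED needs at least 3 eggs")
    if weight_provenance is None:
        weight_provenance = clutch_traits.attrs.get("weight_provenance")
    if weight_provenance not in (None, "reference"):
        warnings.warn(
            "MED threshold 350 was calibrated for reference-scale weights; "
            f"weights here are '{weight_provenance}'"
        )
    X = clutch_traits[TRAIT_COLUMNS].to_numpy(dtype=float)
    D = squareform(pdist(X))
    mean_d = D.sum(axis=1) / (len(egg_ids) - 1)
    per_egg = {e: float(d) for e, d in zip(egg_ids, mean_d)}
    med = float(mean_d.max())
    cid = str(clutch_traits["clutch_id"].iloc[0]) if "clutch_id" in clutch_traits else ""
    return MEDResult(
        clutch_id=cid,
        per_egg_mean_distance=per_egg,
        med=med,
        classified_parasitized=med > threshold,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Unsupervised identification
# ---------------------------------------------------------------------------


def unsupervised_identify(
    pc: ParasitizedClutch, traits: pd.DataFrame, game: int = 1
) -> str | None:
    """Call the parasitic egg by weighted mean distance; ``None`` on exact tie.

    Game 1: per-egg mean over its five pairs among the six eggs, argmax
    called parasitic.  Game 2: each candidate's mean distance to the four
    known host eggs (the candidate-candidate pair is excluded); the larger
    mean is called parasitic.
    """
    if game == 1:
        eggs = pc.all_eggs
        X = _trait_matrix(traits, eggs)
        D = squareform(pdist(X))
        mean_d = D.sum(axis=1) / (len(eggs) - 1)
    elif game == 2:
        if len(pc.known_hosts) != 4 or len(pc.candidates) != 2:
            raise ValueError("game 2 needs 4 known hosts and 2 candidates")
        eggs = pc.candidates
        C = _trait_matrix(traits, pc.candidates)
        H = _trait_matrix(traits, pc.known_hosts)
        mean_d = np.sqrt(((C[:, None, :] - H[None, :, :]) ** 2).sum(-1)).mean(axis=1)
    else:
        raise ValueError("game must be 1 or 2")
    top = mean_d.max()
    winners = [e for e, d in zip(eggs, mean_d) if d == top]
    return winners[0] if len(winners) == 1 else None


# ---------------------------------------------------------------------------
# Supervised same/different voting
# ---------------------------------------------------------------------------


def build_pair_training(
    pool_traits: pd.DataFrame,
    n_same: int = 265,
    n_diff: int = 265,
    seed: int | np.random.Generator = 0,
    forced_host_eggs: set[str] | None = None,
) -> list[PairSample]:
    """Sample a balanced same/different pair training set from an egg pool.

    ``n_same`` within-female and ``n_diff`` between-female pairs are drawn
    uniformly without replacement (with replacement plus a warning if the
    pool is too small).  When ``forced_host_eggs`` is given, every pair
    among those eggs enters as a guaranteed "same" case before the remainder
    is sampled — the leave-one-egg-out construction.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    egg_ids = [str(e) for e in pool_traits["egg_id"]]
    clutch = {str(e): str(c) for e, c in zip(pool_traits["egg_id"], pool_traits["clutch_id"])}
    X = pool_traits.set_index("egg_id")[TRAIT_COLUMNS]
    vec = {e: X.loc[e].to_numpy(dtype=float) for e in egg_ids}

    forced_pairs: list[tuple[str, str]] = []
    if forced_host_eggs:
        fh = sorted(forced_host_eggs)
        forced_pairs = [(a, b) for i, a in enumerate(fh) for b in fh[i + 1 :]]

    # enumerate same pairs per clutch (clutches are small)
    by_clutch: dict[str, list[str]] = {}
    for e in egg_ids:
        by_clutch.setdefault(clutch[e], []).append(e)
    same_pairs = [
        (a, b)
        for eggs in by_clutch.values()
        for i, a in enumerate(eggs)
        for b in eggs[i + 1 :]
    ]
    forced_set = {frozenset(p) for p in forced_pairs}
    same_pool = [p for p in same_pairs if frozenset(p) not in forced_set]
    n_same_draw = n_same - len(forced_pairs)
    if n_same_draw < 0:
        raise ValueError("more forced pairs than requested 'same' cases")
    if n_same_draw > len(same_pool):
        warnings.warn("same-pair pool exhausted; sampling with replacement")
        idx = rng.integers(0, len(same_pool), size=n_same_draw)
    else:
        idx = rng.choice(len(same_pool), size=n_same_draw, replace=False)
    chosen_same = forced_pairs + [same_pool[i] for i in idx]

    # between-female pairs: rejection sampling over random index pairs
    n_eggs = len(egg_ids)
    n_all_pairs = n_eggs * (n_eggs - 1) // 2
    n_diff_avail = n_all_pairs - len(same_pairs)
    chosen_diff: list[tuple[str, str]] = []
    if n_diff > n_diff_avail:
        warnings.warn("different-pair pool exhausted; sampling with replacement")
        while len(chosen_diff) < n_diff:
            i, j = rng.integers(0, n_eggs, size=2)
            if i != j and clutch[egg_ids[i]] != clutch[egg_ids[j]]:
                chosen_diff.append((egg_ids[min(i, j)], egg_ids[max(i, j)]))
    else:
        seen: set[frozenset] = set()
        while len(chosen_diff) < n_diff:
            i, j = rng.integers(0, n_eggs, size=2)
            if i == j or clutch[egg_ids[i]] == clutch[egg_ids[j]]:
                continue
            key = frozenset((egg_ids[i], egg_ids[j]))
            if key in seen:
                continue
            seen.add(key)
            chosen_diff.append((egg_ids[min(i, j)], egg_ids[max(i, j)]))

    samples = [
        PairSample(np.abs(vec[a] - vec[b]), "same", a, b) for a, b in chosen_same
    ]
    samples += [
        PairSample(np.abs(vec[a] - vec[b]), "different", a, b) for a, b in chosen_diff
    ]
    return samples


def supervised_identify(
    pc: ParasitizedClutch,
    pool_traits: pd.DataFrame,
    mode: str = "loco",
    game: int = 1,
    n_repeats: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    n_same: int = 265,
    n_diff: int = 265,
    cache: dict | None = None,
) -> VoteTally:
    """Same/different random-forest voting for one parasitized clutch.

    Per repeat a fresh balanced training set is drawn, a forest fitted, and
    the within-clutch pairs classified; each "different" verdict adds one
    vote to both pair members per direction (two directions per pair, so in
    game 1 every egg accrues 10 comparisons per repeat).  The egg with the
    most votes is called parasitic; exact ties are ambiguous.

    Modes: ``loco`` — training pool excludes the tested clutch entirely;
    ``leo`` (game 2 only) — the four known host eggs join the pool and their
    six "same" pairs are forced into training.

    ``cache`` (an optional dict owned by the caller) memoises fitted
    classifiers across calls: a training set depends only on the pool
    composition, the forced pairs and the repeat index, so clutches sharing
    a pool share fits.  With a cache the per-repeat training seed derives
    from (seed, pool signature, repeat), making results reproducible and
    independent of call order.
    """
    if mode not in ("loco", "leo"):
        raise ValueError("mode must be 'loco' or 'leo'")
    if mode == "leo" and game != 2:
        raise ValueError("leave-one-egg-out is defined for game 2 only")
    if game == 2 and (len(pc.known_hosts) != 4 or len(pc.candidates) != 2):
        raise ValueError("game 2 needs 4 known hosts and 2 candidates")

    tested = set(pc.host_eggs)
    pool = pool_traits[~pool_traits["egg_id"].astype(str).isin(tested)]
    forced = None
    if mode == "leo":
        pool = pool_traits[
            ~pool_traits["egg_id"].astype(str).isin(tested - set(pc.known_hosts))
        ]
        forced = set(pc.known_hosts)

    if game == 1:
        eggs = pc.all_eggs
        pairs = [
            (a, b) for i, a in enumerate(eggs) for b in eggs[i + 1 :]
        ]  # 15 pairs
        tally_eggs = eggs
    else:
        pairs = [(c, h) for c in pc.candidates for h in pc.known_hosts]  # 8 pairs
        tally_eggs = pc.candidates

    Xq = {
        e: _trait_matrix(pool_traits, [e])[0] for e in set(pc.all_eggs)
    }
    votes = {e: 0 for e in tally_eggs}
    pool_sig = zlib.crc32(
        ";".join(
            sorted(str(e) for e in pool["egg_id"])
            + ["|"]
            + sorted(forced or [])
        ).encode()
    )
    for r in range(n_repeats):
        if cache is None:
            ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0xE66, r])
        else:
            ss = np.random.SeedSequence([seed & 0x7FFFFFFF, pool_sig, r])
        key = (pool_sig, r, n_trees, n_same, n_diff)
        rf = cache.get(key) if cache is not None else None
        if rf is None:
            rng = np.random.default_rng(ss)
            training = build_pair_training(
                pool, n_same=n_same, n_diff=n_diff, seed=rng, forced_host_eggs=forced
            )
            Xtr = np.array([s.features for s in training])
            ytr = np.array([s.label for s in training])
            if len(np.unique(ytr)) < 2:
                raise ValueError("degenerate training set: single class")
            rf_seed = int(rng.integers(0, 2**31 - 1))
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=rf_seed, n_jobs=1
            ).fit(Xtr, ytr)
            if cache is not None:
                cache[key] = rf
        Xte = np.array([np.abs(Xq[a] - Xq[b]) for a, b in pairs])
        verdicts = rf.predict(Xte)
        for (a, b), v in zip(pairs, verdicts):
            if v == "different":
                # one credit per direction; symmetric features make the two
                # directions identical, so credit 2 per member of the pair
                for e in (a, b):
                    if e in votes:
                        votes[e] += 2
    top = max(votes.values())
    winners = [e for e, v in votes.items() if v == top]
    ambiguous = len(winners) >= 2
    return VoteTally(
        per_egg_votes=votes,
        n_repeats=n_repeats,
        called_egg=None if ambiguous else winners[0],
        ambiguous=ambiguous,
    )


def summarize_accuracy(
    tallies: list[VoteTally] | list[str | None], truth: list[str]
) -> AccuracySummary:
    """Accuracy with ambiguous calls excluded from the denominator.

    Accepts either VoteTally objects or plain called-egg ids (``None`` =
    ambiguous).  accuracy_pct = 100 * n_correct / (n_total - n_ambiguous).
    """
    if len(tallies) != len(truth):
        raise ValueError("tallies and truth must align")
    calls = [
        (t.called_egg if isinstance(t, VoteTally) else t) for t in tallies
    ]
    n_total = len(calls)
    n_amb = sum(1 for c in calls if c is None)
    n_correct = sum(1 for c, t in zip(calls, truth) if c is not None and c == t)
    denom = n_total - n_amb
    acc = 100.0 * n_correct / denom if denom else 0.0
    return AccuracySummary(
        n_total=n_total, n_ambiguous=n_amb, n_correct=n_correct, accuracy_pct=acc
    )


def accuracy_from_counts(
    n_total: int, n_ambiguous: int, n_correct: int
) -> AccuracySummary:
    """The same ambiguity-excluding formula applied to plain counts."""
    denom = n_total - n_ambiguous
    acc = 100.0 * n_correct / denom if denom else 0.0
    return AccuracySummary(
        n_total=n_total,
        n_ambiguous=n_ambiguous,
        n_correct=n_correct,
        accuracy_pct=acc,
    )
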