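"""Shadow-attribute feature selection with a two-condition stability protocol.

A single shadow run follows the Boruta scheme: at every iteration every
feature still in the model (confirmed or undecided; rejected features are
removed) contributes a "shadow" copy whose rows are independently permuted
-- with the pool padded to at least five shadows -- an ensemble is fitted
on real plus shadow columns, and an undecided feature scores a hit when
its importance exceeds the maximum shadow importance of that iteration.
From iteration ``min_test_iter`` onward each undecided feature's hit count
is tested two-sided against Binomial(n, 1/2) at ``p_threshold`` with a
Bonferroni adjustment over the original feature count (the multiplicity
correction canonical Boruta applies by default): significantly more hits
than half confirms the feature, significantly fewer rejects it. Features
still undecided at ``max_iter`` remain tentative (and count as not
confirmed downstream). The large, fresh shadow pool matters at the small
sample sizes typical of targeted panels: the shadow maximum is itself the
maximum of many chance associations, which is exactly the null a feature's
in-sample importance must beat.

The stability protocol wraps this run in two resampling conditions: R1 runs
on stratified 70% subsamples (training condition) and R2 runs on the full
data (validation condition). A feature is stable when it is confirmed in
more than half of the runs of BOTH conditions. Stable features are ranked
by medianImp -- the median over all confirming runs of the feature's mean
within-run importance -- and validated by signal-to-noise ratios against
the permuted shadows: medianImp divided by the median over runs of the
per-run maximum (Ratio_to_ShadowMax) and mean (Ratio_to_ShadowMean) shadow
importance.

The importance backend is pluggable. The default is a random-ferns
permutation importance: a fern is a depth-D set of random (feature,
threshold) splits whose 2^D leaves hold class frequencies from a bootstrap
sample; a feature's importance is the mean drop in out-of-bag log-score
when its contribution to the fern is permuted. Ferns sample features
uniformly, so equally informative features receive comparable importance
(no winner-take-most), and an ensemble fits in milliseconds at targeted-
panel sizes. An impurity-importance backend over extremely randomized
trees is provided as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier

__all__ = [
    "ImportanceBackend",
    "ferns_importance_backend",
    "tree_importance_backend",
    "ShadowRunResult",
    "StabilityResult",
    "shadow_run",
    "stability_protocol",
    "shadow_ratios",
]

#: An importance backend maps (X, y, seed) to one importance per column.
ImportanceBackend = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def tree_importance_backend(
    n_estimators: int = 200, max_features=None
) -> ImportanceBackend:
    """Impurity importance from an extremely-randomized-trees ensemble."""

    def backend(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        model = ExtraTreesClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
        model.fit(X, y)
        return model.feature_importances_

    return backend


def ferns_importance_backend(n_ferns: int = 1000, depth: int = 3) -> ImportanceBackend:
    """Random-ferns permutation importance (out-of-bag shuffle score drop).

    Each fern draws ``depth`` (feature, uniform threshold) pairs; samples
    land in one of 2^depth leaves whose class frequencies come from a
    bootstrap draw (Laplace-smoothed). A fern's score is the mean
    out-of-bag log-probability of the true class. Each split position is
    then re-evaluated with that feature's out-of-bag values permuted, and
    a feature's importance is the mean score drop over every (fern,
    position) that used it; unused features score 0. Importance can be
    slightly negative for uninformative features.
    """

    def backend(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n, p = X.shape
        F, D = n_ferns, depth
        n_leaves = 1 << D

        feats = rng.integers(0, p, size=(F, D))
        lo, hi = X.min(axis=0), X.max(axis=0)
        thr = lo[feats] + rng.random((F, D)) * (hi[feats] - lo[feats])

        bits = X[:, feats] > thr[None, :, :]  # (n, F, D)
        weights = 1 << np.arange(D)
        leaves = (bits @ weights).T  # (F, n)

        bag = rng.integers(0, n, size=(F, n))
        in_bag = np.zeros((F, n), dtype=bool)
        np.put_along_axis(in_bag, bag, True, axis=1)
        oob = ~in_bag
        oob_count = np.maximum(oob.sum(axis=1), 1)

        counts = np.zeros(F * n_leaves * 2)
        leaf_bag = np.take_along_axis(leaves, bag, axis=1)
        flat = (np.arange(F)[:, None] * n_leaves + leaf_bag) * 2 + y[bag]
        np.add.at(counts, flat.ravel(), 1.0)
        counts = counts.reshape(F, n_leaves, 2)
        logp = np.log(counts + 1.0) - np.log(counts.sum(axis=2, keepdims=True) + 2.0)

        fern_idx = np.arange(F)[:, None]
        per_sample = logp[fern_idx, leaves, y[None, :]]  # (F, n)
        base_score = (per_sample * oob).sum(axis=1) / oob_count

        imp_sum = np.zeros(p)
        imp_count = np.zeros(p)
        perm_template = np.tile(np.arange(n), (F, 1))
        for d in range(D):
            perm = rng.permuted(perm_template, axis=1)  # (F, n)
            col = X[:, feats[:, d]].T  # (F, n): feature d's values per fern
            permuted = np.take_along_axis(col, perm, axis=1)
            new_bit = permuted > thr[:, d][:, None]
            shifted = leaves - bits[:, :, d].T * weights[d] + new_bit * weights[d]
            per_sample_d = logp[fern_idx, shifted, y[None, :]]
            score_d = (per_sample_d * oob).sum(axis=1) / oob_count
            np.add.at(imp_sum, feats[:, d], base_score - score_d)
            np.add.at(imp_count, feats[:, d], 1.0)
        return imp_sum / np.maximum(imp_count, 1.0)

    return backend


@dataclass
class ShadowRunResult:
    """Outcome of one shadow run."""

    decisions: dict[str, str]  # feature -> confirmed | rejected | tentative
    importance_history: dict[str, list[float]]  # while the feature was in the model
    shadow_max: list[float]  # per-iteration max shadow importance
    shadow_mean: list[float]  # per-iteration mean shadow importance
    seed: int
    n_iter: int

    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    def mean_importance(self, feature: str) -> float:
        history = self.importance_history[feature]
        return float(np.mean(history)) if history else float("nan")

    def run_shadow_max(self) -> float:
        """Per-run shadow-max summary: mean over iterations."""
        return float(np.mean(self.shadow_max)) if self.shadow_max else float("nan")

    def run_shadow_mean(self) -> float:
        return float(np.mean(self.shadow_mean)) if self.shadow_mean else float("nan")



@lru_cache(maxsize=4096)
def _decision_bounds(n: int, alpha: float) -> tuple[int, int]:
    """Hit-count bounds equivalent to the two-sided Binomial(n, 1/2) test.

    Returns (k_reject, k_confirm): a feature with <= k_reject hits out of n
    is rejected, one with >= k_confirm hits is confirmed, both at two-sided
    p < alpha. By symmetry of the fair-coin null the two-sided p-value for
    k hits is 2 * min(P(X <= k), P(X >= k)) capped at 1.
    """
    k = np.arange(n + 1)
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    p_two = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    significant = p_two < alpha
    below = np.flatnonzero(significant & (k < n / 2))
    above = np.flatnonzero(significant & (k > n / 2))
    k_reject = int(below.max()) if below.size else -1
    k_confirm = int(above.min()) if above.size else n + 1
    return k_reject, k_confirm


def _validate_xy(X: pd.DataFrame, y: Sequence) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature table contains missing or non-finite values")
    y_arr = np.asarray(y)
    classes = np.unique(y_arr)
    if classes.size != 2:
        raise ValueError(f"labels must be binary, got classes {classes.tolist()}")
    y_codes = (y_arr == classes[1]).astype(int)
    return X, y_codes


def shadow_run(
    X: pd.DataFrame,
    y: Sequence,
    seed: int = 0,
    max_iter: int = 100,
    p_threshold: float = 0.01,
    backend: ImportanceBackend | None = None,
    min_test_iter: int = 5,
    multiplicity_adjust: bool = True,
    min_shadows: int = 5,
) -> ShadowRunResult:
    """One shadow-attribute selection run over a feature table.

    Confirmed and undecided features stay in the model (and keep
    contributing shadows); rejected features are removed from subsequent
    iterations. With ``multiplicity_adjust`` (default) the binomial
    decision threshold is Bonferroni-divided by the original feature count.
    """
    X, y_codes = _validate_xy(X, y)
    if backend is None:
        backend = ferns_importance_backend()
    features = list(X.columns)

    constant = [f for f in features if np.ptp(X[f].to_numpy(dtype=float)) == 0.0]
    if len(constant) == len(features):
        warnings.warn("all features are constant; rejecting everything", stacklevel=2)
        return ShadowRunResult(
            decisions={f: "rejected" for f in features},
            importance_history={f: [] for f in features},
            shadow_max=[],
            shadow_mean=[],
            seed=seed,
            n_iter=0,
        )

    rng = np.random.default_rng(seed)
    undecided = set(features)
    decisions = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    history: dict[str, list[float]] = {f: [] for f in features}
    shadow_max_trace: list[float] = []
    shadow_mean_trace: list[float] = []

    decision_alpha = p_threshold / len(features) if multiplicity_adjust else p_threshold
    values = X.to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(features)}
    for iteration in range(1, max_iter + 1):
        if not undecided:
            break
        active = [f for f in features if decisions[f] in ("tentative", "confirmed")]
        undecided_list = [f for f in active if f in undecided]
        real = values[:, [col_of[f] for f in active]]
        # Shadow pool: permuted copies of the active features, padded back up
        # to ``min_shadows`` columns (drawn cyclically from the original
        # feature list) once most attributes have been decided.
        shadow_idx = [col_of[f] for f in active]
        while len(shadow_idx) < min_shadows:
            shadow_idx.append(len(shadow_idx) % len(features))
        shadows = rng.permuted(values[:, shadow_idx], axis=0)
        fit_seed = int(rng.integers(2**31))
        importances = backend(np.hstack([real, shadows]), y_codes, fit_seed)
        real_imp = importances[: len(active)]
        shadow_imp = importances[len(active):]
        s_max = float(shadow_imp.max())
        s_mean = float(shadow_imp.mean())
        shadow_max_trace.append(s_max)
        shadow_mean_trace.append(s_mean)

        for f, imp in zip(active, real_imp):
            history[f].append(float(imp))
            if f in undecided and imp > s_max:
                hits[f] += 1

        if iteration >= min_test_iter:
            k_reject, k_confirm = _decision_bounds(iteration, decision_alpha)
            for f in undecided_list:
                if hits[f] >= k_confirm:
                    decisions[f] = "confirmed"
                    undecided.discard(f)
                elif hits[f] <= k_reject:
                    decisions[f] = "rejected"
                    undecided.discard(f)

    return ShadowRunResult(
        decisions=decisions,
        importance_history=history,
        shadow_max=shadow_max_trace,
        shadow_mean=shadow_mean_trace,
        seed=seed,
        n_iter=len(shadow_max_trace),
    )


@dataclass
class StabilityResult:
    """Aggregated two-condition stability outcome.

    ``table`` has one row per feature: confirmed_count_subsample,
    confirmed_count_full, stable, medianImp, ratio_to_shadow_max,
    ratio_to_shadow_mean, rank (1 = highest medianImp among stable
    features; NaN elsewhere).
    """

    table: pd.DataFrame
    r1: int
    r2: int
    subsample_fraction: float
    base_seed: int
    run_shadow_max: list[float] = field(default_factory=list)
    run_shadow_mean: list[float] = field(default_factory=list)

    def stable_features(self) -> list[str]:
        stable = self.table.index[self.table["stable"]]
        return list(stable)


def _stratified_subsample(
    groups: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a per-group proportional subsample (round half up)."""
    chosen: list[np.ndarray] = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        k = int(np.floor(fraction * idx.size + 0.5))
        if k < 2:
            raise ValueError(
                f"subsampling fraction {fraction} leaves group {g!r} with {k} samples"
            )
        chosen.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(chosen))


def stability_protocol(
    X: pd.DataFrame,
    y: Sequence,
    R1: int = 100,
    R2: int = 100,
    subsample_fraction: float = 0.70,
    base_seed: int = 0,
    backend: ImportanceBackend | None = None,
    max_iter: int = 100,
    p_threshold: float = 0.01,
    min_shadows: int = 5,
) -> StabilityResult:
    """Two-condition resampling stability selection.

    R1 shadow runs on stratified ``subsample_fraction`` subsamples plus R2
    runs on the full data, all with seeds derived from ``base_seed``. A
    feature is stable when confirmed in more than R1/2 subsample runs AND
    more than R2/2 full-data runs.
    """
    X, _ = _validate_xy(X, y)
    y_arr = np.asarray(y)
    features = list(X.columns)
    if backend is None:
        backend = ferns_importance_backend()

    master = np.random.default_rng(base_seed)
    run_seeds = master.integers(2**31, size=R1 + R2)

    count_sub = {f: 0 for f in features}
    count_full = {f: 0 for f in features}
    confirming_imps: dict[str, list[float]] = {f: [] for f in features}
    run_s_max: list[float] = []
    run_s_mean: list[float] = []

    for r in range(R1 + R2):
        if r < R1:
            idx = _stratified_subsample(y_arr, subsample_fraction, master)
            X_run, y_run = X.iloc[idx], y_arr[idx]
        else:
            X_run, y_run = X, y_arr
        result = shadow_run(
            X_run,
            y_run,
            seed=int(run_seeds[r]),
            max_iter=max_iter,
            p_threshold=p_threshold,
            backend=backend,
            min_shadows=min_shadows,
        )
        run_s_max.append(result.run_shadow_max())
        run_s_mean.append(result.run_shadow_mean())
        for f in result.confirmed():
            if r < R1:
                count_sub[f] += 1
            else:
                count_full[f] += 1
            confirming_imps[f].append(result.mean_importance(f))

    rows = []
    for f in features:
        stable = count_sub[f] > R1 / 2 and count_full[f] > R2 / 2
        median_imp = (
            float(np.median(confirming_imps[f])) if confirming_imps[f] else float("nan")
        )
        rows.append(
            {
                "feature": f,
                "confirmed_count_subsample": count_sub[f],
                "confirmed_count_full": count_full[f],
                "stable": stable,
                "medianImp": median_imp,
            }
        )
    table = pd.DataFrame.from_records(rows).set_index("feature")

    result = StabilityResult(
        table=table,
        r1=R1,
        r2=R2,
        subsample_fraction=subsample_fraction,
        base_seed=base_seed,
        run_shadow_max=run_s_max,
        run_shadow_mean=run_s_mean,
    )
    table["ratio_to_shadow_max"] = np.nan
    table["ratio_to_shadow_mean"] = np.nan
    table["rank"] = np.nan
    if table["stable"].any():
        ratios = shadow_ratios(result)
        for f, (rmax, rmean) in ratios.items():
            table.loc[f, "ratio_to_shadow_max"] = rmax
            table.loc[f, "ratio_to_shadow_mean"] = rmean
        stable_sorted = (
            table.loc[table["stable"], "medianImp"]
            .sort_values(ascending=False)
            .index
        )
        for rank, f in enumerate(stable_sorted, start=1):
            table.loc[f, "rank"] = rank
    return result


def shadow_ratios(result: StabilityResult) -> dict[str, tuple[float, float]]:
    """Signal-to-noise ratios for every stable feature.

    ratio_to_shadow_max = medianImp / median over runs of the per-run
    maximum shadow importance; ratio_to_shadow_mean likewise against the
    per-run mean shadow importance.
    """
    stable = result.stable_features()
    if not stable:
        raise ValueError("no stable features; ratios are undefined")
    med_shadow_max = float(np.nanmedian(result.run_shadow_max))
    med_shadow_mean = float(np.nanmedian(result.run_shadow_mean))
    if med_shadow_max == 0 or med_shadow_mean == 0:
        raise ZeroDivisionError("shadow importance statistics are zero")
    out = {}
    for f in stable:
        median_imp = float(result.table.loc[f, "medianImp"])
        out[f] = (median_imp / med_shadow_max, median_imp / med_shadow_mean)
    return out
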