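"""Diet quality index (DQI) builders.

Three constructions of a single diet-healthiness score from liking data:

* theoretical — conceptual food groups with fixed guideline weights
  (no data-driven fitting; higher is healthier by construction);
* empirical — varimax factors of the individual food/beverage items,
  ridge-weighted against the risk score;
* hybrid — conceptual groups (merged where strongly correlated), standardized
  and ridge-weighted against the risk score.  The hybrid index can be recast
  onto a 0-100 adequacy/moderation scale in the style of the Healthy Eating
  Index.

Empirical and hybrid indexes are reverse-coded so that a higher index always
means lower cardiometabolic risk on the training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import defaults
from .errors import LikingDQIError, MissingGroupError, OrientationError
from .stats import RidgeSpec, fit_ridge, select_lambda

__all__ = [
    "DQIConfig",
    "DQIResult",
    "theoretical_dqi",
    "merge_map_from_correlation",
    "merge_correlated_groups",
    "empirical_dqi",
    "hybrid_dqi",
    "StandardizedScale",
    "standardize_hybrid",
]

#: Covariates controlled for in the ridge models, in canonical order.
COVARIATES = ("male", "patient", "pleasant", "unpleasant")


@dataclass(frozen=True)
class DQIConfig:
    """Tuning knobs of the data-driven index builders."""

    lambda_grid: tuple[float, ...] | None = None   # None -> default grid
    cv_folds: int = 5
    seed: int = 0
    merge_threshold: float = 0.5
    merge_strategy: str = "average"    # "average" linkage or "components"
    n_factors: int = 10
    penalize_covariates: bool = True


@dataclass(frozen=True)
class DQIResult:
    """A built diet quality index.

    ``weights`` are the per-predictor coefficients *after* reverse coding
    (positive = liking associated with lower risk); ``orientation`` is the
    sign that was applied.  ``scorer`` reproduces the index on new subjects
    from the frozen training state.
    """

    method: str                       # theoretical | empirical | hybrid
    scores: pd.Series
    weights: Mapping[str, float]
    orientation: int
    lam: float | None = None
    merged_groups: Mapping[str, tuple[str, ...]] | None = None
    scorer: Callable[[pd.DataFrame], pd.Series] = field(
        repr=False, default=None)

    def apply(self, data: pd.DataFrame) -> pd.Series:
        """Score held-out subjects (group table for theoretical/hybrid,
        item-level survey for empirical)."""
        if self.scorer is None:
            raise LikingDQIError(f"{self.method} index carries no scorer")
        return self.scorer(data)


# --------------------------------------------------------------------------
# Theoretical index
# --------------------------------------------------------------------------

def theoretical_dqi(
    groups: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    aggregate: str = "mean",
) -> DQIResult:
    """Guideline-weighted index: mean over groups of weight x liking.

    ``groups`` must contain every weighted group (including the auxiliary
    lean-protein group).  With the default ten integer weights and the mean
    aggregation the index ranges from -240 to +240.
    """
    weights = dict(weights or defaults.THEORETICAL_WEIGHTS)
    missing = [g for g in weights if g not in groups.columns]
    if missing:
        raise MissingGroupError(f"weighted group(s) missing: {missing}")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    denom = len(weights) if aggregate == "mean" else 1
    w = pd.Series(weights, dtype=float)

    def scorer(data: pd.DataFrame) -> pd.Series:
        absent = [g for g in w.index if g not in data.columns]
        if absent:
            raise MissingGroupError(f"weighted group(s) missing: {absent}")
        return (data[w.index] @ w) / denom

    return DQIResult(
        method="theoretical",
        scores=scorer(groups).rename("dqi_theoretical"),
        weights=weights,
        orientation=1,   # higher is healthier by construction
        scorer=scorer,
    )


# --------------------------------------------------------------------------
# Group merging
# --------------------------------------------------------------------------

def merge_map_from_correlation(
    corr: pd.DataFrame,
    threshold: float = 0.5,
    strategy: str = "average",
) -> dict[str, tuple[str, ...]]:
    """Cluster groups whose (signed) correlation exceeds ``threshold``.

    ``average`` (default) merges agglomeratively: at each step the two
    clusters with the highest average inter-cluster correlation are joined,
    stopping when no pair exceeds the threshold.  This is order-independent
    and keeps clusters internally coherent.  ``components`` instead takes
    connected components of the pairwise r > threshold graph, which is more
    aggressive: a single borderline pair can chain otherwise weakly related
    clusters together.

    Merged groups are named by joining members with '+' in input order.
    """
    names = list(corr.index)
    R = corr.to_numpy(dtype=float)

    clusters: list[list[int]] = [[i] for i in range(len(names))]
    if strategy == "average":
        while len(clusters) > 1:
            best, best_val = None, threshold
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    val = float(np.mean(
                        [R[i, j] for i in clusters[a] for j in clusters[b]]))
                    if val > best_val:
                        best, best_val = (a, b), val
            if best is None:
                break
            a, b = best
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
    elif strategy == "components":
        parent = list(range(len(names)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if R[i, j] > threshold:
                    parent[find(i)] = find(j)
        byroot: dict[int, list[int]] = {}
        for i in range(len(names)):
            byroot.setdefault(find(i), []).append(i)
        clusters = list(byroot.values())
    else:
        raise ValueError(f"unknown merge strategy {strategy!r}")

    out = {}
    for members in sorted(clusters, key=min):
        members = sorted(members)
        key = "+".join(names[i] for i in members)
        out[key] = tuple(names[i] for i in members)
    return out


def merge_correlated_groups(
    group_matrix: pd.DataFrame,
    threshold: float = 0.5,
    strategy: str = "average",
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Merge strongly correlated group columns by per-subject averaging.

    Correlations are computed on the given cohort; each merged column is the
    plain average of its members' likings.  Singleton groups pass through
    unchanged.
    """
    if len(group_matrix) < 3:
        raise ValueError("need >= 3 subjects to estimate correlations")
    merge_map = merge_map_from_correlation(
        group_matrix.corr(), threshold=threshold, strategy=strategy)
    merged = pd.DataFrame(
        {name: group_matrix[list(members)].mean(axis=1)
         for name, members in merge_map.items()},
        index=group_matrix.index)
    return merged, merge_map


# --------------------------------------------------------------------------
# Ridge-weighted indexes
# --------------------------------------------------------------------------

def _ridge_index(X_food: pd.DataFrame, covariates: pd.DataFrame,
                 crfs: pd.Series, config: DQIConfig):
    """Shared machinery: ridge of the risk score on food predictors plus
    covariates, penalty from cross-validation, reverse coding."""
    cov = covariates[list(COVARIATES)]
    X = pd.concat([X_food, cov], axis=1)
    n_food = X_food.shape[1]
    mask = tuple([True] * n_food
                 + [config.penalize_covariates] * cov.shape[1])
    spec = RidgeSpec(penalized=mask, standardize=True)
    lam = select_lambda(
        X.to_numpy(), crfs.to_numpy(), grid=config.lambda_grid,
        k_folds=config.cv_folds, seed=config.seed, spec=spec)
    fit = fit_ridge(X, crfs.to_numpy(),
                    RidgeSpec(lam=lam, penalized=mask, standardize=True))

    food_coef = fit.coef[:n_food]
    food_mean = fit.x_mean[:n_food]
    food_scale = fit.x_scale[:n_food]
    raw = ((X_food.to_numpy() - food_mean) / food_scale) @ food_coef
    corr = float(np.corrcoef(raw, crfs.to_numpy())[0, 1])
    if not np.isfinite(corr) or abs(corr) < 1e-12:
        raise OrientationError(
            "index uncorrelated with the risk score; reverse coding undefined")
    orientation = -1 if corr > 0 else 1
    return fit, lam, food_coef, food_mean, food_scale, orientation


def empirical_dqi(
    survey: pd.DataFrame,
    crfs: pd.Series,
    covariates: pd.DataFrame,
    config: DQIConfig = DQIConfig(),
    item_names: tuple[str, ...] | None = None,
) -> DQIResult:
    """Factor-based index: varimax factors of the individual food/beverage
    items, ridge-weighted against the risk score.

    The top ``config.n_factors`` factors by explained variance become the
    predictors; the index is the coefficient-weighted sum of factor scores,
    reverse-coded.  The factor model and coefficients are frozen for
    held-out scoring.
    """
    from .stats import factor_varimax  # local import keeps module load light

    if item_names is None:
        item_names = tuple(
            i for items in defaults.FOOD_GROUP_ITEMS.values() for i in items)
    item_names = tuple(i for i in item_names if i in survey.columns)
    if len(item_names) < config.n_factors + 1:
        raise LikingDQIError("too few food items for the factor solution")
    if len(survey) < 20:
        raise ValueError("need >= 20 subjects")
    fm = factor_varimax(survey[list(item_names)], n_factors=config.n_factors)
    fit, lam, coef, mean, scale, orientation = _ridge_index(
        fm.factor_scores, covariates, crfs, config)

    def scorer(data: pd.DataFrame) -> pd.Series:
        scores = fm.score(data[list(item_names)]).to_numpy()
        raw = ((scores - mean) / scale) @ coef
        return pd.Series(orientation * raw, index=data.index,
                         name="dqi_empirical")

    weights = {f: orientation * float(c)
               for f, c in zip(fm.factor_scores.columns, coef)}
    return DQIResult(
        method="empirical", scores=scorer(survey), weights=weights,
        orientation=orientation, lam=lam, scorer=scorer)


def hybrid_dqi(
    groups: pd.DataFrame,
    crfs: pd.Series,
    covariates: pd.DataFrame,
    config: DQIConfig = DQIConfig(),
) -> DQIResult:
    """Conceptual-group index with data-driven weights.

    Strongly correlated groups are merged, merged groups are standardized
    (training mean/SD), ridge coefficients are fit against the risk score
    with covariates controlled, and the index is the coefficient-weighted
    sum of standardized groups, reverse-coded.
    """
    if len(groups) < 20:
        raise ValueError("need >= 20 subjects")
    merged, merge_map = merge_correlated_groups(
        groups, threshold=config.merge_threshold,
        strategy=config.merge_strategy)
    fit, lam, coef, mean, scale, orientation = _ridge_index(
        merged, covariates, crfs, config)

    def scorer(data: pd.DataFrame) -> pd.Series:
        m = pd.DataFrame(
            {name: data[list(members)].mean(axis=1)
             for name, members in merge_map.items()},
            index=data.index)
        raw = ((m.to_numpy() - mean) / scale) @ coef
        return pd.Series(orientation * raw, index=data.index, name="dqi_hybrid")

    weights = {g: orientation * float(c)
               for g, c in zip(merged.columns, coef)}
    return DQIResult(
        method="hybrid", scores=scorer(groups), weights=weights,
        orientation=orientation, lam=lam, merged_groups=merge_map,
        scorer=scorer)


# --------------------------------------------------------------------------
# 0-100 standardized scale
# --------------------------------------------------------------------------

def _largest_remainder_points(weights: pd.Series, total: int = 100) -> pd.Series:
    """Integer points proportional to weights, forced to sum to ``total``
    by largest-remainder correction (ties to the larger weight)."""
    exact = weights * total
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    remainders = exact - base
    order = sorted(weights.index,
                   key=lambda g: (-remainders[g], -weights[g], g))
    for g in order[:short]:
        base[g] += 1
    return base


@dataclass(frozen=True)
class StandardizedScale:
    """HEI-style 0-100 recasting of the hybrid index.

    Adequacy components award points for liking (+100 -> full points);
    moderation components award points for disliking (-100 -> full points).
    Normalized weights sum to 1 and integer maximum points sum to 100.
    """

    adequacy: tuple[str, ...]
    moderation: tuple[str, ...]
    normalized_weights: pd.Series
    max_points: pd.Series
    merged_groups: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if not math.isclose(float(self.normalized_weights.sum()), 1.0,
                            abs_tol=1e-9):
            raise ValueError("normalized weights must sum to 1")
        if int(self.max_points.sum()) != 100:
            raise ValueError("maximum points must sum to 100")

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.normalized_weights.index)

    def _component_values(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for comp in self.components:
            if comp in data.columns:
                cols[comp] = data[comp]
                continue
            members = (self.merged_groups or {}).get(comp, tuple(comp.split("+")))
            absent = [m for m in members if m not in data.columns]
            if absent:
                raise MissingGroupError(
                    f"component {comp!r}: missing group(s) {absent}")
            cols[comp] = data[list(members)].mean(axis=1)
        return pd.DataFrame(cols, index=data.index)

    def component_points(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-component contribution (in points, out of 100) per subject."""
        values = self._component_values(data)
        recoded = pd.DataFrame(index=values.index)
        for comp in self.components:
            v = values[comp]
            recoded[comp] = (v + 100.0) / 2.0 if comp in self.adequacy \
                else (100.0 - v) / 2.0
        return recoded * self.normalized_weights

    def score(self, data: pd.DataFrame) -> pd.Series:
        """Total 0-100 score; monotone increasing in every adequacy group's
        liking and decreasing in every moderation group's liking."""
        return self.component_points(data).sum(axis=1).rename("dqi_0_100")

    @classmethod
    def from_points(
        cls,
        standard: Mapping[str, tuple[int, str]] | None = None,
        merged_groups: Mapping[str, tuple[str, ...]] | None = None,
    ) -> "StandardizedScale":
        """Build a scale directly from a published points table
        (component -> (max points, 'adequacy' | 'moderation'))."""
        standard = dict(standard or defaults.SCORING_STANDARD)
        pts = pd.Series({c: p for c, (p, _) in standard.items()}, dtype=int)
        adequacy = tuple(c for c, (_, role) in standard.items()
                         if role == "adequacy")
        moderation = tuple(c for c, (_, role) in standard.items()
                           if role == "moderation")
        return cls(adequacy=adequacy, moderation=moderation,
                   normalized_weights=pts / pts.sum(), max_points=pts,
                   merged_groups=merged_groups)


def standardize_hybrid(result: DQIResult) -> StandardizedScale:
    """Derive the 0-100 scale from a fitted hybrid index.

    Components whose reverse-coded weight is positive (liking associated
    with lower risk) become adequacy components; the rest are moderation.
    Normalized weights are |coefficient| / sum |coefficients| over the food
    components only (covariates are controls and never score points).
    """
    if result.method != "hybrid":
        raise ValueError("standardization applies to the hybrid index")
    w = pd.Series(result.weights, dtype=float)
    if np.allclose(w.to_numpy(), 0.0):
        raise LikingDQIError("all coefficients are zero; scale undefined")
    adequacy = tuple(g for g in w.index if w[g] > 0)
    moderation = tuple(g for g in w.index if w[g] <= 0)
    normalized = w.abs() / w.abs().sum()
    return StandardizedScale(
        adequacy=adequacy, moderation=moderation,
        normalized_weights=normalized,
        max_points=_largest_remainder_points(normalized),
        merged_groups=result.merged_groups)
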