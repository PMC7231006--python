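"""Continuous cardiometabolic risk factor score (CRFS).

The score compresses correlated fasting biomarkers into one continuous
severity axis: candidate measures are screened by a two-factor exploratory
factor analysis (keeping those loading on the dominant factor), transformed
toward normality, standardized, and scored on the first principal component.
The oriented score correlates positively with insulin, so higher CRFS means
worse cardiometabolic risk.

All fitted state (screening outcome, per-measure transforms, component
loadings, orientation, standardization) is frozen in :class:`CRFSModel` so
held-out subjects are scored through the training model without leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import LikingDQIError, OrientationError
from .stats import factor_varimax, pca_first

__all__ = [
    "CANDIDATE_MEASURES",
    "RankNormalTransform",
    "normalize_transform",
    "ScreenResult",
    "screen_measures",
    "CRFSModel",
    "build_crfs",
]

logger = logging.getLogger(__name__)

#: Candidate measures screened for the risk score, in canonical order:
#: plasma (insulin, glucose, HDL, triglycerides), adiposity (BMI,
#: waist-to-hip ratio) and blood pressure (systolic, diastolic).
CANDIDATE_MEASURES = ("insulin", "glucose", "hdl", "triglycerides",
                      "bmi", "whr", "sbp", "dbp")


@dataclass(frozen=True)
class RankNormalTransform:
    """A frozen toward-normality transform for one measure.

    ``method`` is one of ``rank`` (rank-based inverse normal with Blom
    offsets, the default), ``log`` or ``none``.  The training sample is
    stored so held-out values can be pushed through the *training* empirical
    CDF; output is standardized by the training mean/SD of the transformed
    values.
    """

    method: str
    train_sorted: np.ndarray = field(repr=False)
    mean: float
    sd: float

    def _raw(self, x: np.ndarray) -> np.ndarray:
        if self.method == "none":
            return x
        if self.method == "log":
            return np.log(x)
        n = self.train_sorted.size
        # held-out values take their (mid-)rank within the training sample;
        # training values reproduce their fitting-time average rank exactly
        left = np.searchsorted(self.train_sorted, x, side="left")
        right = np.searchsorted(self.train_sorted, x, side="right")
        rank = left + 0.5 * (right - left) + 0.5
        p = (rank - 3.0 / 8.0) / (n + 0.25)
        return sps.norm.ppf(np.clip(p, 1e-7, 1 - 1e-7))

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return (self._raw(x) - self.mean) / self.sd


def normalize_transform(
    values, method: str = "rank"
) -> tuple[np.ndarray, RankNormalTransform]:
    """Transform a training sample toward normality and standardize it.

    The default is the rank-based inverse-normal transform with Blom offsets
    (r - 3/8)/(n + 1/4); it preserves ranks exactly and yields an
    approximately standard-normal margin regardless of the input shape.
    Returns the transformed training values and the frozen transform.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 values to fit a transform")
    if method not in ("rank", "log", "none"):
        raise ValueError(f"unknown transform method {method!r}")
    if method == "rank":
        n_ties = x.size - np.unique(x).size
        if n_ties > 0.5 * x.size:
            logger.warning(
                "rank-based transform with %d/%d tied values", n_ties, x.size)
        ranks = sps.rankdata(x, method="average")
        raw = sps.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))
    elif method == "log":
        raw = np.log(x)
    else:
        raw = x.copy()
    mean, sd = float(raw.mean()), float(raw.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate (constant) sample")
    tr = RankNormalTransform(
        method=method, train_sorted=np.sort(x), mean=mean, sd=sd)
    return (raw - mean) / sd, tr


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the measure-screening factor analysis.

    ``first_factor`` holds the unrotated first principal-factor loadings the
    retention rule applies the threshold to; ``loadings`` holds the rotated
    two-factor solution kept as an interpretive diagnostic.
    """

    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    first_factor: pd.Series
    loadings: pd.DataFrame       # measures x 2 factors, varimax-rotated
    threshold: float


def screen_measures(
    biomarkers: pd.DataFrame,
    threshold: float = 0.4,
    measures: tuple[str, ...] = CANDIDATE_MEASURES,
    transform: str = "rank",
) -> ScreenResult:
    """Retain measures loading at least ``threshold`` (in absolute value) on
    the dominant factor of a two-factor exploratory solution.

    The number of factors is decided by the Kaiser criterion on the
    correlation-matrix eigenvalues, capped at two.  With two factors the
    solution is varimax-rotated and the threshold applies to the rotated
    first (largest-variance) factor — in the intended regime that factor
    carries the plasma/adiposity block while blood pressure loads on the
    second.  When the second eigenvalue is below one the structure is
    effectively unidimensional; rotation of a forced two-factor solution
    would arbitrarily split the common factor, so the threshold applies to
    the single-factor loadings instead.  Retention uses |loading| so
    protective measures (HDL, which loads negatively) are kept.  Requires a
    cohort of at least 30 subjects and at least two retained measures.
    """
    if len(biomarkers) < 30:
        raise ValueError("screening needs a cohort of n >= 30")
    if len(measures) < 3:
        raise ValueError("need >= 3 candidate measures")
    transformed = pd.DataFrame(
        {m: normalize_transform(biomarkers[m].to_numpy(), transform)[0]
         for m in measures},
        index=biomarkers.index)
    fm = factor_varimax(transformed, n_factors=2)
    R = np.corrcoef(transformed.to_numpy(), rowvar=False)
    eigval = np.sort(np.linalg.eigvalsh(R))[::-1]
    if eigval[1] > 1.0:          # Kaiser criterion: genuine second factor
        first = fm.loadings.iloc[:, 0].rename("first_factor")
    else:                        # effectively one factor: use its loadings
        first = factor_varimax(
            transformed, n_factors=1).loadings.iloc[:, 0].rename("first_factor")
    retained = tuple(m for m in measures if abs(first[m]) >= threshold)
    if len(retained) < 2:
        raise LikingDQIError(
            f"fewer than 2 measures passed |loading| >= {threshold}; "
            "risk score undefined")
    excluded = tuple(m for m in measures if m not in retained)
    return ScreenResult(retained=retained, excluded=excluded,
                        first_factor=first, loadings=fm.loadings,
                        threshold=threshold)


@dataclass(frozen=True)
class CRFSModel:
    """Frozen risk-score model.

    ``orientation`` (+1/-1) is the sign applied to the raw first-component
    score so that the final score correlates positively with insulin.
    ``explained_fraction`` is the share of total variance in the retained
    (transformed) measures captured by the first component.
    """

    candidate_measures: tuple[str, ...]
    retained: tuple[str, ...]
    transforms: Mapping[str, RankNormalTransform]
    pc_loadings: pd.Series
    explained_fraction: float
    orientation: int
    score_mean: float
    score_sd: float
    screen: ScreenResult = field(repr=False, default=None)

    def apply(self, biomarkers: pd.DataFrame) -> pd.Series:
        """Score subjects through the frozen transforms and loadings."""
        Z = np.column_stack([
            self.transforms[m].apply(biomarkers[m].to_numpy())
            for m in self.retained])
        raw = Z @ self.pc_loadings.to_numpy()
        score = self.orientation * (raw - self.score_mean) / self.score_sd
        return pd.Series(score, index=biomarkers.index, name="crfs")


def build_crfs(
    biomarkers: pd.DataFrame,
    threshold: float = 0.4,
    transform: str = "rank",
    measures: tuple[str, ...] = CANDIDATE_MEASURES,
    screen: bool = True,
) -> tuple[CRFSModel, pd.Series]:
    """Screen, transform, and score the cohort on the first principal
    component of the retained measures.

    ``screen=False`` skips the factor-analytic screening and scores all
    given measures directly (useful when the retained set is fixed a
    priori).  Returns the frozen model and the in-sample standardized
    scores (cohort mean 0, SD 1, higher = higher risk).
    """
    if screen:
        screen_res = screen_measures(
            biomarkers, threshold=threshold, measures=measures,
            transform=transform)
        retained = screen_res.retained
    else:
        screen_res = None
        retained = tuple(measures)
    transformed = {}
    transforms = {}
    for m in retained:
        values, tr = normalize_transform(biomarkers[m].to_numpy(), transform)
        transformed[m] = values
        transforms[m] = tr
    Z = pd.DataFrame(transformed, index=biomarkers.index)
    pc = pca_first(Z)
    raw = pc.scores["PC1"].to_numpy()
    corr_insulin = float(np.corrcoef(raw, biomarkers["insulin"])[0, 1])
    if abs(corr_insulin) < 1e-10:
        raise OrientationError(
            "first component uncorrelated with insulin; orientation undefined")
    orientation = 1 if corr_insulin > 0 else -1
    mean, sd = float(raw.mean()), float(raw.std(ddof=1))
    model = CRFSModel(
        candidate_measures=tuple(measures),
        retained=retained,
        transforms=transforms,
        pc_loadings=pc.component_loadings["PC1"],
        explained_fraction=float(pc.explained_fraction[0]),
        orientation=orientation,
        score_mean=mean,
        score_sd=sd,
        screen=screen_res,
    )
    scores = pd.Series(
        orientation * (raw - mean) / sd, index=biomarkers.index, name="crfs")
    return model, scores
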