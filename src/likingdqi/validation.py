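"""Out-of-sample comparison of diet quality indexes.

The criterion-validity question is: how much held-out variance in the
cardiometabolic risk score does each index explain beyond the demographic
covariates?  Under k-fold cross-validation, the risk-score model and the
index weights are fitted on the training folds only, frozen, and applied to
the held-out fold; on that fold two ordinary least-squares models of the
risk score (covariates with and without the index) are compared, and the
difference in R-squared is the index's incremental predictive power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crfs import build_crfs
from .dqi import COVARIATES, DQIConfig, empirical_dqi, hybrid_dqi, theoretical_dqi
from .stats import kfold_indices, ks_normality
from .survey import GroupSchema, score_groups_frame

__all__ = [
    "CVSpec",
    "Dataset",
    "IncrementalR2Result",
    "incremental_r2_cv",
    "compare_dqis",
    "describe_dqi",
]

DQI_METHODS = ("theoretical", "empirical", "hybrid")


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: ``k`` folds (sizes differ by at most one),
    re-randomized ``n_repeats`` times from the seed."""

    k: int = 5
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class Dataset:
    """A complete analysis dataset: item-level survey, biomarkers, and the
    sex/patient covariates, all indexed by subject."""

    survey: pd.DataFrame
    biomarkers: pd.DataFrame
    covariates: pd.DataFrame      # columns: male, patient (0/1)
    schema: GroupSchema = field(default_factory=GroupSchema.default)

    def __post_init__(self) -> None:
        for df in (self.biomarkers, self.covariates):
            if not df.index.equals(self.survey.index):
                raise ValueError("survey/biomarkers/covariates must share an index")

    @classmethod
    def from_cohort(cls, cohort) -> "Dataset":
        return cls(survey=cohort.survey,
                   biomarkers=cohort.biomarkers,
                   covariates=cohort.covariates)

    def group_table(self) -> pd.DataFrame:
        """All scored groups (food, auxiliary, experience anchors)."""
        return score_groups_frame(self.survey, self.schema)

    def food_group_table(self) -> pd.DataFrame:
        return self.group_table()[list(self.schema.food_groups)]

    def covariate_table(self) -> pd.DataFrame:
        """Regression covariates: sex, patient status and the two non-food
        hedonic anchors."""
        groups = self.group_table()
        pleasant_cols = list(self.schema.groups_with_role("pleasant_experience"))
        unpleasant_cols = list(self.schema.groups_with_role("unpleasant_experience"))
        return pd.DataFrame({
            "male": self.covariates["male"].astype(float),
            "patient": self.covariates["patient"].astype(float),
            "pleasant": groups[pleasant_cols].mean(axis=1),
            "unpleasant": groups[unpleasant_cols].mean(axis=1),
        }, index=self.survey.index)

    def subset(self, idx) -> "Dataset":
        return Dataset(survey=self.survey.iloc[idx],
                       biomarkers=self.biomarkers.iloc[idx],
                       covariates=self.covariates.iloc[idx],
                       schema=self.schema)


@dataclass(frozen=True)
class IncrementalR2Result:
    """Held-out explained variance with and without one index.

    ``per_fold`` rows: repeat, fold, full-model R2, reduced-model R2 and
    their difference (exactly full - reduced).  Means are arithmetic over
    all folds and repeats.
    """

    method: str
    k: int
    per_fold: pd.DataFrame
    mean_full_r2: float
    mean_reduced_r2: float
    mean_delta_r2: float


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """In-sample R-squared of OLS with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tot = float(((y - y.mean()) ** 2).sum())
    if tot <= 0:
        raise ValueError("outcome has zero variance on the held-out fold")
    return 1.0 - float(resid @ resid) / tot


def heldout_delta_r2(
    covariates: pd.DataFrame, dqi: pd.Series, crfs: pd.Series
) -> tuple[float, float, float]:
    """Full/reduced held-out R-squared of the risk score and their
    difference, for one fold."""
    Xr = covariates[list(COVARIATES)].to_numpy(dtype=float)
    y = crfs.to_numpy(dtype=float)
    r2_reduced = _ols_r2(Xr, y)
    r2_full = _ols_r2(np.column_stack([Xr, dqi.to_numpy(dtype=float)]), y)
    return r2_full, r2_reduced, r2_full - r2_reduced


def _build_dqi(method: str, train: "_FoldViews", crfs_train: pd.Series,
               config: DQIConfig):
    if method == "theoretical":
        return theoretical_dqi(train.groups)
    if method == "empirical":
        return empirical_dqi(train.survey, crfs_train, train.cov, config)
    if method == "hybrid":
        return hybrid_dqi(train.food_groups, crfs_train, train.cov, config)
    raise ValueError(f"unknown DQI method {method!r}")


def _dqi_input(method: str, views: "_FoldViews") -> pd.DataFrame:
    return views.survey if method == "empirical" else (
        views.food_groups if method == "hybrid" else views.groups)


@dataclass(frozen=True)
class _FoldViews:
    survey: pd.DataFrame
    groups: pd.DataFrame
    food_groups: pd.DataFrame
    cov: pd.DataFrame
    biomarkers: pd.DataFrame


def _views(dataset: Dataset) -> _FoldViews:
    groups = dataset.group_table()
    return _FoldViews(
        survey=dataset.survey,
        groups=groups,
        food_groups=groups[list(dataset.schema.food_groups)],
        cov=dataset.covariate_table(),
        biomarkers=dataset.biomarkers,
    )


def incremental_r2_cv(
    dataset: Dataset,
    dqi_method: str,
    spec: CVSpec = CVSpec(),
    config: DQIConfig = DQIConfig(),
    crfs_scope: str = "train",
    min_fold: int = 15,
) -> IncrementalR2Result:
    """k-fold incremental R-squared of one index on the risk score.

    Per fold: fit the risk-score model and the index weights on the k-1
    training folds; apply both (frozen) to the held-out fold; on that fold
    compare OLS of the risk score on sex/patient/pleasant/unpleasant with
    and without the index.  The held-out regressions are fit on the held-out
    subsample itself, so with small folds the difference carries the usual
    one-extra-regressor inflation of in-sample R-squared.

    ``crfs_scope='train'`` (default) rebuilds the risk score inside each
    training split, avoiding any leakage of the transform or loadings;
    ``'full'`` fixes it once on the full sample, which mirrors the simpler
    single-sample convention but lets the outcome see held-out subjects.
    """
    if crfs_scope not in ("train", "full"):
        raise ValueError("crfs_scope must be 'train' or 'full'")
    views = _views(dataset)
    n = len(dataset.survey)
    rows = []
    full_model = None
    if crfs_scope == "full":
        full_model, _ = build_crfs(views.biomarkers)
    for rep in range(spec.n_repeats):
        folds = kfold_indices(n, spec.k, spec.seed + rep)
        for fold_no, test_idx in enumerate(folds):
            if len(test_idx) < min_fold:
                raise ValueError(
                    f"fold size {len(test_idx)} < {min_fold}; "
                    "use fewer folds or more subjects")
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            tr = _FoldViews(*[v.iloc[train_idx] for v in
                              (views.survey, views.groups, views.food_groups,
                               views.cov, views.biomarkers)])
            te = _FoldViews(*[v.iloc[test_idx] for v in
                              (views.survey, views.groups, views.food_groups,
                               views.cov, views.biomarkers)])
            if crfs_scope == "train":
                model, crfs_train = build_crfs(tr.biomarkers)
            else:
                model = full_model
                crfs_train = model.apply(tr.biomarkers)
            dqi = _build_dqi(dqi_method, tr, crfs_train, config)
            dqi_test = dqi.apply(_dqi_input(dqi_method, te))
            crfs_test = model.apply(te.biomarkers)
            r2_full, r2_red, delta = heldout_delta_r2(te.cov, dqi_test, crfs_test)
            rows.append((rep, fold_no, r2_full, r2_red, delta))
    per_fold = pd.DataFrame(
        rows, columns=["repeat", "fold", "r2_full", "r2_reduced", "delta_r2"])
    return IncrementalR2Result(
        method=dqi_method, k=spec.k, per_fold=per_fold,
        mean_full_r2=float(per_fold["r2_full"].mean()),
        mean_reduced_r2=float(per_fold["r2_reduced"].mean()),
        mean_delta_r2=float(per_fold["delta_r2"].mean()),
    )


def compare_dqis(
    dataset: Dataset,
    spec: CVSpec = CVSpec(),
    methods: tuple[str, ...] = DQI_METHODS,
    config: DQIConfig = DQIConfig(),
    crfs_scope: str = "train",
) -> pd.DataFrame:
    """Run the incremental-R2 procedure for several indexes on identical
    folds and seeds; returns one row per method."""
    rows = {}
    for method in methods:
        res = incremental_r2_cv(dataset, method, spec, config, crfs_scope)
        rows[method] = {
            "k": spec.k,
            "mean_full_r2": res.mean_full_r2,
            "mean_reduced_r2": res.mean_reduced_r2,
            "mean_delta_r2": res.mean_delta_r2,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def describe_dqi(
    scores: pd.Series,
    patient_flags: pd.Series,
    two_sample: str = "welch",
) -> Mapping[str, float]:
    """Descriptive summary of an index: distribution, normality, and the
    patient-vs-control contrast.

    The group difference is reported as control mean minus patient mean with
    a Welch two-sample test (``two_sample='ks'`` substitutes a two-sample
    Kolmogorov-Smirnov test).  Normality is the Lilliefors-corrected KS test
    on the pooled scores.
    """
    flags = patient_flags.astype(bool)
    patient = scores[flags.to_numpy()]
    control = scores[~flags.to_numpy()]
    if len(patient) == 0 or len(control) == 0:
        raise ValueError("both patient and control groups must be non-empty")
    d_stat, ks_p = ks_normality(scores.to_numpy())
    if two_sample == "welch":
        stat, p = sps.ttest_ind(control, patient, equal_var=False)
    elif two_sample == "ks":
        stat, p = sps.ks_2samp(control, patient)
    else:
        raise ValueError("two_sample must be 'welch' or 'ks'")
    return {
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)),
        "ks_D": d_stat,
        "ks_p": ks_p,
        "control_mean": float(control.mean()),
        "patient_mean": float(patient.mean()),
        "mean_difference": float(control.mean() - patient.mean()),
        "two_sample_stat": float(stat),
        "two_sample_p": float(p),
    }
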