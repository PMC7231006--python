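"""Synthetic survey-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: group-level likings drawn from a multivariate normal calibrated to
the published group means, SDs and pairwise correlations; item-level ratings
disaggregated so each group hits its published internal consistency
(Cronbach alpha) through the Spearman-Brown relation; and fasting biomarkers
carrying a planted, configurable linear diet -> risk signal.  Plasma and
adiposity biomarkers load on one latent risk factor while blood pressure is
only weakly coupled to it, reproducing the correlation split that justifies
the risk-score screening step.  Insulin, triglycerides and BMI are mapped
through exponential links so the normality-transformation stage has real
work to do.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .errors import ConfigurationError
from .survey import GroupSchema

__all__ = [
    "CohortSpec",
    "Cohort",
    "sample_group_likings",
    "disaggregate_to_items",
    "sample_outcomes",
    "generate_cohort",
    "nearest_psd_correlation",
]

logger = logging.getLogger(__name__)

#: Biomarkers generated by the cohort model, in output order.
BIOMARKERS = ("insulin", "glucose", "hdl", "ldl", "total_cholesterol",
              "triglycerides", "bmi", "whr", "sbp", "dbp")

#: The six measures that share the latent cardiometabolic factor.
CORE_MEASURES = ("insulin", "glucose", "hdl", "triglycerides", "bmi", "whr")

_CORE_LOADING = float(np.sqrt(0.32))  # pairwise core correlation 0.32


def _default_planted_weights() -> dict[str, float]:
    # Direction mirrors the relative importance of the published 0-100
    # scoring standard: moderation components raise latent risk, adequacy
    # components lower it.  Scale is arbitrary (normalized at generation).
    return {
        "fruit": -2.0, "refined carbohydrate": 17.0, "sweet": 17.0,
        "salty": 1.0, "healthy fat": 1.0, "saturated fat": 17.0,
        "vegetable": -18.0, "high-fat protein": 1.0,
        "complex carbohydrate": 15.0, "spicy/flavorful": 4.0,
        "alcohol": -3.0, "low-fat dairy": 3.0,
    }


def _default_patient_shift() -> dict[str, float]:
    # Patients report a modestly less healthy liking pattern; applied
    # centered (+shift/2 for patients, -shift/2 for controls) so the
    # marginal group means stay on target.
    return {
        "vegetable": -6.0, "sweet": 6.0, "saturated fat": 4.0,
        "refined carbohydrate": 4.0, "fruit": -3.0,
        "complex carbohydrate": 3.0,
    }


def _default_biomarker_loadings() -> dict[str, float]:
    lam = _CORE_LOADING
    return {
        "insulin": lam, "glucose": lam, "hdl": -lam,
        "triglycerides": lam, "bmi": lam, "whr": lam,
        "ldl": 0.25,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    The defaults reproduce the study conditions the pipeline was built for:
    a cohort of 212 young adults (62.3% female, half patients), group-liking
    distributions matching the published table, internal consistencies
    matching the published alphas, and a diet signal that explains a
    ``diet_variance`` share of the latent risk with direction mirroring the
    published scoring standard.
    """

    n: int = 212
    seed: int = 0
    group_means: dict[str, float] = field(
        default_factory=lambda: dict(defaults.GROUP_MEANS))
    group_sds: dict[str, float] = field(
        default_factory=lambda: dict(defaults.GROUP_SDS))
    group_correlations: pd.DataFrame = field(
        default_factory=defaults.group_correlations)
    alpha_targets: dict[str, float] = field(
        default_factory=lambda: dict(defaults.GROUP_ALPHAS))
    experience_targets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(defaults.EXPERIENCE_TARGETS))
    planted_weights: dict[str, float] = field(
        default_factory=_default_planted_weights)
    diet_variance: float = 0.08
    sex_effect: float = 0.25        # effect of male sex on latent risk
    patient_effect: float = 0.85    # effect of patient status on latent risk
    patient_liking_shift: dict[str, float] = field(
        default_factory=_default_patient_shift)
    female_rate: float = 0.623
    patient_rate: float = 0.5
    biomarker_loadings: dict[str, float] = field(
        default_factory=_default_biomarker_loadings)
    bp_coupling: float = 0.12 / _CORE_LOADING   # weak latent loading of BP
    bp_shared: float = 0.72                     # SBP/DBP own shared factor

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigurationError(f"n must be >= 10, got {self.n}")
        if not (0 <= self.diet_variance < 1):
            raise ConfigurationError("diet_variance must be in [0, 1)")
        R = self.group_correlations
        if list(R.index) != list(R.columns):
            raise ConfigurationError("correlation matrix index != columns")
        if not np.allclose(R.values, R.values.T) or not np.allclose(
                np.diag(R.values), 1.0):
            raise ConfigurationError(
                "correlation matrix must be symmetric with unit diagonal")
        for g, a in self.alpha_targets.items():
            if not (0 < a < 1):
                raise ConfigurationError(f"alpha target for {g!r} not in (0,1): {a}")
        unknown = set(self.planted_weights) - set(R.index)
        if unknown:
            raise ConfigurationError(f"planted weights for unknown groups: {unknown}")

    # -- derived quantities -------------------------------------------------

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.group_correlations.index)

    def weight_vector(self) -> np.ndarray:
        return np.array(
            [self.planted_weights.get(g, 0.0) for g in self.group_names])

    def _signal_direction(self) -> np.ndarray:
        """Planted weights normalized so the diet signal has unit variance
        on standardized group likings."""
        w = self.weight_vector()
        R = self.group_correlations.values
        denom = float(w @ R @ w)
        if denom <= 0:
            return np.zeros_like(w)
        return w / np.sqrt(denom)

    def covariate_variance(self) -> float:
        """Latent-risk variance contributed by sex and patient status,
        including the diet shift mediated through patient status."""
        pm = 1.0 - self.female_rate
        u = self._signal_direction()
        sds = np.array([self.group_sds[g] for g in self.group_names])
        shift = np.array(
            [self.patient_liking_shift.get(g, 0.0) for g in self.group_names])
        d = np.sqrt(self.diet_variance) * float(u @ (shift / sds))
        pp = self.patient_rate
        return (self.sex_effect ** 2 * pm * (1 - pm)
                + (self.patient_effect + d) ** 2 * pp * (1 - pp))

    def residual_sd(self) -> float:
        resid = 1.0 - self.diet_variance - self.covariate_variance()
        if resid <= 0.01:
            raise ConfigurationError(
                "planted diet and covariate effects leave no residual "
                f"latent variance (residual = {resid:.4f})")
        return float(np.sqrt(resid))

    def attenuation(self) -> float:
        """Squared correlation between the latent risk and the first
        principal component of the six core biomarkers.

        The risk score is built from noisy biomarkers, so any planted
        diet -> risk variance share is attenuated by this factor when
        measured against the score instead of the latent.
        """
        lam = np.array([self.biomarker_loadings[m] for m in CORE_MEASURES])
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        eigval, eigvec = np.linalg.eigh(sigma)
        v1 = eigvec[:, -1]
        rho = abs(float(v1 @ lam)) / np.sqrt(float(eigval[-1]))
        return rho ** 2

    def with_planted_partial_r2(self, r2: float) -> "CohortSpec":
        """Rescale the diet signal so that adding it to the covariate model
        raises the explained variance of the risk score by ``r2``.

        With the patient liking shift removed, diet and covariates are
        orthogonal and the incremental R-squared of the true signal equals
        the diet variance share times the biomarker attenuation, so the
        share is set to ``r2 / attenuation()``.
        """
        rho2 = self.attenuation()
        base = replace(self, patient_liking_shift={})
        return replace(base, diet_variance=float(r2 / rho2))

    def null(self) -> "CohortSpec":
        """Same cohort with the diet -> risk signal removed entirely."""
        return replace(self, diet_variance=0.0, patient_liking_shift={})


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Repair a non-PSD target correlation matrix by eigenvalue clipping,
    rescaled back to unit diagonal."""
    eigval, eigvec = np.linalg.eigh(R)
    if eigval.min() >= eps:
        return R
    logger.warning(
        "target correlation matrix not PSD (min eigenvalue %.3e); "
        "applying nearest-PSD repair", eigval.min())
    fixed = eigvec @ np.diag(np.clip(eigval, eps, None)) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


# --------------------------------------------------------------------------
# Sampling stages
# --------------------------------------------------------------------------

def sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli sex and patient-status draws."""
    male = (rng.random(spec.n) >= spec.female_rate).astype(int)
    patient = (rng.random(spec.n) < spec.patient_rate).astype(int)
    ids = [f"S{i:05d}" for i in range(spec.n)]
    return pd.DataFrame({"male": male, "patient": patient}, index=ids)


def sample_group_likings(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    patient: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw per-subject group likings from the target multivariate normal.

    Scores are clipped to the instrument range [-100, 100]; at the default
    means/SDs the clip bias on moments is small and documented.  When a
    patient indicator is supplied, the configured patient liking shift is
    applied centered (+shift/2 patients, -shift/2 controls) so marginal
    means stay on target.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    names = spec.group_names
    R = nearest_psd_correlation(spec.group_correlations.values.astype(float))
    sds = np.array([spec.group_sds[g] for g in names])
    means = np.array([spec.group_means[g] for g in names])
    cov = R * np.outer(sds, sds)
    X = rng.multivariate_normal(means, cov, size=spec.n, method="cholesky")
    if patient is not None and spec.patient_liking_shift:
        shift = np.array(
            [spec.patient_liking_shift.get(g, 0.0) for g in names])
        X = X + np.outer(np.asarray(patient) - 0.5, shift)
    X = np.clip(X, -100.0, 100.0)
    index = [f"S{i:05d}" for i in range(spec.n)]
    return pd.DataFrame(X, index=index, columns=list(names))


def disaggregate_to_items(
    group_scores: pd.DataFrame,
    schema: GroupSchema,
    alpha_targets: dict[str, float],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Expand group scores into item ratings with target reliability.

    Item j of a k-item group is ``G + e_j - mean(e)`` with independent
    Gaussian noise e, so the item mean reproduces the sampled group score
    exactly and the group-level calibration (means, SDs, correlations)
    survives disaggregation.  The noise SD is solved from the reliability
    identity for a k-item mean, ``alpha = 1 - var(e) / (k var(G))`` (the
    Spearman-Brown reliability of the aggregate), so the scale attains the
    target Cronbach alpha before range clipping.  Items are clipped to the
    instrument range, which biases realized alphas slightly downward at the
    default targets.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    columns: dict[str, np.ndarray] = {}
    n = len(group_scores)
    for group in group_scores.columns:
        items = schema.groups.get(group)
        if items is None or schema.roles.get(group) == "auxiliary":
            continue
        k = len(items)
        if k < 2:
            raise ConfigurationError(f"group {group!r} needs >= 2 items")
        alpha = alpha_targets[group]
        if not (0 < alpha <= 1):
            raise ConfigurationError(
                f"alpha target for {group!r} must be in (0, 1], got {alpha}")
        sd_g = float(group_scores[group].std(ddof=1))
        noise_sd = sd_g * np.sqrt(k * (1.0 - alpha))
        base = group_scores[group].to_numpy()
        e = rng.normal(0.0, noise_sd, (n, k))
        e -= e.mean(axis=1, keepdims=True)
        for j, item in enumerate(items):
            columns[item] = np.clip(base + e[:, j], -100.0, 100.0)
    return pd.DataFrame(columns, index=group_scores.index)


def _links(spec: CohortSpec):
    """Monotone maps from standard-normal biomarker cores to physiological
    ranges; insulin, triglycerides and BMI are exponential (right-skewed)."""
    return {
        "insulin": lambda b: np.maximum(np.exp(2.42 + 0.50 * b), 0.5),
        "glucose": lambda b: np.maximum(89.3 + 8.0 * b, 40.0),
        "hdl": lambda b: np.maximum(57.8 + 12.0 * b, 20.0),
        "triglycerides": lambda b: np.maximum(np.exp(4.49 + 0.47 * b), 10.0),
        "bmi": lambda b: np.clip(np.exp(3.20 + 0.22 * b), 14.0, 60.0),
        "whr": lambda b: np.clip(0.825 + 0.075 * b, 0.45, 1.6),
        "ldl": lambda b: np.maximum(91.0 + 25.0 * b, 20.0),
        "sbp": lambda b: np.maximum(111.6 + 13.0 * b, 70.0),
        "dbp": lambda b: np.maximum(71.7 + 9.0 * b, 40.0),
    }


def sample_outcomes(
    group_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: CohortSpec,
    rng: np.random.Generator | int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate biomarkers from the planted latent-risk model.

    The latent risk is ``T = s + g_sex*male + g_patient*patient + eps`` with
    ``s`` the unit-variance diet signal scaled to the spec's diet variance
    share; the residual SD is solved so Var(T) = 1.  The six core measures
    load on T with the configured loadings (HDL negatively); systolic and
    diastolic pressure receive only the weak coupling plus their own shared
    factor.  Returns (biomarkers, latent diagnostics).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(group_scores)
    names = spec.group_names
    sds = np.array([spec.group_sds[g] for g in names])
    means = np.array([spec.group_means[g] for g in names])
    z = (group_scores[list(names)].to_numpy() - means) / sds

    u = spec._signal_direction()
    s = np.sqrt(spec.diet_variance) * (z @ u) if spec.diet_variance > 0 else np.zeros(n)
    male = covariates["male"].to_numpy()
    patient = covariates["patient"].to_numpy()
    T = (s + spec.sex_effect * male + spec.patient_effect * patient
         + rng.normal(0.0, spec.residual_sd(), n))

    links = _links(spec)
    cores: dict[str, np.ndarray] = {}
    for m in (*CORE_MEASURES, "ldl"):
        lam = spec.biomarker_loadings[m]
        cores[m] = lam * T + np.sqrt(max(1 - lam ** 2, 0.0)) * rng.normal(size=n)
    bp_factor = rng.normal(size=n)
    bp_noise_sd = np.sqrt(max(1 - spec.bp_coupling ** 2 - spec.bp_shared ** 2, 0.0))
    for m in ("sbp", "dbp"):
        cores[m] = (spec.bp_coupling * T + spec.bp_shared * bp_factor
                    + bp_noise_sd * rng.normal(size=n))

    bio = {m: links[m](cores[m]) for m in links}
    bio["total_cholesterol"] = (
        bio["ldl"] + bio["hdl"] + bio["triglycerides"] / 5.0)
    biomarkers = pd.DataFrame(
        {m: bio[m] for m in BIOMARKERS}, index=group_scores.index)
    biomarkers["sex"] = np.where(male == 1, "male", "female")
    biomarkers["patient"] = patient
    latent = pd.DataFrame(
        {"diet_signal": s, "risk_latent": T}, index=group_scores.index)
    return biomarkers, latent


# --------------------------------------------------------------------------
# Cohort container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Cohort:
    """A generated cohort: item ratings, sampled group scores, covariates,
    biomarkers and latent diagnostics."""

    spec: CohortSpec
    survey: pd.DataFrame          # subjects x items
    group_scores: pd.DataFrame    # sampled group-level scores (pre-items)
    covariates: pd.DataFrame      # male, patient indicators
    biomarkers: pd.DataFrame
    latent: pd.DataFrame

    def to_csv_dir(self, path) -> dict[str, str]:
        """Write survey/biomarker/covariate CSVs; returns written paths."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, df in (("survey", self.survey),
                         ("biomarkers", self.biomarkers),
                         ("covariates", self.covariates)):
            p = path / f"{name}.csv"
            df.to_csv(p, index_label="subject_id")
            written[name] = str(p)
        return written


def generate_cohort(spec: CohortSpec, schema: GroupSchema | None = None) -> Cohort:
    """Run the full generative model under the spec's seed.

    Stage order (covariates, group likings, experience scores, item
    disaggregation, outcomes) is fixed, so identical spec + seed give a
    byte-identical cohort.
    """
    schema = schema or GroupSchema.default()
    rng = np.random.default_rng(spec.seed)
    covariates = sample_covariates(spec, rng)
    groups = sample_group_likings(
        spec, rng, patient=covariates["patient"].to_numpy())

    exp_scores = {}
    exp_alphas = {}
    for name in ("pleasant", "unpleasant"):
        mean, sd, alpha = spec.experience_targets[name]
        exp_scores[name] = np.clip(rng.normal(mean, sd, spec.n), -100, 100)
        exp_alphas[name] = alpha
    all_scores = groups.copy()
    for name, vals in exp_scores.items():
        all_scores[name] = vals

    alpha_targets = {**spec.alpha_targets, **exp_alphas}
    survey = disaggregate_to_items(all_scores, schema, alpha_targets, rng)

    biomarkers, latent = sample_outcomes(groups, covariates, spec, rng)
    return Cohort(spec=spec, survey=survey, group_scores=groups,
                  covariates=covariates, biomarkers=biomarkers, latent=latent)
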