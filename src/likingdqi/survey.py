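"""Liking-survey domain model: profiles, group schemas, group scoring,
scale reliability and clinical abnormality counting.

The survey instrument asks respondents to rate foods, beverages and common
experiences on a bipolar hedonic scale from -100 (strongest disliking of any
kind) to +100 (strongest liking).  Items are averaged into conceptual food
groups; the pleasant- and unpleasant-experience items are averaged into two
non-food hedonic anchors that downstream models use as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .errors import ConfigurationError, MissingGroupError, UndefinedAlphaError

__all__ = [
    "LikingProfile",
    "GroupSchema",
    "GroupLikingVector",
    "BiomarkerPanel",
    "AbnormalityReport",
    "score_groups",
    "score_groups_frame",
    "cronbach_alpha",
    "homa_ir",
    "count_abnormalities",
    "load_survey_csv",
    "load_biomarker_csv",
]

RATING_MIN = -100.0
RATING_MAX = 100.0

#: Roles a schema group may take.  Items of ``food`` groups must be disjoint;
#: ``auxiliary`` groups (e.g. the lean-protein list of the guideline index)
#: may reuse items from food groups.
GROUP_ROLES = ("food", "pleasant_experience", "unpleasant_experience", "auxiliary")


@dataclass(frozen=True)
class LikingProfile:
    """One subject's hedonic ratings.

    ``ratings`` maps item name to a value in [-100, 100], or ``None`` for an
    explicitly missing response (a skipped item is recorded, never silently
    treated as zero).
    """

    subject_id: str
    ratings: Mapping[str, float | None]

    def __post_init__(self) -> None:
        for item, value in self.ratings.items():
            if value is None:
                continue
            if not np.isfinite(value) or not (RATING_MIN <= value <= RATING_MAX):
                raise ValueError(
                    f"rating for {item!r} out of range [-100, 100]: {value}"
                )

    def rating_series(self) -> pd.Series:
        """Ratings as a float Series with NaN for missing responses."""
        return pd.Series(
            {k: (np.nan if v is None else float(v)) for k, v in self.ratings.items()},
            dtype=float,
        )


@dataclass(frozen=True)
class GroupSchema:
    """Assignment of survey items to named groups with a role per group."""

    groups: Mapping[str, tuple[str, ...]]
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, items in self.groups.items():
            if not items:
                raise ConfigurationError(f"group {name!r} is empty")
            role = self.roles.get(name)
            if role not in GROUP_ROLES:
                raise ConfigurationError(f"group {name!r} has invalid role {role!r}")
            if role != "food":
                continue
            for item in items:
                if item in seen:
                    raise ConfigurationError(
                        f"item {item!r} appears in food groups "
                        f"{seen[item]!r} and {name!r}"
                    )
                seen[item] = name

    @property
    def food_groups(self) -> tuple[str, ...]:
        return tuple(g for g, r in self.roles.items() if r == "food")

    @property
    def auxiliary_groups(self) -> tuple[str, ...]:
        return tuple(g for g, r in self.roles.items() if r == "auxiliary")

    def groups_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(g for g, r in self.roles.items() if r == role)

    def all_items(self) -> tuple[str, ...]:
        """Unique item names across all groups, in first-seen order."""
        out: list[str] = []
        for items in self.groups.values():
            for item in items:
                if item not in out:
                    out.append(item)
        return tuple(out)

    @classmethod
    def default(cls) -> "GroupSchema":
        """The instrument's shipped schema: 12 food groups, the two
        experience groups and the auxiliary lean-protein group."""
        groups: dict[str, tuple[str, ...]] = dict(defaults.FOOD_GROUP_ITEMS)
        roles = {g: "food" for g in defaults.FOOD_GROUP_ITEMS}
        groups["pleasant"] = defaults.PLEASANT_ITEMS
        roles["pleasant"] = "pleasant_experience"
        groups["unpleasant"] = defaults.UNPLEASANT_ITEMS
        roles["unpleasant"] = "unpleasant_experience"
        groups["low-fat protein"] = defaults.LOW_FAT_PROTEIN_ITEMS
        roles["low-fat protein"] = "auxiliary"
        return cls(groups=groups, roles=roles)

    @classmethod
    def from_yaml(cls, path) -> "GroupSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = {g: tuple(spec["items"]) for g, spec in raw.items()}
        roles = {g: spec.get("role", "food") for g, spec in raw.items()}
        return cls(groups=groups, roles=roles)

    def to_yaml(self, path) -> None:
        raw = {
            g: {"role": self.roles[g], "items": list(items)}
            for g, items in self.groups.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class GroupLikingVector:
    """Per-subject mean liking of each group plus the two hedonic anchors."""

    subject_id: str
    values: Mapping[str, float]
    pleasant: float
    unpleasant: float


def score_groups_frame(
    survey: pd.DataFrame,
    schema: GroupSchema | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Average item ratings into group scores for a whole cohort.

    Parameters
    ----------
    survey
        Subjects x items ratings; NaN marks a missing response.
    schema
        Item-to-group assignment (defaults to the shipped instrument).
    min_coverage
        Minimum fraction of a group's items that must be non-missing for a
        subject; below it the group is unscorable and an error is raised.

    Returns
    -------
    DataFrame with one column per schema group (food, auxiliary, and the
    ``pleasant``/``unpleasant`` experience anchors).
    """
    schema = schema or GroupSchema.default()
    out = {}
    for group, items in schema.groups.items():
        missing_items = [i for i in items if i not in survey.columns]
        if missing_items:
            raise MissingGroupError(
                f"group {group!r}: survey lacks items {missing_items}"
            )
        block = survey.loc[:, list(items)]
        coverage = block.notna().mean(axis=1)
        bad = coverage < max(min_coverage, 1e-12)
        if bad.any():
            raise MissingGroupError(
                f"group {group!r} unscorable for subjects "
                f"{list(survey.index[bad])[:5]} (coverage < {min_coverage:.0%})"
            )
        out[group] = block.mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=survey.index)


def score_groups(
    profile: LikingProfile,
    schema: GroupSchema | None = None,
    min_coverage: float = 0.5,
) -> GroupLikingVector:
    """Score one subject's profile into group mean likings."""
    schema = schema or GroupSchema.default()
    frame = profile.rating_series().to_frame().T
    frame.index = [profile.subject_id]
    scores = score_groups_frame(frame, schema, min_coverage=min_coverage).iloc[0]
    pleasant_groups = schema.groups_with_role("pleasant_experience")
    unpleasant_groups = schema.groups_with_role("unpleasant_experience")
    pleasant = float(scores[list(pleasant_groups)].mean()) if pleasant_groups else np.nan
    unpleasant = (
        float(scores[list(unpleasant_groups)].mean()) if unpleasant_groups else np.nan
    )
    values = {
        g: float(scores[g])
        for g in schema.groups
        if schema.roles[g] in ("food", "auxiliary")
    }
    return GroupLikingVector(
        subject_id=profile.subject_id,
        values=values,
        pleasant=pleasant,
        unpleasant=unpleasant,
    )


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(sum of items)),
    using unbiased (ddof=1) sample variances.  Alpha may be negative for
    incoherent scales and is bounded above by 1.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x items matrix with >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedAlphaError("total score has zero variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass(frozen=True)
class BiomarkerPanel:
    """Fasting biomarkers and anthropometrics of one subject.

    Units: insulin mIU/L; glucose, HDL, LDL, total cholesterol and
    triglycerides mg/dL; BMI kg/m^2; waist-to-hip ratio dimensionless;
    blood pressures mmHg.
    """

    subject_id: str
    insulin: float
    glucose: float
    hdl: float
    ldl: float
    total_cholesterol: float
    triglycerides: float
    bmi: float
    whr: float
    sbp: float
    dbp: float
    sex: str = "female"          # {male, female}
    patient: bool = False

    def __post_init__(self) -> None:
        for name in ("insulin", "glucose", "hdl", "ldl", "total_cholesterol",
                     "triglycerides", "bmi", "whr", "sbp", "dbp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not (0.3 < self.whr < 2.0):
            raise ValueError(f"waist-to-hip ratio implausible: {self.whr}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


def homa_ir(glucose_mg_dl: float, insulin_miu_l: float) -> float:
    """Insulin-resistance index from fasting glucose and insulin.

    Computed with the original closed-form model (glucose [mg/dL] x insulin
    [mIU/L] / 405).  The computer-model variant of the index requires an
    external calculator; callers who have those values can substitute them
    before applying the <2.0 cut-off.
    """
    return glucose_mg_dl * insulin_miu_l / 405.0


@dataclass(frozen=True)
class AbnormalityReport:
    """Per-factor abnormality flags, their count, and the HOMA-IR value."""

    count: int
    flags: Mapping[str, bool]
    homa_ir: float


def count_abnormalities(panel: BiomarkerPanel) -> AbnormalityReport:
    """Count cardiometabolic factors outside their normal ranges.

    Ten factors are screened: BMI, blood pressure (systolic or diastolic
    elevated counts once), fasting glucose, fasting insulin, total
    cholesterol, LDL, triglycerides, HDL and waist-to-hip ratio (both with
    sex-specific cut-offs), and HOMA-IR insulin resistance.  The count is
    monotone: worsening any single factor never lowers it.
    """
    c = defaults.ABNORMALITY_CUTOFFS
    homa = homa_ir(panel.glucose, panel.insulin)
    flags = {
        "bmi": panel.bmi >= c["bmi"][1],
        "blood_pressure": panel.sbp >= c["sbp"][1] or panel.dbp >= c["dbp"][1],
        "glucose": panel.glucose >= c["glucose"][1],
        "insulin": panel.insulin >= c["insulin"][1],
        "total_cholesterol": panel.total_cholesterol >= c["total_cholesterol"][1],
        "ldl": panel.ldl >= c["ldl"][1],
        "triglycerides": panel.triglycerides >= c["triglycerides"][1],
        "hdl": panel.hdl <= c["hdl"][panel.sex][1],
        "whr": panel.whr >= c["whr"][panel.sex][1],
        "homa_ir": homa >= c["homa_ir"][1],
    }
    return AbnormalityReport(count=int(sum(flags.values())), flags=flags, homa_ir=homa)


# --------------------------------------------------------------------------
# CSV interfaces
# --------------------------------------------------------------------------

def load_survey_csv(path) -> pd.DataFrame:
    """Read a survey CSV (one row per subject, header = item names).

    A ``subject_id`` column, when present, becomes the index.  Blank cells
    are missing responses.  Values are validated against the +/-100 scale.
    """
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    df = df.astype(float)
    values = df.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out_of_range = np.nanmax(np.abs(values)) > RATING_MAX
    if out_of_range:
        raise ValueError(f"survey ratings outside [-100, 100] in {path}")
    return df


def load_biomarker_csv(path) -> pd.DataFrame:
    """Read a biomarker CSV with one BiomarkerPanel row per subject."""
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    required = {"insulin", "glucose", "hdl", "ldl", "total_cholesterol",
                "triglycerides", "bmi", "whr", "sbp", "dbp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biomarker CSV lacks columns: {sorted(missing)}")
    return df
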