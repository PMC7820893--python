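"""Exclusions, allele grouping, coding, standardization and design matrices.

Turns a raw long-format cohort into the analysis set used by the beta
regression: participants with no observed score, missing education, or the
ambiguous e2e4 genotype are excluded (in that order); genotypes collapse to
allele groups e2 = {e2e2, e2e3}, e3 = {e3e3} (reference), e4 = {e3e4, e4e4};
age and education are standardized; scores are rescaled onto [0.01, 0.99].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MAX_SCORE, GENOTYPES, validate_cohort

__all__ = [
    "AnalysisSet",
    "Design",
    "ExclusionLog",
    "ModelTerms",
    "CONTRASTS",
    "assign_allele_group",
    "apply_exclusions",
    "rescale_score",
    "inverse_rescale",
    "standardize",
    "build_analysis_set",
    "build_design",
]

CONTRASTS = ("e2_vs_e3", "e4_vs_e3", "all_three")

_GROUP_OF = {
    "e2e2": "e2",
    "e2e3": "e2",
    "e3e3": "e3",
    "e3e4": "e4",
    "e4e4": "e4",
    "e2e4": None,
}

# interaction -> parents; main effects have no parents
_PARENTS = {
    "age2": ("age",),
    "age_x_edu": ("age", "edu"),
    "age_x_apoe": ("age", "apoe"),
    "edu_x_apoe": ("edu", "apoe"),
}

CANDIDATE_TERMS = ("age", "age2", "sex", "edu", "apoe", "age_x_edu", "age_x_apoe", "edu_x_apoe")


def assign_allele_group(genotype: str):
    """Map an ordered-pair genotype to its allele group.

    Returns ``"e2"``, ``"e3"``, ``"e4"``, or ``None`` for the excluded
    e2e4 genotype; raises on unknown strings.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown APOE genotype {genotype!r}")
    return _GROUP_OF[genotype]


@dataclass(frozen=True)
class ExclusionLog:
    n_input: int
    n_missing_score: int
    n_missing_education: int
    n_e2e4: int
    n_retained: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop participants sequentially: no observed score, then missing
    education, then e2e4 carriers.  Counts are per participant, each
    attributed to the first applicable reason."""
    validate_cohort(cohort)
    per = cohort.groupby("participant_id", sort=False).agg(
        any_score=("bimc_score", lambda s: s.notna().any()),
        education=("education_years", "first"),
        genotype=("apoe_genotype", "first"),
    )
    n_input = len(per)
    no_score = ~per["any_score"].astype(bool)
    n_score = int(no_score.sum())
    per = per[~no_score]
    no_edu = per["education"].isna()
    n_edu = int(no_edu.sum())
    per = per[~no_edu]
    is_e2e4 = per["genotype"] == "e2e4"
    n_e2e4 = int(is_e2e4.sum())
    per = per[~is_e2e4]

    kept = cohort[
        cohort["participant_id"].isin(per.index)
        & cohort["bimc_score"].notna()
    ].reset_index(drop=True)
    log = ExclusionLog(n_input, n_score, n_edu, n_e2e4, len(per))
    return kept, log


def rescale_score(y):
    """Map a 0-37 score onto [0.01, 0.99] via y' = 0.01 + 0.98*y/37."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > MAX_SCORE)):
        raise ValueError(f"score outside 0..{MAX_SCORE}")
    out = 0.01 + 0.98 * y / MAX_SCORE
    return out.item() if out.ndim == 0 else out


def inverse_rescale(y_prime):
    """Exact inverse of :func:`rescale_score`, back onto the 0-37 scale."""
    y_prime = np.asarray(y_prime, dtype=float)
    out = (y_prime - 0.01) / 0.98 * MAX_SCORE
    return out.item() if out.ndim == 0 else out


def standardize(values) -> tuple[np.ndarray, float, float]:
    """z-scores with sample SD (n-1 denominator); returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant input (sd = 0)")
    return (x - mean) / sd, mean, sd


@dataclass(frozen=True)
class ModelTerms:
    """A candidate fixed-effect structure (the intercept is implicit).

    ``apoe`` expands to one dummy (two-group contrasts) or two dummies
    (three-group analysis).  Included interactions force inclusion of both
    parents (model hierarchy).
    """

    included: frozenset = frozenset(CANDIDATE_TERMS)

    def __init__(self, included=CANDIDATE_TERMS):
        object.__setattr__(self, "included", frozenset(included))
        unknown = self.included - set(CANDIDATE_TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        for term in self.included:
            for parent in _PARENTS.get(term, ()):
                if parent not in self.included:
                    raise ValueError(
                        f"hierarchy violation: {term} requires parent {parent}"
                    )

    def droppable(self) -> list[str]:
        """Terms removable without violating hierarchy (no dependent child)."""
        out = []
        for term in sorted(self.included):
            if any(
                term in _PARENTS.get(child, ()) for child in self.included
            ):
                continue
            out.append(term)
        return out

    def drop(self, term: str) -> "ModelTerms":
        if term not in self.included:
            raise ValueError(f"{term} not in model")
        return ModelTerms(self.included - {term})

    def parents_of(self, term: str) -> tuple:
        return _PARENTS.get(term, ())

    def __iter__(self):
        return iter(sorted(self.included))

    def __contains__(self, term):
        return term in self.included

    def __len__(self):
        return len(self.included)


@dataclass
class AnalysisSet:
    """Post-exclusion, coded and rescaled data ready for model fitting."""

    rows: pd.DataFrame
    scaling_constants: dict
    contrast: str
    exclusion_log: ExclusionLog

    @property
    def n_participants(self) -> int:
        return int(self.rows["pid_index"].nunique())


def build_analysis_set(cohort: pd.DataFrame, contrast: str = "e2_vs_e3") -> AnalysisSet:
    """Apply exclusions and coding for one of the three analyses.

    ``e2_vs_e3`` keeps the e2 and e3 allele groups, ``e4_vs_e3`` the e4 and
    e3 groups, ``all_three`` all of them; e3 is always the reference.  Age
    is standardized over all retained administrations (it is time-varying),
    education over participants; both sets of constants are recorded so
    fitted curves can be mapped back to raw years.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    kept, log = apply_exclusions(cohort)
    if len(kept) == 0:
        raise ValueError("no rows remain after exclusions")

    group = kept["apoe_genotype"].map(_GROUP_OF)
    if contrast == "e2_vs_e3":
        kept = kept[group.isin(["e2", "e3"])]
    elif contrast == "e4_vs_e3":
        kept = kept[group.isin(["e4", "e3"])]
    kept = kept.reset_index(drop=True)
    group = kept["apoe_genotype"].map(_GROUP_OF)

    z_age, age_mean, age_sd = standardize(kept["age_at_test"].to_numpy(float))

    per = kept.groupby("participant_id", sort=False)["education_years"].first()
    _, edu_mean, edu_sd = standardize(per.to_numpy(float))
    z_edu = (kept["education_years"].to_numpy(float) - edu_mean) / edu_sd

    pid_codes, _ = pd.factorize(kept["participant_id"], sort=False)
    n_obs = np.bincount(pid_codes)
    i_single = (n_obs == 1)[pid_codes]

    rows = pd.DataFrame(
        {
            "participant_id": kept["participant_id"],
            "pid_index": pid_codes,
            "age_at_test": kept["age_at_test"].to_numpy(float),
            "bimc_score": kept["bimc_score"].astype(int),
            "y_prime": rescale_score(kept["bimc_score"].to_numpy(float)),
            "z_age": z_age,
            "z_edu": z_edu,
            "sex_code": (kept["sex"] == "male").astype(float),
            "group_e2": (group == "e2").astype(float),
            "group_e4": (group == "e4").astype(float),
            "i_single": i_single.astype(int),
        }
    )
    constants = {
        "age_mean": age_mean,
        "age_sd": age_sd,
        "edu_mean": edu_mean,
        "edu_sd": edu_sd,
    }
    return AnalysisSet(rows, constants, contrast, log)


@dataclass
class Design:
    """Design matrix plus grouping structure for the hierarchical model."""

    X: np.ndarray  # (n_rows, p) covariates, no intercept column
    columns: list[str]
    y: np.ndarray  # rescaled scores in (0,1)
    pid: np.ndarray  # participant index per row, 0..n_participants-1
    singleton: np.ndarray  # bool per participant
    terms: ModelTerms
    contrast: str

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_participants(self) -> int:
        return len(self.singleton)


def _apoe_dummies(contrast: str) -> list[str]:
    if contrast == "e2_vs_e3":
        return ["group_e2"]
    if contrast == "e4_vs_e3":
        return ["group_e4"]
    return ["group_e2", "group_e4"]


def build_design(analysis_set: AnalysisSet, terms: ModelTerms) -> Design:
    """Expand model terms into covariate columns for the set's contrast.

    Column order: main effects (age, age2, sex, edu, APOE dummies) then
    interactions; interaction columns are element-wise products of their
    parents.  The intercept is handled by the piecewise random-intercept
    device and never appears as a column.
    """
    rows = analysis_set.rows
    dummies = _apoe_dummies(analysis_set.contrast)
    base = {
        "age": rows["z_age"].to_numpy(),
        "sex": rows["sex_code"].to_numpy(),
        "edu": rows["z_edu"].to_numpy(),
    }
    cols: list[str] = []
    mats: list[np.ndarray] = []
    for term in ("age", "age2", "sex", "edu"):
        if term in terms:
            if term == "age2":
                cols.append("age2")
                mats.append(base["age"] ** 2)
            else:
                cols.append(term)
                mats.append(base[term])
    if "apoe" in terms:
        for d in dummies:
            cols.append(d)
            mats.append(rows[d].to_numpy(float))
    for inter, left in (("age_x_edu", "age"), ("age_x_apoe", "age"), ("edu_x_apoe", "edu")):
        if inter in terms:
            if inter == "age_x_edu":
                cols.append(inter)
                mats.append(base["age"] * base["edu"])
            else:
                for d in dummies:
                    cols.append(f"{left}_x_{d}")
                    mats.append(base[left] * rows[d].to_numpy(float))
    X = np.column_stack(mats) if mats else np.empty((len(rows), 0))

    pid = rows["pid_index"].to_numpy(int)
    n_part = pid.max() + 1 if len(pid) else 0
    singleton = np.bincount(pid, minlength=n_part) == 1
    return Design(
        X=X,
        columns=cols,
        y=rows["y_prime"].to_numpy(),
        pid=pid,
        singleton=singleton,
        terms=terms,
        contrast=analysis_set.contrast,
    )
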