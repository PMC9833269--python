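"""Phenotype preparation: treatment-corrected LDL-C, treatment response, and
coronary-artery-calcium (CAC) categorization.

On-treatment LDL-C is converted to an estimated untreated value by the fixed
multiplicative correction 1.43 whenever a measured pre-treatment (baseline)
value is unavailable; a recorded baseline is always preferred.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .panel import Group

__all__ = [
    "TREATMENT_CORRECTION_FACTOR",
    "SubjectPhenotype",
    "CacCategory",
    "PhenotypeError",
    "adjust_ldl_for_treatment",
    "percent_ldl_reduction",
    "categorize_cac",
    "analysis_ldl",
    "read_phenotypes",
    "write_phenotypes",
    "phenotypes_frame",
    "PHENOTYPE_COLUMNS",
]

# multiplier estimating untreated LDL-C from the on-statin/ezetimibe value
TREATMENT_CORRECTION_FACTOR = 1.43

CAC_HIGH_CUTOFF = 100.0

PHENOTYPE_COLUMNS = [
    "subject_id", "group", "age", "sex", "ldl_mgdl", "on_therapy",
    "ldl_baseline_mgdl", "cac", "mi", "stroke", "revasc", "hypertension", "smoking",
]


class PhenotypeError(ValueError):
    pass


@dataclass
class SubjectPhenotype:
    subject_id: str
    group: Group
    age: float
    sex: str  # "F" or "M"
    ldl_observed: float
    on_lipid_therapy: bool
    ldl_baseline: float | None = None
    cac: float | None = None
    mi: bool | None = None
    stroke: bool | None = None
    revasc: bool | None = None
    hypertension: bool | None = None
    smoking: bool | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise PhenotypeError(f"{self.subject_id}: age must be positive")
        if self.sex not in ("F", "M"):
            raise PhenotypeError(f"{self.subject_id}: sex must be 'F' or 'M'")
        if self.ldl_observed is not None and self.ldl_observed <= 0:
            raise PhenotypeError(f"{self.subject_id}: LDL-C must be positive")
        if self.ldl_baseline is not None and self.ldl_baseline <= 0:
            raise PhenotypeError(f"{self.subject_id}: baseline LDL-C must be positive")
        if self.cac is not None and self.cac < 0:
            raise PhenotypeError(f"{self.subject_id}: CAC score cannot be negative")


class CacCategory(enum.Enum):
    """CAC burden category: 0, 1-99, 100-400, >400 Agatston units."""

    ZERO = "ZERO"
    LOW = "LOW"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"

    @property
    def binary_high(self) -> bool:
        """High-burden flag (>= 100 units): exactly MODERATE or SEVERE."""
        return self in (CacCategory.MODERATE, CacCategory.SEVERE)


def adjust_ldl_for_treatment(ldl_observed: float, on_lipid_therapy: bool) -> float:
    """Estimated untreated LDL-C: observed x 1.43 for treated subjects, else unchanged.

    Used only when no measured baseline is available (see analysis_ldl).
    """
    if ldl_observed < 0:
        raise PhenotypeError(f"LDL-C cannot be negative: {ldl_observed}")
    return ldl_observed * TREATMENT_CORRECTION_FACTOR if on_lipid_therapy else ldl_observed


def percent_ldl_reduction(ldl_baseline: float, ldl_on_treatment: float) -> float:
    """Percent LDL-C reduction from baseline to on-treatment (negative if LDL rose)."""
    if ldl_baseline <= 0:
        raise PhenotypeError(f"baseline LDL-C must be positive: {ldl_baseline}")
    return 100.0 * (ldl_baseline - ldl_on_treatment) / ldl_baseline


def categorize_cac(cac: float) -> CacCategory:
    """Map an Agatston score to its category.

    Boundaries are closed on the MODERATE side (100 <= cac <= 400), so the
    binary high-burden flag (cac >= 100) is exactly MODERATE-or-SEVERE.
    """
    if cac < 0:
        raise PhenotypeError(f"CAC score cannot be negative: {cac}")
    if cac == 0:
        return CacCategory.ZERO
    if cac < CAC_HIGH_CUTOFF:
        return CacCategory.LOW
    if cac <= 400:
        return CacCategory.MODERATE
    return CacCategory.SEVERE


def analysis_ldl(pheno: pd.DataFrame, method: Literal["auto", "factor"] = "auto") -> pd.Series:
    """Per-subject LDL-C for association analyses, in mg/dL.

    auto:   a recorded pre-treatment baseline is used whenever present;
            otherwise treated subjects' observed LDL-C is multiplied by 1.43.
    factor: the multiplicative correction is applied to every treated subject,
            ignoring recorded baselines (exposes the alternative convention).
    """
    if method not in ("auto", "factor"):
        raise PhenotypeError(f"unknown LDL adjustment method {method!r}")
    corrected = np.where(
        pheno["on_therapy"].astype(bool),
        pheno["ldl_mgdl"] * TREATMENT_CORRECTION_FACTOR,
        pheno["ldl_mgdl"],
    )
    if method == "factor":
        values = corrected
    else:
        baseline = pheno["ldl_baseline_mgdl"]
        values = np.where(baseline.notna(), baseline, corrected)
    return pd.Series(values, index=pheno.index, name="ldl_analysis")


# -- phenotype file ----------------------------------------------------------

_BOOL_COLS = ["on_therapy", "mi", "stroke", "revasc", "hypertension", "smoking"]


def phenotypes_frame(phenotypes: Iterable[SubjectPhenotype]) -> pd.DataFrame:
    rows = []
    for p in phenotypes:
        rows.append({
            "subject_id": p.subject_id,
            "group": p.group.value,
            "age": p.age,
            "sex": p.sex,
            "ldl_mgdl": p.ldl_observed,
            "on_therapy": p.on_lipid_therapy,
            "ldl_baseline_mgdl": p.ldl_baseline,
            "cac": p.cac,
            "mi": p.mi,
            "stroke": p.stroke,
            "revasc": p.revasc,
            "hypertension": p.hypertension,
            "smoking": p.smoking,
        })
    frame = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).set_index("subject_id")
    return frame


def write_phenotypes(phenotypes: Iterable[SubjectPhenotype] | pd.DataFrame,
                     path: str | Path) -> Path:
    """Write the tab-separated phenotype table (NA for missing)."""
    frame = (phenotypes if isinstance(phenotypes, pd.DataFrame)
             else phenotypes_frame(phenotypes))
    out = frame.copy()
    for col in _BOOL_COLS:
        out[col] = [("NA" if pd.isna(v) else str(int(bool(v)))) for v in out[col]]
    for col in ("age", "ldl_mgdl", "ldl_baseline_mgdl", "cac"):
        out[col] = [("NA" if pd.isna(v) else f"{float(v):.6g}") for v in out[col]]
    out.to_csv(path, sep="\t", na_rep="NA")
    return Path(path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table; validates groups, sexes and value ranges."""
    path = Path(path)
    if not path.exists():
        raise PhenotypeError(f"phenotype file not found: {path}")
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"subject_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in frame.columns and c != "cac"]
    # cac and event columns may legitimately be absent from minimal tables
    required = ["subject_id", "group", "age", "sex", "ldl_mgdl", "on_therapy"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PhenotypeError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame = frame.set_index("subject_id")
    frame["group"] = [Group.parse(g).value for g in frame["group"]]
    bad_sex = set(frame["sex"]) - {"F", "M"}
    if bad_sex:
        raise PhenotypeError(f"{path}: invalid sex value(s): {sorted(bad_sex)}")
    for col in _BOOL_COLS:
        if col in frame.columns:
            frame[col] = frame[col].map(
                lambda v: v if pd.isna(v) else bool(int(v))
            )
    if (frame["age"] <= 0).any():
        raise PhenotypeError(f"{path}: ages must be positive")
    for col in ("ldl_mgdl", "ldl_baseline_mgdl"):
        if col in frame.columns and (frame[col].dropna() <= 0).any():
            raise PhenotypeError(f"{path}: {col} values must be positive")
    if "cac" in frame.columns and (frame["cac"].dropna() < 0).any():
        raise PhenotypeError(f"{path}: CAC scores cannot be negative")
    return frame
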