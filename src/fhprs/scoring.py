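"""Weighted 12-SNP / 6-SNP score computation and analytic oracles.

A subject's score is the weighted sum of risk-allele dosages over the panel's
directly weighted SNPs plus the weight of the subject's APOE epsilon
diplotype.  Analytic companions give the expected score and (under
Hardy-Weinberg and inter-locus independence) its variance from a group's
published frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genotype_io import CohortGenotypes
from .panel import DIPLOTYPES, Group, ScorePanel

__all__ = [
    "ScoreResult",
    "ScoringError",
    "compute_prs",
    "scores_frame",
    "expected_score",
    "score_variance_hwe",
    "score_bounds",
    "write_score_table",
    "read_score_table",
]

PanelSize = Literal[12, 6, "both"]
MissingPolicy = Literal["fail", "omit", "expected_impute"]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreResult:
    """Per-subject score(s); prs12/prs6 are None when not requested."""

    subject_id: str
    prs12: float | None
    prs6: float | None
    n_missing: int
    apoe_diplotype: str
    missing_policy_applied: str


def _weighted_sum(dosage: pd.DataFrame, panel: ScorePanel, panel_size: int,
                  policy: str, impute_group) -> tuple[np.ndarray, np.ndarray]:
    """Return (score contribution, per-subject missing count) for the SNP part."""
    variants = panel.weighted_variants(panel_size)
    cols = [v.rsid for v in variants]
    weights = np.array([v.weight for v in variants])
    mat = dosage[cols].to_numpy(dtype=float)
    missing = np.isnan(mat)
    n_missing = missing.sum(axis=1)
    if policy == "fail" and missing.any():
        rows, cols_idx = np.where(missing)
        detail = ", ".join(
            f"{dosage.index[r]}:{cols[c]}" for r, c in list(zip(rows, cols_idx))[:10]
        )
        raise ScoringError(
            f"missing genotypes under policy 'fail' for {int(missing.any(axis=1).sum())} "
            f"subject(s) (first entries: {detail})"
        )
    filled = mat.copy()
    if policy == "omit":
        filled[missing] = 0.0
    elif policy == "expected_impute":
        expected = np.array([2.0 * v.risk_allele_frequency(impute_group) for v in variants])
        filled[missing] = np.broadcast_to(expected, mat.shape)[missing]
    return filled @ weights, n_missing


def compute_prs(
    genotypes: CohortGenotypes,
    panel: ScorePanel,
    panel_size: PanelSize = "both",
    missing_policy: MissingPolicy = "fail",
    impute_group: Group | str | None = None,
) -> list[ScoreResult]:
    """Compute per-subject weighted scores.

    missing_policy:
      fail            error on any missing genotype among the included variants
                      (the default: the source analyses use complete data);
      omit            missing terms contribute 0 (n_missing is reported);
      expected_impute missing dosage replaced by 2 x risk-allele frequency of
                      impute_group; an UNKNOWN APOE diplotype is replaced by the
                      group's mean diplotype weight (renormalized frequencies).

    n_missing counts unavailable variants over the widest panel computed, the
    APOE pair counting as one diplotype term.
    """
    if panel_size not in (12, 6, "both"):
        raise ScoringError(f"panel_size must be 12, 6 or 'both', got {panel_size!r}")
    if missing_policy not in ("fail", "omit", "expected_impute"):
        raise ScoringError(f"unknown missing_policy {missing_policy!r}")
    if missing_policy == "expected_impute":
        if impute_group is None:
            raise ScoringError("missing_policy 'expected_impute' requires impute_group")
        impute_group = Group.parse(impute_group)

    parts: dict[int, np.ndarray] = {}
    n_missing_by_size: dict[int, np.ndarray] = {}
    sizes = (12, 6) if panel_size == "both" else (panel_size,)
    for size in sizes:
        snp_part, n_miss = _weighted_sum(
            genotypes.dosage, panel, size, missing_policy, impute_group
        )
        parts[size] = snp_part
        n_missing_by_size[size] = n_miss

    diplos = genotypes.apoe_diplotypes()
    unknown = diplos == "UNKNOWN"
    if missing_policy == "fail" and unknown.any():
        bad = ", ".join(map(str, diplos.index[unknown][:10]))
        raise ScoringError(
            f"APOE diplotype unavailable under policy 'fail' for "
            f"{int(unknown.sum())} subject(s): {bad}"
        )
    apoe_w = np.array([
        0.0 if d == "UNKNOWN" else panel.apoe.weights[d] for d in diplos
    ])
    if missing_policy == "expected_impute" and unknown.any():
        apoe_w[unknown.to_numpy()] = panel.apoe.mean_weight(impute_group, normalized=True)
    for size in sizes:
        parts[size] = parts[size] + apoe_w

    widest = max(sizes)
    n_missing = n_missing_by_size[widest] + unknown.to_numpy().astype(int)
    return [
        ScoreResult(
            subject_id=sid,
            prs12=float(parts[12][i]) if 12 in parts else None,
            prs6=float(parts[6][i]) if 6 in parts else None,
            n_missing=int(n_missing[i]),
            apoe_diplotype=diplos.iloc[i],
            missing_policy_applied=missing_policy,
        )
        for i, sid in enumerate(genotypes.subject_ids)
    ]


def scores_frame(results: Iterable[ScoreResult]) -> pd.DataFrame:
    """Tabulate ScoreResults (index subject_id, columns prs12/prs6/...)."""
    rows = list(results)
    return pd.DataFrame(
        {
            "prs12": [r.prs12 for r in rows],
            "prs6": [r.prs6 for r in rows],
            "apoe_diplotype": [r.apoe_diplotype for r in rows],
            "n_missing": [r.n_missing for r in rows],
        },
        index=pd.Index([r.subject_id for r in rows], name="subject_id"),
    )


# -- analytic oracles --------------------------------------------------------

def expected_score(panel: ScorePanel, group: Group | str, panel_size: int = 12) -> float:
    """Population expected score from the panel's published group frequencies.

    Sum of weight x 2 x risk-allele frequency over the included SNPs, plus the
    frequency-weighted APOE diplotype contribution.  Diplotype frequencies are
    used exactly as published (no renormalization), reproducing the arithmetic
    context of the source frequency tables.
    """
    group = Group.parse(group)
    snp_part = sum(
        v.weight * 2.0 * v.risk_allele_frequency(group)
        for v in panel.weighted_variants(panel_size)
    )
    return snp_part + panel.apoe.mean_weight(group, normalized=False)


def score_variance_hwe(panel: ScorePanel, group: Group | str, panel_size: int = 12) -> float:
    """Score variance under Hardy-Weinberg and inter-locus independence.

    Binomial dosage variance 2f(1-f) per SNP plus the variance of the APOE
    diplotype weight under the group's renormalized diplotype distribution.
    Real cohorts carry linkage disequilibrium this ignores; the quantity is
    the simulator's calibration oracle, not an estimate of any observed SD.
    """
    group = Group.parse(group)
    snp_var = sum(
        v.weight ** 2 * 2.0 * f * (1.0 - f)
        for v in panel.weighted_variants(panel_size)
        for f in (v.risk_allele_frequency(group),)
    )
    freqs = panel.apoe.frequencies(group, normalized=True)
    mean_w = sum(freqs[d] * panel.apoe.weights[d] for d in DIPLOTYPES)
    mean_w2 = sum(freqs[d] * panel.apoe.weights[d] ** 2 for d in DIPLOTYPES)
    return snp_var + (mean_w2 - mean_w ** 2)


def score_bounds(panel: ScorePanel, panel_size: int = 12) -> tuple[float, float]:
    """Attainable [min, max] score over complete genotypes."""
    weights = [v.weight for v in panel.weighted_variants(panel_size)]
    w_lo = min(panel.apoe.weights.values())
    w_hi = max(panel.apoe.weights.values())
    return (sum(2.0 * w for w in weights if w < 0) + w_lo,
            sum(2.0 * w for w in weights if w > 0) + w_hi)


# -- tables ------------------------------------------------------------------

def write_score_table(results: Iterable[ScoreResult], path: str | Path) -> Path:
    """Write the tab-separated score table (scores rounded to 2 decimals)."""
    frame = scores_frame(results)
    out = frame.copy()
    for col in ("prs12", "prs6"):
        out[col] = [("NA" if v is None or (isinstance(v, float) and np.isnan(v))
                     else f"{v:.2f}") for v in frame[col]]
    out.to_csv(path, sep="\t")
    return Path(path)


def read_score_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="subject_id",
                        na_values=["NA"], dtype={"apoe_diplotype": str})
    frame.index = frame.index.astype(str)
    return frame
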