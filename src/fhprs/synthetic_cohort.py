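"""Synthetic cohort generator.

Genotypes are drawn per locus under Hardy-Weinberg equilibrium and linkage
equilibrium from a group's published risk-allele frequencies; the APOE
diplotype is drawn from the group's (renormalized) diplotype frequency vector
and back-converted to the two SNP genotypes.  Baseline LDL-C follows an
additive model on the 12-SNP score; familial-hypercholesterolemia (FH) groups
are ascertained by rejection sampling on the cohort inclusion threshold
(baseline LDL-C >= 210 mg/dL), which is what mechanistically attenuates the
within-FH score/LDL-C association.  A zero-inflated CAC sub-model gives a
mostly-zero calcium score in controls with high-burden (>= 100) odds that
rise with age, male sex and score quartile.

All randomness flows from the config seed; independent sub-streams are
derived as ``default_rng([seed, k])`` with documented stream indices
(0 genotypes, 1 phenotypes).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .association import quantile_labels
from .genotype_io import APOE_ALLELES, CohortGenotypes
from .panel import APOE_RSIDS, DIPLOTYPES, Group, ScorePanel
from .phenotype import SubjectPhenotype, phenotypes_frame, write_phenotypes
from .scoring import compute_prs, expected_score

__all__ = [
    "CohortSimConfig",
    "CacParams",
    "SimulationError",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
]


class SimulationError(RuntimeError):
    pass


# diplotype -> (rs429358 genotype, rs7412 genotype), sorted allele strings
_DIPLOTYPE_TO_GENOTYPES = {
    "E2E2": ("TT", "TT"),
    "E2E3": ("TT", "CT"),
    "E2E4": ("CT", "CT"),
    "E3E3": ("TT", "CC"),
    "E3E4": ("CT", "CC"),
    "E4E4": ("CC", "CC"),
}

_GROUP_DEFAULTS = {
    #                     ldl    therapy  red.   age         female  events (mi, stroke, revasc, htn, smoking)
    Group.CONTROL:   dict(ldl=127.0, tp=0.05,   rm=30.0, age=(50.0, 9.0),  f=0.541,
                          mi=None,   stroke=None,  revasc=None,  htn=0.3209, smk=0.1613),
    Group.FH_M_NEG:  dict(ldl=239.0, tp=0.7145, rm=48.0, age=(56.0, 12.5), f=0.684,
                          mi=0.1527, stroke=0.0428, revasc=0.0509, htn=0.4399, smk=0.1323),
    Group.FH_M_POS:  dict(ldl=277.0, tp=0.8229, rm=48.0, age=(47.0, 16.0), f=0.601,
                          mi=0.2383, stroke=0.0466, revasc=0.0880, htn=0.2850, smk=0.1244),
}

# published cohort sizes, for convenience in drivers/tests
GROUP_N = {Group.CONTROL: 1605, Group.FH_M_NEG: 491, Group.FH_M_POS: 193}


@dataclass(frozen=True)
class CacParams:
    """CAC sub-model parameters.

    High-burden (cac >= 100) probability is logistic in age (per year), male
    sex and the within-cohort 12-SNP score quartile; defaults use the
    published age/sex/intercept estimates with quartile log-odds reaching
    0.55 (OR 1.7) in the top quartile.  Subjects not at high burden are zero
    with a logistic probability calibrated so >= 70% of controls score zero.
    """

    high_intercept: float = -10.77
    high_age_beta: float = 0.13103  # ln 1.14 per year
    high_male_beta: float = 1.79176  # ln 6.00
    quartile_logodds: tuple[float, float, float, float] = (0.0, 0.37, 0.24, 0.55)
    zero_intercept: float = 1.6     # P(zero | not high), logistic
    zero_age_beta: float = 0.04     # per year above 50
    zero_male_beta: float = 0.5
    low_log_mean: float = 3.0       # ln Agatston, positive sub-100 stratum
    low_log_sd: float = 1.0
    high_log_mean: float = 4.5      # ln of the excess above 100
    high_log_sd: float = 1.2
    age_log_slope: float = 0.02     # per year above 50, both strata


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-group generative conditions; defaults are the published cohort
    characteristics (sizes, medians, rates) where stated, and documented
    realistic choices otherwise (see docs/methods.md)."""

    group: Group | str
    n: int
    seed: int
    effect_scale: float = 1.0          # mg/dL of baseline LDL-C per score unit
    ldl_intercept: float | None = None  # mg/dL; per-group default
    residual_sd: float = 40.0          # mg/dL; gives control-group R^2 ~ 0.045
    therapy_prob: float | None = None
    reduction_mean: float | None = None  # percent under therapy
    reduction_sd: float = 15.0
    baseline_recorded_prob: float = 0.46  # treated subjects with a recorded baseline
    fh_ldl_floor: float | None = "default"  # 210 for FH groups, None for control
    age_mean: float | None = None
    age_sd: float | None = None
    female_prob: float | None = None
    cac_params: CacParams = field(default_factory=CacParams)
    max_reject_rounds: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "group", Group.parse(self.group))
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        d = _GROUP_DEFAULTS[self.group]
        if self.ldl_intercept is None:
            object.__setattr__(self, "ldl_intercept", d["ldl"])
        if self.therapy_prob is None:
            object.__setattr__(self, "therapy_prob", d["tp"])
        if self.reduction_mean is None:
            object.__setattr__(self, "reduction_mean", d["rm"])
        if self.age_mean is None:
            object.__setattr__(self, "age_mean", d["age"][0])
        if self.age_sd is None:
            object.__setattr__(self, "age_sd", d["age"][1])
        if self.female_prob is None:
            object.__setattr__(self, "female_prob", d["f"])
        if self.fh_ldl_floor == "default":
            floor = 210.0 if self.group in (Group.FH_M_NEG, Group.FH_M_POS) else None
            object.__setattr__(self, "fh_ldl_floor", floor)
        for p in (self.therapy_prob, self.female_prob, self.baseline_recorded_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")

    def subject_ids(self) -> list[str]:
        tag = {Group.CONTROL: "CTL", Group.FH_M_NEG: "FHN", Group.FH_M_POS: "FHP"}[self.group]
        return [f"{tag}{i:05d}" for i in range(1, self.n + 1)]


def _rng(config: CohortSimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def simulate_genotypes(config: CohortSimConfig, panel: ScorePanel) -> CohortGenotypes:
    """Draw risk-allele dosages Binomial(2, f) per locus and an APOE diplotype
    from the group's renormalized diplotype frequencies (stream 0 of the seed)."""
    rng = _rng(config, 0)
    group = config.group
    n = config.n
    subject_ids = config.subject_ids()

    dosage = pd.DataFrame(index=subject_ids, dtype=float)
    for v in panel.snp_variants:
        f = v.risk_allele_frequency(group)
        dosage[v.rsid] = rng.binomial(2, f, size=n).astype(float)

    freqs = panel.apoe.frequencies(group, normalized=True)
    probs = np.array([freqs[d] for d in DIPLOTYPES])
    draws = rng.choice(len(DIPLOTYPES), size=n, p=probs)
    apoe = pd.DataFrame(index=subject_ids, columns=list(APOE_RSIDS), dtype=object)
    g1 = [_DIPLOTYPE_TO_GENOTYPES[DIPLOTYPES[i]][0] for i in draws]
    g2 = [_DIPLOTYPE_TO_GENOTYPES[DIPLOTYPES[i]][1] for i in draws]
    apoe["rs429358"] = g1
    apoe["rs7412"] = g2
    return CohortGenotypes(subject_ids=subject_ids, dosage=dosage, apoe_genotypes=apoe)


def _truncated_noise(rng, mu: np.ndarray, sd: float, floor: float,
                     max_rounds: int) -> np.ndarray:
    """Rejection-sample Normal(mu, sd) noise so that mu + noise >= floor."""
    noise = rng.normal(0.0, sd, size=mu.size)
    for _ in range(max_rounds):
        bad = (mu + noise) < floor
        if not bad.any():
            return noise
        noise[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
    raise SimulationError(
        f"rejection sampling failed to clear the LDL floor {floor} within "
        f"{max_rounds} rounds; lower fh_ldl_floor or raise ldl_intercept/residual_sd"
    )


def simulate_phenotypes(genotypes: CohortGenotypes, config: CohortSimConfig,
                        panel: ScorePanel) -> list[SubjectPhenotype]:
    """Generate phenotypes for simulated (or real, complete) genotypes
    (stream 1 of the seed).

    Baseline LDL-C = intercept + effect_scale x (prs12 - group expected score)
    + Normal(0, residual_sd), rejection-truncated at the group's inclusion
    floor (210 mg/dL for FH groups; a physiological floor of 30 mg/dL
    otherwise).  Treated subjects' observed LDL-C applies a truncated-normal
    percent reduction.  CAC follows the zero-inflated sub-model in CacParams.
    """
    rng = _rng(config, 1)
    n = genotypes.n_subjects
    if n == 0:
        return []
    group = config.group

    results = compute_prs(genotypes, panel, panel_size=12, missing_policy="fail")
    prs12 = np.array([r.prs12 for r in results])
    mu = config.ldl_intercept + config.effect_scale * (
        prs12 - expected_score(panel, group, 12)
    )
    # positivity guard only: low enough (z < -3) to leave the linear-Normal
    # model essentially undistorted in unascertained groups
    floor = config.fh_ldl_floor if config.fh_ldl_floor is not None else 1.0
    noise = _truncated_noise(rng, mu, config.residual_sd, floor, config.max_reject_rounds)
    baseline = mu + noise

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 20.0, 90.0)
    male = rng.random(n) >= config.female_prob
    treated = rng.random(n) < config.therapy_prob
    reduction = np.zeros(n)
    if treated.any():
        a = (0.0 - config.reduction_mean) / config.reduction_sd
        b = (100.0 - config.reduction_mean) / config.reduction_sd
        reduction[treated] = stats.truncnorm.rvs(
            a, b, loc=config.reduction_mean, scale=config.reduction_sd,
            size=int(treated.sum()), random_state=rng,
        )
    observed = np.where(treated, baseline * (1.0 - reduction / 100.0), baseline)
    observed = np.maximum(observed, 1.0)  # degenerate guard at extreme reductions
    baseline_recorded = treated & (rng.random(n) < config.baseline_recorded_prob)

    # CAC sub-model: high-burden logistic, then zero-inflation among the rest
    p = config.cac_params
    quart = quantile_labels(prs12, 4) if np.unique(prs12).size >= 4 else np.ones(n, int)
    q_lo = np.array(p.quartile_logodds)[quart - 1]
    p_high = expit(p.high_intercept + p.high_age_beta * age
                   + p.high_male_beta * male + q_lo)
    high = rng.random(n) < p_high
    p_zero = expit(p.zero_intercept - p.zero_age_beta * (age - 50.0)
                   - p.zero_male_beta * male)
    zero = ~high & (rng.random(n) < p_zero)
    cac = np.zeros(n)
    low = ~high & ~zero
    if low.any():
        logs = rng.normal(p.low_log_mean + p.age_log_slope * (age[low] - 50.0),
                          p.low_log_sd)
        cac[low] = np.clip(np.round(np.exp(logs)), 1, 99)
    if high.any():
        logs = rng.normal(p.high_log_mean + p.age_log_slope * (age[high] - 50.0),
                          p.high_log_sd)
        cac[high] = 100.0 + np.round(np.exp(logs))

    d = _GROUP_DEFAULTS[group]
    def _events(rate):
        if rate is None:
            return [None] * n
        return [bool(x) for x in rng.random(n) < rate]

    mi, stroke, revasc = _events(d["mi"]), _events(d["stroke"]), _events(d["revasc"])
    htn, smk = _events(d["htn"]), _events(d["smk"])

    phenos = []
    for i, sid in enumerate(genotypes.subject_ids):
        phenos.append(SubjectPhenotype(
            subject_id=sid,
            group=group,
            age=float(age[i]),
            sex="M" if male[i] else "F",
            ldl_observed=float(observed[i]),
            on_lipid_therapy=bool(treated[i]),
            ldl_baseline=float(baseline[i]) if baseline_recorded[i] else None,
            cac=float(cac[i]),
            mi=mi[i], stroke=stroke[i], revasc=revasc[i],
            hypertension=htn[i], smoking=smk[i],
        ))
    return phenos


def simulate_cohort(config: CohortSimConfig, panel: ScorePanel,
                    ) -> tuple[CohortGenotypes, list[SubjectPhenotype]]:
    genotypes = simulate_genotypes(config, panel)
    return genotypes, simulate_phenotypes(genotypes, config, panel)


# -- output ------------------------------------------------------------------

def _vcf_lines(genotypes: CohortGenotypes, panel: ScorePanel) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=fhprs synthetic cohort",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    has_samples = genotypes.n_subjects > 0
    if has_samples:
        cols += ["FORMAT"] + list(genotypes.subject_ids)
    lines.append("\t".join(cols))
    for idx, v in enumerate(panel.variants):
        # positions are synthetic placeholders; matching is by rsID only
        pos = 10000 + idx * 1000
        if v.is_apoe:
            alt, ref = APOE_ALLELES[v.rsid]  # (minor, common) -> ALT, REF
        else:
            ref, alt = v.other_allele, v.risk_allele
        row = ["1", str(pos), v.rsid, ref, alt, ".", "PASS", "."]
        if has_samples:
            row.append("GT")
            for sid in genotypes.subject_ids:
                if v.is_apoe:
                    g = genotypes.apoe_genotypes.at[sid, v.rsid]
                    if g is None or (isinstance(g, float) and np.isnan(g)):
                        row.append("./.")
                    else:
                        n_alt = str(g).count(alt)
                        row.append(["0/0", "0/1", "1/1"][n_alt])
                else:
                    dval = genotypes.dosage.at[sid, v.rsid]
                    row.append("./." if np.isnan(dval) else ["0/0", "0/1", "1/1"][int(dval)])
        lines.append("\t".join(row))
    return lines


def write_cohort(genotypes: CohortGenotypes, phenotypes: Sequence[SubjectPhenotype],
                 out_dir: str | Path, panel: ScorePanel, fmt: str = "vcf",
                 config: CohortSimConfig | None = None) -> dict[str, Path]:
    """Write the cohort as genotype file + phenotype TSV + manifest.

    fmt 'vcf' writes a plain-text VCF (REF = non-risk, ALT = risk allele);
    'dosages' writes the tab-separated dosage matrix.  Outputs are byte-stable
    for a fixed cohort and round-trip losslessly through the readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "vcf":
        gpath = out_dir / "genotypes.vcf"
        gpath.write_text("\n".join(_vcf_lines(genotypes, panel)) + "\n")
    elif fmt == "dosages":
        from .genotype_io import write_dosage_table
        gpath = out_dir / "dosages.tsv"
        write_dosage_table(genotypes, gpath)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    paths["genotypes"] = gpath
    ppath = out_dir / "phenotypes.tsv"
    write_phenotypes(phenotypes_frame(phenotypes), ppath)
    paths["phenotypes"] = ppath

    manifest = {
        "panel_version": panel.panel_version,
        "n_subjects": genotypes.n_subjects,
        "genotype_format": fmt,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths.values()
        },
    }
    if config is not None:
        cfg = asdict(config)
        cfg["group"] = config.group.value
        cfg["cac_params"] = asdict(config.cac_params)
        manifest["config"] = cfg
    mpath = out_dir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = mpath
    return paths
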