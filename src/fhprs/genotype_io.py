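"""Genotype input: VCF / dosage-table readers oriented to risk alleles, and the
APOE epsilon diplotype caller.

Variants are matched by rsID only; positions, genome build and strand are
deliberately ignored (an allele set that matches neither panel orientation is
an error, never silently complemented or flipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import APOE_RSIDS, ScorePanel

__all__ = [
    "CohortGenotypes",
    "GenotypeError",
    "AlleleMismatchError",
    "GenotypeParseError",
    "read_vcf",
    "read_dosage_table",
    "write_dosage_table",
    "call_apoe_diplotype",
    "APOE_ALLELES",
]

log = logging.getLogger(__name__)

# allele sets of the two epsilon-defining SNPs: (minor, common)
APOE_ALLELES = {"rs429358": ("C", "T"), "rs7412": ("T", "C")}

# epsilon haplotypes as (rs429358 allele, rs7412 allele)
_EPS_HAPLOTYPES = {"E2": ("T", "T"), "E3": ("T", "C"), "E4": ("C", "C")}


class GenotypeError(ValueError):
    """Base class for genotype input problems."""


class AlleleMismatchError(GenotypeError):
    """REF/ALT (or a genotype string) matches neither panel allele orientation."""


class GenotypeParseError(GenotypeError):
    """Malformed genotype file content."""


@dataclass
class CohortGenotypes:
    """Risk-allele dosages for a cohort plus raw APOE SNP genotypes.

    dosage: subjects x non-APOE-panel-variants frame; entries 0/1/2 count
    copies of the risk allele, NaN marks missing.  apoe_genotypes: per-subject
    unphased genotype strings ("TC") at rs429358 and rs7412, NaN when missing.
    """

    subject_ids: list[str]
    dosage: pd.DataFrame
    apoe_genotypes: pd.DataFrame

    def __post_init__(self):
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise GenotypeError("duplicate subject ids")
        self.dosage = self.dosage.astype(float)
        vals = self.dosage.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = sorted(set(vals[~ok].tolist()))
            raise GenotypeError(f"dosage entries must be 0/1/2 or missing; found {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def apoe_diplotypes(self) -> pd.Series:
        """Per-subject diplotype calls (E2E2..E4E4 or UNKNOWN)."""
        calls = []
        ambiguous = 0
        for sid in self.subject_ids:
            g1 = self.apoe_genotypes.at[sid, "rs429358"]
            g2 = self.apoe_genotypes.at[sid, "rs7412"]
            if _is_double_het(g1, g2):
                ambiguous += 1
                log.info("subject %s: APOE (CT, CT) is phase-ambiguous; assigned E2E4", sid)
            calls.append(call_apoe_diplotype(g1, g2))
        if ambiguous:
            log.info("%d subject(s) with phase-ambiguous APOE genotypes resolved to E2E4",
                     ambiguous)
        return pd.Series(calls, index=self.subject_ids, name="apoe_diplotype")


def _is_missing(g) -> bool:
    if g is None:
        return True
    if isinstance(g, float) and np.isnan(g):
        return True
    return isinstance(g, str) and g.strip().upper() in ("", "NA", ".", "..", "./.")


def _norm_genotype(g, rsid: str) -> str | None:
    """Normalize an unphased genotype to a sorted 2-char string, or None if missing."""
    if _is_missing(g):
        return None
    if isinstance(g, (tuple, list)):
        g = "".join(str(a) for a in g)
    s = str(g).strip().upper().replace("/", "").replace("|", "")
    if len(s) != 2:
        raise GenotypeError(f"{rsid}: not a diploid genotype: {g!r}")
    alleles = set(APOE_ALLELES[rsid])
    for a in s:
        if a not in alleles:
            raise AlleleMismatchError(
                f"{rsid}: allele {a!r} outside the variant's allele set {sorted(alleles)}"
            )
    return "".join(sorted(s))


def _is_double_het(g1, g2) -> bool:
    try:
        n1, n2 = _norm_genotype(g1, "rs429358"), _norm_genotype(g2, "rs7412")
    except GenotypeError:
        return False
    return n1 == "CT" and n2 == "CT"


def call_apoe_diplotype(g429358, g7412) -> str:
    """Call the APOE epsilon diplotype from the two unphased SNP genotypes.

    Haplotypes: e2 = (rs429358-T, rs7412-T), e3 = (T, C), e4 = (C, C).  The
    doubly heterozygous genotype (CT, CT) is phase-ambiguous between e2/e4 and
    the vanishingly rare e1/e3 and is resolved to E2E4; any combination that
    forces an e1 = (C, T) haplotype returns UNKNOWN, as does any missing input.
    """
    g1 = _norm_genotype(g429358, "rs429358")
    g2 = _norm_genotype(g7412, "rs7412")
    if g1 is None or g2 is None:
        return "UNKNOWN"
    n4 = g1.count("C")  # haplotypes carrying rs429358-C (e4, or e1)
    n2 = g2.count("T")  # haplotypes carrying rs7412-T (e2, or e1)
    n3 = 2 - n4 - n2
    if n3 < 0:
        return "UNKNOWN"  # only consistent with an e1 haplotype
    haps = ["E2"] * n2 + ["E3"] * n3 + ["E4"] * n4
    return haps[0] + haps[1]


# -- VCF ---------------------------------------------------------------------

def read_vcf(path: str | Path, panel: ScorePanel) -> CohortGenotypes:
    """Read risk-allele dosages for panel variants from a VCF (matched by rsID).

    REF/ALT must equal the panel's two alleles in either order: (other, risk)
    counts ALT copies directly, (risk, other) flips the count (2 - ALT copies).
    Panel variants absent from the file are missing for every subject; ./.
    and half-calls are missing for that subject.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on malformed input
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc

    subject_ids = list(vcf.samples)
    n = len(subject_ids)
    snp_rsids = [v.rsid for v in panel.snp_variants]
    dosage = pd.DataFrame(np.nan, index=subject_ids, columns=snp_rsids)
    apoe = pd.DataFrame(np.nan, index=subject_ids, columns=list(APOE_RSIDS), dtype=object)
    seen: set[str] = set()

    for rec in vcf:
        rsid = rec.ID
        if rsid is None or rsid not in panel:
            continue
        if rsid in seen:
            raise GenotypeParseError(f"duplicate VCF record for panel variant {rsid}")
        seen.add(rsid)
        if len(rec.ALT) != 1:
            raise GenotypeParseError(f"{rsid}: panel variants must be biallelic SNVs")
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        variant = panel.variant(rsid)
        if variant.is_apoe:
            minor, common = APOE_ALLELES[rsid]
            if {ref, alt} != {minor, common}:
                raise AlleleMismatchError(
                    f"{rsid}: VCF alleles {ref}/{alt} do not match panel alleles "
                    f"{minor}/{common}"
                )
            by_index = {0: ref, 1: alt}
            for i, gt in enumerate(rec.genotypes or []):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    continue  # missing or half-call
                apoe.iat[i, list(APOE_RSIDS).index(rsid)] = "".join(
                    sorted(by_index[a] + by_index[b])
                )
            continue
        risk, other = variant.risk_allele, variant.other_allele
        if (ref, alt) == (other, risk):
            flip = False
        elif (ref, alt) == (risk, other):
            flip = True
        else:
            raise AlleleMismatchError(
                f"{rsid}: VCF alleles {ref}/{alt} match neither panel orientation "
                f"({other}/{risk} or {risk}/{other}); no strand flipping is attempted"
            )
        col = dosage.columns.get_loc(rsid)
        for i, gt in enumerate(rec.genotypes or []):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            alt_count = int(a > 0) + int(b > 0)
            dosage.iat[i, col] = float(2 - alt_count if flip else alt_count)

    matched = len(seen)
    log.info("VCF %s: %d subjects, %d/%d panel variants matched (%s missing)",
             path.name, n, matched, len(panel.variants),
             ", ".join(sorted(set(panel.rsids) - seen)) or "none")
    return CohortGenotypes(subject_ids=subject_ids, dosage=dosage, apoe_genotypes=apoe)


# -- dosage table -------------------------------------------------------------

def read_dosage_table(path: str | Path, panel: ScorePanel) -> CohortGenotypes:
    """Read a tab-separated dosage matrix: rows subjects, columns rsIDs.

    Non-APOE columns hold risk-allele dosages 0/1/2 or NA; the two APOE columns
    hold genotype strings such as "TC" or NA.  Columns naming no panel variant
    are ignored with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"dosage table not found: {path}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise GenotypeParseError(f"cannot parse dosage table {path}: {exc}") from exc
    if "subject_id" not in raw.columns:
        raise GenotypeParseError(f"{path}: missing required column 'subject_id'")
    raw = raw.set_index("subject_id")
    if raw.index.has_duplicates:
        raise GenotypeError(f"{path}: duplicate subject ids")

    snp_rsids = [v.rsid for v in panel.snp_variants]
    unknown = [c for c in raw.columns if c not in panel.rsids]
    if unknown:
        log.warning("dosage table %s: ignoring %d unknown column(s): %s",
                    path.name, len(unknown), ", ".join(unknown))

    subject_ids = [str(s) for s in raw.index]
    dosage = pd.DataFrame(np.nan, index=subject_ids, columns=snp_rsids)
    for rsid in snp_rsids:
        if rsid not in raw.columns:
            continue
        for sid, cell in raw[rsid].items():
            if _is_missing(cell):
                continue
            cell = str(cell).strip()
            try:
                value = float(cell)
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: {rsid} for subject {sid}: non-numeric dosage {cell!r}"
                ) from None
            if value not in (0.0, 1.0, 2.0):
                raise GenotypeParseError(
                    f"{path}: {rsid} for subject {sid}: dosage must be 0, 1 or 2, got {cell}"
                )
            dosage.at[str(sid), rsid] = value

    apoe = pd.DataFrame(np.nan, index=subject_ids, columns=list(APOE_RSIDS), dtype=object)
    for rsid in APOE_RSIDS:
        if rsid not in raw.columns:
            continue
        for sid, cell in raw[rsid].items():
            g = _norm_genotype(cell, rsid)  # raises on alleles outside the set
            if g is not None:
                apoe.at[str(sid), rsid] = g

    n_missing_cols = sum(1 for r in snp_rsids + list(APOE_RSIDS) if r not in raw.columns)
    log.info("dosage table %s: %d subjects, %d/%d panel variants present",
             path.name, len(subject_ids), 12 - n_missing_cols, 12)
    return CohortGenotypes(subject_ids=subject_ids, dosage=dosage, apoe_genotypes=apoe)


def write_dosage_table(genotypes: CohortGenotypes, path: str | Path) -> Path:
    """Write the tab-separated dosage matrix read_dosage_table accepts (round-trips)."""
    path = Path(path)
    out = pd.DataFrame(index=pd.Index(genotypes.subject_ids, name="subject_id"))
    for col in genotypes.dosage.columns:
        vals = genotypes.dosage[col]
        out[col] = ["NA" if np.isnan(v) else str(int(v)) for v in vals]
    for rsid in APOE_RSIDS:
        out[rsid] = ["NA" if _is_missing(g) else str(g)
                     for g in genotypes.apoe_genotypes[rsid]]
    out.to_csv(path, sep="\t")
    return path
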